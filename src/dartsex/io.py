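"""Readers and writers for DArT-style reports, sex registries and QC.

Input CSVs are UTF-8, comma-separated, with a header row of individual IDs
and the locus ID in the first column.  Optional per-locus metadata columns
``RepAvg``, ``CallRate`` and ``AvgCountRef`` are recognized by name and kept
aside from the call matrix.  On input "-", "–" (en-dash), "NA" and the empty
string are all accepted as the missing code; output always prints "–".
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .matrices import (
    ABSENT,
    HET,
    METADATA_COLUMNS,
    MISSING,
    PRESENT,
    REF_HOM,
    SNP_HOM,
    MatrixValidationError,
    PaMatrix,
    QcThresholds,
    Sex,
    SexRegistry,
    SnpGenotypeMatrix,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"-", "–", "NA", ""}
MISSING_OUT = "–"

_SNP_TOKEN_TO_CODE = {"0": REF_HOM, "1": SNP_HOM, "2": HET}
_SNP_CODE_TO_TOKEN = {REF_HOM: "0", SNP_HOM: "1", HET: "2", MISSING: MISSING_OUT}
_PA_TOKEN_TO_CODE = {"1": PRESENT, "0": ABSENT}
_PA_CODE_TO_TOKEN = {PRESENT: "1", ABSENT: "0", MISSING: MISSING_OUT}


class ReportParseError(ValueError):
    """Raised when a DArT report cell or layout cannot be parsed."""


def _read_raw(path: Union[str, Path]) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a report CSV, splitting off recognized metadata columns."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=0)
    raw.index = raw.index.astype(str)
    meta_cols = [c for c in raw.columns if c in METADATA_COLUMNS]
    meta = None
    if meta_cols:
        meta = raw[meta_cols].apply(pd.to_numeric, errors="coerce")
        meta = meta.rename(columns=METADATA_COLUMNS)
    calls = raw.drop(columns=meta_cols)
    return calls, meta


def _map_cells(
    raw: pd.DataFrame, token_map: dict[str, int], what: str
) -> pd.DataFrame:
    stripped = np.char.strip(raw.to_numpy(dtype=str))
    known = set(token_map) | MISSING_TOKENS
    bad = [t for t in pd.unique(stripped.ravel()) if t not in known]
    if bad:
        i, j = np.argwhere(stripped == bad[0])[0]
        raise ReportParseError(
            f"unparseable {what} cell at locus {raw.index[i]!r}, "
            f"individual {raw.columns[j]!r}: token {bad[0]!r}"
        )
    out = np.full(raw.shape, MISSING, dtype=np.int8)
    for token, code in token_map.items():
        out[stripped == token] = code
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def read_snp_report(
    path: Union[str, Path], dialect: str = "one_row"
) -> SnpGenotypeMatrix:
    """Read a DArT SNP report.

    ``dialect`` must be declared: ``"one_row"`` has one row per locus with
    cells 0/1/2/–; ``"two_row"`` has two rows per locus (reference-allele
    row then SNP-allele row, sharing the locus ID) with 1/0 presence cells,
    collapsed here to the one-row coding: (1,0)→REF_HOM, (0,1)→SNP_HOM,
    (1,1)→HET, (0,0) or missing in either row → MISSING.
    """
    if dialect not in ("one_row", "two_row"):
        raise ValueError(f"unknown SNP report dialect: {dialect!r}")
    raw, meta = _read_raw(path)
    if dialect == "one_row":
        return SnpGenotypeMatrix(_map_cells(raw, _SNP_TOKEN_TO_CODE, "SNP"), meta)

    if raw.shape[0] % 2 != 0:
        raise ReportParseError("two_row report must have an even number of rows")
    pa_like = _map_cells(raw, _PA_TOKEN_TO_CODE, "SNP allele-presence")
    ref_rows = pa_like.iloc[0::2]
    alt_rows = pa_like.iloc[1::2]
    if not np.array_equal(ref_rows.index.to_numpy(), alt_rows.index.to_numpy()):
        raise ReportParseError(
            "two_row report: consecutive row pairs must share a locus ID"
        )
    ref = ref_rows.to_numpy()
    alt = alt_rows.to_numpy()
    out = np.full(ref.shape, MISSING, dtype=np.int8)
    out[(ref == 1) & (alt == 0)] = REF_HOM
    out[(ref == 0) & (alt == 1)] = SNP_HOM
    out[(ref == 1) & (alt == 1)] = HET
    # (0,0) and any missing allele row stay MISSING (double-null)
    calls = pd.DataFrame(out, index=ref_rows.index, columns=pa_like.columns)
    if meta is not None:
        meta = meta.iloc[0::2]
    return SnpGenotypeMatrix(calls, meta)


def read_pa_report(path: Union[str, Path]) -> PaMatrix:
    """Read a silicoDArT presence/absence report (cells 1/0/–)."""
    raw, meta = _read_raw(path)
    return PaMatrix(_map_cells(raw, _PA_TOKEN_TO_CODE, "PA"), meta)


def _write_report(
    matrix, code_to_token: dict[int, str], path: Union[str, Path]
) -> None:
    arr = matrix.values()
    tok = np.empty(arr.shape, dtype=object)
    for code, token in code_to_token.items():
        tok[arr == code] = token
    tokens = pd.DataFrame(tok, index=matrix.calls.index, columns=matrix.calls.columns)
    out = tokens
    if matrix.metadata is not None:
        back = {v: k for k, v in METADATA_COLUMNS.items()}
        meta = matrix.metadata.rename(columns=back)
        out = pd.concat([meta, tokens], axis=1)
    out.index.name = matrix.calls.index.name or "locus"
    out.to_csv(path)


def write_snp_report(matrix: SnpGenotypeMatrix, path: Union[str, Path]) -> None:
    _write_report(matrix, _SNP_CODE_TO_TOKEN, path)


def write_pa_report(matrix: PaMatrix, path: Union[str, Path]) -> None:
    _write_report(matrix, _PA_CODE_TO_TOKEN, path)


_DEFAULT_SEX_TOKENS = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
}


def read_sex_registry(
    path: Union[str, Path], sex_tokens: dict[str, Sex] | None = None
) -> SexRegistry:
    """Read a two-column (id, sex) CSV/TSV registry; delimiter auto-detected.

    Sex tokens default to M/F (case-insensitive, "male"/"female" accepted).
    Duplicate IDs, unknown tokens and empty files are hard errors.
    """
    tokens = {k.lower(): v for k, v in (sex_tokens or _DEFAULT_SEX_TOKENS).items()}
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"empty sex registry file: {path}")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    table = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter,
                        header=None)
    if table.shape[1] < 2:
        raise ValueError("sex registry must have two columns (id, sex)")
    # tolerate a header row such as "id,sex"
    head = [str(table.iloc[0, j]).strip().lower() for j in (0, 1)]
    if head[0] in ("id", "individual", "individual_id") or head[1] == "sex":
        table = table.iloc[1:]
        if table.empty:
            raise ValueError(f"sex registry has no data rows: {path}")
    assignments: dict[str, Sex] = {}
    for _, row in table.iterrows():
        ind = str(row.iloc[0]).strip()
        token = str(row.iloc[1]).strip().lower()
        if ind in assignments:
            raise ValueError(f"duplicate individual ID in sex registry: {ind!r}")
        if token not in tokens:
            raise ValueError(f"unknown sex token for {ind!r}: {row.iloc[1]!r}")
        assignments[ind] = tokens[token]
    registry = SexRegistry(assignments)
    n_m, n_f = registry.counts()
    logger.info("sex registry: %d males, %d females", n_m, n_f)
    return registry


def write_sex_registry(registry: SexRegistry, path: Union[str, Path]) -> None:
    rows = [(i, registry[i].value) for i in registry.individual_ids]
    pd.DataFrame(rows, columns=["id", "sex"]).to_csv(path, index=False)


def qc_filter(matrix, thresholds: QcThresholds):
    """Restrict a matrix to loci meeting all supplied metadata thresholds.

    A threshold whose metadata column is absent is skipped with a warning
    (the deposited DArT data arrives already DArTsoft-filtered, so missing
    metadata is normal).  Original locus order is preserved and per-criterion
    removal counts are logged.
    """
    if matrix.metadata is None:
        meta = pd.DataFrame(index=matrix.calls.index)
    else:
        meta = matrix.metadata
    keep = pd.Series(True, index=matrix.calls.index)
    criteria = [
        ("reproducibility", thresholds.min_reproducibility),
        ("call_rate", thresholds.min_call_rate),
        ("mean_depth", thresholds.min_mean_depth),
    ]
    for column, cutoff in criteria:
        if cutoff <= 0:
            continue
        if column not in meta.columns:
            logger.warning("qc_filter: no %r metadata; criterion skipped", column)
            continue
        passed = meta[column] >= cutoff
        logger.info("qc_filter: %s >= %s removed %d loci",
                    column, cutoff, int((~passed & keep).sum()))
        keep &= passed
    kept = matrix.calls.index[keep]
    if len(kept) == 0:
        logger.warning("qc_filter: no loci meet the thresholds; empty matrix")
    return matrix.subset_loci(list(kept))
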