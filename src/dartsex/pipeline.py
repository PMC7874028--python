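"""End-to-end orchestration: QC → classification → per-criterion statistics
→ spurious-linkage expectation → optional homology annotation → figures.

The bundle written to the output directory is plain TSV/JSON (+PNG
figures): a per-locus classification table, per-criterion distance
matrices and summaries, trend-test and PIC tables, and one ``summary.json``
holding every parameter and count of the run.  Given the same inputs and
parameters the TSV/JSON outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .filtering import (
    DEFAULT_GRID,
    ClassificationResult,
    FilterCriterion,
    as_fraction,
    classify_loci,
)
from .homology import annotate_candidates, classify_subjects, filter_homology_hits
from .matrices import (
    ABSENT,
    PRESENT,
    Hypothesis,
    PaMatrix,
    QcThresholds,
    Sex,
    SexRegistry,
    SnpGenotypeMatrix,
)
from .io import qc_filter
from .plotting import distance_heatmap, locus_index_plot
from .stats import (
    catt_per_locus,
    compare_criterion_groups,
    distance_summary,
    expected_spurious,
    hamming_matrix,
    pic_per_locus,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunParams:
    """Tunable parameters of a pipeline run."""

    grid: tuple = DEFAULT_GRID
    min_called_fraction: Union[float, Fraction] = Fraction(1, 2)
    dispersion_kind: str = "SD"            # "SD" or "SEM" for the ± summaries
    catt_alpha: float = 0.001              # per-locus verification cut-off
    pool_male_homozygotes: bool = True
    qc: Optional[QcThresholds] = None
    make_plots: bool = True

    def as_dict(self) -> dict:
        return {
            "grid": [float(as_fraction(t)) for t in self.grid],
            "min_called_fraction": float(as_fraction(self.min_called_fraction)),
            "dispersion_kind": self.dispersion_kind,
            "catt_alpha": self.catt_alpha,
            "pool_male_homozygotes": self.pool_male_homozygotes,
            "qc": None if self.qc is None else {
                "min_reproducibility": self.qc.min_reproducibility,
                "min_call_rate": self.qc.min_call_rate,
                "min_mean_depth": self.qc.min_mean_depth,
            },
            "version": __version__,
        }


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _clean_nan(obj):
    """Replace NaN with None recursively so the JSON is strictly valid."""
    if isinstance(obj, dict):
        return {k: _clean_nan(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean_nan(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(
    snp: Optional[SnpGenotypeMatrix],
    pa: Optional[PaMatrix],
    registry: SexRegistry,
    outdir: Union[str, Path],
    params: RunParams = RunParams(),
    hits: Optional[pd.DataFrame] = None,
) -> dict:
    """Execute the full analysis and write the report bundle to ``outdir``.

    Returns the summary dictionary that is also written to summary.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if snp is None and pa is None:
        raise ValueError("need at least one marker matrix")

    if params.qc is not None:
        if snp is not None:
            snp = qc_filter(snp, params.qc)
        if pa is not None:
            pa = qc_filter(pa, params.qc)

    n_m, n_f = registry.counts()
    result = classify_loci(
        snp, pa, registry,
        grid=params.grid,
        min_called_fraction=params.min_called_fraction,
        pool_male_homozygotes=params.pool_male_homozygotes,
    )
    _write_tsv(result.table, outdir / "classification.tsv")

    matrices = {}
    if pa is not None:
        matrices["PA"] = pa
    if snp is not None:
        matrices["SNP"] = snp

    summary: dict = {
        "run_params": params.as_dict(),
        "n_males": n_m,
        "n_females": n_f,
        "n_loci": {mt: m.n_loci for mt, m in matrices.items()},
        "selection": result.summary(),
        "criteria": {},
    }

    # per-marker-type locus statistics
    for mt, matrix in matrices.items():
        _write_tsv(catt_per_locus(matrix, registry), outdir / f"catt_{mt}.tsv")
        _write_tsv(pic_per_locus(matrix), outdir / f"pic_{mt}.tsv")

    # per-criterion Hamming / CATT verification
    heterozygosity_groups: dict[str, np.ndarray] = {}
    pa_state_groups: dict[str, dict[str, tuple[int, int]]] = {"M": {}, "F": {}}
    for hyp in Hypothesis:
        for t in result.grid:
            for mt, matrix in matrices.items():
                selected = result.selections[(hyp, mt, t)]
                label = FilterCriterion(hyp, t, mt).label()
                key = f"{hyp.value}_{mt}_{label}"
                entry: dict = {"n_selected": len(selected)}
                if selected:
                    dist = hamming_matrix(matrix, selected)
                    _write_tsv(dist, outdir / f"hamming_{key}.tsv")
                    ds = distance_summary(dist, registry, params.dispersion_kind)
                    entry["distance"] = ds.as_dict()
                    ct = catt_per_locus(matrix, registry, loci=selected)
                    entry["catt_significant"] = int(
                        (ct["p"] < params.catt_alpha).sum()
                    )
                    entry["catt_chi2_range"] = [
                        float(np.nanmin(ct["chi2"])), float(np.nanmax(ct["chi2"]))
                    ]
                    if mt == "PA":
                        sub = matrix.subset_loci(selected)
                        for sex_code, sex in (("M", Sex.MALE), ("F", Sex.FEMALE)):
                            ids = [i for i in sub.individual_ids
                                   if registry[i] is sex]
                            block = sub.calls[ids].to_numpy()
                            pa_state_groups[sex_code][f"{hyp.value}_{label}"] = (
                                int((block == PRESENT).sum()),
                                int((block == ABSENT).sum()),
                            )
                    else:
                        freqs = pic_per_locus(matrix, loci=selected)
                        heterozygosity_groups[f"{hyp.value}_{label}"] = (
                            freqs["pic"].to_numpy()
                        )
                summary["criteria"][key] = entry

    # criterion-group comparisons (only where >= 2 non-empty groups exist)
    summary["group_comparisons"] = {}
    for sex_code, groups in pa_state_groups.items():
        if len(groups) >= 2:
            res = compare_criterion_groups(groups, mode="chi2_pa")
            summary["group_comparisons"][f"chi2_pa_{sex_code}"] = {
                "groups": list(res.group_names),
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "defined": res.defined,
            }
    if len(heterozygosity_groups) >= 2:
        res = compare_criterion_groups(heterozygosity_groups, mode="kruskal_snp")
        summary["group_comparisons"]["kruskal_snp"] = {
            "groups": list(res.group_names),
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "defined": res.defined,
        }

    # spurious perfect-linkage expectation over the full scored panel
    total_loci = sum(m.n_loci for m in matrices.values())
    spurious = expected_spurious(n_m + n_f, total_loci)
    summary["expected_spurious"] = {
        "n": spurious.n,
        "n_loci": spurious.n_loci,
        "p_single": spurious.p_single,
        "expected_count": spurious.expected_count,
        "display": spurious.display(),
    }

    # optional homology annotation of candidate loci
    if hits is not None:
        filtered = filter_homology_hits(hits)
        filtered = classify_subjects(filtered)
        candidates = result.table[
            (result.table["xy_category"] != "UNLINKED")
            | (result.table["zw_category"] != "UNLINKED")
        ]
        report = annotate_candidates(candidates, filtered)
        _write_tsv(report.table, outdir / "annotation.tsv")
        summary["annotation"] = report.summary

    # figures for the widest criterion of each hypothesis
    if params.make_plots and pa is not None:
        t0 = result.grid[0]
        for hyp in Hypothesis:
            selected = result.selections[(hyp, "PA", t0)]
            if not selected:
                continue
            label = FilterCriterion(hyp, t0, "PA").label()
            dist = hamming_matrix(pa, selected)
            distance_heatmap(
                dist, registry, outdir / f"heatmap_{hyp.value}_{label}.png",
                title=f"PA loci, criterion {label} (male:female)",
            )
            locus_index_plot(
                pa, selected, registry,
                outdir / f"locus_index_{hyp.value}_{label}.png",
                title=f"{len(selected)} moderately sex-linked PA loci ({label})",
            )

    summary = _clean_nan(summary)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    logger.info("report bundle written to %s", outdir)
    return summary
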