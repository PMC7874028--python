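"""Core genotype containers for DArT-style marker tables.

Two marker tables come out of a DArTseq run: a co-dominant SNP table in
which every locus × individual cell is one of four codes (reference-allele
homozygote, SNP-allele homozygote, heterozygote, or missing), and a dominant
silicoDArT presence/absence (PA) table whose cells record whether the
restriction fragment was sequenced in that individual at all.  Both are
stored loci-by-individuals (loci as rows), matching the DArT report
orientation, with calls held as small integers in a pandas DataFrame.

Loci are anonymous reduced-representation tags: IDs are opaque strings and
no genomic coordinate system is imposed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# Integer cell codes.  MISSING is shared by both marker types.
MISSING: int = -1

# SNP codes (co-dominant): the string codes of the DArT one-row report.
REF_HOM: int = 0   # "0" reference-allele homozygote
SNP_HOM: int = 1   # "1" SNP-allele homozygote
HET: int = 2       # "2" heterozygote

# PA codes (dominant).
ABSENT: int = 0    # "0" fragment absent
PRESENT: int = 1   # "1" fragment present

SNP_CODES = (REF_HOM, SNP_HOM, HET)
PA_CODES = (ABSENT, PRESENT)

#: metadata column names recognized in DArT reports
METADATA_COLUMNS = {
    "RepAvg": "reproducibility",
    "CallRate": "call_rate",
    "AvgCountRef": "mean_depth",
}


class Sex(enum.Enum):
    MALE = "M"
    FEMALE = "F"


class Hypothesis(enum.Enum):
    """Candidate heterogamety: XY = male heterogametic, ZW = female."""

    XY = "XY"
    ZW = "ZW"

    @property
    def heterogametic_sex(self) -> "Sex":
        return Sex.MALE if self is Hypothesis.XY else Sex.FEMALE

    @property
    def homogametic_sex(self) -> "Sex":
        return Sex.FEMALE if self is Hypothesis.XY else Sex.MALE

    def swapped(self) -> "Hypothesis":
        return Hypothesis.ZW if self is Hypothesis.XY else Hypothesis.XY


class MatrixValidationError(ValueError):
    """Raised when a genotype matrix violates its structural invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate {what} IDs: {dups[:10]}")


@dataclass
class _GenotypeMatrix:
    """Shared implementation of the two marker-table containers.

    Parameters
    ----------
    calls
        Integer DataFrame, index = locus IDs, columns = individual IDs.
        Cells must be drawn from the subclass code set or ``MISSING``.
    metadata
        Optional per-locus DataFrame (same index) with columns such as
        ``reproducibility``, ``call_rate``, ``mean_depth``.  Analysis
        operations never require it; it only feeds QC filtering.
    """

    calls: pd.DataFrame
    metadata: Optional[pd.DataFrame] = None

    _valid_codes: tuple = field(default=(), repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "locus")
        _check_unique(self.calls.columns, "individual")
        values = self.calls.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise MatrixValidationError("calls must be an integer matrix")
        allowed = set(self._valid_codes) | {MISSING}
        observed = set(np.unique(values).tolist())
        bad = observed - allowed
        if bad:
            raise MatrixValidationError(f"invalid cell codes: {sorted(bad)}")
        if self.metadata is not None and not self.metadata.index.equals(self.calls.index):
            raise MatrixValidationError("metadata index must equal the locus index")

    # -- accessors -------------------------------------------------------
    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_loci(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def values(self) -> np.ndarray:
        """Calls as a 2-D int array (loci × individuals)."""
        return self.calls.to_numpy()

    def subset_loci(self, loci: Sequence[str]) -> "_GenotypeMatrix":
        """Restrict to the given loci, preserving their listed order."""
        missing = [l for l in loci if l not in self.calls.index]
        if missing:
            raise KeyError(f"unknown loci: {missing[:10]}")
        meta = self.metadata.loc[list(loci)] if self.metadata is not None else None
        return type(self)(self.calls.loc[list(loci)], meta)

    def missing_fraction(self) -> float:
        return float((self.values() == MISSING).mean())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, type(self)):
            return NotImplemented
        same_calls = self.calls.equals(other.calls)
        if self.metadata is None or other.metadata is None:
            return same_calls and (self.metadata is None) == (other.metadata is None)
        return same_calls and self.metadata.equals(other.metadata)


@dataclass(eq=False)
class SnpGenotypeMatrix(_GenotypeMatrix):
    """Co-dominant SNP calls: REF_HOM / SNP_HOM / HET / MISSING."""

    _valid_codes: tuple = field(default=SNP_CODES, repr=False)

    marker_type = "SNP"


@dataclass(eq=False)
class PaMatrix(_GenotypeMatrix):
    """Dominant presence/absence calls: PRESENT / ABSENT / MISSING."""

    _valid_codes: tuple = field(default=PA_CODES, repr=False)

    marker_type = "PA"


class SexRegistry:
    """Mapping from individual ID to phenotypic sex.

    Every individual in a matrix being analysed must appear exactly once,
    and any filtering run needs at least one individual of each sex.
    """

    def __init__(self, assignments: dict[str, Sex]):
        for ind, sex in assignments.items():
            if not isinstance(sex, Sex):
                raise ValueError(f"invalid sex for {ind!r}: {sex!r}")
        self._assignments = dict(assignments)

    def __len__(self) -> int:
        return len(self._assignments)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._assignments

    def __getitem__(self, individual_id: str) -> Sex:
        return self._assignments[individual_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SexRegistry):
            return NotImplemented
        return self._assignments == other._assignments

    @property
    def individual_ids(self) -> list[str]:
        return list(self._assignments)

    def ids_of(self, sex: Sex) -> list[str]:
        return [i for i, s in self._assignments.items() if s is sex]

    @property
    def males(self) -> list[str]:
        return self.ids_of(Sex.MALE)

    @property
    def females(self) -> list[str]:
        return self.ids_of(Sex.FEMALE)

    def counts(self) -> tuple[int, int]:
        """(n_males, n_females)."""
        return len(self.males), len(self.females)

    def check_covers(self, individual_ids: Sequence[str]) -> None:
        absent = [i for i in individual_ids if i not in self._assignments]
        if absent:
            raise KeyError(
                f"{len(absent)} individual(s) missing from sex registry: {absent[:10]}"
            )

    def swapped(self) -> "SexRegistry":
        """Registry with every male relabelled female and vice versa."""
        flip = {Sex.MALE: Sex.FEMALE, Sex.FEMALE: Sex.MALE}
        return SexRegistry({i: flip[s] for i, s in self._assignments.items()})


@dataclass(frozen=True)
class QcThresholds:
    """Marker-level QC cut-offs applied to DArTsoft per-locus metadata."""

    min_reproducibility: float = 0.0
    min_call_rate: float = 0.0
    min_mean_depth: float = 0.0

    def __post_init__(self) -> None:
        for name in ("min_reproducibility", "min_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.min_mean_depth < 0:
            raise ValueError("min_mean_depth must be >= 0")
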