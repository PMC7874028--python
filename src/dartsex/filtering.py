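"""Graded sex-linkage filtering of SNP and presence/absence loci.

A locus supports an XX/XY system when the diagnostic state is concentrated
in males and (nearly) absent from females; a ZZ/ZW candidate is the mirror
image.  Because occasional X–Y (or Z–W) recombination lets a sex-linked
allele leak into the "wrong" sex, the filters run over a graded threshold
grid — 70%, 80%, 90%, 100% by default.  A locus passing the 100% criterion
is *perfectly* sex-linked; one passing only at 70–90% is *moderately*
sex-linked.

Selection rules at threshold t (all frequencies over CALLED individuals of
the sex, compared as exact rationals, never floats; ≥ is inclusive):

* PA, XY:  freq_present(males) ≥ t  AND  freq_absent(females) ≥ t.
* PA, ZW:  sexes swapped.
* SNP, XY: females  freq_ref_hom ≥ t, freq_snp_hom ≤ 1−t, freq_het ≤ 1−t;
           males    freq_ref_hom ≤ 1−t and freq_het + freq_snp_hom ≥ t
           (the male side pools heterozygotes with SNP-allele homozygotes,
           admitting Y-linked alleles driven to homozygosity by
           recombination; a strict heterozygote-only mode is available).
* SNP, ZW: sexes swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .matrices import (
    ABSENT,
    HET,
    MISSING,
    PRESENT,
    REF_HOM,
    SNP_HOM,
    Hypothesis,
    PaMatrix,
    Sex,
    SexRegistry,
    SnpGenotypeMatrix,
)

#: default threshold grid (ascending)
DEFAULT_GRID: tuple[Fraction, ...] = (
    Fraction(7, 10),
    Fraction(8, 10),
    Fraction(9, 10),
    Fraction(1, 1),
)

PERFECT = "PERFECT"
MODERATE = "MODERATE"
UNLINKED = "UNLINKED"


def as_fraction(t: Union[float, Fraction]) -> Fraction:
    """Canonicalize a threshold: 0.7 (float) means the rational 7/10."""
    if isinstance(t, Fraction):
        return t
    return Fraction(t).limit_denominator(10**6)


def _check_threshold(t: Fraction) -> None:
    if not Fraction(1, 2) < t <= 1:
        raise ValueError(f"threshold must be in (0.5, 1], got {float(t)}")


@dataclass(frozen=True)
class FilterCriterion:
    hypothesis: Hypothesis
    threshold: Fraction
    marker_type: str  # "SNP" | "PA"
    min_called_fraction: Fraction = Fraction(1, 2)
    pool_male_homozygotes: bool = True  # SNP: count SNP_HOM with HET on the het side

    def __post_init__(self) -> None:
        object.__setattr__(self, "threshold", as_fraction(self.threshold))
        object.__setattr__(
            self, "min_called_fraction", as_fraction(self.min_called_fraction)
        )
        _check_threshold(self.threshold)
        if not 0 < self.min_called_fraction <= 1:
            raise ValueError("min_called_fraction must be in (0, 1]")
        if self.marker_type not in ("SNP", "PA"):
            raise ValueError(f"unknown marker_type {self.marker_type!r}")

    def label(self) -> str:
        """Report-style 'male:female' percentage label, e.g. '70:30' for XY."""
        pct = round(float(self.threshold) * 100)
        return (f"{pct}:{100 - pct}" if self.hypothesis is Hypothesis.XY
                else f"{100 - pct}:{pct}")


@dataclass
class SexFrequencyTable:
    """Per-locus per-sex call counts (the exact-arithmetic substrate).

    ``counts`` is indexed by locus with integer columns ``n_called_m`` /
    ``n_called_f`` plus, for PA, ``n_present_{m,f}`` and, for SNP,
    ``n_ref_hom_{m,f}``, ``n_snp_hom_{m,f}``, ``n_het_{m,f}``.  ``n_males``
    and ``n_females`` are the registry totals used for called-fraction
    guards.  Frequencies are derived views; selection always runs on the
    counts.
    """

    marker_type: str
    counts: pd.DataFrame
    n_males: int
    n_females: int

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def flagged(self) -> pd.Series:
        """Loci with zero called individuals in at least one sex."""
        return (self.counts["n_called_m"] == 0) | (self.counts["n_called_f"] == 0)

    def frequencies(self) -> pd.DataFrame:
        """Fractions of called individuals per sex (NaN where none called)."""
        c = self.counts
        out = {}
        for sex in ("m", "f"):
            called = c[f"n_called_{sex}"].to_numpy(dtype=float)
            denom = np.where(called > 0, called, np.nan)
            out[f"n_called_{sex}"] = c[f"n_called_{sex}"]
            if self.marker_type == "PA":
                out[f"freq_present_{sex}"] = c[f"n_present_{sex}"] / denom
                out[f"freq_absent_{sex}"] = (
                    c[f"n_called_{sex}"] - c[f"n_present_{sex}"]
                ) / denom
            else:
                for state in ("ref_hom", "snp_hom", "het"):
                    out[f"freq_{state}_{sex}"] = c[f"n_{state}_{sex}"] / denom
        return pd.DataFrame(out, index=c.index)


def sex_call_frequencies(
    matrix: Union[SnpGenotypeMatrix, PaMatrix], registry: SexRegistry
) -> SexFrequencyTable:
    """Count per-locus calls separately for males and females.

    Frequencies are defined over called (non-missing) individuals of each
    sex; loci with no called individuals in a sex are flagged rather than
    erroring.  Every matrix individual must be in the registry.
    """
    registry.check_covers(matrix.individual_ids)
    cols = pd.Index(matrix.individual_ids)
    male_mask = np.array([registry[i] is Sex.MALE for i in cols])
    values = matrix.values()
    out: dict[str, np.ndarray] = {}
    for sex, mask in (("m", male_mask), ("f", ~male_mask)):
        block = values[:, mask]
        called = block != MISSING
        out[f"n_called_{sex}"] = called.sum(axis=1)
        if matrix.marker_type == "PA":
            out[f"n_present_{sex}"] = (block == PRESENT).sum(axis=1)
        else:
            out[f"n_ref_hom_{sex}"] = (block == REF_HOM).sum(axis=1)
            out[f"n_snp_hom_{sex}"] = (block == SNP_HOM).sum(axis=1)
            out[f"n_het_{sex}"] = (block == HET).sum(axis=1)
    counts = pd.DataFrame(out, index=matrix.calls.index)
    return SexFrequencyTable(
        marker_type=matrix.marker_type,
        counts=counts,
        n_males=int(male_mask.sum()),
        n_females=int((~male_mask).sum()),
    )


def _ge(count: np.ndarray, n: np.ndarray, t: Fraction) -> np.ndarray:
    """count/n >= t on exact integers (False where n == 0)."""
    return (count.astype(np.int64) * t.denominator >= t.numerator * n.astype(np.int64)) & (n > 0)


def _le(count: np.ndarray, n: np.ndarray, t: Fraction) -> np.ndarray:
    """count/n <= t on exact integers (False where n == 0)."""
    return (count.astype(np.int64) * t.denominator <= t.numerator * n.astype(np.int64)) & (n > 0)


def select_sex_linked_loci(
    freq: SexFrequencyTable, criterion: FilterCriterion
) -> list[str]:
    """Loci passing the criterion, in input order.

    Loci whose per-sex called fraction falls below ``min_called_fraction``
    (of all registry individuals of that sex) are excluded before testing.
    """
    if freq.marker_type != criterion.marker_type:
        raise ValueError(
            f"frequency table is {freq.marker_type}, criterion wants "
            f"{criterion.marker_type}"
        )
    t = criterion.threshold
    _check_threshold(t)
    c = freq.counts
    n_m = c["n_called_m"].to_numpy()
    n_f = c["n_called_f"].to_numpy()
    mcf = criterion.min_called_fraction
    totals = np.array([freq.n_males, freq.n_females], dtype=np.int64)
    eligible = (
        _ge(n_m, np.full_like(n_m, totals[0]), mcf)
        & _ge(n_f, np.full_like(n_f, totals[1]), mcf)
    )

    # orient: "het side" = heterogametic sex (carries the diagnostic state)
    if criterion.hypothesis is Hypothesis.XY:
        het, hom = "m", "f"
    else:
        het, hom = "f", "m"
    n_het = c[f"n_called_{het}"].to_numpy()
    n_hom = c[f"n_called_{hom}"].to_numpy()

    if criterion.marker_type == "PA":
        present_het = c[f"n_present_{het}"].to_numpy()
        absent_hom = n_hom - c[f"n_present_{hom}"].to_numpy()
        passed = _ge(present_het, n_het, t) & _ge(absent_hom, n_hom, t)
    else:
        one_minus_t = 1 - t
        ref_hom_side = c[f"n_ref_hom_{hom}"].to_numpy()
        snp_hom_side = c[f"n_snp_hom_{hom}"].to_numpy()
        het_hom_side = c[f"n_het_{hom}"].to_numpy()
        hom_ok = (
            _ge(ref_hom_side, n_hom, t)
            & _le(snp_hom_side, n_hom, one_minus_t)
            & _le(het_hom_side, n_hom, one_minus_t)
        )
        ref_het_side = c[f"n_ref_hom_{het}"].to_numpy()
        if criterion.pool_male_homozygotes:
            carrier = c[f"n_het_{het}"].to_numpy() + c[f"n_snp_hom_{het}"].to_numpy()
        else:
            carrier = c[f"n_het_{het}"].to_numpy()
        het_ok = _le(ref_het_side, n_het, one_minus_t) & _ge(carrier, n_het, t)
        passed = hom_ok & het_ok

    keep = eligible & passed
    return [l for l, k in zip(c.index, keep) if k]


@dataclass
class ClassificationResult:
    """Per-locus classification plus the raw per-criterion selections."""

    table: pd.DataFrame
    selections: dict[tuple[Hypothesis, str, Fraction], list[str]]
    grid: tuple[Fraction, ...]
    n_loci: dict[str, int] = field(default_factory=dict)

    def selected(
        self, hypothesis: Hypothesis, marker_type: str, t: Union[float, Fraction]
    ) -> list[str]:
        return self.selections[(hypothesis, marker_type, as_fraction(t))]

    def summary(self) -> dict:
        """Counts per hypothesis × threshold × marker type, shaped like the
        classic two-table (ZZ/ZW, XX/XY) report layout."""
        out: dict = {}
        for hyp in Hypothesis:
            rows = {}
            for t in self.grid:
                crit_label = FilterCriterion(hyp, t, "PA").label()
                rows[crit_label] = {
                    mt: {
                        "total_loci": self.n_loci.get(mt, 0),
                        "selected": len(self.selections[(hyp, mt, t)]),
                    }
                    for mt in ("PA", "SNP")
                }
            out[hyp.value] = rows
        return out


def _categorize(best: Optional[Fraction]) -> str:
    if best is None:
        return UNLINKED
    return PERFECT if best == 1 else MODERATE


def classify_loci(
    snp: Optional[SnpGenotypeMatrix],
    pa: Optional[PaMatrix],
    registry: SexRegistry,
    grid: Sequence[Union[float, Fraction]] = DEFAULT_GRID,
    min_called_fraction: Union[float, Fraction] = Fraction(1, 2),
    pool_male_homozygotes: bool = True,
) -> ClassificationResult:
    """Run both hypotheses over the threshold grid and classify every locus.

    The grid must be ascending, all in (0.5, 1].  For each locus and
    hypothesis the highest threshold passed is recorded; a locus passing
    t = 1.00 is PERFECT, one passing only lower thresholds MODERATE, the
    rest UNLINKED.  A locus may be classified under both hypotheses
    independently.
    """
    grid = tuple(as_fraction(t) for t in grid)
    if list(grid) != sorted(grid) or len(set(grid)) != len(grid):
        raise ValueError("threshold grid must be strictly ascending")
    for t in grid:
        _check_threshold(t)
    mcf = as_fraction(min_called_fraction)

    matrices = [(m.marker_type, m) for m in (snp, pa) if m is not None]
    if not matrices:
        raise ValueError("at least one of snp/pa must be given")

    selections: dict[tuple[Hypothesis, str, Fraction], list[str]] = {}
    rows = []
    n_loci: dict[str, int] = {}
    for marker_type, matrix in matrices:
        n_loci[marker_type] = matrix.n_loci
        freq = sex_call_frequencies(matrix, registry)
        best: dict[Hypothesis, dict[str, Fraction]] = {h: {} for h in Hypothesis}
        for hyp in Hypothesis:
            for t in grid:
                crit = FilterCriterion(
                    hyp, t, marker_type, mcf,
                    pool_male_homozygotes=pool_male_homozygotes,
                )
                sel = select_sex_linked_loci(freq, crit)
                selections[(hyp, marker_type, t)] = sel
                for locus in sel:
                    best[hyp][locus] = t  # grid ascending: last pass is highest
        for locus in matrix.locus_ids:
            bx = best[Hypothesis.XY].get(locus)
            bz = best[Hypothesis.ZW].get(locus)
            rows.append(
                {
                    "locus_id": locus,
                    "marker_type": marker_type,
                    "xy_best_t": float(bx) if bx is not None else np.nan,
                    "xy_category": _categorize(bx),
                    "zw_best_t": float(bz) if bz is not None else np.nan,
                    "zw_category": _categorize(bz),
                }
            )
    # missing marker types still get (empty) selection entries
    for marker_type in ("PA", "SNP"):
        for hyp in Hypothesis:
            for t in grid:
                selections.setdefault((hyp, marker_type, t), [])
    table = pd.DataFrame(rows).set_index("locus_id")
    return ClassificationResult(table=table, selections=selections,
                                grid=grid, n_loci=n_loci)
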