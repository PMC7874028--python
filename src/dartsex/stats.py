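"""Quantitative support for sex-linkage candidates.

Pairwise genotype Hamming distances with within/between-sex summaries, the
Cochran–Armitage trend test (CATT) that verifies per-locus association with
phenotypic sex, polymorphism information content (PIC), the closed-form
expectation for spurious perfect sex-linkage under a finite sample, and the
between-criterion group comparisons (Pearson chi-square for PA,
Kruskal–Wallis with Nemenyi post-hoc for SNP heterozygosity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrices import (
    ABSENT,
    HET,
    MISSING,
    PRESENT,
    REF_HOM,
    SNP_HOM,
    PaMatrix,
    Sex,
    SexRegistry,
    SnpGenotypeMatrix,
)

#: default CATT column weights by marker type
CATT_WEIGHTS = {
    "SNP": (0.0, 1.0, 2.0),  # REF_HOM, HET, SNP_HOM copies of the SNP allele
    "PA": (0.0, 1.0),        # ABSENT, PRESENT
}

#: SNP state order used when tabulating CATT counts (matches weights above)
SNP_CATT_STATES = (REF_HOM, HET, SNP_HOM)
PA_CATT_STATES = (ABSENT, PRESENT)


# ---------------------------------------------------------------------------
# Hamming distances
# ---------------------------------------------------------------------------

def hamming_matrix(
    matrix: Union[SnpGenotypeMatrix, PaMatrix],
    loci: Optional[Sequence[str]] = None,
    missing_as_mismatch: bool = False,
) -> pd.DataFrame:
    """Pairwise proportional Hamming distance between individuals.

    Entry (a, b) is the fraction of loci, among those called in both a and
    b (pairwise deletion), at which the two individuals carry different
    codes.  With ``missing_as_mismatch`` the denominator becomes all
    selected loci and a missing call in exactly one individual counts as a
    difference.  Pairs sharing no called locus are undefined (NaN) under
    pairwise deletion.
    """
    if loci is not None:
        if len(loci) == 0:
            raise ValueError("empty locus set")
        matrix = matrix.subset_loci(loci)
    elif matrix.n_loci == 0:
        raise ValueError("empty locus set")
    X = matrix.values()
    n = matrix.n_individuals
    called = X != MISSING
    diff = np.zeros((n, n))
    shared = np.zeros((n, n))
    # chunk over loci to bound the L×N×N intermediates
    for start in range(0, X.shape[0], 2048):
        blk = X[start : start + 2048]
        cblk = called[start : start + 2048]
        both = cblk[:, :, None] & cblk[:, None, :]
        ne = blk[:, :, None] != blk[:, None, :]
        if missing_as_mismatch:
            # a call vs a missing counts as a difference; both-missing matches
            diff += (ne & (cblk[:, :, None] | cblk[:, None, :])).sum(axis=0)
            shared += blk.shape[0]
        else:
            diff += (ne & both).sum(axis=0)
            shared += both.sum(axis=0)
    with np.errstate(invalid="ignore"):
        d = np.where(shared > 0, diff / np.maximum(shared, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.individual_ids, columns=matrix.individual_ids)


@dataclass
class DistanceSummary:
    """Within/between-sex strata of a pairwise distance matrix.

    ``dispersion_kind`` records whether the ± values are the standard
    deviation over pairs (default) or the standard error of the mean.
    Strata with zero pairs are NaN and listed in ``undefined_strata``.
    """

    mean_within_male: float
    mean_within_female: float
    mean_between: float
    dispersion_within_male: float
    dispersion_within_female: float
    dispersion_between: float
    dispersion_kind: str
    n_pairs_within_male: int
    n_pairs_within_female: int
    n_pairs_between: int
    undefined_strata: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__
                if k != "undefined_strata"} | {
                    "undefined_strata": list(self.undefined_strata)}


def _stratum(values: np.ndarray, kind: str) -> tuple[float, float]:
    if values.size == 0:
        return (math.nan, math.nan)
    mean = float(np.mean(values))
    if values.size == 1:
        return (mean, 0.0)
    sd = float(np.std(values, ddof=1))
    return (mean, sd if kind == "SD" else sd / math.sqrt(values.size))


def distance_summary(
    dist: pd.DataFrame, registry: SexRegistry, dispersion_kind: str = "SD"
) -> DistanceSummary:
    """Mean ± dispersion of distances within males, within females, and
    between the sexes (unordered pairs, diagonal excluded)."""
    if dispersion_kind not in ("SD", "SEM"):
        raise ValueError("dispersion_kind must be 'SD' or 'SEM'")
    individuals = list(dist.index)
    registry.check_covers(individuals)
    males = [i for i in individuals if registry[i] is Sex.MALE]
    females = [i for i in individuals if registry[i] is Sex.FEMALE]
    d = dist.to_numpy()
    pos = {ind: k for k, ind in enumerate(individuals)}

    def pairs(ids_a, ids_b=None):
        if ids_b is None:
            idx = [(pos[a], pos[b]) for a, b in combinations(ids_a, 2)]
        else:
            idx = [(pos[a], pos[b]) for a in ids_a for b in ids_b]
        return np.array([d[i, j] for i, j in idx]) if idx else np.array([])

    wm = pairs(males)
    wf = pairs(females)
    bt = pairs(males, females)
    mean_wm, disp_wm = _stratum(wm, dispersion_kind)
    mean_wf, disp_wf = _stratum(wf, dispersion_kind)
    mean_bt, disp_bt = _stratum(bt, dispersion_kind)
    undefined = tuple(
        name
        for name, arr in (("within_male", wm), ("within_female", wf), ("between", bt))
        if arr.size == 0
    )
    return DistanceSummary(
        mean_within_male=mean_wm,
        mean_within_female=mean_wf,
        mean_between=mean_bt,
        dispersion_within_male=disp_wm,
        dispersion_within_female=disp_wf,
        dispersion_between=disp_bt,
        dispersion_kind=dispersion_kind,
        n_pairs_within_male=wm.size,
        n_pairs_within_female=wf.size,
        n_pairs_between=bt.size,
        undefined_strata=undefined,
    )


# ---------------------------------------------------------------------------
# Cochran–Armitage trend test
# ---------------------------------------------------------------------------

@dataclass
class TrendTestResult:
    chi2: float          # NaN when the statistic is undefined
    p_value: float       # NaN when undefined
    weights: tuple[float, ...]
    defined: bool
    locus_id: Optional[str] = None


def catt(
    counts: Union[np.ndarray, Sequence[Sequence[float]]],
    weights: Optional[Sequence[float]] = None,
) -> TrendTestResult:
    """Cochran–Armitage trend test on a 2 × k table of per-sex state counts.

    With row-1 cell counts n1k, column totals nk, row-1 total N1, grand
    total N and weights w:

        chi2 = N (N Σ w n1k − N1 Σ w nk)²
               / [ N1 (N − N1) (N Σ w² nk − (Σ w nk)²) ],  df = 1

    p is the upper tail of chi-square with 1 df.  When every individual
    falls in one weighted column the variance term vanishes and the
    statistic is undefined (flagged, not raised).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("counts must be a 2 × k table with k >= 2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if weights is None:
        weights = tuple(float(i) for i in range(table.shape[1]))
    w = np.asarray(weights, dtype=float)
    if w.shape != (table.shape[1],):
        raise ValueError("weights length must match the number of columns")
    n1k = table[0]
    nk = table.sum(axis=0)
    N1 = n1k.sum()
    N = table.sum()
    if N1 == 0 or N1 == N:
        raise ValueError("both rows must have positive totals")
    s_w_n1 = float(w @ n1k)
    s_w_n = float(w @ nk)
    s_w2_n = float((w**2) @ nk)
    var_term = N * s_w2_n - s_w_n**2
    if var_term <= 0:
        return TrendTestResult(math.nan, math.nan, tuple(w), defined=False)
    chi2 = N * (N * s_w_n1 - N1 * s_w_n) ** 2 / (N1 * (N - N1) * var_term)
    p = float(sps.chi2.sf(chi2, df=1))
    return TrendTestResult(float(chi2), p, tuple(w), defined=True)


def catt_per_locus(
    matrix: Union[SnpGenotypeMatrix, PaMatrix],
    registry: SexRegistry,
    loci: Optional[Sequence[str]] = None,
    weights: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """CATT of every locus against phenotypic sex (males = row 1).

    MISSING calls are excluded from the counts.  Returns a DataFrame with
    columns chi2, p, n_called_m, n_called_f, indexed by locus.
    """
    if loci is not None:
        matrix = matrix.subset_loci(loci)
    registry.check_covers(matrix.individual_ids)
    states = PA_CATT_STATES if matrix.marker_type == "PA" else SNP_CATT_STATES
    if weights is None:
        weights = CATT_WEIGHTS[matrix.marker_type]
    male_mask = np.array([registry[i] is Sex.MALE for i in matrix.individual_ids])
    X = matrix.values()
    rows = []
    for i, locus in enumerate(matrix.locus_ids):
        m_counts = [int((X[i, male_mask] == s).sum()) for s in states]
        f_counts = [int((X[i, ~male_mask] == s).sum()) for s in states]
        n_m, n_f = sum(m_counts), sum(f_counts)
        if n_m == 0 or n_f == 0:
            rows.append((locus, math.nan, math.nan, n_m, n_f))
            continue
        res = catt([m_counts, f_counts], weights)
        rows.append((locus, res.chi2, res.p_value, n_m, n_f))
    return pd.DataFrame(
        rows, columns=["locus_id", "chi2", "p", "n_called_m", "n_called_f"]
    ).set_index("locus_id")


# ---------------------------------------------------------------------------
# PIC and the spurious-linkage expectation
# ---------------------------------------------------------------------------

def pic(p: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Two-allele polymorphism information content, 2p(1−p).

    Ranges from 0 (fixation of one allele) to 0.5 (both alleles equally
    frequent), the expected heterozygosity of a biallelic locus.
    """
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("allele frequency must be in [0, 1]")
    out = 2.0 * arr * (1.0 - arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def pic_per_locus(
    matrix: Union[SnpGenotypeMatrix, PaMatrix],
    loci: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-locus PIC with the underlying two-state frequency.

    SNP loci: allele frequency by gene counting over called genotypes
    (each SNP_HOM contributes two SNP alleles, each HET one).  PA loci: the
    presence frequency over called individuals.
    """
    if loci is not None:
        matrix = matrix.subset_loci(loci)
    X = matrix.values()
    called = (X != MISSING).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if matrix.marker_type == "PA":
            p = (X == PRESENT).sum(axis=1) / called
        else:
            snp_alleles = 2 * (X == SNP_HOM).sum(axis=1) + (X == HET).sum(axis=1)
            p = snp_alleles / (2 * called)
    p = np.where(called > 0, p, np.nan)
    values = 2.0 * p * (1.0 - p)
    return pd.DataFrame(
        {"p": p, "pic": values}, index=matrix.calls.index
    )


@dataclass
class SpuriousEstimate:
    """Expected number of loci perfectly sex-linked by chance alone.

    With n sexed individuals the probability that one locus shows a perfect
    sex pattern by chance is P_i = 0.5^n; multiplying by the number of
    scored loci gives the genome-wide expectation.
    """

    n: int
    n_loci: int
    p_single: float
    expected_count: float

    def display(self) -> dict[str, str]:
        """P_i to 3 significant figures, expected count to 2 (the
        conventional reporting precision)."""
        return {
            "p_single": _sig(self.p_single, 3),
            "expected_count": _sig(self.expected_count, 2),
        }


def _sig(x: float, figures: int) -> str:
    if x == 0:
        return "0"
    return f"{x:.{figures - 1}e}"


def expected_spurious(n: int, n_loci: int) -> SpuriousEstimate:
    """Spurious perfect sex-linkage expectation: P_i = 0.5^n, scaled by the
    locus count."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    p_single = 0.5**n
    return SpuriousEstimate(
        n=n, n_loci=n_loci, p_single=p_single, expected_count=p_single * n_loci
    )


# ---------------------------------------------------------------------------
# Between-criterion group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    mode: str
    statistic: float
    df: float
    p_value: float
    defined: bool
    group_names: tuple[str, ...]
    posthoc: Optional[pd.DataFrame] = None
    note: str = ""


def _nemenyi(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Nemenyi test on joint ranks (studentized-range p-values)."""
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(values)
    sizes = [len(groups[g]) for g in names]
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = [r.mean() for r in np.split(ranks, splits)]
    n_total = len(values)
    k = len(names)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(
                n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * math.sqrt(2.0)
            p[i, j] = p[j, i] = float(sps.studentized_range.sf(q, k, np.inf))
    return pd.DataFrame(p, index=names, columns=names)


def compare_criterion_groups(
    groups: dict[str, Union[tuple[int, int], Sequence[float], np.ndarray]],
    mode: str,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Test whether loci selected under different criteria differ.

    ``chi2_pa``: each group is a (n_present, n_absent) count pair pooled
    over the loci selected at one threshold; Pearson chi-square on the
    groups × 2 table.  ``kruskal_snp``: each group is a vector of per-locus
    heterozygosities; Kruskal–Wallis omnibus with an all-pairs Nemenyi
    post-hoc when the omnibus rejects at ``alpha``.  A group with no loci
    makes the comparison undefined (flagged, mirroring empty selection
    sets) rather than an exception.
    """
    if mode not in ("chi2_pa", "kruskal_snp"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = tuple(groups)

    if mode == "chi2_pa":
        table = np.asarray([list(groups[g]) for g in names], dtype=float)
        if table.shape[1] != 2:
            raise ValueError("chi2_pa groups must be (n_present, n_absent) pairs")
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            return GroupComparisonResult(
                mode, math.nan, math.nan, math.nan, False, names,
                note="a group or state has zero total; chi-square undefined",
            )
        chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
        return GroupComparisonResult(mode, float(chi2), float(df), float(p),
                                     True, names)

    vectors = {g: np.asarray(groups[g], dtype=float) for g in names}
    if any(v.size == 0 for v in vectors.values()):
        return GroupComparisonResult(
            mode, math.nan, math.nan, math.nan, False, names,
            note="a group has no loci; Kruskal-Wallis undefined",
        )
    pooled = np.concatenate(list(vectors.values()))
    if np.ptp(pooled) == 0:
        # all observations identical: H = 0 by definition, p = 1
        return GroupComparisonResult(mode, 0.0, float(len(names) - 1), 1.0,
                                     True, names)
    h, p = sps.kruskal(*vectors.values())
    posthoc = _nemenyi(vectors) if p < alpha else None
    return GroupComparisonResult(mode, float(h), float(len(names) - 1),
                                 float(p), True, names, posthoc=posthoc)
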