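"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions alone — plain Python
loops, exact Fractions, direct enumeration — and deliberately shares no
code with the package's vectorized paths.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

MISSING = -1


def brute_select(
    calls: np.ndarray,
    locus_ids: list[str],
    sexes: list[str],           # "M"/"F" per column
    marker_type: str,           # "PA" | "SNP"
    hypothesis: str,            # "XY" | "ZW"
    t: Fraction,
    min_called_fraction: Fraction = Fraction(1, 2),
) -> list[str]:
    """Direct per-locus count enumeration of the selection rules."""
    n_m_total = sexes.count("M")
    n_f_total = sexes.count("F")
    het_sex, hom_sex = ("M", "F") if hypothesis == "XY" else ("F", "M")
    out = []
    for i, locus in enumerate(locus_ids):
        by_sex = {"M": [], "F": []}
        for j, sex in enumerate(sexes):
            if calls[i, j] != MISSING:
                by_sex[sex].append(int(calls[i, j]))
        n_m, n_f = len(by_sex["M"]), len(by_sex["F"])
        if n_m == 0 or n_f == 0:
            continue
        if Fraction(n_m, n_m_total) < min_called_fraction:
            continue
        if Fraction(n_f, n_f_total) < min_called_fraction:
            continue
        het_calls = by_sex[het_sex]
        hom_calls = by_sex[hom_sex]
        if marker_type == "PA":
            present_het = Fraction(sum(1 for c in het_calls if c == 1), len(het_calls))
            absent_hom = Fraction(sum(1 for c in hom_calls if c == 0), len(hom_calls))
            if present_het >= t and absent_hom >= t:
                out.append(locus)
        else:
            nh = len(hom_calls)
            ref_hom = Fraction(sum(1 for c in hom_calls if c == 0), nh)
            snp_hom = Fraction(sum(1 for c in hom_calls if c == 1), nh)
            het_hom = Fraction(sum(1 for c in hom_calls if c == 2), nh)
            nt = len(het_calls)
            ref_het = Fraction(sum(1 for c in het_calls if c == 0), nt)
            carrier = Fraction(sum(1 for c in het_calls if c in (1, 2)), nt)
            if (
                ref_hom >= t
                and snp_hom <= 1 - t
                and het_hom <= 1 - t
                and ref_het <= 1 - t
                and carrier >= t
            ):
                out.append(locus)
    return out


def brute_hamming(calls: np.ndarray) -> np.ndarray:
    """Pairwise-deletion Hamming distances by explicit double loop."""
    n = calls.shape[1]
    d = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(n):
            if a == b:
                d[a, b] = 0.0
                continue
            shared = diff = 0
            for i in range(calls.shape[0]):
                if calls[i, a] != MISSING and calls[i, b] != MISSING:
                    shared += 1
                    if calls[i, a] != calls[i, b]:
                        diff += 1
            if shared:
                d[a, b] = diff / shared
    return d


def pearson_chi2(table: np.ndarray) -> float:
    """Textbook Pearson chi-square from observed/expected cell sums."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def catt_chi2_direct(table: np.ndarray, weights) -> float:
    """CATT as N·r² — the squared Pearson correlation between group
    membership and the weighted state, over expanded individuals."""
    table = np.asarray(table, dtype=float)
    ys, ws = [], []
    for r in range(2):
        for k, w in enumerate(weights):
            count = int(table[r, k])
            ys.extend([1 - r] * count)
            ws.extend([w] * count)
    y = np.asarray(ys, dtype=float)
    w = np.asarray(ws, dtype=float)
    r = np.corrcoef(y, w)[0, 1]
    return float(len(y) * r**2)


def permutation_catt_p(
    table: np.ndarray, weights, n_perm: int, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Monte-Carlo permutation p-value bracket for the CATT statistic.

    Permuting group labels with the table margins fixed makes the row-1
    cell counts multivariate-hypergeometric.  Because the permutation null
    is a lattice distribution, the permutation p is only defined up to tie
    inclusion at the observed statistic; the returned tuple is
    (p_strictly_greater, p_greater_or_equal, sigma_mc) and a continuous
    approximation should fall inside that bracket up to Monte-Carlo noise.
    """
    table = np.asarray(table, dtype=float)
    w = np.asarray(weights, dtype=float)
    nk = table.sum(axis=0).astype(int)
    N1 = int(table[0].sum())
    N = int(table.sum())

    def chi2_of(n1k: np.ndarray) -> np.ndarray:
        s_w_n1 = n1k @ w
        s_w_n = float(nk @ w)
        s_w2_n = float(nk @ (w**2))
        var = N * s_w2_n - s_w_n**2
        return N * (N * s_w_n1 - N1 * s_w_n) ** 2 / (N1 * (N - N1) * var)

    observed = chi2_of(table[0])
    draws = rng.multivariate_hypergeometric(nk, N1, size=n_perm).astype(float)
    perm = chi2_of(draws)
    p_gt = float(np.mean(perm > observed + 1e-9))
    p_geq = float(np.mean(perm >= observed - 1e-9))
    sigma = float(np.sqrt(0.25 / n_perm))  # conservative binomial bound
    return p_gt, p_geq, sigma
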