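"""Synthetic DArT-style datasets with planted sex-linked structure.

The generator emulates a reduced-representation genotyping study of 15
phenotypically sexed males and 15 females in which XY-linked (male-specific
fragment) and ZW-linked (female-specific fragment) presence/absence loci
co-exist in the same individuals, on top of an autosomal background, so
that every downstream filtering and statistics stage can be exercised
without any external data download.

Generative model, per locus and individual, before missingness:

* XY-linked PA — males carry the fragment (PRESENT) with probability
  ``1 − leakage``, females with probability ``leakage``; the leakage
  parameter models occasional X–Y recombination moving the fragment onto
  the X.  ZW-linked PA is the mirror image with the sexes swapped.
* Autosomal PA — PRESENT with a per-locus frequency drawn uniformly in
  [0.2, 0.8], identical in both sexes.
* XY-linked SNP — males heterozygous with probability ``1 − leakage``
  (else reference homozygote); females reference homozygote with
  probability ``1 − leakage`` (else heterozygous).  ZW-linked SNP mirrors.
* Autosomal SNP — Hardy–Weinberg genotype draws at a per-locus minor
  allele frequency drawn uniformly from ``autosomal_maf_range``.

Missingness is applied last: every cell independently becomes MISSING with
probability ``missing_rate``.  All randomness comes from one seeded
generator consumed in a fixed, documented order (see ``simulate_dataset``),
so identical configs yield bit-identical outputs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

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

PA_AUTOSOMAL_FREQ_RANGE = (0.2, 0.8)


class LocusClass(enum.Enum):
    AUTOSOMAL = "AUTOSOMAL"
    XY_LINKED = "XY_LINKED"
    ZW_LINKED = "ZW_LINKED"


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 15 + 15 sexed individuals, a 5,000-locus
    autosomal PA background with 50 XY- and 50 ZW-linked PA loci planted in
    the same individuals, 10% leakage and 5% missing calls.  SNP sex-linked
    counts default to zero, mirroring a study in which the sex signal is
    carried by fragment presence/absence only; planted SNP loci are
    available to exercise the SNP criteria."""

    n_males: int = 15
    n_females: int = 15
    n_autosomal_pa: int = 5000
    n_xy_pa: int = 50
    n_zw_pa: int = 50
    n_autosomal_snp: int = 2000
    n_xy_snp: int = 0
    n_zw_snp: int = 0
    leakage: float = 0.1
    missing_rate: float = 0.05
    autosomal_maf_range: tuple[float, float] = (0.4, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one individual of each sex")
        for name in ("n_autosomal_pa", "n_xy_pa", "n_zw_pa",
                     "n_autosomal_snp", "n_xy_snp", "n_zw_snp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("leakage", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        lo, hi = self.autosomal_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("autosomal_maf_range must lie in (0, 0.5]")


@dataclass
class SimTruth:
    """Planted class labels (covering exactly the generated loci) plus the
    config that produced them."""

    classes: dict[str, LocusClass]
    config: SimConfig

    def loci_of(self, locus_class: LocusClass) -> list[str]:
        return [l for l, c in self.classes.items() if c is locus_class]


def _locus_ids(prefix: str, classes: list[LocusClass]) -> tuple[list[str], dict]:
    ids = [f"{prefix}{i + 1:06d}" for i in range(len(classes))]
    return ids, dict(zip(ids, classes))


def _present_probs(
    classes: np.ndarray, auto_freq: np.ndarray, leakage: float,
    n_males: int, n_females: int,
) -> np.ndarray:
    """Per-cell PRESENT probability matrix (loci × individuals, males first)."""
    n_loci = len(classes)
    p = np.empty((n_loci, n_males + n_females))
    is_auto = classes == LocusClass.AUTOSOMAL.value
    is_xy = classes == LocusClass.XY_LINKED.value
    is_zw = classes == LocusClass.ZW_LINKED.value
    p[is_auto, :] = auto_freq[is_auto, None]
    p[np.ix_(is_xy, np.arange(n_males))] = 1.0 - leakage
    p[np.ix_(is_xy, np.arange(n_males, n_males + n_females))] = leakage
    p[np.ix_(is_zw, np.arange(n_males))] = leakage
    p[np.ix_(is_zw, np.arange(n_males, n_males + n_females))] = 1.0 - leakage
    return p


def simulate_dataset(
    config: SimConfig,
) -> tuple[SnpGenotypeMatrix, PaMatrix, SexRegistry, SimTruth]:
    """Generate one synthetic dataset.

    Individuals are named ``M01..`` and ``F01..`` (males first).  Loci are
    named ``PA000001..`` / ``SNP000001..`` in block order autosomal,
    XY-linked, ZW-linked; the truth object records each locus's class.

    Random draws consume a single ``numpy.random.default_rng(seed)`` stream
    in this order: (1) autosomal PA per-locus frequencies; (2) PA call
    uniforms, loci-major/individuals-minor; (3) autosomal SNP minor-allele
    frequencies; (4) SNP call uniforms, loci-major; (5) PA missingness
    uniforms; (6) SNP missingness uniforms.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    males = [f"M{i + 1:02d}" for i in range(cfg.n_males)]
    females = [f"F{i + 1:02d}" for i in range(cfg.n_females)]
    individuals = males + females
    n_ind = len(individuals)
    registry = SexRegistry(
        {**{m: Sex.MALE for m in males}, **{f: Sex.FEMALE for f in females}}
    )

    pa_classes = (
        [LocusClass.AUTOSOMAL] * cfg.n_autosomal_pa
        + [LocusClass.XY_LINKED] * cfg.n_xy_pa
        + [LocusClass.ZW_LINKED] * cfg.n_zw_pa
    )
    snp_classes = (
        [LocusClass.AUTOSOMAL] * cfg.n_autosomal_snp
        + [LocusClass.XY_LINKED] * cfg.n_xy_snp
        + [LocusClass.ZW_LINKED] * cfg.n_zw_snp
    )
    pa_ids, pa_truth = _locus_ids("PA", pa_classes)
    snp_ids, snp_truth = _locus_ids("SNP", snp_classes)
    pa_cls = np.array([c.value for c in pa_classes])
    snp_cls = np.array([c.value for c in snp_classes])

    # (1) + (2): PA block
    lo, hi = PA_AUTOSOMAL_FREQ_RANGE
    pa_auto_freq = rng.uniform(lo, hi, size=len(pa_classes))
    p_present = _present_probs(pa_cls, pa_auto_freq, cfg.leakage,
                               cfg.n_males, cfg.n_females)
    u = rng.random((len(pa_classes), n_ind))
    pa_calls = np.where(u < p_present, PRESENT, ABSENT).astype(np.int8)

    # (3) + (4): SNP block
    mlo, mhi = cfg.autosomal_maf_range
    snp_maf = rng.uniform(mlo, mhi, size=len(snp_classes))
    u = rng.random((len(snp_classes), n_ind))
    snp_calls = np.empty((len(snp_classes), n_ind), dtype=np.int8)
    is_auto = snp_cls == LocusClass.AUTOSOMAL.value
    # Hardy–Weinberg: cumulative (ref-hom, +het, +snp-hom) cut points
    q = snp_maf[is_auto, None]
    c1 = (1 - q) ** 2
    c2 = c1 + 2 * q * (1 - q)
    ua = u[is_auto]
    snp_calls[is_auto] = np.select(
        [ua < c1, ua < c2], [REF_HOM, HET], default=SNP_HOM
    ).astype(np.int8)
    male_cols = np.arange(cfg.n_males)
    female_cols = np.arange(cfg.n_males, n_ind)
    for cls, het_cols, ref_cols in (
        (LocusClass.XY_LINKED.value, male_cols, female_cols),
        (LocusClass.ZW_LINKED.value, female_cols, male_cols),
    ):
        rows = snp_cls == cls
        # heterogametic sex: HET w.p. 1-leakage, else REF_HOM
        snp_calls[np.ix_(rows, het_cols)] = np.where(
            u[np.ix_(rows, het_cols)] < 1 - cfg.leakage, HET, REF_HOM
        )
        # homogametic sex: REF_HOM w.p. 1-leakage, else HET
        snp_calls[np.ix_(rows, ref_cols)] = np.where(
            u[np.ix_(rows, ref_cols)] < 1 - cfg.leakage, REF_HOM, HET
        )

    # (5) + (6): missingness last
    # missingness draws are skipped entirely at rate 0, so the stream
    # position depends on whether missing_rate is zero
    if cfg.missing_rate > 0:
        pa_calls[rng.random(pa_calls.shape) < cfg.missing_rate] = MISSING
        snp_calls[rng.random(snp_calls.shape) < cfg.missing_rate] = MISSING

    pa = PaMatrix(pd.DataFrame(pa_calls, index=pa_ids, columns=individuals))
    snp = SnpGenotypeMatrix(
        pd.DataFrame(snp_calls, index=snp_ids, columns=individuals)
    )
    truth = SimTruth({**pa_truth, **snp_truth}, cfg)
    return snp, pa, registry, truth


def _min_count(t: Union[float, Fraction], n: int) -> int:
    """Smallest integer count c with c/n >= t, computed exactly."""
    frac = t if isinstance(t, Fraction) else Fraction(*float(t).as_integer_ratio())
    return int(math.ceil(frac * n))


def expected_pass_rate(
    config: SimConfig,
    hypothesis: Union[Hypothesis, str],
    t: Union[float, Fraction],
    locus_class: Union[LocusClass, str] = LocusClass.AUTOSOMAL,
    autosomal_freq: Optional[float] = None,
    n_called_males: Optional[int] = None,
    n_called_females: Optional[int] = None,
) -> float:
    """Analytic probability that a PA locus passes the filter at threshold t.

    For the XY hypothesis a locus passes when at least ``ceil(t·n_m)`` of
    the n_m males are PRESENT and at least ``ceil(t·n_f)`` of the n_f
    females are ABSENT, so the pass probability is the product of two
    binomial upper tails with per-sex PRESENT probabilities implied by the
    locus class and the leakage rate.  Missingness is ignored unless
    effective per-sex called counts are supplied.  Serves as the analytic
    oracle for the simulator's empirical pass rates.
    """
    t = Fraction(*float(t).as_integer_ratio()) if not isinstance(t, Fraction) else t
    if not 0 < t <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {float(t)}")
    hyp = Hypothesis(hypothesis) if not isinstance(hypothesis, Hypothesis) else hypothesis
    cls = LocusClass(locus_class) if not isinstance(locus_class, LocusClass) else locus_class
    n_m = config.n_males if n_called_males is None else n_called_males
    n_f = config.n_females if n_called_females is None else n_called_females

    if cls is LocusClass.AUTOSOMAL:
        if autosomal_freq is None:
            raise ValueError("autosomal_freq required for an autosomal locus")
        p_m = p_f = autosomal_freq
    elif cls is LocusClass.XY_LINKED:
        p_m, p_f = 1.0 - config.leakage, config.leakage
    else:  # ZW_LINKED
        p_m, p_f = config.leakage, 1.0 - config.leakage

    if hyp is Hypothesis.XY:
        present_n, present_p = n_m, p_m     # present side: males
        absent_n, absent_p = n_f, p_f       # absent side: females
    else:
        present_n, present_p = n_f, p_f
        absent_n, absent_p = n_m, p_m

    tail_present = stats.binom.sf(_min_count(t, present_n) - 1, present_n, present_p)
    tail_absent = stats.binom.sf(_min_count(t, absent_n) - 1, absent_n, 1.0 - absent_p)
    return float(tail_present * tail_absent)


def expected_autosomal_pass_rate(
    config: SimConfig,
    hypothesis: Union[Hypothesis, str],
    t: Union[float, Fraction],
    min_called_fraction: Union[float, Fraction] = Fraction(1, 2),
    n_quad: int = 241,
) -> float:
    """Marginal probability that one autosomal PA locus passes the filter.

    Averages the pass probability over the generator's uniform per-locus
    presence-frequency distribution and over the per-sex called-count
    distribution induced by the missingness rate (counts below the
    ``min_called_fraction`` eligibility guard contribute zero).  Multiplied
    by the autosomal locus count this gives the expected number of
    spurious selections; since frequencies are drawn independently per
    locus, the count is binomial with this marginal rate.
    """
    hyp = Hypothesis(hypothesis) if not isinstance(hypothesis, Hypothesis) else hypothesis
    t = t if isinstance(t, Fraction) else Fraction(*float(t).as_integer_ratio())
    mcf = (min_called_fraction if isinstance(min_called_fraction, Fraction)
           else Fraction(*float(min_called_fraction).as_integer_ratio()))
    lo, hi = PA_AUTOSOMAL_FREQ_RANGE
    q = np.linspace(lo, hi, n_quad)                       # presence frequency

    def sex_tail(n_total: int, success_prob: np.ndarray) -> np.ndarray:
        """E over called count of the per-sex binomial tail, eligible only."""
        called = np.arange(n_total + 1)
        w = stats.binom.pmf(called, n_total, 1.0 - config.missing_rate)
        out = np.zeros_like(q)
        for n_called, weight in zip(called, w):
            if n_called == 0 or Fraction(int(n_called), n_total) < mcf:
                continue
            k_min = _min_count(t, int(n_called))
            out = out + weight * stats.binom.sf(k_min - 1, int(n_called),
                                                success_prob)
        return out

    if hyp is Hypothesis.XY:
        tails = sex_tail(config.n_males, q) * sex_tail(config.n_females, 1.0 - q)
    else:
        tails = sex_tail(config.n_females, q) * sex_tail(config.n_males, 1.0 - q)
    return float(np.trapezoid(tails, q) / (hi - lo))
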