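# Methods

## Genetic model and assumptions

The analysis targets reduced-representation genotyping (DArTseq-style) of a
panel of phenotypically sexed individuals. Two marker classes are handled:

* **PA (silicoDArT) loci** — dominant presence/absence of a restriction
  fragment. A Y-specific (or W-specific) fragment appears in the
  heterogametic sex and is absent from the homogametic sex; this is the
  primary carrier of a sex signal in species with young, largely
  undifferentiated sex chromosomes.
* **SNP loci** — co-dominant calls (reference homozygote / SNP homozygote /
  heterozygote / missing). Under an XY system with a Y-borne SNP allele,
  males are expected heterozygous and females reference-homozygous; ZW is
  the mirror image.

Assumptions: individuals are unrelated (no kinship correction); phenotypic
sexing is correct; loci are anonymous tags with no genomic coordinates; an
XY and a ZW signal may co-exist in the same panel and are therefore
evaluated as two independent hypotheses per locus, never exclusively.

Because recombination between still-recombining sex chromosomes moves
diagnostic alleles into the "wrong" sex, perfect association is not
required: filters run over a graded threshold grid and a locus is
classified **PERFECT** (passes t = 1.00), **MODERATE** (passes some
t ∈ [0.70, 0.90] but not 1.00) or **UNLINKED**, independently under each
hypothesis.

## Selection rules

Per-locus per-sex state frequencies use **called individuals of that sex**
as the denominator. The publication-style criterion label "70:30
male:female" corresponds to t = 0.70 under XY ("30:70" under ZW).

* PA/XY at t: freq_present(males) ≥ t AND freq_absent(females) ≥ t.
* SNP/XY at t: females freq_ref_hom ≥ t, freq_snp_hom ≤ 1−t,
  freq_het ≤ 1−t; males freq_ref_hom ≤ 1−t, freq_het + freq_snp_hom ≥ t.
* ZW: the same rules with the sexes exchanged.

The SNP male side pools SNP-allele homozygotes with heterozygotes because
X–Y recombination can drive a Y-linked allele to homozygosity in males; a
strict heterozygote-only mode is available
(`pool_male_homozygotes=False`). The female-side rule is deliberately
conjunctive (retain on ref-homozygosity AND bound both alternative
genotypes): of the conceivable readings of a retain/discard formulation for
the homogametic sex, it is the only internally consistent one.

All threshold comparisons are **exact rational arithmetic**: a frequency
c/n passes t = p/q iff c·q ≥ p·n, with ≥ inclusive ("at least"). Float
thresholds are canonicalized via `Fraction.limit_denominator(10⁶)` so 0.7
means 7/10 exactly; 12/15 therefore passes t = 0.80 exactly, and no
boundary case depends on binary rounding.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| threshold grid | 0.70, 0.80, 0.90, 1.00 | graded criteria (fractions of called individuals) |
| `min_called_fraction` | 0.5 | per-sex called fraction (of all registry individuals of that sex) a locus needs to be testable; guards against loci scored in a handful of individuals |
| `catt_alpha` | 0.001 | per-locus trend-test verification cut-off |
| `dispersion_kind` | SD | ± summaries over pairwise distances; SEM also computed on request, and the kind used is recorded in every output |
| QC thresholds | off | reproducibility / call-rate / mean-depth minima applied only when the export carries the metadata columns |
| homology filters | E < 0.05, coverage > 50%, identity > 50% | strict inequalities; best hit per query by lowest E, ties by identity |

## Statistics

**Hamming distances** use pairwise deletion: entry (a,b) is the fraction of
differing calls over loci called in both a and b. The alternative
(missing-in-one counts as a difference over all loci) is available behind
`missing_as_mismatch`. Distances for a criterion are computed over the loci
that criterion selected, i.e. the combined moderately sex-linked set.
Strata (within-male, within-female, between) are means over unordered
pairs: C(n_m,2), C(n_f,2) and n_m·n_f pairs respectively.

**Cochran–Armitage trend test**: the classical closed form with weights
(0,1) for PA absent/present and (0,1,2) for SNP ref-hom/het/SNP-hom
genotypes, df = 1, p from the χ²₁ upper tail; missing calls are excluded
from the counts. When every called individual falls in one state column
the variance term vanishes and the statistic is reported as undefined
(flagged, not an exception). No multiplicity correction is applied by
default (raw p-values are always emitted; Benjamini–Hochberg can be applied
downstream). Note that on a discrete 2×k lattice the exact permutation
p-value is only defined up to the tie mass at the observed statistic; the
test suite validates the closed form against a multivariate-hypergeometric
permutation oracle via the [P(>obs), P(≥obs)] bracket.

**PIC** is the two-allele form 2p(1−p), range [0, 0.5] with the maximum at
equifrequent alleles — the variant consistent with reporting PIC up to 0.5
(the Botstein variant maxes at 0.375). SNP allele frequency is estimated by
gene counting; PA uses the presence frequency as the two-state p.

**Spurious-linkage expectation**: with n sexed individuals the probability
that one locus shows a perfect sex pattern by chance is P = 0.5ⁿ
(each individual independently "agrees" with probability ½); multiplied by
the panel size it gives the expected count of spurious perfect loci.
Reported at full precision and display-rounded to 3 (P) and 2 (count)
significant figures.

**Criterion-group comparisons**: pooled present/absent counts of the loci
selected at different thresholds are compared per sex by Pearson chi-square
(no continuity correction); SNP per-locus heterozygosity vectors by
Kruskal–Wallis with an all-pairs Nemenyi post-hoc (joint-rank studentized
range, infinite df) when the omnibus rejects. Empty selection groups make
the comparison undefined rather than raising.

## Synthetic-data generator

`simulate_dataset` emulates the study design: 15 males + 15 females; PA and
SNP matrices with autosomal background plus XY- and ZW-linked loci planted
in the *same* individuals (the co-existence scenario); per-individual
leakage probability for a sex-linked locus to show the wrong-sex state
(modelling X–Y / Z–W recombination, default 0.1, symmetric in both
directions); independent per-cell missingness (default 0.05). Autosomal PA
presence frequencies are uniform on [0.2, 0.8]; autosomal SNP genotypes are
Hardy–Weinberg draws at a minor-allele frequency uniform on the
`autosomal_maf_range` (default [0.4, 0.5], matching panels reported with
per-locus PIC near 0.5). Default locus counts (5,000 autosomal + 50 + 50 PA;
2,000 autosomal SNP, no sex-linked SNPs) are a scaled-down version of a
~118k-PA / ~43k-SNP study in which the sex signal was carried by PA loci
only; planted sex-linked SNPs can be switched on to exercise the SNP
criteria.

Randomness comes from one `numpy.random.default_rng(seed)` stream consumed
in a fixed order (PA autosomal frequencies; PA call uniforms loci-major;
SNP MAFs; SNP call uniforms; PA then SNP missingness masks — skipped
entirely when the rate is 0), so identical configs are bit-identical and
the scheme is documented for re-implementation.

The analytic companions `expected_pass_rate` (exact binomial tail product
for a given locus class) and `expected_autosomal_pass_rate` (marginalized
over the frequency distribution, the missingness-induced called-count
distribution, and the eligibility guard) provide the oracle for empirical
pass rates; because per-locus frequencies are i.i.d., the autosomal
false-positive count is binomial with the marginal rate.

What the generator does **not** emulate: linkage disequilibrium between
tags, related individuals, genotyping error other than missingness,
locus-specific call-rate/depth structure, allelic dropout correlated with
sex, or reference-panel ascertainment. Passing recovery tests on synthetic
data therefore demonstrates the machinery is correct under the stated
model, not that a given real dataset satisfies that model.

## Problem sizes used in tests

The test and acceptance runs use scaled-down panels chosen to keep Monte
Carlo error informative at desk scale: 5,000 autosomal + 50 + 50 planted PA
loci for recovery (matching the planted-to-background ratio of a real
screen), 10,000 loci for null calibration, 10,000 permutation draws per
table, 1,000 / 500 / 300 random instances for the structural property
checks. Full-size deposited matrices (~160k loci) run through the same code
path; only wall-clock time changes.

## Known limitations and open choices

* The denominator convention (frequencies over called individuals) and the
  ± dispersion convention (SD over pairs, SEM available) are choices where
  published reports are commonly silent; both are recorded in outputs.
* Homology classification is name-based (regex on subject id/description):
  repeat libraries cannot be redistributed, so a curated annotation map
  should be supplied for serious use; unmatched filtered hits default to
  GENE (configurable to UNKNOWN).
* The pipeline consumes pre-computed alignment hit tables; it never runs
  BLAST itself.
* No linkage-group assignment or genome mapping: inputs carry no positions.
* Full-data reproduction of published tables requires the original data
  deposit placed under `data/dryad/` (see `tests/test_acceptance.py`); it
  is not redistributed with the package.
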