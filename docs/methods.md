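# Methods

## Scope and model

The package implements a cross-sectional screening analysis for monogenic
diabetes in a paediatric diabetes clinic population. Its stages are (i) a
weighted polygenic type 1 diabetes genetic risk score (T1D-GRS) with
centile-based risk categories, (ii) a genotype-only triage rule deciding
which children receive gene-panel testing, (iii) zygosity-based inheritance
classification of confirmed pathogenic findings, and (iv) exact inference:
prevalence with Clopper–Pearson intervals and per-criterion odds ratios
with exact conditional CIs and Fisher p values.

### Risk score

For dosages `d_i ∈ {0,1,2}` and positive log-odds weights `w_i`,

    score = Σ w_i d_i / (2 Σ w_i).

The normalisation by the maximum attainable weighted dosage places scores
in [0, 1] and makes them commensurate with the published centile thresholds
(0.234 and 0.280). The original score's HLA DR3/DR4 interaction term is
not modelled; all 30 SNPs enter additively. This is a deliberate
simplification: the pipeline's validity requires only a monotone score with
calibrated centiles, and the interaction encoding is not reproducible from
public sources. Missing genotypes are handled by restricting numerator and
denominator to observed SNPs (equivalent to scoring against the reduced
weight table); no imputation is attempted, because it would require allele
frequencies the pipeline does not otherwise need. Children missing more
than 20% of SNPs (default ceiling) are flagged with an undefined score and
are refused by the triage rule rather than silently dropped or zeroed.

### Categories and thresholds

Low / moderate / high categories are `score < t_low`,
`t_low ≤ score ≤ t_high`, `score > t_high`. Both boundary values belong to
the moderate band, matching the closed printed interval "0.234–0.280".
Thresholds are configuration, not derivation: the published values are the
5th and 50th centiles of 1963 gold-standard European type 1 diabetes
patients, and `calibrate_thresholds` can re-derive them from any supplied
reference cohort of ≥ 100 scores using linear-interpolation empirical
quantiles (numpy's default, "type 7" — stated explicitly because several
quantile conventions exist). Fewer than 100 reference scores is rejected:
a 5th-centile estimate from a smaller tail is too unstable to serve as a
clinical cut-off.

### Triage

Eligibility is diabetes onset at 0.5–20 years, both bounds inclusive (the
verbal phrase "between 6 months and 20 years" does not specify open or
closed ends; inclusive was chosen and is applied consistently). The
testing rule is a function of (GRS category, islet autoantibody status)
only: low → tested regardless of antibody status (including missing);
moderate and antibody-negative → tested; everyone else (high GRS, moderate
antibody-positive or antibody-missing) → untested. Ineligible children are
retained in outputs with reason `ineligible` for auditability.

### Inheritance classification

Monoallelic pathogenic variants → autosomal dominant; biallelic (homozygous
or compound heterozygous, phasing out of scope) → autosomal recessive;
mitochondrial variants → other. The gene symbol never influences the class.
A child with both a monoallelic and a biallelic pathogenic call — not a
combination the screening design expects — is classified by the biallelic
call with a warning, keeping the rule total while prioritising the
recessive finding. X-linked modes are representable in the panel but no
special rule exists for them; calls in such genes follow the zygosity rule.

### Exact statistics

* **Clopper–Pearson** intervals via beta-quantile inversion
  (statsmodels `proportion_confint(method="beta")`); limits are exactly 0
  at x = 0 and 1 at x = n.
* **Fisher's exact test** (in-package): two-sided by the probability-mass
  convention — sum over the hypergeometric support of every table whose
  probability is at most the observed one, with a relative tie tolerance of
  1e-7 for floating-point ties. Zero-margin tables carry no information and
  return p = 1 with a warning. The test suite checks this implementation
  against an exact integer-arithmetic enumeration for *every* 2×2 table
  with total ≤ 40, and against scipy on random tables.
* **Odds ratios**: the conditional maximum-likelihood estimate under the
  noncentral hypergeometric model, with Cornfield-style exact CIs
  (scipy's `contingency.odds_ratio`); the sample cross-product OR is also
  reported for transparency. A zero margin is an explicit error; a single
  zero cell yields a one-sided interval. Because the exact CI inverts
  equal-tailed one-sided tests while the Fisher p is two-sided by
  probability mass, p < 0.05 and "CI excludes 1" can disagree near the
  boundary; the pipeline reports such rows in `consistency_flags` instead
  of hiding them.
* **Two-sample proportion test**: pooled-variance normal z without
  continuity correction (the common default; the variant is otherwise
  unspecified in clinical reporting).
* **Mann–Whitney and two-sample Kolmogorov–Smirnov**: when
  `n_x·n_y ≤ 400` and the pooled sample is tie-free, exact null
  distributions (scipy `method="exact"`); with ties, full enumeration of
  label permutations using mid-ranks, provided the permutation count is
  ≤ 250,000 (the two-sided Mann–Whitney permutation p is the probability
  of a |U − n_x n_y/2| at least as large as observed, which coincides with
  the classical two-tailed definition in the tie-free case); otherwise
  tie-corrected asymptotics. The cut-offs trade exactness against runtime
  and are stated here because they are behavioural, not cosmetic.

### Criterion evaluation

Each built-in criterion (non-insulin treatment; parent with diabetes;
HbA1c ≤ 58 mmol/mol, boundary inclusive; MODY clinical probability ≥ 10%,
boundary inclusive — the stricter ≥ reading of a threshold reported
ambiguously as ">10%" elsewhere; any extra-pancreatic feature; parental
consanguinity) is tabulated as criterion presence × (target-class case vs
rest of cohort). Children with a missing datum for a criterion are excluded
pairwise and counted in `n_excluded_missing`. HbA1c is carried in mmol/mol
(IFCC); the percentage accessor uses the DCCT conversion
`% = mmol/mol / 10.929 + 2.15` for display only.

## Synthetic data generator

`generate_cohort` emulates the structure of a high-consanguinity clinic
population of 1093 children:

* **Classes.** Monogenic prevalence 3.1%, split 41% recessive / 3%
  mitochondrial-other / 56% dominant; the remaining 96.9% are autoimmune.
  Autoimmune children have a recorded positive islet autoantibody with
  probability 0.45 and a missing result with probability 0.12 — values
  chosen so the expected numbers of definite type 1 diabetes children
  (~475) and antibody-missing children (~130) match the published cohort
  structure.
* **Genotypes.** Autoimmune children draw risk-allele dosages from
  case-enriched frequencies, monogenic children from background-population
  frequencies (their type 1 diabetes genetic risk is by premise ordinary),
  independently across SNPs — no linkage disequilibrium is modelled.
* **Clinical criteria** are Bernoulli draws, conditionally independent
  given the class, with class rates derived from baseline rates `p0` and a
  per-class odds ratio via `p = OR·o0/(1 + OR·o0)`, `o0 = p0/(1−p0)`. This
  makes the population odds ratio against the rest of the cohort equal the
  configured value by construction. Default odds ratios: 105.1 (non-insulin),
  6.2 (parent with diabetes), 10.3 (HbA1c ≤ 58), 38 (MODY probability
  ≥ 10%) for dominant cases; 66.9 (extra-pancreatic features) and 4
  (consanguinity) for recessive cases. Baseline rates are free parameters
  (defaults 0.02/0.15/0.08/0.05/0.02/0.20); the consanguinity baseline is
  the population's 20% rate, the others are plumbing chosen to keep case
  cells non-degenerate at n = 1093.
* **Continuous measures** (HbA1c, MODY probability) are drawn from
  class-conditional distributions consistent with their thresholded binary
  criteria; ages are uniform over the eligibility window.
* **Truth layer.** Each monogenic child carries exactly one pathogenic
  call; recessive genes are sampled with WFS1 and SLC19A2 commonest,
  dominant genes with GCK and HNF1A commonest.
* **Determinism.** All draws flow from `numpy.random.default_rng` seeded by
  a single integer; identical parameters and seed give identical cohorts.

### SNP fixture calibration

The bundled 30-SNP weight table is synthetic: one dominant-effect HLA-like
SNP (weight 0.90, case frequency 0.99) plus 29 SNPs with weights
0.42–0.22, a high-frequency block and a graded rare block. Case
frequencies were calibrated once, analytically plus simulation, so that the
simulated reference cohort reproduces the published score distribution of
gold-standard type 1 diabetes patients: the median lands at 0.280 and the
IQR at ≈ (0.263, 0.290) against the published (0.262, 0.298). The
empirical 5th centile of the fixture is ≈ 0.228 rather than the published
0.234: with 30 additive binomial SNPs constrained to this mean and
variance, the left tail is slightly heavier than the real score's. The
category thresholds are therefore always the published constants, never
re-derived from the fixture. Background frequencies put the background
median at ≈ 0.19, placing ~84% of background-genotype children below the
low threshold and ~98% at or below the moderate ceiling, so ~96% of
simulated monogenic children fall inside the tested triage subset.

A further fixture artefact: because frequencies are extreme, the simulated
score distribution is visibly discrete (large exact point masses). All
scoring paths share one numerical kernel so that equal dosage vectors give
bit-identical scores; rank tests then see genuine ties rather than
float-noise pseudo-ties.

### What passing tests do and do not show

The generator realises the marginal structure the analysis assumes: class
mixture, genotype separation, per-criterion marginal odds ratios. It does
not model criterion–criterion correlation (real syndromic features
co-occur), linkage disequilibrium, family structure, measurement error in
antibody assays, or secular referral patterns. Recovery results on
synthetic cohorts therefore validate the *inference machinery* —
estimators, exact intervals, triage bookkeeping — under the stated
assumptions, not the clinical performance of the criteria in any real
population.

## Problem sizes in tests

The test suite exercises the Fisher implementation exhaustively over all
2×2 tables with total ≤ 40 (~10^5 tables), rank-test enumeration up to
n_x·n_y ≤ 36, exact OR CIs against tail-inversion on 100 random tables
with cells ≤ 15, Clopper–Pearson coverage with 10,000 binomial replicates
at n = 1000, and parameter recovery over 200 seeded cohorts of 1093
children. These sizes give Monte-Carlo error comfortably below the
assertion bands while keeping the default run in the low tens of seconds.

## Known limitations

* The SNP weight table, allele frequencies and gene panel are synthetic
  stand-ins with realistic shapes, not published values; real tables can be
  supplied as TSVs.
* VCF ingestion matches variants by ID and requires exact allele agreement
  with the weight table (either orientation); strand flips are rejected,
  not harmonised.
* No multiple-testing adjustment is applied across criteria (none is
  standard in this reporting style); the criteria report is descriptive.
* C-peptide, BMI centiles and the internals of the MODY clinical
  probability model are out of scope; the MODY probability is consumed as a
  precomputed column and only thresholded.
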