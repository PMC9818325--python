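# Methods

## The prioritization cascade

The cascade models a clinical-genetics review of panel-sequencing calls as
ten sequential exclusion predicates followed by a final retention rule.
The stages act on annotations only — no sequence context or genome
coordinates are consumed — which is what makes the procedure portable
across calling pipelines and exactly testable.

Attribution semantics: a removed variant is labelled with the *first*
failing stage in the fixed order i→x. Order affects only attribution,
never membership — the retained set equals the conjunction of all ten
pass-predicates plus the final rule, a property the test suite asserts
against an independently coded predicate table on random variant batches.

Numerical and boundary choices:

- **Quality.** "Below 150" is strict: quality exactly 150 passes. The
  score is treated as an opaque caller unit (`quality_min`, default 150).
- **Allele frequency.** The ceiling (`maf_max`, default 0.004) is strict:
  MAF exactly 0.4% passes. A variant absent from a frequency resource is
  treated as frequency 0 (absence of evidence of commonness). At the
  population stage a variant is removed if *any* of the four databases
  (gnomAD, 1000 Genomes, ESP, ExAC) exceeds the ceiling — the most
  conservative aggregation.
- **Intronic geometry.** Stage iii covers UTR / upstream / downstream /
  intergenic consequences and in-frame indels. Intronic records within
  ±`splice_window_bp` (default 2) of an exon boundary are treated as
  splice-relevant and survive stages iii/viii; intronic records beyond the
  window are removed at stage viii. This split keeps "non-coding" and
  "deep intronic" separately attributable without double counting.
- **Known-pathogenic whitelist.** The whitelist exempts variants only from
  the sequencing-error stage (x), not from the exon-geometry stages
  vii–ix. A last-exon ClinVar-pathogenic variant is therefore removed at
  stage vii; the scope of the exemption is the one genuinely open design
  choice here, and the narrow reading was chosen because the whitelist
  exists to rescue known variants from a *technical* blacklist, not to
  override biological filters.
- **Copy-number records.** Multi-exon deletions/duplications carry
  consequence `cnv_deletion` / `cnv_duplication`. Exon-geometry predicates
  (iii, vii, viii, ix) are undefined for them and are skipped; quality,
  repeat, frequency, ClinVar and sequencing-error stages still apply.
  Deletions count as truncating for the final rule; duplications are
  retained only through the ClinVar route.
- **Final rule.** Retained iff ClinVar pathogenic / likely-pathogenic, or
  truncating: stop-gain, frameshift, splice within the window, or a CNV
  deletion. ClinVar `vus` and `conflicting` do not qualify.

## Burden statistics

Carrier counts use distinct-sample semantics throughout (a double carrier
within a gene counts once; across genes, once per gene and once per
class/set union). Each label is tested on a 2×2 table with:

- **Odds ratio** `ad/bc`, undefined ("n.d.") when any cell is zero. No
  continuity (Haldane) correction is applied — undefined is reported as
  such, matching clinical-report conventions.
- **Woolf (logit) CI** `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`. Woolf was
  chosen because it is closed-form, standard and exactly reproducible.
  Commercial packages often default to different hybrid 2×2 intervals;
  against the bundled reference table the Woolf lower bounds agree within
  one unit in the second decimal and upper bounds within ~0.2% relative,
  which is the documented tolerance for cross-method comparison.
- **Pearson chi-square** without continuity correction, 1 df, two-sided.
  This choice reproduces the reference table's significant p-values
  (0.012, 0.010, 0.029, 0.021, 0.001) where Yates-corrected or exact
  tests do not; Fisher's exact test is available behind a flag. p is
  undefined when a table margin is zero.
- **Multiple testing.** None is applied, deliberately mirroring the
  single-gene reporting style of the reference analysis; users comparing
  many genes should treat isolated p ≈ 0.01–0.05 results as hypothesis
  generating.

When burden rows are built from per-gene *counts* (rather than carrier
matrices), class and set totals on the control side are sums of per-gene
counts restricted to genes observed in cases — a control subject carrying
variants in two listed genes would be double-counted. The matrix-based
path uses true distinct-sample unions on both sides. The bundled
reference control data are per-gene counts, where the summation assumption
is consistent with the published class totals (4+4+0+2 = 10 established;
104 candidate; NBN 4 + RAD50 3 = 7 for the MRN set).

Report rendering mimics the reference table: percentages and odds ratios
to one decimal (half-up), CI bounds to two, p-values to three decimals
below 0.05 and one decimal otherwise. Comparisons against the printed
reference values use agreement within one unit in the last printed digit,
because the source table's rounding is not uniformly half-up (a Pearson p
of 0.9965 is printed as 0.9, and 0.0204 as 0.021).

## Clinical comparison

Continuous characteristics default to Mann–Whitney (Kruskal–Wallis for
more than two strata; Student's t-test by option) — a robust default for
skewed clinical variables such as AFP or age at diagnosis. Categorical
characteristics use the Pearson chi-square on the full levels × groups
table. A characteristic that is constant in both strata, or a stratum
that is empty, is flagged untestable rather than failing the run. The
0.05 threshold is reported, never asserted.

Survival uses the Kaplan–Meier product-limit estimator and the log-rank
test (χ², groups − 1 df), both delegated to `lifelines`. Tied
event/censoring times follow the dominant convention: censored subjects
at time *t* remain at risk for events at *t*. The test suite validates
the estimator against hand-computed product-limit values and the log-rank
p against a 20,000-draw permutation distribution of an independently
coded statistic.

## The synthetic cohort generator

The generator's job is to make every downstream stage testable with known
ground truth, while structurally resembling the reference study:

- **Carriers.** Per subject and gene, carrier status is Bernoulli with a
  group-specific probability; defaults equal the reference cohort's
  observed carrier fractions (e.g. NBN 4/334 in cases, 4/1662 in
  controls). Planted carrier variants are constructed to pass all ten
  stages and the final rule through a randomly chosen retention route.
- **Nuisance variants.** Per subject and removal stage, a Poisson number
  of variants (default rate 0.2 per stage — no pre-filter per-subject
  call counts are published for the reference study, so this is a package
  choice sized to exercise every stage) each engineered to fail *exactly*
  its intended stage's predicate and no other, so removal-stage
  attribution is uniquely determined.
- **Covariates.** Sex, cirrhosis etiology, diabetes, obesity, smoking,
  tumor features and family history are sampled independently at the
  reference cohort's marginal prevalences (cirrhosis 98.5%, alcoholic
  etiology 38.6%, …); age is truncated normal (mean 62, SD 9, range
  25–80) matching the reference median of 63. Cirrhosis is implied by a
  non-"none" etiology. No covariate correlations are modeled, because
  only marginal carrier/non-carrier comparisons are performed.
- **Survival.** Exponential with hazard 0.008/month (median ≈ 7 years,
  plausible for a transplant-candidate cohort) and administrative
  censoring at 264 months (the reference follow-up maximum of 22 years).

Determinism contract: an identical `SimulationConfig` (including the
seed) yields byte-identical variant, phenotype and ground-truth outputs.

**What passing tests do and do not show.** Synthetic cohorts have
independent subjects, independent covariates, exactly one variant per
planted event and annotation fields drawn from clean distributions. Exact
cascade recall on them certifies the *logic* of the predicates and
attribution, not robustness to real-data pathologies (annotation
missingness beyond absent MAFs, inconsistent transcript choices,
relatedness, population structure, batch effects in quality scores).
Calibration results likewise certify the test machinery under the
simulated null, not the adequacy of an unadjusted chi-square for
confounded real cohorts.

## Problem sizes used in checks

The bundled reference computations (48-variant table, 36 burden rows) are
instantaneous. Simulation-based checks use cohorts of 334 + 1662 subjects
for cascade recall, 50 replicates for null-calibration of the chi-square
and log-rank tests (n = 1800 and 400 per replicate), and n = 10,000
subjects for carrier-frequency recovery against exact binomial 95%
intervals — sizes at which the binomial and asymptotic approximations the
checks rely on are comfortably valid.

## Known limitations

- The ten-stage predicate set is panel-oriented; it does not implement
  ACMG/AMP criteria scoring, and the sequencing-error blacklist is an
  input flag, not a computed property.
- The gene panel ships with the 62 symbols needed for the bundled
  reference analysis; full screening panels (the reference design targets
  226 genes) must be supplied by the user as YAML.
- Burden testing is carrier-count based (2×2); no regression or
  kernel-based rare-variant tests, and no covariate adjustment.
- The counts-based control aggregation can double-count multi-gene
  control carriers (see above); supply carrier matrices when control
  sample identities are available.
- Undefined odds ratios ("n.d.") are reported, not rescued by continuity
  corrections, so single-carrier genes with zero control carriers carry
  no effect-size estimate.
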