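# Methods

## The phenomenon under study

Microbiome sequencing data are compositional: the total read count of a
sample is arbitrary, so only relative abundances carry information. The
centered log-ratio (CLR) transform maps a strictly positive composition
`x = (x_1 … x_D)` to

    clr_j(x) = ln(x_j / g(x)),     g(x) = (∏_k x_k)^(1/D)

Because logarithms are undefined at zero, a small pseudocount `c` is added
first. For a feature that is zero in every sample, every post-pseudocount
value equals `c`, so its CLR value in sample *i* is exactly

    ln c − ln g_i

— a deterministic, strictly decreasing function of the sample's geometric
mean. The CLR uses no phenotype labels and no other samples; it is a purely
sample-wise map. Yet if a phenotype is associated with the geometric mean
(equivalently, with Shannon alpha diversity, since
`H = −ln ∏ p_k^{p_k}` is the negative log of the abundance-weighted
geometric mean), the transformed empty feature inherits that association.
The package demonstrates this mechanism, quantifies it, and provides the
direct audit (label permutation) that distinguishes it from genuine
information leakage.

## The counterexample simulation

`simulate_counterexample` draws 100 samples over 31 features. The 50
"positive" samples have their first 30 features i.i.d. Uniform(0,1); the 50
"negative" samples have their first 20 features Uniform(0,1) with the
remaining 11 zero. The 31st feature is zero everywhere (variant `empty`).
Rows are normalized to relative abundances. These group sizes, feature
counts and distributions are the study conditions; they are not tuning
knobs.

After adding `c = 1e-6` in relative-abundance space, the per-sample
geometric mean over all 31 entries is approximately

    g ≈ exp( (k·(E[ln u] − ln E[S]) + z·ln c) / D )

with `k` occupied features, `z` pseudocount-only features, `E[ln u] = −1`
for Uniform(0,1) and row sum `S ≈ k/2`. This gives ≈0.0177 for the positive
group (k=30, z=1) and ≈8.8e-4 for the negative group (k=20, z=11), hence
CLR values of the empty feature near `ln(1e-6) − ln g`, i.e. −9.8 and −6.8.
The generator was validated against this closed form and a multi-hundred
replicate Monte-Carlo before its medians were frozen into tests; the test
suite re-checks the analytic approximation at 10% tolerance over 30 seeds.

**Pseudocount default.** The conventional zero-handling rule ("largest
power of 10 strictly below the smallest observed positive relative
abundance") is implemented in `default_pseudocount` and is exercised by the
sweep and the reanalysis chain. For the counterexample the package uses the
fixed value 1e-6 as its default: the rule's outcome on this generator
depends on the realized global minimum (typically in (1e-5, 1e-4), giving
1e-5; in roughly a quarter of realizations in (1e-6, 1e-5], giving 1e-6),
and 1e-6 is the value at which the headline medians (0.018 / 0.00090,
−9.80 / −6.80) are defined. `pseudocount="auto"` applies the rule to the
realized table instead.

**Sparse-feature variants.** `nonzero` fills the 31st feature with
Uniform(0,1) draws identically distributed in both groups, so any post-CLR
association is attributable solely to the geometric-mean denominator;
`partial` fills a label-blind random 20% of samples. Both are qualitative
variants: tests assert significance and direction, not specific p-values.

## The cohort emulator

`simulate_cohort` emulates the structure of real case/control tables in
which alpha diversity tracks the phenotype: group compositions are
symmetric-Dirichlet draws with concentration 0.1 (dominated, low diversity)
vs 10 (even, high diversity), counts are multinomial at a uniform depth of
10,000 reads, and an optional singleton taxon holds exactly one read in one
random sample. Defaults (20 per group, 50 taxa) give the Shannon comparison
near-certain power at α = 0.05 (≥95% of 200 replicates, verified in the
suite) while equal concentrations give nominal type-I behavior.

What it does *not* emulate: heterogeneous sequencing depth, batch
structure, realistic taxonomies, overdispersion beyond the Dirichlet, or
contamination. Passing tests therefore show that the pipeline recovers the
diversity→CLR mechanism under clean conditions; they say nothing about
batch-correction artifacts in real archives.

## Statistics

All two-group comparisons are two-sided Mann-Whitney U; the CLR-vs-diversity
relation uses Pearson's R with the `t = R√((n−2)/(1−R²))` two-sided p.
Mann-Whitney has two routes:

- pooled n ≤ 16: exact enumeration of all C(n_a+n_b, n_a) assignments with
  the two-sided p defined as `P(|U − n_a n_b/2| ≥ |U_obs − n_a n_b/2|)`;
  midranks make ties exact for free;
- pooled n > 16: normal approximation with midrank tie correction and
  continuity correction.

The exact enumerator doubles as the oracle for the asymptotic route. By
full enumeration of the null distribution, the two routes differ by at most
0.0375 in p for tie-free data with at least 3 observations per group; with
a group of 2 the worst case is 0.088, and heavy ties can widen it further
(the tie-corrected variance shrinks while the enumeration p saturates), so
the agreement tests draw continuous data with n ≥ 3 per group and check
tied data at an order-of-magnitude tolerance only. All-constant pooled data
yields p = 1 with a warning rather than an error so that chains survive an
all-zero feature.

No multiple-testing correction is applied anywhere: each report carries a
handful of named comparisons, not a screen.

## The reanalysis chain

`run_sparse_feature_reanalysis` fixes the stage order: contaminant removal
→ relative abundances → per-sample Shannon diversity (computed on
pre-pseudocount relative abundances of the contaminant-filtered table) →
diversity-vs-phenotype test → raw relative abundance of the chosen taxon vs
phenotype → pseudocount (power-of-ten rule in relative space; 1 in count
space, where the pseudocount is added to raw counts before normalization
and therefore interacts with depth) → CLR → taxon CLR vs diversity
(Pearson) and vs phenotype (Mann-Whitney). Labels reach only the four
association steps; no transformation receives them, which is the structural
guarantee the whole argument rests on.

First-timepoint filtering keeps each subject's minimum timepoint, breaking
ties by lexicographically smallest sample ID (real studies are assumed to
have unique first visits; the tie-break just makes the operation a
function).

## The leakage audit

`permutation_leakage_test` shuffles the phenotype labels *before* the
audited pipeline runs — normalization included — and reports the
+1-corrected empirical p, `(1 + #{permuted ≥ observed}) / (1 + n_perm)`.
The verdict threshold (empirical p ≤ 0.05 → `leakage_suspected`) is a
reporting convention, and the verdict is advisory: on data with a genuine
label association a leak-free pipeline also earns a small p, which is
signal, not leakage. The audit is discriminating only on data where labels
are known (or engineered) to be independent of the features; the test suite
uses exactly such a fixture with a scorer that peeks at the true labels
through its closure.

## Numerical choices and degenerate inputs

- Natural log everywhere (CLR, Shannon, geometric mean), so
  `H = −ln(weighted geometric mean)` holds to 1e-10 and the empty-feature
  identity `clr = ln c − ln g` to 1e-10.
- Relative-space pseudocount addition does not renormalize rows; the CLR's
  scale invariance (checked to 1e-9 under row rescaling over 12 orders of
  magnitude) makes the choice immaterial.
- Entries are validated strictly positive before any log; there is no
  silent clipping. Errors name the offending sample and feature.
- A one-feature composition CLR-transforms to zero; permitted, logged as a
  warning.
- A pseudocount at or above the table's smallest positive entry is flagged
  in sweep output (`exceeds_data_scale`) but still computed.
- Row sums of relative tables are validated to 1e-9 at construction and
  1e-6 at per-row entry points (the looser bound tolerates accumulated
  float error in user-supplied rows).

## Problem sizes

The shipped suite and the acceptance script use: 50 seeds of the 100×31
counterexample; a 7-point pseudocount grid; 200 replicates each for the
cohort power, cohort null, and chain-recovery checks (40 samples × 50 taxa
× 10,000 reads); 500 instances for the exact-vs-asymptotic comparison and
2,000 replicates for the type-I calibration. These sizes give Monte-Carlo
standard errors comfortably inside every asserted band (e.g. a binomial
3σ band of ±0.046 around a 0.95 success rate at n=200) while keeping the
whole suite under half a minute.

## Known limitations

- The package demonstrates a mechanism; it does not validate or invalidate
  any particular published pipeline, and it deliberately omits voom-SNM,
  batch correction, classifiers, and scale-uncertainty models.
- The power-of-ten pseudocount rule and the CLR are one zero-handling
  convention among several; ALR/ILR and pseudocount-free zero-replacement
  methods are out of scope.
- Real-data reanalyses (vaginal microbiome, tumor-type tables) require
  external downloads; the package ships only their statistical emulator,
  so printed real-data values (e.g. a CLR-vs-diversity R of −0.62) are
  optional verification targets, not test assertions.
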