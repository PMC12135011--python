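# Methods

`lineagefit` analyses pooled fitness-competition experiments in which
barcoded lineages of two genotype classes — wild type and an
ivermectin-resistant GluCl triple mutant (*avr-14*; *avr-15* *glc-1*) — are
mixed, serially transferred through a drug gradient, and sequenced at every
transfer. This note records the models, the defaults and why they were
chosen, and what the synthetic-data generator does and does not emulate.

## Barcode classification

Lineage barcodes are engineered with constant bases among random positions
so the genotype class can be read off the sequence. A class template is a
degenerate string over {A, C, G, T, N}; a barcode matches when lengths agree
and every literal slot matches (case-insensitive). The defaults are
`NANNNTNTNNCNNNN` (mutant) and the 15-slot wild-type form `NNNCNNTNTNANNNN`.
The wild-type template also circulates in a 14-symbol form
(`NNNCNNTNTNANNN`); known wild-type exemplar barcodes are 15 bases and match
the 15-slot extension at every constant position, so that is the default,
with the 14-mer kept available (`WILDTYPE_PATTERN_PRINTED_14`). The two
defaults demand different bases at position 11 (C vs A), so no barcode can
match both; a barcode matching two user-supplied templates raises an error
rather than tie-breaking silently. Non-conforming barcodes are treated as
sequencing/preparation errors and excluded (with conserved counts in a
rejection log), not error-corrected: no Levenshtein clustering is attempted.
IUPAC codes beyond N are rejected at parse time.

## Serial-transfer model and simulator

One transfer ≈ one generation (`g = 1` by default, tunable). With
per-generation Malthusian coefficients `s_i`, frequencies propagate as

    x_i <- x_i * exp(g * s_i) / sum_j x_j * exp(g * s_j)

The simulator applies, per transfer: (i) this deterministic selection
update; (ii) in stochastic mode, a single multinomial founder draw of
`floor(bottleneck_fraction * census_N)` individuals (the 10% volumetric
transfer is the dominant drift source; growth back to census is not
modelled because only frequencies are observed); (iii) sequencing counts as
a multinomial draw of `read_depth` reads on the current frequencies
(deterministic mode rounds expectations instead). Defaults mirror the study
design: census 10^6, bottleneck 0.10, 5 transfers plus parental P0, 48
lineages per class, starting mixes of 10% wild type at 0 nM, 30% at 1 nM
and 50% at 2–5 nM, concentrations 0–5 nM with 3 replicates each plus 2
extra at 3 nM. Read depth per timepoint is not a published quantity and is
a free parameter (default 10^6).

Ground-truth mutant fitness follows the quadratic dose-response
`S(c) = 0.053 c^2 + 0.18 c − 0.5` with wild type pinned at `s = 0`. Around
the class mean, each mutant lineage deviates with sd `lineage_sd = 0.15`
and each replicate is shifted with sd `replicate_sd = 0.01`. These two
scales were fixed once, up front, from the reported dispersion of the
system: lineage-level scatter of this size implies an adjusted R² of ~0.95
for the quadratic under the study layout, consistent with the strong
reported fit, while keeping replicates as internally consistent as the
experiment's were. Whole-replicate failures (e.g. drug misapplication) are
emulated by `outlier_shifts`, an additive shift applied to every mutant
lineage of a chosen replicate.

What the generator does **not** emulate: PCR/amplification bias and
overdispersed sequencing noise (counts are exactly multinomial), de novo
mutation (none was observed over five transfers), age structure,
males/outcrossing, and concentration-dependent lineage variance (scatter is
homoscedastic in c). Passing tests therefore demonstrate correctness of the
estimators under the stated sampling model, not robustness to unmodelled
real-data artefacts.

## Fitness inference

Per-lineage selection coefficients are estimated from counts `r_i(k)` with
totals `R(k)` by maximising a Poisson read-count likelihood under one-step
conditional propagation anchored on the previous observed frequencies:

    xhat_i(k) = x_i(k-1) e^{g s_i} / sum_j x_j(k-1) e^{g shat_j}
    L_i(s_i)  = sum_k r_i(k) ln(R(k) xhat_i(k)) - R(k) xhat_i(k)

Numerical scheme: estimates are initialised from least-squares slopes of
`ln(x + eps)` over generations (`eps = 0.5/R(k)`, used only here), centred
to read-weighted mean zero; then Gauss–Seidel sweeps run a bounded 1-D
maximisation (`s` in [−5, 5], golden-section/Brent with tolerance well
below the 1e-6 convergence threshold on max |Δs|) for each lineage in turn.
During a lineage's 1-D step the normalising denominator (the population
mean-fitness term) is held fixed at the current estimates *including the
lineage's own contribution*; this makes the sweep's fixed point a
coordinate-wise stationary point of the joint likelihood (the update
condition is Σ_k (r − R·xhat) = 0), which is what the grid-search oracle
tests verify. Because the likelihood is invariant to a common shift of all
coefficients (only differences are identified by frequency data), the gauge
is pinned by re-centring the read-weighted mean to zero after every sweep.
Non-convergence after 100 sweeps and estimates pinned at a bound are
flagged with warnings, never silently accepted. Transitions from an
observed zero frequency carry no information and are skipped; interior
zeros in the response are handled natively by the Poisson term.

Quality control before estimation, applied identically to both classes:
lineages with parental (P0) count ≤ 10 are excluded
(`low_parental_count`; the count floor's timepoint scope is configurable to
any/total), and lineages with zero reads at the final transfer are excluded
as `not_surviving` — the operational form of a Wrightian fitness of
`w = e^s − 1 = −1` (extinction). If either class loses all its lineages the
replicate is unusable and an error is raised. Reported coefficients are
Malthusian; `FitnessEstimateSet.wrightian()` converts. Normalisation
subtracts the mean estimate over included wild-type lineages, making wild
type the zero reference exactly.

Observation noise is Poisson only — the simplest model with a tractable,
grid-checkable likelihood; the module boundary allows a richer likelihood
to be swapped in without touching the propagation or QC code.

## Dose-response analysis

The quadratic `S = a c² + b c + c0` is fitted by OLS on lineage-level
points (each retained mutant lineage is one observation), giving R²,
adjusted R², and F with df (2, n−3). Per-concentration summaries use an
explicit two-stage aggregation honouring the nesting of lineages within
replicates: replicate mean → unweighted mean of replicate means, with a
95% t-interval on the between-replicate standard error. This is a
dependency-free stand-in for a mixed-model LS-means analysis; for balanced
designs the point estimates coincide, and it is documented here as an
approximation rather than a re-implementation of REML. Outlier replicates
are flagged when a replicate's mean sits more than 3 robust SDs
(1.4826 × MAD of the other replicates' means) from the others' median;
with only three replicates this rule is deliberately permissive (false
flags are possible) because flags are advisory — every downstream fit takes
an explicit include/exclude list so expert judgment can override. The
neutrality crossover is the closed-form root of the fitted quadratic on the
concentration range; note that the root of the reported curve itself is
≈1.81 nM, whereas linear interpolation of LS-means between 1 and 2 nM gives
a similar value — both readings are provided
(`neutrality_crossover`, `interpolate_neutrality`).

## Developmental analysis

Adult fractions pool drops (`Σ adults / Σ total`) with Wilson score
intervals. Dose-response is a binomial GLM `logit p(c) = β0 + β1 c` per
genotype × timepoint, fitted by IRLS with drops as sampling units — a fully
specified approximation to the mixed-model analysis such data sometimes
receives, sufficient for the crossover estimate. Complete separation is
flagged and coefficients are reported clamped at ±50. The developmental
crossover is the root of `p_wt(c) − p_mut(c)` by Brent bisection
(tolerance 1e-6), equal to `(β0_wt − β0_mut)/(β1_mut − β1_wt)` when both
slopes differ.

The default generator truth for the 72 h assay is a wild-type logistic
through the observed endpoint fractions (63.1% adult at 0 nM, 3.4% at
5 nM) and a flat mutant response at the wild-type curve's 2.5 nM value —
placing the true developmental crossover at 2.5 nM. Per-drop totals are
Poisson around `n_per_drop`. The reproduction runs use 100 drops of ~100
animals per genotype × concentration so that binomial sampling error
(≈0.2 percentage points at the 3.4% endpoint) does not obscure the
underlying fractions being recomputed.

## Degenerate inputs, tie-breaks, tolerances

* Empty timepoints, rank-deficient regression designs (<3 distinct
  concentrations), groups with zero animals, and all-wildcard patterns are
  errors, not warnings.
* Frequency normalisation is enforced to Σ = 1 within 1e-12 after every
  update; the wild-type normalised mean is exactly 0 by construction.
* Identical logistic fits have no unique crossover (None, with a warning);
  a = b = 0 admits no neutrality crossover (error).
* Zero-MAD outlier comparisons (other replicates exactly equal) flag any
  deviation above 1e-9.
* Deterministic simulation mode ignores the seed for dynamics (the seed
  still fixes barcode sequences); stochastic mode is bit-reproducible per
  seed.

## Problem sizes used in tests and reproduction runs

The reproduction script (`scripts/acceptance.py`) simulates the full
20-replicate gradient at census 10^6 / depth 10^6 and runs inference on all
of it (~10 s); the test suite uses the same design for end-to-end checks,
smaller lineage counts (10–20) for repeated-replicate properties
(e.g. RMSE of the class-mean estimate over ~100 stochastic replicates at
census 10^5), and 1000 small neutral populations for the drift-unbiasedness
check. These sizes were chosen so the statistical assertions have ~3σ
margins while the whole suite stays fast.

## Known limitations

* Exact numerical agreement with other FitSeq implementations is not
  expected: noise model, regularisation and iteration details differ;
  agreement is asserted at the level of regression summaries.
* The two-stage LS-means and the per-genotype GLM are stand-ins for
  mixed-model analyses; with strongly unbalanced designs they will diverge
  from lmer/emmeans results.
* The Poisson observation model underestimates variance if sequencing
  counts are overdispersed; estimated coefficients remain consistent but
  their implicit precision is optimistic.
* Flank location in read extraction is exact substring match (optionally
  ≤1 mismatch); no quality-score use, no UMI handling, forward orientation
  by default.
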