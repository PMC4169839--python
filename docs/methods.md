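# Methods

## Model

Phenotypes of an introgression population are modelled as
`y = 1·β₀ + Z u + e`.  The design matrix `Z` is built by collapsing
markers whose donor-dosage columns are identical across the whole
population ("complete linkage disequilibrium") into donor segments;
only maximal runs of *consecutive* identical columns on one chromosome are
merged, so identical patterns on different chromosomes stay distinct and
positional interpretation of each effect is preserved.  An all-recipient
marker column belongs to no segment and breaks a run.  Segment spans are
the closed interval between the first and last member marker (no midpoint
extension — conservative and reproducible).  Dosage columns enter `Z`
as-is (0/1/2 zygosity coding, no centring or scaling).

Assumptions: genotypes are clean consensus calls in {0,1,2}; markers with
missing data are rejected (no imputation); exact column equality defines
complete LD, including for heterozygous calls in non-doubled-haploid
material — a coarser similarity rule would need phased data and is out of
scope.

## Estimators

* **LSQ**: `u = argmin ‖y − Zu‖²`, no intercept, requires full column
  rank.  `σ̂²ₑ = SSE/(N−S)`.  Per-segment contrasts `uᵢ = 0` are tested
  with F(1, N−S).
* **BLUP**: the mixed-model equations with an unpenalised intercept and a
  common ridge penalty `λ` on all segments.  When `λ` is not supplied it
  is estimated by REML: the restricted log-likelihood is profiled over
  `log₁₀ λ ∈ [−6, 6]` with bounded scalar minimisation (tolerance 1e-6,
  S-dimensional Woodbury algebra so each evaluation is O(S³)).  A profile
  optimum at an interval bound is used as-is with a warning; with weak or
  absent genetic signal REML legitimately drives `σ²ᵤ → 0` (λ at the upper
  bound) and all effects shrink to ~0.
* **RMLV**: stage 1 is the BLUP fit.  Each of `n_updates` passes (default
  1; unlimited iteration degenerates to hard sparsity) sets per-segment
  variances `σ²ᵢ = max(ûᵢ², ε·σ̂²ᵤ)` with relative floor `ε = 1e-6` and
  re-solves the ridge system with `λᵢ = σ̂²ₑ/σ²ᵢ`.  The residual variance
  is carried over from stage 1 rather than re-estimated, avoiding feedback
  between shrinkage and the noise estimate.  The variance rule is isolated
  in `update_segment_variances` so an alternative heteroscedastic update
  can be swapped in.

Because LSQ omits the intercept while BLUP/RMLV include it, raw effect
scales are method-dependent; comparisons across methods should be made on
detection decisions or on predictions, not on raw `û`.

## Significance

BLUP/RMLV effects are tested with a per-segment column-permutation test:
column *i* of `Z` is permuted `r` times, `uᵢ` is re-estimated *jointly*
with all other effects for each permutation, and
`p = (1 + #{|û_perm| ≥ |û_obs|}) / (1 + r)` (two-sided — donor alleles can
act in either direction; add-one keeps p strictly positive and valid).
Shrinkage factors are frozen at their observed-data values by default,
reducing each permutation to one linear solve; the r systems per segment
differ from the cached base system only in one row/column and are solved
in a single batched LAPACK call.  `refit_variances=True` restores full
REML/RMLV re-estimation inside every permutation (orders of magnitude
slower, and in our experiments not materially different).  Per-column RNG
streams derive from `(seed, column index)`, so each segment's p-value is
reproducible independently of iteration order.  Exact ties (the identity
arrangement) are counted via a 1e-9 *relative* tolerance on `|û_obs|`.

Raw p-values are adjusted with Holm's step-down procedure by default
(Hochberg and Bonferroni selectable, or none); `significant` means
adjusted p ≤ α.

**Resolution rule.**  The smallest attainable adjusted p is `S/(1+r)`
under Holm.  A protocol that is meant to declare significance at level α
must satisfy `(1+k)/(1+r) ≤ α/S` with headroom for at least `k = 1` tied
permutation; for S = 9 segments at α = 0.01 this means r ≥ 1799 (the
worked-example tests use r = 2000).  Conversely, at desk-scale r = 200 no
Holm-adjusted decision at α = 0.01 is possible for S > 2 — by
construction, not by lack of power.

**Granularity and replication.**  With line-mean phenotypes an ideal
library has single-carrier segments: the permuted column has a single
nonzero entry and the permutation null collapses to ≤ N atoms, so p can
never fall below ~1/N.  Likewise LSQ with `Z = 2·I` has zero residual
degrees of freedom.  Both analyses therefore operate on replicated *plot
values*: the default trial design uses 4 replicate plots per line plus
replicated recipient checks, with the design-matrix rows repeated per plot
(`DesignMatrix.expand`).  Analysing plot values rather than entry means
also keeps the pure experimental error in the model's residual variance,
which the tests then estimate faithfully; `adjust_plot_values` removes
fixed design-factor effects (location, year, replication, …) first when a
trial has such structure.

With collinear design columns (overlapping segments, S > N) the
permutation test is approximate and need not hold its nominal type-I error
— significant neighbours of a causal block ("leakage" false positives) are
expected and grow with signal strength.

## Synthetic populations and traits

The genome is 3 chromosomes × 120 cM with markers every 10 cM, registered
at bin midpoints (5, 15, …, 115 cM) so that donor-block boundaries
(multiples of the spacing) never fall on a marker and non-overlapping
blocks never share a boundary marker.

* *Ideal population*: 9 lines, each homozygous donor over one 40-cM block,
  blocks tiling the genome in line order; collapse yields exactly 9
  segments and `Z = 2·I₉`.
* *Overlapping population*: per line 1–3 homozygous blocks of 20–60 cM at
  random grid positions; a draw is accepted only if the collapsed segments
  outnumber the lines (S > N), at least one marker is carried by ≥ 2
  lines, and ≥ 95% of markers are covered.  The canonical fixture uses
  seed 2014 (21 segments, rank 9).

Traits are additive: `n_loci ∈ {2,4,6}` causal loci drawn uniformly over
the continuous genome and snapped to the nearest marker of their
chromosome (donor blocks are marker-delimited, so a gene between markers
is indistinguishable from one at the nearest marker; snapping also keeps
locus dosage and span-containment classification mutually consistent).
Each favourable allele is worth `donor_advantage/(2·n_loci)` units
(defaults 25 / 12.5 / 8.33 for a donor advantage of 100).  Environmental
noise is normal with line-mean variance `V̂_g(1−h²)/h²`; with `n_reps`
plots per line the per-plot variance is `n_reps` times that, so line means
retain the target h².  Architectures whose loci all fall in uncovered
regions (V̂_g = 0) are redrawn; a *supplied* zero-effect architecture (the
global-null calibration mode) uses unit noise variance instead, since the
h² rule is then undefined and calibration is scale-invariant.

## Power experiment

Per run: fresh architecture and noise, one fit and one test per method,
then classification: a causal locus counts as correctly detected when at
least one significant segment's span contains it (each locus at most
once); every significant segment containing no causal locus is one false
positive.  Rates are reported alongside raw sums (the sums depend on run
count).  The desk-scale profile is 300 runs with r = 200 permutations and
*unadjusted* per-segment p at α = 0.01 — false-positive rates are then
directly comparable to the nominal per-test type-I error, and the
adjusted variants are selectable; the full-scale profile (5000 runs,
r = 1000) uses the same code path behind `--full`.  LSQ is admissible only
on the ideal population (full column rank).  All randomness derives from
one seed via spawned generator streams; identical seeds reproduce results
exactly.

Observed behaviour at desk scale (seed 1, 300 runs, 2 loci): on the
overlapping population at h² = 0.5 RMLV detects ~16% of causal loci vs
~5% for BLUP; from h² = 0.5 to 0.9 the BLUP false-positive sum rises
steeply (14 → 313) while RMLV's rises far more slowly (67 → 257).  We did
not observe a regime in which the RMLV false-positive sum *decreases* with
heritability: leakage onto neighbours of causal blocks grows with signal
for both ridge methods, and the add-one empirical permutation test does
not fire heavily on noise at low h² under any of the protocol variants we
tried (α ∈ {0.01, 0.05}; Holm or none; 1–8 RMLV updates; frozen or
refitted shrinkage; 2–6 loci).

## Numerical choices

* Ridge systems are solved by Cholesky on the (intercept-augmented) normal
  equations; `λ = 0` falls back to least squares and demands full rank.
* Rank classification uses numpy's default singular-value tolerance
  `max(N,S)·eps·σ_max`.
* REML degeneracies (constant y) are guarded by clamping the profiled
  residual variance away from zero; RMLV variance floors keep every `λᵢ`
  finite.
* Text outputs use 17 significant digits so read/write round trips are
  exact; coordinates are real-valued cM, 0-based per chromosome, closed
  intervals.

## What the synthetic study does and does not show

The generator emulates clean, balanced introgression trials: exact dosage
calls, homozygous (doubled-haploid-like) donor blocks aligned to the
marker grid, independent normal plot errors, no genotype-by-environment
interaction, no epistasis or dominance, and an imposed (not bred) segment
layout.  Passing tests therefore demonstrate the statistical machinery —
estimability, shrinkage behaviour, calibration, relative power — not
robustness to marker errors, segregation distortion, population structure
or sister-line collinearity in real libraries, where permutation error
rates can exceed nominal levels.  Real-data prediction accuracy is outside
the test scope.

## Limitations

* Complete LD is exact column equality; noisy or missing genotypes must be
  cleaned upstream.
* The RMLV variance update is a two-pass plug-in rule, not a full
  variational or Bayesian treatment; alternatives (Bayesian regressions,
  heteroscedastic EM variants, kinship-based GBLUP) are deliberately out
  of scope.
* Plot-value adjustment fits fixed factor effects only; mixed-model
  adjustment is not implemented.
* The permutation test's nominal level is only approximate under
  collinearity, and any familywise-adjusted decision requires the
  resolution rule above.
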