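# Methods

`beadsig` analyzes Luminex antigen-bead assay data — sample × bead matrices of
median fluorescence intensity (MFI) — for pre-transplant risk assessment of
acute cellular rejection (ACR) after kidney transplantation. It implements and
contrasts two processing strategies for the same data:

1. **Conventional thresholding.** Serum profiles are normalized to a
   negative-control serum and converted to binary reactivity calls by an MFI
   threshold, then screened bead-by-bead with exact tests.
2. **Rank-normalized multiparameter classification.** Raw MFIs are replaced by
   their within-sample ranks and fed, untouched otherwise, to a Potential
   Support Vector Machine (P-SVM) evaluated by leave-one-out cross-validation
   (LOOCV) with label-permutation significance and ROC/AUC.

## Conventional processing

Normalization has two conventions, both exposed:

- **background ratio** (mixed-antigen screening, MAB): sample MFI divided by
  the negative-control MFI per bead; a bead is positive when the ratio
  strictly exceeds 3;
- **baseline normalization** (single-antigen, SAB): negative-control MFI
  subtracted per bead, floored at 0; a bead is positive when the normalized
  MFI strictly exceeds either a fixed cut (default 1000 MFI) or a per-sample
  adaptive cut at 30% of that sample's strongest bead.

"Exceeds" is read as strict inequality (`>`) everywhere; the boundary cases
are pinned by tests. Binary screening uses a two-sided Fisher exact test per
bead (scipy's 2×2 implementation) with Benjamini–Hochberg adjustment across
beads; "significant" is defined on the raw p at 0.05, mirroring common
screening practice, and both raw and adjusted values are reported.

Baseline cohort tables use the Mann-Whitney U test for metric variables and
chi-squared or Fisher exact tests for categorical ones. The r×c Fisher test is
a full enumeration of tables with the observed margins under the classic
probability-ordering two-sided definition (sum of probabilities of tables no
more probable than the observed, with a 1 + 1e−7 relative comparison
tolerance). This convention was chosen deliberately: it is the one R's
`fisher.test` implements and the one under which the 2×3 HLA-DR mismatch
example reproduces its published rounding; scipy 1.15+ offers an r×c Fisher
test with a different two-sided convention that does not.

Confounder scans correlate median-centered bead MFIs (per-bead across-sample
median subtracted) with a covariate by Spearman rank correlation, reporting
mean ± sd across beads; a constant covariate is flagged degenerate and
reported as zero correlations rather than NaN.

## Rank normalization

Each serum profile's raw MFIs are replaced by their ranks 1..n_beads
(ascending, average ranks on ties). Ranking is **within-sample**: this is the
variant that acts as a between-sample normalization and makes the downstream
classifier invariant to any strictly increasing per-sample distortion of the
fluorescence scale (a property test drives random monotone maps through the
transform). Per-bead ranking across samples is available behind a flag.
Ranks are kept on the 1..n_beads scale, not rescaled to [0, 1], so that the
hyperparameter grids below retain their meaning for matching panel sizes.

## The P-SVM

The P-SVM is a linear classifier whose dual multipliers attach to *features*
(beads), giving built-in feature selection. With training matrix X column-
centered to Xc and labels y ∈ {−1, +1}, the multipliers solve

    min F(α) = ½ αᵀ(XcᵀXc)α − (Xcᵀy)ᵀα + ε‖α‖₁   s.t.  −C ≤ α_j ≤ C,

with offset b = mean(y). ε ≥ 0 is the L1 shrinkage (ε ≥ ‖Xcᵀy‖∞ gives the
all-zero model), C > 0 the box bound, and `epsitol` the termination tolerance,
interpreted as the maximal KKT (stationarity) residual of F at the returned
point — the only reading under which the conventional value 0.05 is a
tolerance. Decision values are d(u) = (u − means)ᵀα + b with training means
only (no test leakage); class calls are +1 iff d > 0, with d = 0 resolving to
−1 (documented tie-break). Zero-variance training columns get α_j = 0 by
construction.

The reference solver is cyclic coordinate descent with closed-form
soft-threshold-then-clip updates and an incrementally maintained gradient,
hard-stopped at 10⁵ sweeps with a convergence warning. Its optimality is
checked in the test suite against an independent generic QP solver
(split-variable L-BFGS-B) to 1e−6 in objective on dozens of random instances,
plus closed-form limits (ε = 0 / large C → least squares; large ε → zero).

Note that with epsitol = 0.05 the program's solution set is specified only up
to that tolerance; when n_samples < n_beads the Gram matrix is singular and
two certified solutions can differ in null-space components. All reported
results come from deterministic solvers, so runs are exactly reproducible.

## Evaluation

- **LOOCV**: every sample is predicted by a model trained on the remaining
  n − 1 samples, with column means recomputed per fold. Metrics are
  sensitivity, specificity and balanced accuracy BACC = (Sens + Spec)/2,
  kept at full precision internally and rounded to one decimal in reports.
- **Grid search**: LOOCV at every (C, ε) point; default grids are
  ε ∈ {0.25, 0.5, 0.75, 1} × C ∈ {1, 6} for SAB panels and
  ε ∈ {8, 9, 10, 11} × C ∈ {1, 6} for MAB panels; epsitol = 0.05 throughout.
  Best point = maximal BACC, ties broken toward smaller ε, then smaller C.
- **Permutation test**: the observed statistic is the grid-maximal BACC, and
  for each of n_perm (default 1000) seeded label permutations the FULL grid
  search is re-run, so selection over the grid is inside the null;
  p = (1 + #{null ≥ observed}) / (1 + n_perm), which is never zero.
- **ROC/AUC**: sorted decision values serve as boundaries (predict +1 iff
  d > boundary); endpoints (0,0) and (1,1) are appended. AUC is the
  Mann-Whitney pair-counting statistic with ties half-weighted, which equals
  the area under the step ROC exactly (asserted to 1e−12 in tests).

### The batched permutation engine

A permutation test at n = 52, 96 beads, 8 grid points and 1000 permutations
requires ~4×10⁵ P-SVM fits. Two structural facts make this tractable: the
LOOCV fold geometry (centering means, Gram matrices Q = XcᵀXc) depends only
on X, never on labels; and the ADMM x-update for the P-SVM program uses one
fixed matrix (Q + ρI)⁻¹ per fold. The engine therefore solves all
(fold × permutation × grid point) programs jointly by over-relaxed ADMM whose
iteration is a stack of small matrix products, with per-problem KKT
certificates (the same `epsitol` as the reference solver; certificates are
always evaluated in float64, while the x-update product runs in float32 for
speed), freezing of converged problems, warm starts down the ε ladder, and
reuse of large-C solutions for smaller C whenever they already lie inside the
smaller box. ρ defaults to 0.1·tr(Q)/m with halving restarts if an iteration
cap is hit. The permutation test computes observed and null statistics with
this identical procedure. `grid_search`/`loocv_decisions` default to the
coordinate-descent path; because of the tolerance-level solution
non-uniqueness noted above, the two paths may differ at the level the
certificate permits, which is immaterial for the exchangeability argument the
permutation p relies on.

## Synthetic cohorts

No clinical data ship with the package; a generator emulates the statistical
structure the method assumes:

- per-bead log-normal backgrounds, log10 MFI ~ N(2.0, 0.4) — positive,
  right-skewed, spanning decades, typical background ~100 MFI;
- per-cell multiplicative assay noise, log10 sd 0.25;
- a noise-free negative-control serum at the background level;
- class-independent strong reactivities (1–3 beads at 2000–5000 MFI in ~30%
  of samples), which push per-sample adaptive thresholds into the
  few-hundred-to-~1000 MFI range seen in practice;
- a sparse class signal: +0.25 log10 MFI (~1.8-fold) on 10 of 96 beads in
  ACR samples — additive on the log scale, i.e. multiplicative on MFI;
- class-independent covariates (age, BMI, HLA mismatch counts) in realistic
  adult-recipient ranges;
- default cohort size 34 ACR + 18 controls on a 96-bead panel.

The `weak_signal_scenario` uses exactly these defaults; by construction ≥ 90%
of signal-bead values in ACR samples stay below 1000 MFI after control
subtraction, so the class signal is essentially invisible to the fixed
threshold while remaining detectable in within-sample ranks. This is the
structure under which binarization provably loses information, and the
paired-seed comparison (rank vs fixed-threshold pipeline) reproduces the
qualitative ordering of the two strategies at desk scale. A truth record of
signal-bead identities is emitted so feature recovery can be scored.

What the generator does **not** emulate: HLA allele specificities, epitope
cross-reactivity between beads, donor-specific antibody structure, inter-lot
bead variation, or MFI saturation. Passing tests therefore demonstrate the
statistical machinery and the threshold-versus-rank information argument, not
clinical performance on real sera.

## Numerical choices and degenerate inputs

- Strict `>` at every threshold boundary; d = 0 predicts −1.
- Fisher enumeration uses log-gamma arithmetic and a 1 + 1e−7 relative cutoff.
- Missing values in input tables are rejected, not imputed.
- A sample with all-zero normalized MFIs makes the adaptive threshold
  undefined and raises; a constant covariate flags the confounder scan.
- Metrics are rounded only at the reporting layer.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs give bit-identical outputs.

## Problem sizes used in checks

The acceptance script and test suite run the full pipeline at the study's
cohort scale (52 × 96): 20 paired weak-signal cohorts for the rank-versus-
threshold comparison, a 999-permutation significance test on one cohort, and
100–200 null cohorts at 99 permutations each for type-I-error calibration —
sizes chosen so the whole suite completes comfortably on a single CPU while
keeping every estimate's Monte-Carlo error well inside the asserted bands.

## Known limitations

- The P-SVM solution is certified only to `epsitol`; with singular Gram
  matrices the decision values of alternative certified solutions can differ
  slightly. Fixing epsitol = 0.05 follows the evaluated configuration.
- The exact r×c Fisher enumeration is exponential in table size; it is meant
  for baseline-characteristics tables (a handful of rows/columns, n ≲ 200).
- The permutation p is conditional on the hyperparameter grid; changing the
  grid changes the null distribution.
- Odds-ratio confidence intervals, logistic covariate modeling, nested
  cross-validation and AUC confidence intervals are out of scope.
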