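# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generator, and the known limitations of `lmmcbp`.

## Model

At every electrode × time sample `(e, t)` of the epoched data the package
fits the linear mixed model

```
y_i = x_i' β(e,t) + b_subj(i)(e,t) + b_word(i)(e,t) + ε_i(e,t)
b_subj ~ N(0, σ²_s),  b_word ~ N(0, σ²_w),  ε ~ N(0, σ²)
```

with one observation per retained trial. The fixed design contains an
intercept, lexical (log) frequency, and per-sentence-type slopes for
logit predictability and ordinal word position. *Per-type slope coding*:
an interaction `Cont:Cat` expands to one column per level of `Cat`,
equal to the mean-centered continuous covariate on that level's trials
and zero elsewhere. The coefficients are then directly the within-type
slopes (e.g. the predictability effect inside common sentences), not
difference contrasts — matching how the per-term result maps are
reported. With mean-centered covariates the intercept map estimates the
grand-average ERP.

Word forms (the strings) are the levels of the word random factor:
repeated forms share an intercept. Random slopes, correlated random
effects and non-Gaussian responses are out of scope.

### Covariate transforms

Cloze predictability is a proportion of `n` respondents and reaches 0
and 1 in practice, where the logit diverges; the package smooths the
count before the transform, `p' = (raw·n + 0.5)/(n + 1)`, which keeps
the logit finite and strictly increasing on [0, 1]. Tercile
categorisation is rank-based with ties broken by stable input order, so
it is invariant under monotone transforms.

### Preprocessing filters

Baseline correction subtracts the per-trial per-electrode mean over the
half-open window [−100, 0) ms (the onset sample belongs to the
response). Epoch rejection removes a trial when **more than 5**
electrodes contain at least one sample with |amplitude| ≥ 80 μV (the
threshold is read as absolute amplitude; rejection is monotone in the
threshold). Word filters keep content words (adjective/verb/noun) of at
least three characters that are not sentence-initial.

## REML solver

Fitting ~10³–10⁴ samples, and refitting all of them for hundreds of
permutations, rules out calling a general mixed-model library per
sample. The built-in solver profiles both the fixed effects and the
residual variance out of the REML criterion analytically, leaving a
2-parameter problem in the log variance *ratios* `g_k = σ²_k/σ²`. All
linear algebra runs through the q × q mixed-model-equations system
`M = G⁻¹ + Z'Z` (q = number of random levels), so the per-candidate cost
is one Cholesky of `M` plus triangular solves, independent of the trial
count once the cross-products `X'X, Z'X, Z'Z` (shared by all samples)
and `[X Z]'y` (one matrix product for the whole grid) are formed.

The criterion is minimised by a bounded derivative-free **pattern search
on a successively refined lattice** (log-ratio spacing 2.0 halved down
to 1/32 over the box [−12, 8]) followed by a per-axis quadratic
interpolation through the final three-point stencil. Lattice candidates
are shared: each unique candidate is evaluated once, vectorised over all
samples that consider it. Design properties:

- a ratio pinned at the lower bound is treated as **exactly zero**
  variance — the factor is dropped from the system, so a fully-boundary
  fit reproduces ordinary least squares to machine precision; such fits
  are flagged `singular`, not errors;
- each sample's optimum depends only on its own response, never on the
  batch, and `fit_grid` always uses fixed 64-column chunks — blocked
  BLAS kernels give different last-bit results for different operand
  widths, so fixed chunking is what makes serial and parallel runs
  bitwise identical;
- a sample whose algebra fails falls back to OLS with status `fallback`
  and never aborts the grid.

The solver is validated against R's lme4 on a frozen crossed-design
fixture (estimates to ~1e-7 relative, SEs to ~1e-4, variance components
to ~5e-3) and against closed-form OLS at the zero-variance boundary.

Inference per coefficient is the Wald t (estimate/SE) with no
degrees-of-freedom correction; |t| > 2 is the per-sample significance
criterion (two-sided α ≈ 0.05 at the trial counts involved). The
cluster-level correction below does not depend on this calibration being
exact — the threshold only defines cluster membership, identically for
observed and permuted data.

## Clustering

Supra-threshold samples form clusters under the spatiotemporal relation:
two samples connect iff they share a time point and their electrodes are
adjacent, or share an electrode and are adjacent in time. No diagonal
links. Positive and negative samples never mix; components smaller than
2 samples are discarded ("at least two neighbours"); the cluster
statistic is the signed t-mass. Electrode adjacency comes from an
explicit edge list or is built from sensor coordinates (distance
threshold or planar Delaunay triangulation); a practical distance
default is 1.5 × the median nearest-neighbour spacing.

## Permutation inference

Each permutation draws a bijection on trial indices (a deterministic
function of seed and iteration, precomputed and applied identically at
every sample and in every worker) and reassigns every epoch a complete
covariate row, keeping the covariate correlation structure intact. The
`within_subject` scheme permutes only inside each subject's trials; the
`within_word` scheme only inside each word form's trials; a level with
one trial stays fixed — the only permutation consistent with the
constraint. The per-term null collects, for each permutation, the
maximal cluster mass; the default test is two-sided (maximum *absolute*
mass over both signs). Observed data are not added to the permutation
set; with zero exceedances the p-value is reported as the strict bound
1/N_P (the `add_observed` switch gives the (N+1)-convention instead).

### What each scheme protects — and the joint decision rule

A permutation test is exact only if the data distribution is invariant
under the permutation group. Trials within a subject are exchangeable
under the null **given no word-level structure**, and vice versa — but
with both random factors present, within-subject shuffling destroys the
cross-subject word-sharing pattern (word intercepts are constant across
the grid, so their leakage into the estimates shifts whole t-maps
coherently), and the subject-scheme null misses that source of observed
variability. This is a property of the published procedure, not of this
implementation: simulations in the test suite show the within-subject
scheme calibrated to its nominal level when word variance is zero, and
anti-conservative for word-tied covariates when it is not. The
practically meaningful guarantee — verified by the type-I acceptance
test — is for the **joint rule**: declare a term present only when it is
significant under *both* schemes, which is also how reliable effects are
reported. The `effective_shuffling_fraction` diagnostic flags
near-degenerate schemes (a corpus of mostly-unique words makes the
within-word scheme mostly swap a word's epochs between subjects, which
changes no fixed-effect column and yields a conservative null).

## Partial-effect removal

The predicted contribution of any subset of fitted coefficients is the
per-sample product of the design columns with the estimate maps;
removal subtracts it from the single-trial amplitudes. Predictions are
linear in the selection (union = sum, removal order commutes) and use
the already-fitted unpermuted estimates — no refit. Random-intercept
contributions are always retained; per-level random-effect removal is
out of scope. Refitting the same model on cleaned data returns
essentially exact zeros for the removed terms (the refit differs from
the algebraic zero only through re-estimated variance ratios).
Condition averages are computed subject-first (subject × condition cell
means, then grand mean), with across-subject standard errors as the
dispersion band.

## Classical baselines

The two-level windowed test is the Wilcoxon **signed-rank** test on
paired per-subject condition means (the matched-pairs reading of the
rank test; scipy's exact null when ties permit). The k-level test is
Kruskal–Wallis with tie correction. The pooled window regression adds
one indicator column per subject (reference dropped) and reports the
predictor's slope and its *partial* R² beyond the subject dummies. The
two-condition CBP reduces a continuous covariate to its outer terciles
(middle dropped), forms subject-level condition-mean difference maps,
tests them with a per-sample one-sample t, and builds the null by random
sign-flips of whole difference maps — the exact within-subject label
exchange for two conditions.

## Synthetic data

The generator emulates the data-generating structure the analysis
assumes, not neural biophysics:

- **Corpus** — `n_memory` + `n_common` sentences of 5–12 words. Latent
  predictability is 0.15 before and 0.85 from the Recognition Point on
  (memory-encoded), or ~0.35–0.6 with a mild positional increase
  (common); observed predictability is Binomial(`n_respondents`,
  latent)/n with `n_respondents = 18`, so raw 0s and 1s occur. The RP is
  recorded as the word with the maximal observed jump. Word forms are
  mostly corpus-unique with a configurable repetition tail of filler
  words; log frequency is N(3, 1) per form; part-of-speech tags are
  drawn so that roughly half the slots survive the content-word filter.
  Defaults (50 memory-encoded + 80 common sentences, 18 cloze
  respondents, 25 subjects) correspond to a full-scale reading study.
- **Epochs** — additive: ERP intercept template (N1–P2 morphology) +
  per-term spatiotemporal kernels × covariates (in exactly the
  analysis model's coding) + subject and word random intercepts +
  noise. The reference kernels place the predictability effect for
  common sentences on centro-parietal electrodes in a 300–450 ms
  window (positive: higher predictability attenuates the N400) and the
  position drift broadly across the scalp from ~170 ms onward,
  sustained. Noise is correlated across electrodes (exponential decay
  in sensor distance, length scale 0.6 head radii) and smoothly
  correlated in time (40 ms scale) — pure white noise would make
  spatiotemporal clusters unrealistically rare. Default SDs: subject
  2 μV, word 1.5 μV, residual 8 μV.
- All draws are deterministic in the seed; random draws happen before
  and independently of kernel values, so the generator is exactly
  additive across kernels at a fixed seed; the full ground truth is
  serialisable to JSON for recovery tests.

What the generator does **not** emulate: oscillatory content, ocular or
movement artifacts, volume-conduction forward models, non-Gaussian
amplitude distributions, autocorrelation between successive words of a
sentence beyond the shared covariates. Passing tests therefore show the
statistical machinery is correct under its own assumptions, not that
those assumptions hold for any particular recording.

## Problem sizes used in the test suite

Tests run the pipeline at desk scale; the sizes are the package's own
test-design choices. The type-I simulation uses 16 null replicates on a
6-electrode × 10-sample grid (5 subjects, 12 sentences, N_P = 40) with
the acceptance bound recomputed at that replicate count
(0.05 + 2·√(0.05·0.95/16)). The effect-recovery simulation uses a
12-electrode × 24-sample grid (6 subjects, 20 sentences, N_P = 80) with
injected amplitudes chosen by a power calculation so the half-maximum
kernel support is supra-threshold (t ≈ 3 at the support edge) — a
strong-effect regime appropriate for verifying recovered geometry, not
a claim about typical physiological effect sizes. The full-scale
128 × 103 grid is supported (it is the configuration whose 13,184
per-sample fits the bookkeeping test checks) but not exercised end to
end in the default suite.

## Known limitations

- Wald t with no Satterthwaite/Kenward–Roger correction: anti-
  conservative per sample at very small group counts; the cluster-level
  permutation calibration absorbs this for the corrected inference.
- One joint trial-label shuffle serves all model terms of a permutation
  pass; with strongly correlated covariates the per-term nulls are not
  independent across terms.
- Variance-ratio resolution is bounded by the search lattice and
  quadratic polish (~1e-4 relative in practice); t-values are insensitive
  at this level but exact likelihood values may differ from lme4 in the
  last digits.
- The within-word scheme is near-degenerate on corpora of mostly-unique
  words (by design it then mainly permutes subject assignment); its
  conservatism is reported, not corrected.
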