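# Methods

## The prediction model

Correlation-based regression compresses an *n* × *m* matrix **A** of
vectorized connectomes (subjects × edges, strict upper triangle of the
symmetric connectivity matrix, diagonal excluded) into one predictor score
per subject. The correlation vector **R** holds the sample Pearson
correlation of every edge column with the attribute vector **b**; the score
*S*ⱼ is the scalar product of subject row *j* with **R**; a univariate
ordinary-least-squares fit of **b** on *S* (attribute regressed on score,
since the score is used to *predict* the attribute) provides the
calibration applied to held-out subjects. The method has no tunable
hyperparameters: no edge selection, no regularization, every edge
contributes with its signed correlation weight.

Two index conventions are worth fixing explicitly: **A** is subjects ×
edges throughout, and *S*ⱼ = Σₓ *A*ⱼₓ·*R*ₓ (rows are subjects). Edge order
is lexicographic in (ROI-position *a*, ROI-position *b*) with *a* < *b*,
persisted with fitted models so predictions are well defined across files.

Consequences used as test invariants: **R** is invariant to positive
rescaling and per-edge shifts of the weights, and the OLS step absorbs the
scale and offset of *S*, so predictions are exactly invariant under a
global positive rescaling of all connectivity data and under adding a
constant to any edge column. Negating **b** negates **R**.

### Degenerate inputs

- A constant attribute makes every correlation undefined: hard error.
- An edge column with zero variance in training has no defined
  correlation; it receives R = 0 (equivalent to dropping it from the sum)
  and is recorded. This is the only convention that keeps *S* defined
  without changing *m* across folds.
- If *S* itself is constant (e.g. **R** ≡ 0), the model degenerates to
  predicting the training mean, with slope 0 and a logged warning rather
  than an error — a legitimate null model.
- Roundoff can push |r| infinitesimally past 1; values are clipped to
  [−1, 1].

## Evaluation

10-fold cross-validation with simple random folds (seeded permutation cut
into contiguous blocks differing in size by at most one; no
stratification). The *entire* model — correlation vector **and**
calibration — is refitted on the out-of-fold subjects for every fold, so no
test-fold information can flow into fitting; the suite verifies this
operationally by permuting a fold's attribute values and asserting that the
fold's own predictions are unchanged.

Metrics are pooled across folds: every subject is predicted exactly once,
giving one Pearson r (nominal two-sided p from the t distribution with
n − 2 degrees of freedom; no correction for the dependence induced by CV),
one MAE with its sample standard deviation (ddof = 1), and
NMAE = MAE / (max − min of the evaluated group's *actual* values). Using
the group's own observed range — rather than a nominal instrument range —
is forced by subgroup arithmetic: a female-only analysis must normalize by
the female range. Pooling rather than per-fold averaging is what the
paired-error tests require (one absolute error per subject); a
per-fold-averaged variant is exposed (`per_fold_metrics`) for comparison.

Sex-specific results are independent cross-validations *within* the
subgroup (refit), not post-hoc slices of the pooled run; subgroup quality
can therefore legitimately exceed or fall short of the total. The slicing
variant is kept available (`slice_cv_result`).

## Statistical comparison layer

Conditions sharing a subject set are compared by the two-sided Wilcoxon
signed-rank test on paired per-subject absolute errors. Conventions:
zero differences discarded before ranking (Wilcoxon's original
convention, effective n reported); exact null distribution for effective
n ≤ 25 without ties, otherwise the normal approximation with tie and
continuity corrections; all-zero differences give p = 1 with a degeneracy
flag. The computation is delegated to `scipy.stats.wilcoxon`; the test
suite pins the exact path against full 2ⁿ enumeration of sign patterns.

Each family of comparisons — all pairwise dataset comparisons for one
(attribute, subgroup), or the per-dataset crystallized-vs-fluid tests — is
corrected together by the Benjamini-Hochberg step-up procedure at
q = 0.05 (via `statsmodels`; the tests re-derive decisions from the
step-up definition independently). Note that BH adjusted p-values are not
idempotent in the strict sense: re-adjusting adjusted p-values can lose
rejections (it can never add any); decisions should always be taken from
one adjustment pass.

## Synthetic cohorts

Real structural-connectome cohorts (HCP young adults; ADNI-3 controls) are
restricted-access, so the generator states a minimal world with known
ground truth:

- **Attributes.** Truncated normals with the published descriptors — HCP:
  age 22–37 (mean 28.75, sd 3.68) and the three NIH-Toolbox composites;
  ADNI: age 56.5–91.5 (mean 74.43, sd 7.86); sex by independent draws at
  the published female fractions (564/1048, 54/94). Truncation is by
  rejection sampling so the stated mean/sd remain interpretable
  parameters (clipping would distort both).
- **Background edges.** A fixed random mask at `edge_density` (default
  0.3 — structural connectomes leave most ROI pairs unconnected), i.i.d.
  log-normal weights (σ = 1, median `base_weight_scale` = 100),
  independent of all attributes. Log-normal is a stand-in for the unknown
  marginal of streamline counts: nonnegative, right-skewed, heavy-tailed.
  It is a choice, not an inference about real data.
- **Signal edges.** Drawn uniformly without replacement from the upper
  triangle (disjoint across attributes; no spatial structure — the
  analysis never uses topology). Weight = offset + β(b − b̄) + ε with
  ε ~ N(0, noise_sd²) and β = ρ·noise_sd/(σ_b·√(1−ρ²)), which makes the
  population correlation with the attribute exactly `planted_rho` at any
  noise scale. The default noise_sd (100) matches `base_weight_scale` so a
  planted edge disperses like a background edge — necessary for the planted
  signal to be recoverable against m − k background edges, and what a real
  informative edge would look like. The offset sits 4 total-sd above zero
  so clipping to nonnegativity is a ~3·10⁻⁵-tail event; any clipping that
  still moves a realized correlation more than 10% off its analytic value
  is recorded as a warning in the ground-truth manifest rather than
  silently resampled.
- **Determinism.** (spec, seed) fully determines the cohort; stages draw
  from `SeedSequence(seed, spawn_key)` children, and the pipeline fans one
  global seed out the same way, so every stage is individually
  reproducible.

What a green test does **not** establish: the generator has no spatial or
topological structure, no site/motion confounds, no correlated attribute
noise, and a chosen (not measured) edge-weight marginal — so passing
recovery tests certify the *pipeline's* correctness on its stated world,
not performance on real cohorts. Desk-scale defaults (≈300 subjects,
20–30 ROIs) keep suites fast; they scale down the real regime (1048
subjects, 379 ROIs → 71 631 edges), where absolute r values would differ.

## Numerical choices

- Symmetry tolerance on load: 1e−8 absolute; asymmetric matrices are
  rejected (never silently symmetrized); nonzero diagonals are zeroed with
  a warning (some tools emit self-loops).
- Weights are used unnormalized — no density normalization or log
  transform — matching the model's definition on raw connection strengths.
- Matrix text formats round-trip bit-exactly (repr-precision floats,
  round-trip float parsing).
- Fold sizes: n mod k folds of size ⌈n/k⌉, the rest ⌊n/k⌋ (1048 at k = 10
  gives eight folds of 105 and two of 104).

## Known limitations

- The generator's linear-Gaussian signal cannot express nonlinear or
  interaction effects; CBR itself is linear, so this is matched to the
  model class, not to real biology.
- CV p-values are nominal; fold dependence means they are optimistic.
- With several attributes planted on disjoint edges, cross-attribute
  correlations in the cohort table are only approximately zero, so signal
  can bleed weakly between attributes at small n.
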