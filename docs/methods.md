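# Methods

This note documents the models, parameters and numerical choices behind
`psmem`, and what the synthetic data can and cannot show.

## Paradigm and design constraints

Each simulated participant has 24 objects, 8 per semantic room category
(kitchen, bathroom, bedroom), placed in a three-room apartment with a
corridor. The design generator deals the 8 objects of each category into
fixed counterbalancing slots — 4 congruent in the category's own room (2
task-relevant), and 4 incongruent split 1 task-relevant + 1 task-irrelevant
into each of the two other rooms — so every room holds 4 congruent + 4
incongruent and 4 task-relevant + 4 task-irrelevant objects, balanced for
category of origin, and every participant has exactly 6 incongruent
task-relevant and 6 incongruent task-irrelevant objects. These counts hold
by construction for any seed; the tests assert them over 1,000 seeds.

Apartment geometry is not fixed by the paradigm, so the package uses three
10×10 unit rectangles in a row plus a 30×3 corridor strip. All distance
measures (drop error, retrieved distance) are relative comparisons, so the
absolute scale is irrelevant; drop error is reported in these arbitrary
units. Room membership of a drop coordinate is boundary-inclusive with ties
going to the lower room index; drops in the corridor are classified as
"unrelated" (they cannot be episodic or semantic for any object).

The picture-viewing schedule per day is 2 sessions × 6 blocks × 24 objects
(12 presentations per object per day); `round(fly_rate × 288)` trials are
flagged as fly catch trials (default rate 0.05) and excluded from pattern
estimation.

## Synthetic pattern model

Patterns are built from shared latent components so every pairwise
correlation is available in closed form (documented in
`psmem/patterns.py`). The knobs that matter:

| parameter | default | meaning |
|---|---|---|
| `n_voxels` | 60 | ROI size (dimension of each pattern) |
| `category_effect` | 0.1 | latent correlation between same-category objects pre-encoding |
| `reorg_gap_congruent` / `_incongruent` | 0.2 / 0.4 | fraction of the pre-encoding latent replaced by fresh signal post-encoding |
| `group_reorg_shift` | 0.1 | reduction of the gap under cortisol (higher pattern retention) |
| `relevance_sim_boost` | 0.15 | extra post-encoding category loading for incongruent task-relevant objects |
| `noise_sd` | 1.0 | per-session observation noise (attenuates all correlations by 1/(1+σ²)) |

The observed same-category Pearson correlation is
`category_effect / (1 + noise_sd²)` and the pre-to-post self-correlation is
`sqrt(1 − gap) / (1 + noise_sd²)`; population Spearman values follow via
`(6/π)·asin(ρ/2)` for Gaussian data. The calibration test checks the
empirical mean over 200 seeds against this closed form within three
standard errors. The default gap ordering (incongruent > congruent, i.e.,
lower cross-day self-similarity for incongruent objects) is one of the two
plausible directions of the congruence effect; the knobs are signed so
either direction can be generated.

Behavior: every object receives a recognition outcome
(miss rate 0.23, matching roughly three quarters of objects recognized) and
a spatial-recall drop for all 24 objects — the recall task covers
unrecognized objects too, and the recognition filter is applied per
analysis downstream, because one analysis (incongruent-to-congruent
category means) deliberately retains unrecognized objects. Room choice for
incongruent objects is multinomial over (episodic, semantic, unrelated)
with defaults (0.70, 0.15, 0.15) for task-relevant and (0.40, 0.40, 0.20)
for task-irrelevant objects — an episodic advantage for task-relevant
objects and a semantic-over-unrelated bias for task-irrelevant ones, the
qualitative pattern the behavioral analyses are designed to detect. For
congruent objects the episodic and semantic rooms coincide, so the encoded
room is drawn with the combined probability. The drop position is anchored
at the true position (episodic choice) or the chosen room's centroid
(otherwise) plus isotropic Gaussian noise (sd 2 units, clipped to the
room). Confidence is a 1–100 logistic function of negative drop error
(midpoint 5 units, scale 3) plus Gaussian noise (sd 5); only its ordinal
use matters.

Time series for the GLM path: HRF-convolved boxcars (canonical double
gamma: shapes 6 and 16 s, undershoot ratio 1/6, peak-normalized) weighted
by per-voxel object amplitudes from the same latent model, plus linear
drift, white noise and a random-walk motion trace; spike volumes get a
permanent 2 mm translation step so framewise displacement flags exactly the
injected indices.

What the generator does **not** emulate: spatial autocorrelation and
physiological noise structure of real BOLD data, hemodynamic variability
across regions, scanner drift nonlinearity, realistic motion-artifact
coupling between signal and displacement, or inter-object visual
similarity within categories. Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the assumed
generative structure, not the empirical claims themselves on real data.

## Estimation choices

- FD = Σ|Δtranslation| + 50 mm·Σ|Δrotation| (50 mm head radius, the common
  convention); DVARS = RMS over in-mask voxels of the temporal difference;
  both 0 at the first volume.
- Outlier volumes: FD > 0.5 mm or robust z of DVARS (median/MAD) > 3. The
  published split-DVARS inference this stands in for has no published
  parameter set for this paradigm; the detector is a pluggable function.
- "Noise normalization" of betas is implemented as the univariate t map,
  β/(σ̂·design scale); plain betas remain available from the GLM result.
  The exact scaling used by SPM's residual matrix is an interpretation
  choice and is documented as such.
- An object whose every presentation in a run is fly-flagged has no
  regressor; its pattern is missing (NaN) for that run and propagates as
  missing similarity.

## RSA numerical choices

- Fisher z is applied before any averaging (run-order symmetrization,
  session crossings): z is the additive scale for correlations.
- Correlations are clipped to ±(1−10⁻⁷) before `atanh`; clip events are
  counted on the matrix object. Constant patterns give missing values,
  never zeros.
- Within-day matrices are symmetrized as the mean of the two run
  orderings; the diagonal of a within-day matrix is not a construct used by
  any analysis and is left undefined (NaN).
- MDS is classical (Torgerson) scaling of d = 1 − tanh(z), centered, with
  each axis flipped so object 0 has non-negative coordinates (a fixed
  orientation convention, since MDS is rotation/reflection-invariant).

## Group statistics

Mixed models are random-intercept models fit by REML (statsmodels MixedLM,
with the closed-form restricted likelihood of the random-intercept model
used to polish the optimum, since the generic optimizer occasionally stops
at the zero-variance boundary). Factors are coded sum-to-zero so each
term's F test is the type-III test. Denominator df use the Satterthwaite
approximation: the gradient of each contrast variance with respect to
(σ²_u, σ²_e) and the inverse REML Hessian (central finite differences),
with multi-column terms combined through the eigen-decomposition of the
contrast covariance and moment matching — the same construction lmerTest
uses, and the test suite pins the package to lmerTest's output on a frozen
fixture to four significant digits. Cohen's f² uses the marginal
(fixed-effects) R², `var(Xβ)/(var(Xβ)+σ²_u+σ²_e)`, of the full versus the
term-deleted model; the conditional-R² flavor would include the random
intercept in both and is deliberately not used, since the predictors of
interest are fixed effects. Singular fits (σ̂²_u = 0) are flagged on the
result, not raised. VIFs above 5 indicate collinearity and are reported
per column.

Wilcoxon signed-rank: zero differences dropped; V = sum of positive ranks;
exact p for n ≤ 25 without ties, else normal approximation with tie
correction. Holm: step-down with running maximum, capped at 1. Holm is
intentionally *not* claimed to be idempotent (it is not, in general).

## Searchlight and TFCE

Spheres use Euclidean distance in voxel units, boundary-inclusive, one per
in-mask voxel, dropped below `min_size` members (production defaults:
radius 6, min 20; the toy-scale tests use radius 2, min 10 on 10–12³
grids so the whole chain runs in seconds). Per sphere, dichotomous item
predictors give a t statistic across items (pairs for the category
contrast, objects for reorganization contrasts) plus the two level means;
continuous predictors give a Pearson correlation across items. Whether the
across-items unit is pairs or objects is pluggable behind one interface.

TFCE integrates `e(h)^0.5 · h² · dh` over thresholds (defaults of the
method's original recommendation; 6-connectivity), with `dh = max/100`
unless given; negative values are enhanced on the negated map. Voxels with
zero between-participant variance would give infinite t and are capped at
10⁶ — they can only arise in degenerate fixtures. Group inference flips
each participant's map with probability ½ per permutation and uses the
maximum enhanced statistic over voxels for FWE correction:
p(v) = (1 + #{perm max ≥ TFCE_obs(v)}) / (n_perm + 1). The minimum
attainable p is therefore bounded both by 1/(n_perm+1) and by the
2^-(n−1) probability of an all-equal sign assignment, which is why the
toy fixtures use ≥8 participants. Permutation counts: 5000 is the
production default; tests and the pipeline default use 60–200, which the
calibration test shows is already near-nominal at toy scale.

## Pipeline

The pipeline feeds RSA from directly simulated per-session patterns by
default; `estimation.use_glm_path = true` routes pattern extraction through
the synthetic time series and the GLM instead. The two paths are
statistically equivalent by construction (the GLM path's amplitudes come
from the same latent model), so the faster path is the default and the GLM
path is exercised by its own tests and example at small grid size. Stage
problem sizes in the defaults (12 participants, 60 voxels, 10³ searchlight
grid, 200 permutations) are chosen so a full run completes in well under a
minute; they are configuration, not constants.

All randomness flows from one global seed through named
`SeedSequence`-derived streams (stage × participant × day), so stages are
reproducible in isolation and two runs with the same configuration are
byte-identical on all tidy outputs.

## Known limitations

- Only random intercepts are supported in the mixed models (matching the
  analyses the pipeline implements); random slopes would need a different
  Satterthwaite machinery.
- The Holm families in the pipeline group by analysis; the exact family
  partition across the many models of a full study is a configuration
  choice.
- The searchlight assumes maps from all participants are already on a
  common grid (the simulation guarantees this; real data would be
  normalized upstream).
- TFCE step error is O(dh); the analytic single-voxel test quantifies it.
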