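# psmem

Pattern-similarity analysis of episodic versus semantic memory retrieval.

When people recall *where* they saw an object, correct episodic retrieval
competes with prior semantic knowledge: a toaster encountered in the
bathroom may later be "remembered" in the kitchen. `psmem` implements the
full analysis chain for a paradigm that probes this conflict with fMRI:
24 everyday objects from three semantic room categories are encoded in a
virtual three-room apartment, either in their expected room (congruent) or
elsewhere (incongruent), half of them task-relevant; voxel activation
patterns for each object are measured in picture-viewing sessions before
and after encoding, and spatial recall is scored on a bird's-eye map of the
apartment.

The package is a library first (see `examples/`), with a thin `psmem` CLI
for running the end-to-end pipeline. Everything is testable offline: a
first-class synthetic-data module generates designs, voxel patterns, 4D
time series and recall behavior with the statistical structure the
analyses assume.

## What it computes

**Pattern similarity (PS).** For patterns *a*, *b* over voxels,
`PS = atanh(ρ_s(a, b))` — the Fisher-z Spearman correlation (average ranks
for ties, correlations clipped to ±(1−10⁻⁷)). Four constructs:

- *PS pre / PS post*: object×object matrices correlating the two runs of a
  day, symmetrized over run order (276 unordered pairs for 24 objects);
- *PS change*: post − pre, entrywise;
- *pattern reorganization*: an object's cross-day self-similarity, the mean
  of the four Fisher-z pre-session × post-session self-correlations —
  lower values mean the post-encoding representation departed more from the
  pre-encoding one.

**Pattern estimation.** Voxelwise OLS with one HRF-convolved regressor per
object, a fly regressor, six motion parameters, spike regressors for
FD/DVARS outlier volumes, and drift; betas are noise-normalized to t values
(`t = β / (σ̂_resid · √[(XᵀX)⁻¹]_jj)`). Participant QC excludes runs with
more than three missed fly catch trials or objects with fewer than two
usable presentations per day.

**Behavioral scoring.** Drop error (Euclidean distance between retrieved
and true position), geometric room lookup of the drop coordinate, and
classification of each incongruent object's room choice as episodic /
semantic / unrelated, aggregated into semantic-bias proportions.

**Group statistics.** Random-intercept linear mixed models with
sum-to-zero (type III) contrasts, Satterthwaite denominator df, Cohen's
f² from marginal R², and VIF reporting; split-plot mixed ANOVA with
partial η²; Wilcoxon signed-rank tests; Holm step-down correction.

**Searchlight.** Spheres (Euclidean radius in voxel units, minimum member
count) are treated as small ROIs; per-sphere statistics across items feed a
group-level sign-flip permutation test with threshold-free cluster
enhancement, `TFCE(v) = Σ_h e(h,v)^E · h^H · dh` (defaults E = 0.5, H = 2,
6-connectivity), and max-statistic FWE-corrected p-values.

## Worked example

```sh
python examples/02_pattern_similarity.py
```

prints, for one simulated participant at default conditions:

```
pair rows per matrix: 276
pre-encoding Fisher-z similarity: same-category 0.053, different-category 0.014
cross-day self-similarity (reorganization z):
congruent
False    0.434226
True     0.446396
```

Same-category object pairs are more similar than different-category pairs
before encoding (the semantic-category structure of visual object
representations), and incongruently encountered objects show lower
cross-day self-similarity — more pattern reorganization — than congruent
ones. `examples/04_group_statistics.py` takes the same constructs through
the mixed model (the same-category effect at 20 participants:
F(1, 5499) = 269.1, p ≈ 5·10⁻⁵⁹, f² = 0.048), and
`examples/05_searchlight_tfce.py` recovers a planted category effect with
zero FWE false positives outside the planted region.

The full pipeline (`psmem all --seed 7 --out psmem_out`, or
`examples/06_full_pipeline.py`) writes tidy TSV tables, a searchlight
p-map, a markdown report and a hash manifest.

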