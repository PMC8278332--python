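# Methods

## The statistic: neural variability of connectivity profiles

For one participant, the cleaned ROI time series (volumes × nodes) is split
into nonoverlapping windows of 40 s (`WindowingSpec`; robustness set
{30, 40, 50} s). Window length in volumes is `floor(window_seconds / TR)`;
windows are anchored at the first retained volume and the trailing remainder
is dropped, so 145 volumes at TR = 2 s give seven 20-volume windows with 5
volumes discarded. Within each window the full node × node Pearson
functional-connectivity (FC) matrix is computed.

The neural variability of node *k* is

    NV_k = 1 − mean over window pairs (i, j), i ≠ j, of
               corr( F_{i,k}, F_{j,k} )

where `F_{i,k}` is node *k*'s whole-brain FC profile in window *i*. NV is 0
when the profile is identical across windows and 2 when profiles are
perfectly anti-correlated; high NV marks a node whose connectivity
fingerprint is unstable over time.

**Self-entry convention.** The *k*-th entry of `F_{i,k}` equals 1 in every
window. Sharing a constant entry mechanically inflates the window-pair
correlation, so by default the self-entry is removed, leaving length
n_nodes − 1 profiles; `include_self=True` selects the other convention. Both
are oracle-tested; on a 264-node parcellation the difference is ~1/264 of
the profile and does not change any qualitative result. No Fisher
z-transform is applied to FC entries before the profile comparison: the
statistic correlates raw coefficients.

## The feature: self-dependent neural variability (SDNV)

The moderator is interdependent self-construal: mean of the 12
interdependent Self-Construal Scale items minus mean of the 12 independent
items (range −6 to 6). The outcome is the life-satisfaction change score:
the 5-item Satisfaction with Life Scale sum (range 5–35) at the second
assessment minus the first. Participants missing the second assessment stay
in the cohort record but are excluded listwise from outcome analyses; no
imputation.

Per participant *s* and node *k*,

    SDNV_{s,k} = z(NV_k)_s · z(interdependence)_s

an interaction feature that is large and positive for interdependent
participants with variable nodes *and* for independent participants with
stable nodes. z-scores use the sample (n − 1) standard deviation; this
rescales SDNV values but leaves every correlation-based statistic unchanged.
A participant at the cohort mean of the moderator has an exactly zero SDNV
row; a constant NV column is flagged unusable and can never be selected.

## Prediction: leave-one-out cross-validation with feature selection

Each of the n complete cases is held out once (n = 58 in the reference
design → 58 iterations). On the training set:

1. **Selection** — Pearson correlation of each node's SDNV with the outcome;
   nodes with two-sided p < α (default 0.05; robustness {0.10, 0.05, 0.01})
   join the positive or negative feature set by the sign of r.
2. **Strengths** — positive strength = mean SDNV over the positive set;
   negative strength = mean of −SDNV over the negative set; total strength
   pools the sign-weighted SDNV over the union (`total_rule="pooled"`) or
   averages the two set strengths (`"averaged"`). The two rules coincide
   exactly when the sets have equal size; pooled is the default.
3. **Models** — simple linear regression of the outcome on each strength
   (total / positive / negative models), fitted on training participants
   only, then applied to the held-out participant.

Predictive power is the Pearson correlation between the n cross-validated
predictions and the observed outcomes; success requires it significantly
positive (two-sided p < 0.05 *and* r > 0). If any iteration produces an
empty feature set for a model, that model is skipped outright so every
reported model rests on the same number of iterations. Nodes selected in
strictly more than 95% of iterations are the important nodes, tracked per
sign.

**Partial mode** adjusts for the two main effects: selection uses the SDNV
coefficient of a per-node multiple regression (outcome ~ SDNV + NV +
interdependence), and the model stage regresses the outcome on strength, NV
strength (built from the same selected features with the same sign-weighted
averaging) and interdependence.

**Permutation inference** shuffles the outcome and reruns the entire
leave-one-out analysis (default 1,000 permutations). The p-value is the
add-one estimator p = (1 + #{null r ≥ observed r}) / (1 + #valid), one-sided
because only positive power counts as success. Permutations that hit the
empty-feature rule are excluded from the valid count and tabulated
separately.

**Network restriction** reruns the analysis within each network's node
subset, excluding the "uncertain" network; Benjamini–Hochberg FDR correction
is applied across the tested networks separately within each model family
(a documented configuration choice — the family definition is not dictated
by the procedure itself). A network needs at least two nodes.

**Leave-two-out** holds out every unordered pair with distinct outcomes
(tied observed pairs are excluded; C(58,2) = 1,653 pairs minus ties),
trains on the rest, and scores 1 when the predicted ordering matches the
observed ordering; tied predictions conservatively score 0. Mean accuracy is
compared against Binomial(n_pairs, ½) one-sided.

**Moderation (simple slopes)** fits y = b0 + b1·NVs + b2·Int + b3·NVs·Int
and reports the conditional NV slope b1 + b3·m at m = mean ± SD of the
moderator, with delta-method standard errors and normal-theory 95% CIs, in
both the raw and the z-scored-predictor parameterization (the raw slope is
per unit NV and therefore depends on the NV spread, which is small; the
standardized slope is the comparable quantity).

## Specificity battery

All controls reuse `loo_predict` itself, so differences can only come from
inputs: NV-only features (z-scored NV columns), substituted outcomes
(first/second assessment, place of origin treated as numeric 1–6, ethnic
identity), and the plain moderator–outcome correlation. Head motion is
screened with 12 per-participant summaries (six per-parameter maximum
absolute values; their overall/translation/rotation maxima; their
overall/translation/rotation sums) plus mean framewise displacement — 13
correlations with the outcome, uncorrected, since the desired pattern is
uniform non-significance. FD is Power-style: sum of absolute frame-to-frame
translation deltas plus rotation deltas converted to arc length on a 50-mm
sphere (radius configurable), rotations read as degrees by default.

## Synthetic cohorts

Real resting-state data for this design are not redistributable, so cohorts
are simulated with known ground truth.

*Time series.* Each participant has a base loading matrix (5 latent factors,
standard-normal loadings). Within every 40-s block the loadings of the
designated signal nodes are re-mixed toward a freshly drawn direction with
participant weight d_s ~ Uniform(0.2, 0.8) (rows renormalized to preserve
variance); non-signal nodes keep fixed loadings. Observation noise SD 0.5 on
unit-scale factor signal. Signal-node FC profiles therefore decorrelate
across windows at a rate governed by d_s, making NV monotone in d_s
(measured Spearman ≈ 0.98 between d_s and mean signal-node NV). Default
design: 58 participants, 264 nodes in 14 networks with atlas-like
proportions, 145 volumes at TR = 2 s; 20 default-mode nodes carry the
planted effect.

*Behavior.* A latent trait t_s ~ N(0,1) loads +0.8 on interdependent and
−0.8 on independent SCS items (item noise SD 0.9, responses rounded and
clipped to 1..7), giving scored-moderator–trait correlations ≈ 0.9.
First-assessment SWLS items are drawn independently of everything; the
second assessment is constructed so the change score equals
effect_size · z(d_s) · z(t_s) + N(0, noise_sd²), rounded onto the 5–35 item
sum. Place of origin (uniform 1–6) and ethnic identity (N(3, 0.5) clipped to
1–4) are independent fillers. Motion is a zero-mean random walk (step SD =
`magnitude` mm for translations, half that in degrees for rotations),
independent of the outcome.

*Calibration.* The defaults effect_size = 3.0, noise_sd = 4.6 were fixed by
the pre-build sweep in `scripts/calibration.py` as the pair putting the
measured correlation between mean signal-node SDNV and the outcome at
r ≈ 0.5 — a realistically strong brain–behavior effect for n = 58. At that
operating point the sweep measured total/positive-model success in ~91% of
replicates and mean signal-node recovery into the positive important set of
~0.84.

*Determinism.* One integer seed drives everything through a documented
stream-splitting rule: sub-stream b is `default_rng([seed, b])` (0 latents,
1 time series, 2 behavior, 3 motion, 4 atlas), per-participant streams
`[seed, b, s]`. Identical specs regenerate bit-identical cohorts, and blocks
can be regenerated independently.

*What the generator does not emulate.* No hemodynamics, no autocorrelation
spectra, no spatial smoothness, no realistic motion–signal coupling, no
demographic covariates. Passing tests therefore show that the estimator and
inference machinery behave correctly under the assumed statistical
structure — not that the effect exists in real cohorts.

## Numerical choices

- Leave-one-out selection and regression are computed by sufficient-statistic
  downdates (full-sample sums minus the held-out row), verified in the tests
  to match the explicit per-iteration path to ~1e-9.
- Correlation p-values use the exact t transform; perfectly correlated
  features get p = 0; zero-variance features get r = NaN and are barred from
  selection.
- FC matrices are symmetrized, clipped to [−1, 1], with the diagonal set to
  exactly 1; NV is clipped to [0, 2] against rounding excursions.
- Constant strength vectors in a training fold mark the model failed with a
  diagnostic rather than producing NaN predictions; a collinear moderation
  design is rejected with a condition-number message (threshold 1e8).
- "More than 95% of iterations" is strict inequality on the count.

## Problem sizes in the test suite

The acceptance tests run the full pipeline at the reference scale
(58 × 264 × 145). Replicate rates use a committed bank of 150 planted
cohorts (seeds 0–149); null calibration uses 100 null cohorts with 99
permutations each; behavior/motion-dependent specificity controls use the
first 30 bank cohorts. The null leave-two-out check compares the *mean*
accuracy across replicates with the central 95% Binomial(n_pairs, ½) band:
within one cohort the ~1,550 pair comparisons share fitted models, so
per-cohort accuracies spread wider than the binomial width even under the
null, while their mean is correctly centered.

## Known limitations

- The linear factor model yields FC distributions narrower than real rs-fMRI;
  absolute NV levels are not comparable with empirical values, only the
  between-participant ordering is meaningful.
- The skip rule censors null cohorts asymmetrically when the node pool is
  small (few candidate features); null calibration is therefore run at the
  full 264-node design.
- Ordinal outcomes (place of origin) are treated as numeric, mirroring the
  analysis being reproduced, not as a recommendation.
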