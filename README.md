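# sdnv — self-dependent neural variability prediction

`sdnv` is a Python package for asking whether the *temporal instability* of a
brain region's functional-connectivity profile, crossed with a person's
*self-construal*, predicts changes in their life satisfaction. It implements
the full analysis chain for resting-state fMRI cohorts — from cleaned ROI
time series to cross-validated prediction with permutation inference — plus
a synthetic-cohort generator with a planted, recoverable effect for
validating every stage.

It is aimed at researchers in functional connectomics and social/cultural
neuroscience who want a tested, reproducible implementation of
mesoscale dynamic-connectivity prediction (and a test bed for methods work
on it), without access to the original scans.

## The statistic and the model

For each node *k*, split the scan into nonoverlapping 40-s windows, compute
the whole-brain Pearson FC matrix per window, and define **neural
variability**

> NV_k = 1 − mean over window pairs (i ≠ j) of corr(F_{i,k}, F_{j,k})

where F_{i,k} is node *k*'s FC profile in window *i* (NV ∈ [0, 2]; 0 =
perfectly stable profile). With the interdependence score from the
Self-Construal Scale (mean interdependent minus mean independent item), the
**self-dependent neural variability** of node *k* is the interaction feature

> SDNV_k = z(NV_k) ⊙ z(interdependence)

per participant. Leave-one-out cross-validation then selects nodes whose
SDNV correlates with the life-satisfaction change score in the training set
(p < 0.05, sign-split into positive/negative sets), averages SDNV over the
selected nodes into feature strengths, regresses the outcome on each
strength, and predicts the held-out participant. Predictive power is the
correlation between cross-validated predictions and observed outcomes,
backed by permutation tests, network-restricted analysis with FDR
correction, leave-two-out ordering accuracy, moderation (simple-slopes)
analysis and a battery of specificity controls (NV-only features,
alternative outcomes, head-motion screens). See `docs/methods.md` for the
complete account.

## Worked example

```python
import numpy as np
from sdnv import (CohortSpec, generate_cohort, variability_map,
                  compute_sdnv, loo_predict, permutation_test)

# a 58-participant cohort with a planted effect on 20 default-mode nodes
cohort = generate_cohort(CohortSpec(seed=1))
nv = np.vstack([variability_map(ts).nv for ts in cohort.timeseries])
inter = cohort.behavior["interdependence"].to_numpy(float)
y = cohort.behavior["ls_change"].to_numpy(float)

sdnv = compute_sdnv(nv, inter)
perm = permutation_test(sdnv, y, n_perm=1000, seed=1)
total = perm.observed.models["total"]
print(f"iterations: {perm.observed.n_iterations}")
print(f"total model: r = {total.r:.3f}, p = {total.p:.2g}, "
      f"permutation p = {perm.p_values['total']:.4f}")
print(f"positive important nodes: "
      f"{len(perm.observed.important_nodes['positive'])}")
```

Output:

```
iterations: 58
total model: r = 0.522, p = 2.7e-05, permutation p = 0.0010
positive important nodes: 69
```

The 58 held-out predictions correlate with the observed change scores at
r = 0.52, and fewer than 1 in 1000 outcome shuffles reach that power. The
positive important-node set (selected in >95% of iterations) recovers 19 of
the 20 planted default-mode nodes; the extra members are moderator-coupled
bystanders — all SDNV columns share the z-scored interdependence factor, so
nodes whose NV happens to co-vary with the planted drift ride along, exactly
as whole-brain feature selection behaves on real data. On a null cohort
(`effect_size=0`) the same call gives a non-significant r and a roughly
uniform permutation p.

The same pipeline is scriptable from the shell:

```sh
sdnv simulate --n-participants 58 --seed 1 --out cohort/
sdnv run-prediction --timeseries-dir cohort/ --alpha 0.05 --window 40 \
    --n-perm 1000 --seed 1 --out results/
sdnv specificity --timeseries-dir cohort/ --seed 1 --out controls/
```

## Layout

| Module | Contents |
| --- | --- |
| `sdnv.variability` | windowing, per-window FC, neural variability |
| `sdnv.scales` | SCS / SWLS scoring, change scores, z-normalization |
| `sdnv.prediction` | SDNV, LOO engine, permutation, networks, leave-two-out, simple slopes |
| `sdnv.specificity` | NV-only and alternative-outcome controls, motion summaries, FD |
| `sdnv.synthetic` | cohort generator with planted interaction effect |
| `sdnv.io`, `sdnv.config`, `sdnv.cli` | TSV/CSV/JSON readers and writers, validated config, CLI |
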