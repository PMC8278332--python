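"""Synthetic rs-fMRI cohorts with a planted variability-by-self-construal effect.

Real resting-state cohorts for this analysis are not redistributable, so this
module generates cohorts that carry the statistical structure the pipeline
assumes, with known ground truth:

* **Time series** come from a latent factor model.  Each participant has a
  base loading matrix; within every nonoverlapping 40-s block the loadings of
  the designated *signal nodes* are re-mixed toward a freshly drawn direction
  with participant-specific weight ``d_s`` (the drift magnitude, uniform on
  ``drift_range``).  Connectivity profiles of signal nodes therefore decorrelate
  across windows at a rate controlled by ``d_s``, so their neural variability
  increases monotonically with it.  Non-signal nodes keep fixed loadings;
  everything gets i.i.d. observation noise.
* **Behavior**: a latent interdependence trait ``t_s`` drives the 24
  Self-Construal Scale items (loaded positively on the interdependent
  subscale, negatively on the independent one), so the scored difference
  correlates strongly with ``t_s``.  First-assessment SWLS items are drawn
  independently of everything; the second assessment is constructed so that
  the change score equals ``effect_size * z(d_s) * z(t_s) + noise`` (rounded
  onto the 5-35 item-sum scale).  Place of origin (1-6) and ethnic identity
  are independent fillers.
* **Motion**: zero-mean random-walk realignment traces, independent of the
  outcome.

One integer seed controls everything through a documented stream-splitting
rule: sub-stream ``b`` of a cohort is ``np.random.default_rng([seed, b])``
(0 = participant latents, 1 = time series, 2 = behavior, 3 = motion), with
per-participant streams ``[seed, b, s]``.  Regenerating from the same spec is
bit-identical, and each block can be regenerated independently.

The default ``effect_size``/``noise_sd`` pair was calibrated once by
simulation so that the measured SDNV of signal nodes correlates with the
outcome at about r = 0.5 in the population — the regime the predictive
analysis is designed to detect at n = 58.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import (SCS_INDEP_COLS, SCS_INTER_COLS, SWLS_T1_COLS, SWLS_T2_COLS,
                     change_scores, score_behavior)
from .variability import ROITimeSeries

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "generate_motion",
           "default_network_labels", "NETWORK_SIZES"]

#: Node counts per network mirroring the canonical 264-node functional atlas.
NETWORK_SIZES = {
    "default mode": 58,
    "visual": 31,
    "hand somatomotor": 30,
    "uncertain": 28,
    "frontoparietal": 25,
    "salience": 18,
    "cingulo-opercular": 14,
    "auditory": 13,
    "subcortical": 13,
    "dorsal attention": 11,
    "ventral attention": 9,
    "memory retrieval": 5,
    "mouth somatomotor": 5,
    "cerebellar": 4,
}

_N_FACTORS = 5          # latent factors per participant
_OBS_NOISE_SD = 0.5     # observation noise on unit-scale factor signal
_REDRAW_BLOCK_SECONDS = 40.0  # loading-redraw block, matching the default window


def default_network_labels(n_nodes: int) -> list[str]:
    """Assign network labels with atlas-like proportions, 'default mode' first."""
    labels: list[str] = []
    total = sum(NETWORK_SIZES.values())
    for name, size in NETWORK_SIZES.items():
        labels.extend([name] * max(1, round(size * n_nodes / total)))
    labels = labels[:n_nodes]
    while len(labels) < n_nodes:
        labels.append("uncertain")
    return labels


@dataclass
class CohortSpec:
    """Generating conditions for one synthetic cohort.

    Defaults mirror the study design the pipeline targets: 58 participants
    with complete outcomes, 264 nodes in 14 networks, 145 retained volumes at
    TR = 2 s.  ``signal_nodes`` (default: 20 default-mode nodes) carry the
    planted drift; ``effect_size`` scales the interaction term planted on the
    life-satisfaction change score.
    """

    n_participants: int = 58
    n_nodes: int = 264
    n_volumes: int = 145
    tr_seconds: float = 2.0
    network_labels: list[str] | None = None
    signal_nodes: np.ndarray | None = None
    effect_size: float = 3.0
    drift_range: tuple[float, float] = (0.2, 0.8)
    noise_sd: float = 4.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_nodes, self.n_volumes) <= 0:
            raise ValueError("cohort dimensions must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.network_labels is None:
            self.network_labels = default_network_labels(self.n_nodes)
        if len(self.network_labels) != self.n_nodes:
            raise ValueError("network_labels must have one entry per node")
        if self.signal_nodes is None:
            dmn = [i for i, lab in enumerate(self.network_labels) if lab == "default mode"]
            pool = dmn if len(dmn) >= 2 else list(range(self.n_nodes))
            self.signal_nodes = np.asarray(pool[:min(20, len(pool))])
        self.signal_nodes = np.asarray(self.signal_nodes, dtype=int)
        if self.signal_nodes.size and (self.signal_nodes.min() < 0
                                       or self.signal_nodes.max() >= self.n_nodes):
            raise ValueError("signal_nodes out of range")
        lo, hi = self.drift_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("drift_range must be ordered within [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        vpw = int(_REDRAW_BLOCK_SECONDS // self.tr_seconds)
        if self.n_volumes < 2 * vpw:
            raise ValueError(
                f"n_volumes={self.n_volumes} cannot form 2 windows of {vpw} volumes "
                f"at the default {_REDRAW_BLOCK_SECONDS:.0f}-s window; at least "
                f"{2 * vpw} volumes are required"
            )

    def participant_ids(self) -> list[str]:
        return [f"sub-{i + 1:03d}" for i in range(self.n_participants)]


@dataclass
class SyntheticCohort:
    timeseries: list[ROITimeSeries]
    behavior: pd.DataFrame
    motion: dict[str, np.ndarray]
    atlas: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec = field(repr=False, default=None)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _latents(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = _rng(spec.seed, 0)
    lo, hi = spec.drift_range
    d = rng.uniform(lo, hi, spec.n_participants)
    t = rng.standard_normal(spec.n_participants)
    return d, t


def _participant_timeseries(spec: CohortSpec, s: int, d_s: float) -> np.ndarray:
    rng = _rng(spec.seed, 1, s)
    q = _N_FACTORS
    base = rng.standard_normal((spec.n_nodes, q))
    base_norm = np.linalg.norm(base, axis=1, keepdims=True)
    vpw = int(_REDRAW_BLOCK_SECONDS // spec.tr_seconds)
    n_blocks = int(np.ceil(spec.n_volumes / vpw))
    sig = spec.signal_nodes
    rows = []
    for b in range(n_blocks):
        load = base.copy()
        if sig.size and d_s > 0:
            fresh = rng.standard_normal((sig.size, q))
            mixed = (1.0 - d_s) * base[sig] + d_s * fresh
            mixed_norm = np.linalg.norm(mixed, axis=1, keepdims=True)
            mixed_norm[mixed_norm == 0] = 1.0
            load[sig] = mixed / mixed_norm * base_norm[sig]
        n_t = min(vpw, spec.n_volumes - b * vpw)
        factors = rng.standard_normal((n_t, q))
        rows.append(factors @ load.T / np.sqrt(q))
    x = np.vstack(rows)
    x += _OBS_NOISE_SD * rng.standard_normal(x.shape)
    return x


def _swls_items_from_total(total: np.ndarray) -> np.ndarray:
    """Distribute integer totals in [5, 35] over 5 items in 1..7."""
    total = np.clip(np.round(total), 5, 35).astype(int)
    base, rem = np.divmod(total - 5, 5)
    items = np.tile(base[:, None] + 1, (1, 5))
    for i in range(items.shape[0]):
        items[i, :rem[i]] += 1
    return items


def _behavior(spec: CohortSpec, d: np.ndarray, t: np.ndarray) -> pd.DataFrame:
    rng = _rng(spec.seed, 2)
    n = spec.n_participants
    inter_items = np.clip(np.round(4 + 0.8 * t[:, None]
                                   + 0.9 * rng.standard_normal((n, 12))), 1, 7)
    indep_items = np.clip(np.round(4 - 0.8 * t[:, None]
                                   + 0.9 * rng.standard_normal((n, 12))), 1, 7)
    swls_t1 = np.clip(np.round(4.7 + rng.standard_normal((n, 5))), 1, 7)

    def _z(v):
        sd = v.std(ddof=1)
        if sd == 0:   # degenerate latent (e.g. drift_range width 0): no interaction term
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    change = spec.effect_size * _z(d) * _z(t) + spec.noise_sd * rng.standard_normal(n)
    swls_t2 = _swls_items_from_total(swls_t1.sum(axis=1) + change)
    origin = rng.integers(1, 7, n)
    ethnic = np.round(np.clip(rng.normal(3.0, 0.5, n), 1.0, 4.0), 2)

    table = pd.DataFrame({"participant_id": spec.participant_ids()})
    table[SCS_INTER_COLS] = inter_items.astype(int)
    table[SCS_INDEP_COLS] = indep_items.astype(int)
    table[SWLS_T1_COLS] = swls_t1.astype(int)
    table[SWLS_T2_COLS] = swls_t2.astype(int)
    table["origin"] = origin
    table["ethnic_identity"] = ethnic
    return change_scores(score_behavior(table))


def _atlas(spec: CohortSpec) -> pd.DataFrame:
    rng = _rng(spec.seed, 4)
    coords = np.round(rng.uniform(-70, 70, (spec.n_nodes, 3)), 1)
    return pd.DataFrame({
        "node_id": [f"node_{k + 1:03d}" for k in range(spec.n_nodes)],
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "network": spec.network_labels,
    })


def generate_motion(spec: CohortSpec, magnitude: float = 0.1) -> dict[str, np.ndarray]:
    """Random-walk realignment traces (mm / degrees), independent of the outcome.

    ``magnitude`` is the per-frame step SD in mm (rotations use half the step
    in degrees); 0 yields all-zero traces.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    motion = {}
    for s, pid in enumerate(spec.participant_ids()):
        rng = _rng(spec.seed, 3, s)
        steps = rng.standard_normal((spec.n_volumes, 6))
        steps[:, :3] *= magnitude
        steps[:, 3:] *= 0.5 * magnitude
        steps[0] = 0.0
        motion[pid] = np.cumsum(steps, axis=0)
    return motion


def generate_cohort(spec: CohortSpec, motion_magnitude: float = 0.1) -> SyntheticCohort:
    """Generate a fully populated cohort; same spec -> bit-identical output."""
    d, t = _latents(spec)
    atlas = _atlas(spec)
    node_ids = atlas["node_id"].tolist()
    timeseries = [
        ROITimeSeries(data=_participant_timeseries(spec, s, d[s]),
                      tr_seconds=spec.tr_seconds,
                      participant_id=pid, node_ids=node_ids)
        for s, pid in enumerate(spec.participant_ids())
    ]
    behavior = _behavior(spec, d, t)
    motion = generate_motion(spec, magnitude=motion_magnitude)
    truth = pd.DataFrame({
        "participant_id": spec.participant_ids(),
        "drift": d,
        "latent_interdependence": t,
        "effect_size": spec.effect_size,
        "noise_sd": spec.noise_sd,
    })
    return SyntheticCohort(timeseries=timeseries, behavior=behavior, motion=motion,
                           atlas=atlas, truth=truth, spec=spec)
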