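"""Per-node neural variability from nonoverlapping windowed functional connectivity.

The statistic implemented here treats a node's whole-brain connectivity
profile as a fingerprint that may or may not be stable over time.  A cleaned
ROI time series (volumes x nodes) is split into nonoverlapping windows, a
full Pearson functional-connectivity (FC) matrix is computed per window, and
the neural variability of node k is

    NV_k = 1 - mean over window pairs (i, j), i != j, of
               corr(profile of k in window i, profile of k in window j)

so NV_k lies in [0, 2]: 0 when the profile is identical in every window, 2
when profiles are perfectly anti-correlated.  The default window length is
40 s (robustness set {30, 40, 50} s); 145 volumes at TR = 2 s therefore give
seven 20-volume windows with the 5-volume remainder dropped.

By default the node's self-entry (always exactly 1) is removed from its
profile before the window-pair correlation, since a constant shared entry
mechanically inflates agreement; pass ``include_self=True`` for the other
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROITimeSeries",
    "WindowingSpec",
    "WindowedFCStack",
    "NeuralVariabilityMap",
    "split_windows",
    "window_fc",
    "node_variability",
    "variability_map",
]


@dataclass
class ROITimeSeries:
    """One participant's cleaned signal matrix (volumes x nodes) plus TR."""

    data: np.ndarray
    tr_seconds: float
    participant_id: str = ""
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D volumes x nodes matrix")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError(f"time series for {self.participant_id!r} contains non-finite values")
        variances = self.data.var(axis=0)
        if (variances == 0).any():
            k = int(np.argmax(variances == 0))
            raise ValueError(f"node {k} has zero variance in participant {self.participant_id!r}")
        if self.node_ids is not None and len(self.node_ids) != self.data.shape[1]:
            raise ValueError("node_ids length does not match the number of columns")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowingSpec:
    """Nonoverlapping windowing; length in seconds (default 40)."""

    window_length_seconds: float = 40.0
    scheme: str = "nonoverlapping"

    def __post_init__(self) -> None:
        if self.window_length_seconds <= 0:
            raise ValueError("window_length_seconds must be positive")
        if self.scheme != "nonoverlapping":
            raise ValueError("only the nonoverlapping scheme is supported")

    def volumes_per_window(self, tr_seconds: float) -> int:
        v = int(self.window_length_seconds // tr_seconds)
        if v < 2:
            raise ValueError(
                f"window of {self.window_length_seconds} s spans {v} volumes at "
                f"TR {tr_seconds} s; at least 2 are required"
            )
        return v


@dataclass
class WindowedFCStack:
    """Per-window node x node Pearson FC matrices (windows x nodes x nodes)."""

    fc: np.ndarray
    window_spec: WindowingSpec = field(default_factory=WindowingSpec)
    participant_id: str = ""

    @property
    def n_windows(self) -> int:
        return self.fc.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.fc.shape[1]


@dataclass
class NeuralVariabilityMap:
    """Per-node NV values for one participant, with the window spec used."""

    nv: np.ndarray
    window_spec: WindowingSpec = field(default_factory=WindowingSpec)
    participant_id: str = ""
    include_self: bool = False


def split_windows(ts: ROITimeSeries, spec: WindowingSpec | None = None) -> list[np.ndarray]:
    """Cut the scan into consecutive nonoverlapping windows; drop the remainder.

    Windows are anchored at the first retained volume; the trailing
    ``n_volumes mod volumes_per_window`` volumes are discarded.  Raises if
    fewer than two full windows fit, naming the minimum volume count.
    """
    spec = spec or WindowingSpec()
    vpw = spec.volumes_per_window(ts.tr_seconds)
    n_windows = ts.n_volumes // vpw
    if n_windows < 2:
        raise ValueError(
            f"{ts.n_volumes} volumes fit only {n_windows} window(s) of {vpw} "
            f"volumes; at least {2 * vpw} volumes are required"
        )
    return [ts.data[w * vpw:(w + 1) * vpw] for w in range(n_windows)]


def window_fc(segments: list[np.ndarray], spec: WindowingSpec | None = None,
              participant_id: str = "") -> WindowedFCStack:
    """Pearson FC matrix per window: symmetric, unit diagonal, entries in [-1, 1]."""
    mats = []
    for w, seg in enumerate(segments):
        seg = np.asarray(seg, dtype=float)
        if seg.shape[0] < 2:
            raise ValueError(f"window {w} has fewer than 2 volumes")
        var = seg.var(axis=0)
        if (var == 0).any():
            k = int(np.argmax(var == 0))
            raise ValueError(f"node {k} has zero variance within window {w}")
        m = np.corrcoef(seg, rowvar=False)
        m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(m, 1.0)
        mats.append(m)
    return WindowedFCStack(fc=np.stack(mats), window_spec=spec or WindowingSpec(),
                           participant_id=participant_id)


def node_variability(stack: WindowedFCStack, include_self: bool = False) -> NeuralVariabilityMap:
    """NV_k = 1 - mean pairwise window correlation of node k's FC profile.

    Profiles are the rows of each window's FC matrix; with
    ``include_self=False`` (default) the k-th entry is removed before the
    window-pair Pearson correlation, leaving length n_nodes-1 vectors.
    """
    fc = stack.fc
    n_w, n_nodes = fc.shape[0], fc.shape[1]
    if n_w < 2:
        raise ValueError("at least 2 windows are required")
    if include_self:
        profiles = fc.copy()  # (windows, nodes, nodes)
    else:
        mask = ~np.eye(n_nodes, dtype=bool)
        profiles = fc[:, mask].reshape(n_w, n_nodes, n_nodes - 1)

    centered = profiles - profiles.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)
    if (norms == 0).any():
        w, k = np.argwhere(norms == 0)[0]
        raise ValueError(f"node {k} has a constant FC profile in window {w}")
    unit = centered / norms[:, :, None]

    pair_sum = np.zeros(n_nodes)
    n_pairs = 0
    for i in range(n_w):
        for j in range(i + 1, n_w):
            pair_sum += np.einsum("kp,kp->k", unit[i], unit[j])
            n_pairs += 1
    nv = 1.0 - pair_sum / n_pairs
    nv = np.clip(nv, 0.0, 2.0)
    return NeuralVariabilityMap(nv=nv, window_spec=stack.window_spec,
                                participant_id=stack.participant_id,
                                include_self=include_self)


def variability_map(ts: ROITimeSeries, specs: WindowingSpec | list[WindowingSpec] | None = None,
                    include_self: bool = False) -> NeuralVariabilityMap | list[NeuralVariabilityMap]:
    """Full chain split -> window FC -> NV, for one or several window specs."""
    single = not isinstance(specs, (list, tuple))
    spec_list = [specs or WindowingSpec()] if single else list(specs)
    maps = []
    for spec in spec_list:
        segments = split_windows(ts, spec)
        stack = window_fc(segments, spec, participant_id=ts.participant_id)
        maps.append(node_variability(stack, include_self=include_self))
    return maps[0] if single else maps
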