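"""Readers and writers for the pipeline's on-disk formats.

Formats (all plain text):

* time series — one TSV per participant, volumes as rows, a header row of
  node ids matching the atlas;
* atlas — CSV with columns ``node_id, x, y, z, network``;
* behavior — CSV, one row per participant, fixed column names
  (see `sdnv.scales`), missing values as empty cells;
* motion — whitespace-delimited text, 6 columns per volume (translations in
  mm, rotations in degrees);
* reports — JSON summary plus per-iteration selection, strength, important
  node and permutation-null CSVs, deterministically ordered.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .prediction import MODEL_KINDS, PermutationResult, PredictionResult
from .scales import change_scores, score_behavior
from .specificity import MotionTrace
from .synthetic import SyntheticCohort
from .variability import ROITimeSeries

ATLAS_COLUMNS = ["node_id", "x", "y", "z", "network"]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    node_ids = ts.node_ids or [f"node_{k + 1:03d}" for k in range(ts.n_nodes)]
    pd.DataFrame(ts.data, columns=node_ids).to_csv(path, sep="\t", index=False,
                                                   float_format="%.10g")

def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas[ATLAS_COLUMNS].to_csv(path, index=False)

def write_behavior(behavior: pd.DataFrame, path: str | Path) -> None:
    behavior.to_csv(path, index=False)

def write_motion(params: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, params, fmt="%.10g")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort in exactly the layout `read_cohort` consumes."""
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(parents=True, exist_ok=True)
    for ts in cohort.timeseries:
        write_timeseries(ts, outdir / "timeseries" / f"{ts.participant_id}.tsv")
    for pid, params in cohort.motion.items():
        write_motion(params, outdir / "motion" / f"{pid}.txt")
    write_atlas(cohort.atlas, outdir / "atlas.csv")
    write_behavior(cohort.behavior, outdir / "behavior.csv")
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    return outdir


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path)
    missing = [c for c in ATLAS_COLUMNS if c not in atlas.columns]
    if missing:
        raise ValueError(f"atlas {path}: missing column(s) {missing}")
    if atlas["node_id"].duplicated().any():
        dup = atlas.loc[atlas["node_id"].duplicated(), "node_id"].iloc[0]
        raise ValueError(f"atlas {path}: duplicate node_id {dup!r}")
    return atlas


def read_timeseries(path: str | Path, tr_seconds: float, atlas: pd.DataFrame | None = None,
                    participant_id: str | None = None) -> ROITimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"{path}, line {int(r) + 2}, column {df.columns[c]!r}: "
                         f"missing or non-numeric cell")  # +2: header row, 1-based
    df = numeric
    if atlas is not None:
        unknown = [c for c in df.columns if c not in set(atlas["node_id"])]
        if unknown:
            raise ValueError(f"{path}: column {unknown[0]!r} absent from the atlas")
        missing = [n for n in atlas["node_id"] if n not in df.columns]
        if missing:
            raise ValueError(f"{path}: atlas node {missing[0]!r} missing from the header")
        df = df[list(atlas["node_id"])]
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from None
    return ROITimeSeries(data=data, tr_seconds=tr_seconds,
                         participant_id=participant_id or path.stem,
                         node_ids=df.columns.tolist())


def read_motion(path: str | Path, participant_id: str | None = None,
                rotation_unit: str = "degrees") -> MotionTrace:
    params = np.loadtxt(path)
    if params.ndim == 1:
        params = params.reshape(1, -1)
    return MotionTrace(params=params, participant_id=participant_id or Path(path).stem,
                       rotation_unit=rotation_unit)


def read_behavior(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "participant_id" not in table.columns:
        raise ValueError(f"behavior {path}: missing participant_id column")
    if "interdependence" not in table.columns or "ls_change" not in table.columns:
        table = change_scores(score_behavior(table))
    return table


def read_cohort(datadir: str | Path, tr_seconds: float,
                rotation_unit: str = "degrees", expected_volumes: int | None = None):
    """Load and cross-validate a cohort directory written by `write_cohort`.

    Returns (timeseries list, behavior table, motion dict, atlas).  Headers
    must match the atlas node ids; motion volume counts must match the time
    series; participants missing the second assessment are loaded but flagged.
    """
    datadir = Path(datadir)
    atlas = read_atlas(datadir / "atlas.csv")
    behavior = read_behavior(datadir / "behavior.csv")
    timeseries, motion = [], {}
    for pid in behavior["participant_id"]:
        ts_path = datadir / "timeseries" / f"{pid}.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(f"no time series for participant {pid!r} ({ts_path})")
        ts = read_timeseries(ts_path, tr_seconds, atlas=atlas, participant_id=pid)
        if expected_volumes is not None and ts.n_volumes != expected_volumes:
            raise ValueError(f"{ts_path}: {ts.n_volumes} volumes, expected {expected_volumes}")
        timeseries.append(ts)
        mo_path = datadir / "motion" / f"{pid}.txt"
        if mo_path.exists():
            trace = read_motion(mo_path, participant_id=pid, rotation_unit=rotation_unit)
            if trace.params.shape[0] != ts.n_volumes:
                raise ValueError(f"{mo_path}: {trace.params.shape[0]} volumes, "
                                 f"time series has {ts.n_volumes}")
            motion[pid] = trace
    return timeseries, behavior, motion, atlas


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def write_report(result: PredictionResult, outdir: str | Path,
                 atlas: pd.DataFrame | None = None,
                 permutation: PermutationResult | None = None,
                 seed: int | None = None) -> Path:
    """Write the JSON summary and CSV side-tables for one prediction run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"config": {k: _jsonable(v) for k, v in result.config.items()},
                     "seed": seed, "models": {}}
    for kind in MODEL_KINDS:
        m = result.models[kind]
        if m.skipped:
            summary["models"][kind] = {"skipped": True, "reason": m.reason}
        else:
            summary["models"][kind] = {"skipped": False, "r": m.r, "p": m.p,
                                       "significant": m.significant}
    summary["important_nodes"] = {s: _jsonable(v) for s, v in result.important_nodes.items()}
    if permutation is not None:
        summary["permutation"] = {
            "n_perm": permutation.n_perm,
            "p_values": permutation.p_values,
            "n_skipped": permutation.n_skipped,
        }
        for kind in MODEL_KINDS:
            pd.DataFrame({"null_r": permutation.null_r[kind]}).to_csv(
                outdir / f"permutation_null_{kind}.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    pd.DataFrame([
        {"iteration": rec.iteration,
         "n_positive": rec.positive_set.size,
         "n_negative": rec.negative_set.size,
         "positive_nodes": ";".join(map(str, rec.positive_set)),
         "negative_nodes": ";".join(map(str, rec.negative_set))}
        for rec in result.selection_records
    ]).to_csv(outdir / "selection.csv", index=False)

    rows = []
    for sign, nodes in result.important_nodes.items():
        for k in nodes:
            row = {"node_index": int(k), "sign": sign,
                   "selection_fraction": float(result.selection_fraction[sign][k])}
            if atlas is not None:
                arow = atlas.iloc[int(k)]
                row.update({"node_id": arow["node_id"], "x": arow["x"], "y": arow["y"],
                            "z": arow["z"], "network": arow["network"]})
            rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "important_nodes.csv", index=False)

    preds = {"observed": result.observed}
    for kind in MODEL_KINDS:
        m = result.models[kind]
        if not m.skipped:
            preds[f"predicted_{kind}"] = m.predicted
    pd.DataFrame(preds).to_csv(outdir / "predictions.csv", index=False)
    return outdir
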