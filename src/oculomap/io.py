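"""File formats: gaze samples, events, maps, clusters, images, configs.

All formats are plain text.  Samples and events are comma-separated
with fixed headers; maps are whitespace-delimited matrices (rows = y)
with a JSON metadata sidecar; clusters are JSON; stimulus images are
8-bit grayscale PNG holding gray levels 1-256 (stored as value - 1).
Round trips are lossless to at least 9 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .events import Event, EventSequence, GazeRecording
from .fixmap import StatMap
from .pixel_test import Cluster, ClusterSet

__all__ = [
    "read_samples", "write_samples",
    "read_events", "write_events",
    "read_map", "write_map",
    "read_clusters", "write_clusters",
    "read_image", "write_image",
    "load_config", "config_hash",
]

SAMPLE_COLUMNS = ["trial_id", "t_ms", "x_px", "y_px", "pupil"]
EVENT_COLUMNS = ["trial_id", "kind", "onset_ms", "offset_ms", "x_px", "y_px", "duration_ms"]
_FLOAT_FMT = "%.9g"


def write_samples(recordings: Sequence[GazeRecording], path) -> None:
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "trial_id": rec.trial_id,
            "t_ms": rec.t,
            "x_px": rec.x,
            "y_px": rec.y,
            "pupil": rec.pupil,
        }))
    pd.concat(frames).to_csv(path, index=False, float_format="%.9g", na_rep="")


def read_samples(path, rate: float = 1000.0, px_per_deg: float = 25.0) -> List[GazeRecording]:
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False)
    missing_cols = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)} (line 1)")
    recs = []
    for trial_id, sub in df.groupby("trial_id", sort=False):
        t = sub["t_ms"].to_numpy(float)
        if np.isnan(t).any() or not np.all(np.diff(t) > 0):
            raise ValueError(f"{path}: non-monotone or missing time in trial {trial_id!r}")
        if sub[["x_px", "y_px"]].isna().any().any():
            raise ValueError(f"{path}: NaN gaze coordinates in trial {trial_id!r}")
        recs.append(GazeRecording(
            str(trial_id), t,
            sub["x_px"].to_numpy(float), sub["y_px"].to_numpy(float),
            sub["pupil"].to_numpy(float), rate=rate, px_per_deg=px_per_deg,
        ))
    return recs


def write_events(sequences: Sequence[EventSequence], path) -> None:
    rows = []
    for seq in sequences:
        for ev in seq:
            rows.append((seq.trial_id, ev.kind, ev.onset, ev.offset,
                         ev.x if ev.x is not None else "",
                         ev.y if ev.y is not None else "",
                         ev.duration))
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        path, index=False, float_format="%.9g")


def read_events(path, px_per_deg: float = 25.0, rate: float = 1000.0) -> List[EventSequence]:
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False)
    missing_cols = set(EVENT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)} (line 1)")
    out = []
    for trial_id, sub in df.groupby("trial_id", sort=False):
        events = []
        for row in sub.itertuples():
            x = None if pd.isna(row.x_px) else float(row.x_px)
            y = None if pd.isna(row.y_px) else float(row.y_px)
            events.append(Event(str(row.kind), float(row.onset_ms),
                                float(row.offset_ms), x=x, y=y))
        out.append(EventSequence(events, str(trial_id), px_per_deg, rate))
    return out


def write_map(m: StatMap, prefix) -> None:
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".txt"), m.grid, fmt=_FLOAT_FMT)
    meta = {k: v for k, v in m.meta.items()}
    meta.setdefault("width", m.shape[1])
    meta.setdefault("height", m.shape[0])
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=float))


def read_map(prefix) -> StatMap:
    prefix = Path(prefix)
    grid = np.loadtxt(prefix.with_suffix(".txt"))
    sidecar = prefix.with_suffix(".json")
    meta: Dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if meta.get("kind") == "smoothed" and "sigma_smooth_px" not in meta:
        warnings.warn(f"{sidecar}: no smoothing sigma recorded; assuming 10 px")
        meta["sigma_smooth_px"] = 10.0
    return StatMap(grid, meta)


def write_clusters(cs: ClusterSet, path) -> None:
    payload = {
        "z_crit": cs.z_crit,
        "shape": list(cs.shape),
        "clusters": [
            {"sign": c.sign, "peak_z": c.peak_z, "area_px": c.area_px,
             "pixels": c.pixels.tolist()}
            for c in cs.clusters
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_clusters(path) -> ClusterSet:
    payload = json.loads(Path(path).read_text())
    clusters = [
        Cluster(np.asarray(c["pixels"], dtype=int).reshape(-1, 2),
                c["sign"], float(c["peak_z"]), int(c["area_px"]))
        for c in payload["clusters"]
    ]
    return ClusterSet(clusters, float(payload["z_crit"]), tuple(payload["shape"]))


def write_image(img: np.ndarray, path) -> None:
    """Save gray levels 1-256 as an 8-bit grayscale PNG (stored as v-1)."""
    arr = np.clip(np.round(np.asarray(img, dtype=float)) - 1.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_image(path) -> np.ndarray:
    """Load a grayscale PNG back onto the 1-256 gray-level scale."""
    with Image.open(path) as im:
        if im.mode != "L":
            im = im.convert("L")
        return np.asarray(im, dtype=float) + 1.0


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
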