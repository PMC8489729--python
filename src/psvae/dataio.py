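"""Reading/writing frames, pose labels, configs and checkpoints.

HDF5 layout (one file per session):

* ``/trial_%04d/images``       uint8 or float32, (T, C, H, W)
* ``/trial_%04d/labels``       float64, (T, n_labels)
* ``/trial_%04d/likelihoods``  float64, (T, n_labels)
* ``/trial_%04d/neural``       float64, (T, n_neurons), optional
* root attribute ``session_id``

Pose CSVs follow the DeepLabCut convention: three header rows
(scorer / bodyparts / coords) with ``coords`` in {x, y, likelihood}.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import h5py
import numpy as np
import yaml

from .synthgen import LabeledTrial

__all__ = [
    "SplitAssignment", "LabelScaler",
    "load_pose_csv", "write_pose_csv",
    "zscore_labels", "make_splits",
    "write_session_h5", "load_session_h5",
    "load_config", "save_config",
    "save_checkpoint", "load_checkpoint",
]

# positional pattern within each consecutive block of 10 trials
_BLOCK_PATTERN = ["train"] * 8 + ["val", "test"]


@dataclass
class SplitAssignment:
    """Trial-index -> {train, val, test} assignment."""

    assignment: dict

    def indices(self, split: str) -> list:
        return [i for i, s in sorted(self.assignment.items()) if s == split]

    def __getitem__(self, trial: int) -> str:
        return self.assignment[trial]


def make_splits(n_trials: int) -> SplitAssignment:
    """Block data split: within every 10 consecutive trials, the first 8 are
    training, the next is validation, the next is test; a partial final block
    follows the same positional pattern."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return SplitAssignment({i: _BLOCK_PATTERN[i % 10] for i in range(n_trials)})


@dataclass
class LabelScaler:
    """Per-dimension affine scaler (z-scoring in original label units)."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, labels: np.ndarray) -> np.ndarray:
        return (labels - self.mean) / self.sd

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return scaled * self.sd + self.mean


def zscore_labels(labels: np.ndarray):
    """Individually z-score each label dimension (population sd).

    Returns ``(scaled, scaler)``. The caller is expected to fit this on
    training frames only and apply the returned scaler to validation/test
    labels. Raises on zero-variance dimensions (e.g. coordinates fixed by an
    alignment step), naming the offending dimension so the caller can drop it.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim != 2 or labels.shape[0] < 2:
        raise ValueError("labels must be (n_frames >= 2, n_dims)")
    mean = labels.mean(axis=0)
    sd = labels.std(axis=0)  # population (divide-by-n) convention
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"label dimension(s) {bad.tolist()} have zero variance; "
                         "drop fixed coordinates before z-scoring")
    scaler = LabelScaler(mean=mean, sd=sd)
    return scaler.transform(labels), scaler


# ---------------------------------------------------------------------------
# DeepLabCut-style pose CSV
# ---------------------------------------------------------------------------

def write_pose_csv(path, labels: np.ndarray, likelihoods: np.ndarray | None = None,
                   keypoint_names=None, scorer: str = "psvae") -> None:
    """Write labels (T, 2K) (+ per-keypoint likelihoods) as a DLC-style CSV."""
    labels = np.asarray(labels, dtype=np.float64)
    T, n_dims = labels.shape
    if n_dims % 2:
        raise ValueError("label matrix must have an even number of columns (x, y pairs)")
    K = n_dims // 2
    if keypoint_names is None:
        keypoint_names = [f"kp{k}" for k in range(K)]
    if likelihoods is not None:
        likelihoods = np.asarray(likelihoods, dtype=np.float64)

    header1 = ["scorer"] + [scorer] * (3 * K)
    header2 = ["bodyparts"] + [name for name in keypoint_names for _ in range(3)]
    header3 = ["coords"] + ["x", "y", "likelihood"] * K
    lines = [",".join(header1), ",".join(header2), ",".join(header3)]
    for t in range(T):
        row = [str(t)]
        for k in range(K):
            lk = 1.0 if likelihoods is None else likelihoods[t, 2 * k]
            row += [repr(float(labels[t, 2 * k])), repr(float(labels[t, 2 * k + 1])),
                    repr(float(lk))]
        lines.append(",".join(row))
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def load_pose_csv(path):
    """Parse a DeepLabCut-style pose CSV.

    Returns ``(labels, likelihoods, keypoint_names)`` with columns ordered
    (kp1_x, kp1_y, kp2_x, ...). The per-keypoint likelihood is expanded to
    both coordinates; missing likelihood columns default to 1.0.
    """
    with open(path) as f:
        lines = [ln.rstrip("\n") for ln in f if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: not a 3-header pose CSV")
    h1, h2, h3 = (ln.split(",") for ln in lines[:3])
    if h1[0] != "scorer" or h2[0] != "bodyparts" or h3[0] != "coords":
        raise ValueError(f"{path}: unknown header layout "
                         f"(expected scorer/bodyparts/coords rows)")
    coords = h3[1:]
    bodyparts = h2[1:]
    n_cols = len(coords)

    # column index per (keypoint, coord)
    kp_names: list = []
    col_map: dict = {}
    for i, (bp, c) in enumerate(zip(bodyparts, coords)):
        if c not in ("x", "y", "likelihood"):
            raise ValueError(f"{path}: unexpected coords entry {c!r}")
        if bp not in kp_names:
            kp_names.append(bp)
        col_map[(bp, c)] = i

    rows = []
    for r, ln in enumerate(lines[3:]):
        cells = ln.split(",")
        if len(cells) != n_cols + 1:
            raise ValueError(f"{path}: ragged row {r} "
                             f"({len(cells)} cells, expected {n_cols + 1})")
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as e:
            raise ValueError(f"{path}: non-numeric cell in row {r}: {e}") from None
    data = np.asarray(rows, dtype=np.float64)
    T = data.shape[0]
    K = len(kp_names)
    labels = np.empty((T, 2 * K))
    likelihoods = np.ones((T, 2 * K))
    for k, bp in enumerate(kp_names):
        labels[:, 2 * k] = data[:, col_map[(bp, "x")]]
        labels[:, 2 * k + 1] = data[:, col_map[(bp, "y")]]
        if (bp, "likelihood") in col_map:
            lk = data[:, col_map[(bp, "likelihood")]]
            likelihoods[:, 2 * k] = lk
            likelihoods[:, 2 * k + 1] = lk
    return labels, likelihoods, kp_names


# ---------------------------------------------------------------------------
# Session HDF5
# ---------------------------------------------------------------------------

def write_session_h5(path, trials, session_id: str = "S0",
                     images_dtype: str = "float32") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["session_id"] = session_id
        for i, tr in enumerate(trials):
            g = f.create_group(f"trial_{i:04d}")
            frames = tr.frames
            if images_dtype == "uint8":
                g.create_dataset("images", data=np.round(frames * 255).astype(np.uint8))
            else:
                g.create_dataset("images", data=frames.astype(np.float32))
            g.create_dataset("labels", data=tr.labels.astype(np.float64))
            g.create_dataset("likelihoods", data=tr.likelihoods.astype(np.float64))
            if tr.neural is not None:
                g.create_dataset("neural", data=tr.neural.astype(np.float64))


def load_session_h5(path):
    """Load a session file; uint8 images are divided by 255 on load."""
    trials = []
    with h5py.File(path, "r") as f:
        session_id = str(f.attrs.get("session_id", "S0"))
        for key in sorted(k for k in f.keys() if k.startswith("trial_")):
            g = f[key]
            frames = g["images"][()]
            if frames.dtype == np.uint8:
                frames = frames.astype(np.float32) / 255.0
            else:
                frames = frames.astype(np.float32)
            neural = g["neural"][()] if "neural" in g else None
            trials.append(LabeledTrial(
                frames=frames, labels=g["labels"][()],
                likelihoods=g["likelihoods"][()],
                session_id=session_id, neural=neural))
    return trials, session_id


# ---------------------------------------------------------------------------
# YAML config and checkpoints
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(path, model, config: dict, scaler: LabelScaler | None = None) -> None:
    """Single-file checkpoint: weights + config (and its hash) + label scaler."""
    arrays = model.state_arrays()
    meta = {"config": config, "config_hash": config_hash(config)}
    extra = {}
    if scaler is not None:
        extra["_scaler_mean"] = scaler.mean
        extra["_scaler_sd"] = scaler.sd
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays, **extra)


def load_checkpoint(path):
    """Returns ``(arrays, config, scaler_or_None)``; rebuild the model from the
    config and call ``model.load_state_arrays(arrays)``."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["_meta"]).decode())
        arrays = {k: npz[k] for k in npz.files
                  if k not in ("_meta", "_scaler_mean", "_scaler_sd")}
        scaler = None
        if "_scaler_mean" in npz.files:
            scaler = LabelScaler(mean=npz["_scaler_mean"], sd=npz["_scaler_sd"])
    return arrays, meta["config"], scaler
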