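"""Latent traversals and multi-session background swaps.

A traversal takes a base frame, computes its posterior means (no sampling),
then sweeps one chosen dimension across percentile values of that dimension's
training distribution while holding every other coordinate fixed, decoding a
frame at each step. Supervised dimensions are manipulated in label (pixel)
space through the invertible map y = D z_s + d and pulled back via
z_s = D^-1 (y - d), so e.g. a paw's horizontal position can be set in pixel
units; because D is invertible this is equivalent to manipulating z_s
directly. Unsupervised dimensions are manipulated directly in z_u.

A session swap re-decodes a frame's (z_s, z_u) with another session's
background latents z_b set to the per-dimension median of that session's
training frames.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hyperopt import extract_latents
from .model import PSVAE
from .training import TrialDataset

__all__ = ["TraversalSpec", "TrainingLatentStats", "collect_latent_stats",
           "traverse", "session_swap", "swap_latents", "save_frame_strip"]

DEFAULT_PERCENTILES = tuple(np.linspace(10, 90, 9))


@dataclass
class TraversalSpec:
    """What to traverse: ``target`` is ``("label", i)`` or ``("z_u", j)``.

    ``values`` overrides the percentile lookup with explicit target values
    (in label units for supervised targets, latent units otherwise).
    """

    target: tuple
    percentiles: tuple = DEFAULT_PERCENTILES
    values: tuple | None = None

    def __post_init__(self):
        kind, _ = self.target
        if kind not in ("label", "z_u"):
            raise ValueError("target kind must be 'label' or 'z_u'")
        p = np.asarray(self.percentiles, dtype=float)
        if p.size == 0 or np.any(p < 0) or np.any(p > 100) or np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be increasing values in [0, 100]")


@dataclass
class TrainingLatentStats:
    """Pooled training-set labels and latents for percentile lookups."""

    labels: np.ndarray | None          # (N, n_labels), model (z-scored) units
    z_u: np.ndarray | None             # (N, |z_u|)
    z_b_median: dict = field(default_factory=dict)  # session -> (|z_b|,)


def collect_latent_stats(model: PSVAE, dataset: TrialDataset) -> TrainingLatentStats:
    trials = dataset.split_trials("train")
    lat = extract_latents(model, trials)
    labels = np.concatenate([t.labels for t in trials], axis=0) if model.n_s else None
    z_u = np.concatenate([d["z_u"] for d in lat], axis=0) if model.n_u else None
    med = {}
    if model.n_b:
        by_sid = {}
        for d in lat:
            by_sid.setdefault(d["session_id"], []).append(d["z_b"])
        med = {sid: np.median(np.concatenate(chunks, axis=0), axis=0)
               for sid, chunks in by_sid.items()}
    return TrainingLatentStats(labels=labels, z_u=z_u, z_b_median=med)


def _base_latents(model: PSVAE, base_frame: np.ndarray):
    frames = base_frame[None] if base_frame.ndim == 3 else base_frame
    part, _, y_hat, _ = model.forward(frames, rng=None)
    z_s = part.mean_s.data[0] if part.mean_s is not None else None
    z_u = part.mean_u.data[0] if part.mean_u is not None else None
    z_b = part.mean_b.data[0] if part.mean_b is not None else None
    y = y_hat.data[0] if y_hat is not None else None
    return z_s, z_u, z_b, y


def _decode(model: PSVAE, z_s, z_u, z_b):
    z = np.concatenate([p for p in (z_s, z_u, z_b) if p is not None])
    frame = model.decode_frame(z[None]).data[0]
    return np.clip(frame, 0.0, 1.0)


def traverse(model: PSVAE, base_frame: np.ndarray, spec: TraversalSpec,
             stats: TrainingLatentStats):
    """Generate the traversal frame sequence for one dimension.

    Returns a dict with ``frames`` (n_steps, C, H, W), the swept ``values``,
    and ``base_recon`` — the base-frame reconstruction produced through the
    exact same label-transform code path (so a step whose target value equals
    the base value reproduces it bit for bit).
    """
    kind, idx = spec.target
    z_s, z_u, z_b, y_hat = _base_latents(model, base_frame)
    if kind == "label":
        if y_hat is None:
            raise ValueError("supervised traversal needs a label-trained model")
        if spec.values is not None:
            values = np.asarray(spec.values, dtype=float)
        elif stats.labels is not None:
            values = np.percentile(stats.labels[:, idx], spec.percentiles,
                                   method="linear")
        else:
            raise ValueError("supervised traversal needs training label statistics")
        base_recon = _decode(model, model.labels_to_latents(y_hat), z_u, z_b)
        frames = []
        for v in values:
            y_bar = y_hat.copy()
            y_bar[idx] = v
            frames.append(_decode(model, model.labels_to_latents(y_bar), z_u, z_b))
    else:
        if spec.values is not None:
            values = np.asarray(spec.values, dtype=float)
        elif stats.z_u is not None:
            values = np.percentile(stats.z_u[:, idx], spec.percentiles,
                                   method="linear")
        else:
            raise ValueError("unsupervised traversal needs training z_u statistics")
        base_recon = _decode(model, z_s, z_u, z_b)
        frames = []
        for v in values:
            z_bar = z_u.copy()
            z_bar[idx] = v
            frames.append(_decode(model, z_s, z_bar, z_b))
    return {"frames": np.stack(frames), "values": values, "base_recon": base_recon}


def swap_latents(z_b: np.ndarray, target_median: np.ndarray) -> np.ndarray:
    """Replace background latents with a session median (idempotent)."""
    out = np.broadcast_to(target_median, z_b.shape).copy()
    return out


def session_swap(model: PSVAE, frames: np.ndarray, target_session: str,
                 stats: TrainingLatentStats):
    """Re-render frames with another session's median background latents.

    Returns ``(generated_frames, swapped_latents)``; the pose subspaces
    (z_s, z_u) are untouched, so label predictions are identical before and
    after the swap.
    """
    if model.variant != "msps-vae":
        raise ValueError("session swaps require an msps-vae model")
    if target_session not in stats.z_b_median:
        raise ValueError(f"unknown session {target_session!r}; "
                         f"have {sorted(stats.z_b_median)}")
    part, _, _, _ = model.forward(frames, rng=None)
    z_s = part.mean_s.data if part.mean_s is not None else None
    z_u = part.mean_u.data if part.mean_u is not None else None
    z_b = swap_latents(part.mean_b.data, stats.z_b_median[target_session])
    z = np.concatenate([p for p in (z_s, z_u, z_b) if p is not None], axis=1)
    out = np.clip(model.decode_frame(z).data, 0.0, 1.0)
    return out, {"z_s": z_s, "z_u": z_u, "z_b": z_b}


def save_frame_strip(path, frames: np.ndarray) -> None:
    """Export a traversal as a horizontal PNG strip (first channel)."""
    import imageio.v3 as iio
    strip = np.concatenate([f[0] for f in frames], axis=1)
    iio.imwrite(path, (np.clip(strip, 0, 1) * 255).astype(np.uint8))
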