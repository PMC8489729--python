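"""Synthetic behavioral-video generator with known generative factors.

Emulates the data regime of head-fixed rodent video experiments: grayscale
frames organized into trials of contiguous frames, pose-style labels (x, y
keypoint coordinates) with per-frame likelihood scores, smooth AR(1) factor
dynamics, and — for the multi-session case — a static per-session background
texture. Every generated quantity is deterministic given the seed, and the
true factor traces are returned so recovery can be tested exactly.

Rendered scene:

* each *supervised* factor is a bright Gaussian blob whose 2-D center roams
  the left portion of the frame (so labels come in x, y pairs);
* each *unsupervised* factor modulates the intensity of a separate blob at a
  fixed position on the right side of the frame (an analogue of
  hand-engineered intensity features such as a whisker-pad crop);
* the session background is a static smoothed-noise texture added to every
  frame; frames are clipped to [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneSpec", "FactorTraces", "LabeledTrial",
    "generate_session", "generate_multisession", "render_background",
    "unsupervised_blob_center", "unsupervised_crop_slices",
]

LIKELIHOOD_THRESHOLD = 0.9  # pose-estimator confidence below this is "dropped"


@dataclass
class SceneSpec:
    """Parameters of the synthetic scene.

    All geometry is in pixels with the image-array convention: origin at the
    top-left, ``x`` = column index, ``y`` = row index, 0-based.
    """

    frame_size: int = 32
    n_supervised_factors: int = 2     # number of keypoints; labels are (x, y) pairs
    n_unsupervised_factors: int = 1
    label_noise_sd: float = 0.25      # pixels
    dropout_rate: float = 0.1         # fraction of frames with likelihood < 0.9
    ar_coef: float = 0.98             # AR(1) coefficient shared by all factors
    blob_sigma: float = 3.0           # supervised (keypoint) blob width, pixels
    unsup_blob_sigma: float = 3.5     # intensity-feature blob width, pixels
    background_amplitude: float = 0.3
    background_smoothness: float = 3.0
    background_seed: int = 0

    def validate(self) -> None:
        if self.frame_size < 16:
            raise ValueError(f"frame_size must be >= 16, got {self.frame_size}")
        for name in ("dropout_rate",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError(f"ar_coef must lie in (-1, 1), got {self.ar_coef}")
        if self.label_noise_sd < 0:
            raise ValueError(f"label_noise_sd must be >= 0, got {self.label_noise_sd}")
        # blob must fit inside the frame with room to move
        if 6.0 * self.blob_sigma >= self.frame_size:
            raise ValueError(
                f"blob_sigma={self.blob_sigma} renders a blob wider than the "
                f"{self.frame_size}px frame; reduce blob_sigma")


@dataclass
class FactorTraces:
    """Ground-truth factor values, retained for recovery tests."""

    supervised: np.ndarray    # (T, 2 * n_supervised_factors) pixel positions
    unsupervised: np.ndarray  # (T, n_unsupervised_factors) arbitrary units


@dataclass
class LabeledTrial:
    """One trial: frames plus pose labels and their likelihoods."""

    frames: np.ndarray       # (T, C, H, W) float32 in [0, 1]
    labels: np.ndarray       # (T, n_labels) pixel units
    likelihoods: np.ndarray  # (T, n_labels) in [0, 1]
    session_id: str = "S0"
    neural: np.ndarray | None = None  # optional (T, n_neurons)


def _stationary_ar1(rng: np.random.Generator, n_steps: int, n_dims: int,
                    coef: float) -> np.ndarray:
    """Zero-mean unit-variance stationary AR(1) traces, (n_steps, n_dims)."""
    innov_sd = np.sqrt(1.0 - coef ** 2)
    x = np.empty((n_steps, n_dims))
    x[0] = rng.normal(0.0, 1.0, size=n_dims)
    eta = rng.normal(0.0, innov_sd, size=(n_steps - 1, n_dims))
    for t in range(1, n_steps):
        x[t] = coef * x[t - 1] + eta[t - 1]
    return x


def unsupervised_blob_center(spec: SceneSpec, j: int = 0) -> tuple:
    """(x, y) pixel center of the j-th unsupervised (intensity) blob."""
    F = spec.frame_size
    x = 0.80 * F
    n = max(spec.n_unsupervised_factors, 1)
    y = F * (j + 1) / (n + 1)
    return (x, y)


def unsupervised_crop_slices(spec: SceneSpec, j: int = 0, half: int = 4) -> tuple:
    """Row/column slices of a crop around the j-th unsupervised blob."""
    cx, cy = unsupervised_blob_center(spec, j)
    F = spec.frame_size
    r0, r1 = max(int(cy) - half, 0), min(int(cy) + half, F)
    c0, c1 = max(int(cx) - half, 0), min(int(cx) + half, F)
    return slice(r0, r1), slice(c0, c1)


def render_background(spec: SceneSpec) -> np.ndarray:
    """The session's static additive background texture, (F, F) in [0, amplitude]."""
    return _render_background(spec)


def _render_background(spec: SceneSpec) -> np.ndarray:
    """Static per-session surround texture.

    The texture is suppressed in a soft window around each unsupervised
    (intensity-feature) blob so that between-session appearance differences
    live in the surround — as equipment/enclosure variation surrounds an
    animal — and do not add a session-specific offset to the intensity
    feature itself, which would make the unsupervised factor inherently
    session-identifying.
    """
    rng = np.random.default_rng(spec.background_seed)
    noise = rng.uniform(0.0, 1.0, size=(spec.frame_size, spec.frame_size))
    bg = gaussian_filter(noise, spec.background_smoothness, mode="wrap")
    bg = bg - bg.min()
    if bg.max() > 0:
        bg = bg / bg.max()
    yy, xx = np.mgrid[0:spec.frame_size, 0:spec.frame_size].astype(np.float64)
    keep = np.ones_like(bg)
    for j in range(spec.n_unsupervised_factors):
        cx, cy = unsupervised_blob_center(spec, j)
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        keep *= 1.0 - np.exp(-r2 / (2.0 * (1.6 * spec.unsup_blob_sigma) ** 2))
    return (spec.background_amplitude * bg * keep).astype(np.float64)


def _render_frames(spec: SceneSpec, sup_pos: np.ndarray, unsup_val: np.ndarray,
                   background: np.ndarray) -> np.ndarray:
    """Render (T, 1, F, F) frames from positions and factor values."""
    F = spec.frame_size
    T = sup_pos.shape[0]
    yy, xx = np.mgrid[0:F, 0:F].astype(np.float64)
    frames = np.broadcast_to(background, (T, F, F)).copy()
    for k in range(spec.n_supervised_factors):
        # each keypoint gets a distinct width/brightness so its identity is
        # visually unambiguous (as with real body parts)
        sig_k = spec.blob_sigma * (1.0 + 0.5 * k)
        amp_k = 1.0 / (1.0 + 0.45 * k)
        px = sup_pos[:, 2 * k][:, None, None]
        py = sup_pos[:, 2 * k + 1][:, None, None]
        frames += amp_k * np.exp(
            -((xx[None] - px) ** 2 + (yy[None] - py) ** 2) / (2.0 * sig_k ** 2))
    for j in range(spec.n_unsupervised_factors):
        cx, cy = unsupervised_blob_center(spec, j)
        amp = np.clip(0.5 + 0.3 * unsup_val[:, j], 0.05, 0.95)[:, None, None]
        frames += amp * np.exp(-((xx[None] - cx) ** 2 + (yy[None] - cy) ** 2)
                               / (2.0 * spec.unsup_blob_sigma ** 2))
    np.clip(frames, 0.0, 1.0, out=frames)
    return frames[:, None].astype(np.float32)


def _supervised_position_bounds(spec: SceneSpec) -> tuple:
    """Allowed (x_lo, x_hi, y_lo, y_hi) for supervised blob centers.

    The x-range stops short of the unsupervised blobs so the right-hand crop
    stays uncontaminated, mirroring how hand-engineered crop features are
    chosen away from tracked body parts.
    """
    F = spec.frame_size
    margin = 2.0 * spec.blob_sigma
    return (margin, 0.55 * F, margin, F - margin)


def generate_session(spec: SceneSpec, n_trials: int = 30, trial_len: int = 100,
                     seed: int = 0, session_id: str = "S0"):
    """Generate one session of labeled trials.

    Returns ``(trials, traces)`` where ``trials`` is a list of
    :class:`LabeledTrial` and ``traces`` a list of per-trial
    :class:`FactorTraces`. Deterministic given ``(spec, seed)``.
    """
    spec.validate()
    if trial_len < 10:
        raise ValueError(f"trial_len must be >= 10, got {trial_len}")
    rng = np.random.default_rng(seed)
    background = _render_background(spec)
    x_lo, x_hi, y_lo, y_hi = _supervised_position_bounds(spec)

    trials, traces = [], []
    for _ in range(n_trials):
        raw = _stationary_ar1(rng, trial_len, 2 * spec.n_supervised_factors, spec.ar_coef)
        # map unit-variance traces into the allowed box (x coords even, y odd)
        sup = np.empty_like(raw)
        sup[:, 0::2] = np.clip((x_lo + x_hi) / 2 + raw[:, 0::2] * (x_hi - x_lo) / 6, x_lo, x_hi)
        sup[:, 1::2] = np.clip((y_lo + y_hi) / 2 + raw[:, 1::2] * (y_hi - y_lo) / 6, y_lo, y_hi)
        unsup = _stationary_ar1(rng, trial_len, spec.n_unsupervised_factors, spec.ar_coef) \
            if spec.n_unsupervised_factors else np.zeros((trial_len, 0))

        frames = _render_frames(spec, sup, unsup, background)
        labels = sup + rng.normal(0.0, spec.label_noise_sd, size=sup.shape)

        like_kp = np.ones((trial_len, spec.n_supervised_factors))
        dropped = rng.uniform(size=like_kp.shape) < spec.dropout_rate
        like_kp[dropped] = rng.uniform(0.0, LIKELIHOOD_THRESHOLD, size=int(dropped.sum()))
        likelihoods = np.repeat(like_kp, 2, axis=1)  # one score per keypoint, both coords

        trials.append(LabeledTrial(frames=frames, labels=labels,
                                   likelihoods=likelihoods, session_id=session_id))
        traces.append(FactorTraces(supervised=sup, unsupervised=unsup))
    return trials, traces


def generate_multisession(spec: SceneSpec, n_sessions: int = 4,
                          per_session_trials: int = 10, trial_len: int = 100,
                          seed: int = 0):
    """Generate sessions sharing factor dynamics but with distinct backgrounds.

    Returns a list of ``(session_id, trials, traces)`` triples. Inter-session
    variation is purely the static background texture (distinct
    ``background_seed`` per session), the synthetic stand-in for variation in
    lighting, equipment and animal appearance.
    """
    if n_sessions < 2:
        raise ValueError(f"n_sessions must be >= 2, got {n_sessions}")
    sessions = []
    for s in range(n_sessions):
        s_spec = replace(spec, background_seed=spec.background_seed + 1000 * (s + 1))
        sid = f"S{s}"
        trials, traces = generate_session(
            s_spec, n_trials=per_session_trials, trial_len=trial_len,
            seed=seed + 7919 * s, session_id=sid)
        sessions.append((sid, trials, traces))
    return sessions
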