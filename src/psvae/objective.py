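"""Loss terms of the PS-VAE / MSPS-VAE objective.

The objective to *maximize* is

    L = L_frames + alpha * L_labels - L_KL-s - L_ICMI - beta * L_TC
        - L_DWKL - gamma * L_orth                       (PS-VAE)
    L = ... - delta * L_triplet  (instead of gamma term)  (MSPS-VAE)

with unit observation noise on frames and labels, so the log-likelihood
terms reduce to -1/2 sum-of-squares (additive constants dropped), summed over
pixels / label dimensions and averaged over the frames in the batch.

The three terms of the unsupervised KL decomposition

    KL[q(z_u | n) || p(z_u)] = ICMI + TC + DWKL

cannot be computed exactly under minibatching because the aggregate posterior
q(z) marginalizes over the whole dataset; they are estimated with the
minibatch Monte-Carlo approximation

    E_q(z)[log q(z)] ~= (1/M) sum_i log( (1/(N M)) sum_j q(z(n_i) | n_j) )

where q(z(n_i) | n_j) evaluates sample i under the posterior of batch member
j, M is the batch size and N the number of training frames. All batch sums of
densities are computed in log space via log-sum-exp. The estimated ICMI / TC /
DWKL can individually be negative on small batches; only the closed-form
supervised KL is guaranteed non-negative.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, logsumexp

__all__ = [
    "LossBreakdown", "frame_loglik", "label_loglik_masked", "kl_supervised",
    "kl_unsup_decomposition", "orth_penalty", "triplet_term",
    "aggregate_triplet", "total_objective",
]

LOG_2PI = float(np.log(2.0 * np.pi))
DEFAULT_LIKELIHOOD_THRESHOLD = 0.9


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _value(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)


@dataclass
class LossBreakdown:
    """Per-term values for one batch/epoch, plus the weights in force."""

    frames: float = 0.0
    labels: float = 0.0
    kl_s: float = 0.0
    icmi: float = 0.0
    tc: float = 0.0
    dwkl: float = 0.0
    orth: float = 0.0
    triplet: float = 0.0
    weighted_total: float = 0.0
    weights: dict = field(default_factory=dict)
    mse_per_pixel: float = 0.0
    mse_per_label: float = 0.0

    def recompute_total(self) -> float:
        """Recombine stored parts with stored weights (identity check)."""
        w = self.weights
        return (self.frames + w.get("alpha", 0.0) * self.labels
                - w.get("kl_s", 0.0) * self.kl_s
                - w.get("icmi", 0.0) * self.icmi
                - w.get("tc", 0.0) * self.tc
                - w.get("dwkl", 0.0) * self.dwkl
                - w.get("orth", 0.0) * self.orth
                - w.get("triplet", 0.0) * self.triplet)


def frame_loglik(x, x_hat):
    """Gaussian frame log-likelihood (unit variance, constants dropped).

    Returns ``(L_frames, mse_per_pixel)``: -1/2 the squared error summed over
    pixels and averaged over batch frames, plus the per-pixel MSE metric.
    """
    x_t, xh_t = _as_tensor(x), _as_tensor(x_hat)
    if x_t.shape != xh_t.shape:
        raise ValueError(f"frame shapes differ: {x_t.shape} vs {xh_t.shape}")
    B = x_t.shape[0]
    n_pix = int(np.prod(x_t.shape[1:]))
    sq = (x_t - xh_t) ** 2
    L = sq.sum() * (-0.5 / B)
    mse = float(sq.data.sum() / (B * n_pix))
    return L, mse


def label_loglik_masked(y, y_hat, likelihoods=None,
                        threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD):
    """Masked Gaussian label log-likelihood.

    Entries whose pose likelihood falls below ``threshold`` contribute exactly
    zero to both the value and the gradient (the model still produces label
    estimates there, interpolating through missing tracking).
    """
    y_t, yh_t = _as_tensor(y), _as_tensor(y_hat)
    if y_t.shape != yh_t.shape:
        raise ValueError(f"label shapes differ: {y_t.shape} vs {yh_t.shape}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    B, n_labels = y_t.shape
    if likelihoods is None:
        mask = np.ones((B, n_labels))
    else:
        mask = (np.asarray(likelihoods) >= threshold).astype(np.float64)
    # zero masked *residuals* before squaring so gradients vanish exactly
    sq = ((y_t - yh_t) * Tensor(mask)) ** 2
    L = sq.sum() * (-0.5 / B)
    n_kept = mask.sum()
    mse = float(sq.data.sum() / n_kept) if n_kept else 0.0
    return L, mse


def kl_supervised(mean, logvar) -> Tensor:
    """Closed-form KL( N(mean, diag exp(logvar)) || N(0, I) ), summed over
    dimensions and averaged over the batch."""
    m, lv = _as_tensor(mean), _as_tensor(logvar)
    if m.shape != lv.shape:
        raise ValueError("mean and logvar shapes differ")
    B = m.shape[0]
    kl = (m ** 2 + lv.exp() - 1.0 - lv) * 0.5
    return kl.sum() * (1.0 / B)


def _log_q_matrix(z: Tensor, mean: Tensor, logvar: Tensor) -> Tensor:
    """(M, M, L) tensor of log q(z_i,l | n_j): sample i under posterior j."""
    M, L = z.shape
    zi = z.reshape(M, 1, L)
    mj = mean.reshape(1, M, L)
    lvj = logvar.reshape(1, M, L)
    return ((zi - mj) ** 2 * (lvj * -1.0).exp() + lvj + LOG_2PI) * -0.5


def kl_unsup_decomposition(z, mean, logvar, dataset_size: int):
    """Minibatch estimators of (L_ICMI, L_TC, L_DWKL).

    ``z`` holds one posterior sample per batch member (each drawn from its own
    posterior), ``mean``/``logvar`` the posterior parameters, and
    ``dataset_size`` (N) the number of training frames. Satisfies exactly

        ICMI + TC + DWKL = (1/M) sum_i [log q(z_i | n_i) - log p(z_i)]

    since the log(N M) terms cancel, and the closed-form edge cases
    M=1 => ICMI = log N and L=1 => TC = 0.
    """
    z_t, m_t, lv_t = _as_tensor(z), _as_tensor(mean), _as_tensor(logvar)
    M, L = z_t.shape
    N = int(dataset_size)
    if N < M:
        raise ValueError(f"dataset_size N={N} must be >= batch size M={M}")
    log_NM = float(np.log(N * M))

    lq_dims = _log_q_matrix(z_t, m_t, lv_t)          # (M, M, L)
    lq_joint = lq_dims.sum(axis=2)                   # (M, M)
    diag = lq_joint[np.arange(M), np.arange(M)]      # log q(z_i | n_i)
    lse_joint = logsumexp(lq_joint, axis=1)          # log sum_j q(z_i | n_j)
    lse_dims = logsumexp(lq_dims, axis=1)            # (M, L)
    log_p_dims = (z_t ** 2 + LOG_2PI) * -0.5         # (M, L) standard-normal prior

    icmi = (diag - lse_joint).mean() + log_NM
    tc = (lse_joint - lse_dims.sum(axis=1)).mean() + (L - 1) * log_NM
    dwkl = (lse_dims - log_p_dims).sum(axis=1).mean() - L * log_NM
    return icmi, tc, dwkl


def orth_penalty(U) -> Tensor:
    """Squared Frobenius norm || U U^T - I ||_F^2 (U = [A; B] row-stacked)."""
    U_t = _as_tensor(U)
    n = U_t.shape[0]
    G = U_t @ U_t.T - Tensor(np.eye(n))
    return (G ** 2).sum()


def _pairwise_dist(a: Tensor, b: Tensor) -> Tensor:
    # sqrt offset keeps the gradient finite at zero distance
    return (((a - b) ** 2).sum(axis=1) + 1e-12).sqrt()


def triplet_term(anchor, positive, negative, margin: float = 1.0) -> Tensor:
    """Per-triplet hinge max{d(a, p) - d(a, n) + m, 0}, summed over rows."""
    a, p, n = (_as_tensor(t) for t in (anchor, positive, negative))
    if a.ndim == 1:
        a, p, n = (t.reshape(1, -1) for t in (a, p, n))
    return (_pairwise_dist(a, p) - _pairwise_dist(a, n) + margin).relu().sum()


def aggregate_triplet(zb_k, zb_j, margin: float = 1.0,
                      session_k=None, session_j=None) -> Tensor:
    """Aggregate triplet loss over two session batches of background latents.

    Each batch is split into three equally sized groups; anchors and positives
    come from one session, negatives from the other, and the symmetric term
    with the sessions swapped is added.
    """
    if session_k is not None and session_k == session_j:
        raise ValueError("triplet batches must come from two different sessions")
    k, j = _as_tensor(zb_k), _as_tensor(zb_j)
    Mk, Mj = k.shape[0], j.shape[0]
    if Mk != Mj:
        raise ValueError(f"session batches must be the same size, got {Mk} and {Mj}")
    if Mk % 3:
        raise ValueError(f"batch size {Mk} is not divisible into three groups")
    g = Mk // 3
    k1, k2, k3 = k[:g], k[g:2 * g], k[2 * g:]
    j1, j2, j3 = j[:g], j[g:2 * g], j[2 * g:]
    return triplet_term(k1, k2, j3, margin) + triplet_term(j1, j2, k3, margin)


def total_objective(terms: dict, variant: str, alpha: float = 0.0,
                    beta: float = 1.0, gamma: float = 0.0, delta: float = 0.0,
                    anneal: float = 1.0):
    """Combine per-term Tensors into the variant's weighted objective.

    ``terms`` maps term names (frames, labels, kl_s, icmi, tc, dwkl, orth,
    triplet) to Tensors (or floats for logging-only use). The annealing
    multiplier scales the KL terms and their decompositions toward their
    final weights (1 for KL-s/ICMI/DWKL, beta for TC); alpha, gamma and delta
    apply at full strength from the start. Returns
    ``(total, LossBreakdown)`` where ``total`` is the Tensor to maximize.
    """
    need = {
        "vae": ("frames", "kl_s"),
        "beta-tc-vae": ("frames", "icmi", "tc", "dwkl"),
        "ps-vae": ("frames", "labels", "kl_s", "icmi", "tc", "dwkl", "orth"),
        "msps-vae": ("frames", "labels", "kl_s", "icmi", "tc", "dwkl", "triplet"),
    }
    if variant not in need:
        raise ValueError(f"unknown variant {variant!r}")
    missing = [k for k in need[variant] if k not in terms]
    if missing:
        raise ValueError(f"variant {variant!r} requires loss terms {missing}")

    w = {
        "alpha": alpha if variant in ("ps-vae", "msps-vae") else 0.0,
        "kl_s": anneal if "kl_s" in need[variant] else 0.0,
        "icmi": anneal if "icmi" in need[variant] else 0.0,
        "tc": anneal * beta if "tc" in need[variant] else 0.0,
        "dwkl": anneal if "dwkl" in need[variant] else 0.0,
        "orth": gamma if variant == "ps-vae" else 0.0,
        "triplet": delta if variant == "msps-vae" else 0.0,
    }

    zero = Tensor(np.zeros(()))
    t = {k: _as_tensor(v) if not isinstance(v, Tensor) else v
         for k, v in terms.items()}
    total = (t["frames"]
             + w["alpha"] * t.get("labels", zero)
             - w["kl_s"] * t.get("kl_s", zero)
             - w["icmi"] * t.get("icmi", zero)
             - w["tc"] * t.get("tc", zero)
             - w["dwkl"] * t.get("dwkl", zero)
             - w["orth"] * t.get("orth", zero)
             - w["triplet"] * t.get("triplet", zero))

    breakdown = LossBreakdown(
        frames=_value(t["frames"]), labels=_value(t.get("labels", zero)),
        kl_s=_value(t.get("kl_s", zero)), icmi=_value(t.get("icmi", zero)),
        tc=_value(t.get("tc", zero)), dwkl=_value(t.get("dwkl", zero)),
        orth=_value(t.get("orth", zero)), triplet=_value(t.get("triplet", zero)),
        weighted_total=float(total.data), weights=w,
        mse_per_pixel=terms.get("mse_per_pixel", 0.0),
        mse_per_label=terms.get("mse_per_label", 0.0),
    )
    return total, breakdown
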