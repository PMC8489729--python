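"""The Partitioned Subspace VAE network and its variants.

A convolutional encoder ``f(x)`` maps frames to an embedding ``mu(x)`` whose
dimension equals the total latent dimension. Linear maps then carve the
embedding into subspaces:

* ``z_s = A mu(x) + noise`` — supervised latents, tied to pose labels through
  an invertible diagonal affine map ``y_hat = D z_s + d``;
* ``z_u = B mu(x) + noise`` — unsupervised latents, disentangled via the
  total-correlation decomposition of their KL term;
* ``z_b = C mu(x)`` — deterministic background latents (multi-session
  variant only), trained with a triplet loss to absorb static inter-session
  appearance.

Variance heads for the probabilistic subspaces are dense layers parallel to
the ``mu`` head on the shared convolutional trunk. The frame decoder ``g(z)``
mirrors the encoder with transposed convolutions and a final logistic
squashing so reconstructions live in [0, 1] like the normalized input frames.

Variants:

``vae``          one unstructured probabilistic latent block, closed-form KL
``beta-tc-vae``  adds the TC decomposition with weight beta, no labels
``ps-vae``       supervised + unsupervised subspaces, soft orthogonality (gamma)
``msps-vae``     adds deterministic background subspace; [A;B;C] is a frozen
                 orthonormal basis (QR of a seeded random matrix)

The convolutional stack uses 5x5 kernels at stride 2 with (1, 2, 1, 2)
padding so each layer exactly halves the spatial size; depth is chosen so the
pre-dense feature map is 4-8 px per side (5 layers at 192x192, 2 at 32x32),
with channels doubling from 32 and capped at 512.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["PSVAE", "EncoderOutput", "LatentPartition", "SubspaceMaps",
           "conv_depth_for"]

VARIANTS = ("vae", "beta-tc-vae", "ps-vae", "msps-vae")


def conv_depth_for(frame_size: int) -> int:
    """Number of stride-2 conv layers so the bottleneck map is ~4-6 px
    (5 layers at 192x192, 3 at 32x32)."""
    size, depth = frame_size, 0
    while size > 6:
        if size % 2:
            raise ValueError(
                f"frame size {frame_size} is not repeatedly halvable; "
                f"use a multiple of a power of two (e.g. 32, 64, 96, 192)")
        size //= 2
        depth += 1
    if size < 4 or depth < 1:
        raise ValueError(f"frame size {frame_size} too small for the conv stack "
                         "(need a bottleneck of 4-6 px after >= 1 halving)")
    return depth


@dataclass
class EncoderOutput:
    mu: Tensor               # (B, n_mu)
    logvar_s: Tensor | None  # (B, |z_s|)
    logvar_u: Tensor | None  # (B, |z_u|)


@dataclass
class LatentPartition:
    mean_s: Tensor | None
    mean_u: Tensor | None
    mean_b: Tensor | None
    logvar_s: Tensor | None
    logvar_u: Tensor | None
    z_s: Tensor | None
    z_u: Tensor | None
    z_b: Tensor | None      # deterministic, no sampled noise
    z: Tensor               # concatenation in (z_s, z_u, z_b) order


class SubspaceMaps(nn.Module):
    """Linear subspace machinery: projections A/B/C and the label map (D, d)."""

    def __init__(self, n_s: int, n_u: int, n_b: int, n_mu: int,
                 rng: np.random.Generator, frozen: bool):
        n_rows = n_s + n_u + n_b
        if n_rows > n_mu:
            raise ValueError("total latent dimension exceeds embedding dimension")
        q, _ = np.linalg.qr(rng.normal(size=(n_mu, n_mu)))
        basis = q.T[:n_rows]  # orthonormal rows
        self.A = nn.Tensor(basis[:n_s].copy(), requires_grad=not frozen)
        self.B = nn.Tensor(basis[n_s:n_s + n_u].copy(), requires_grad=not frozen)
        self.C = nn.Tensor(basis[n_s + n_u:].copy(), requires_grad=False)
        self.D_diag = nn.Parameter(np.ones(n_s))
        self.d = nn.Parameter(np.zeros(n_s))
        self.n_s, self.n_u, self.n_b = n_s, n_u, n_b

    def U(self) -> Tensor:
        """Row-stacked [A; B] used by the orthogonality penalty."""
        return nn.concat([self.A, self.B], axis=0)

    def full_basis(self) -> np.ndarray:
        return np.concatenate([self.A.data, self.B.data, self.C.data], axis=0)


class PSVAE(nn.Module):
    def __init__(self, frame_size: int = 32, n_channels: int = 1,
                 n_labels: int = 4, n_unsupervised: int = 2,
                 n_background: int = 3, variant: str = "ps-vae",
                 channel_base: int = 32, max_channels: int = 512,
                 seed: int = 0, dtype: str = "float32"):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.variant = variant
        self.frame_size = frame_size
        self.n_channels = n_channels
        self.n_s = 0 if variant in ("vae", "beta-tc-vae") else n_labels
        self.n_u = n_unsupervised
        self.n_b = n_background if variant == "msps-vae" else 0
        self.n_mu = self.n_s + self.n_u + self.n_b
        if self.n_mu < 1:
            raise ValueError("model needs at least one latent dimension")

        rng = np.random.default_rng(seed)
        depth = conv_depth_for(frame_size)
        chans = [min(channel_base * 2 ** i, max_channels) for i in range(depth)]
        self.bottleneck = frame_size // 2 ** depth
        self._chans = chans

        # encoder trunk
        self.enc_convs = []
        c_prev = n_channels
        for c in chans:
            self.enc_convs.append(nn.Conv2d(c_prev, c, 5, 2, (1, 2, 1, 2), rng))
            c_prev = c
        n_feat = chans[-1] * self.bottleneck ** 2
        self.mu_head = nn.Dense(n_feat, self.n_mu, rng)
        self.logvar_s_head = nn.Dense(n_feat, self.n_s, rng) if self.n_s else None
        self.logvar_u_head = nn.Dense(n_feat, self.n_u, rng) if self.n_u else None

        # subspace machinery ([A;B;C] frozen orthonormal in msps mode)
        self.maps = SubspaceMaps(self.n_s, self.n_u, self.n_b, self.n_mu, rng,
                                 frozen=(variant == "msps-vae"))

        # decoder
        self.dec_dense = nn.Dense(self.n_mu, n_feat, rng)
        self.dec_convs = []
        rev = list(reversed(chans))
        for i, c in enumerate(rev):
            c_out = rev[i + 1] if i + 1 < len(rev) else n_channels
            self.dec_convs.append(nn.ConvTranspose2d(c, c_out, 5, 2, (1, 2, 1, 2), rng))

        self.dtype = np.dtype(dtype)
        self.astype(self.dtype)

    # -- spec operations -----------------------------------------------------
    def encode(self, frames) -> EncoderOutput:
        """frames: (B, C, H, W) array or Tensor in [0, 1]."""
        x = frames if isinstance(frames, Tensor) else Tensor(
            np.asarray(frames, dtype=self.dtype))
        B, C, H, W = x.shape
        if (H, W) != (self.frame_size, self.frame_size) or C != self.n_channels:
            raise ValueError(
                f"encoder expects ({self.n_channels}, {self.frame_size}, "
                f"{self.frame_size}) frames, got ({C}, {H}, {W})")
        h = x
        for conv in self.enc_convs:
            h = conv(h).relu()
        h = h.reshape(B, -1)
        mu = self.mu_head(h)
        logvar_s = self.logvar_s_head(h) if self.logvar_s_head else None
        logvar_u = self.logvar_u_head(h) if self.logvar_u_head else None
        return EncoderOutput(mu=mu, logvar_s=logvar_s, logvar_u=logvar_u)

    def partition_means(self, mu: Tensor):
        """Project the embedding onto each subspace (Eqs of the model)."""
        maps = self.maps
        mean_s = mu @ maps.A.T if self.n_s else None
        mean_u = mu @ maps.B.T if self.n_u else None
        mean_b = mu @ maps.C.T if self.n_b else None
        return mean_s, mean_u, mean_b

    @staticmethod
    def sample(mean: Tensor, logvar: Tensor, noise: np.ndarray) -> Tensor:
        """Reparameterized draw z = mean + exp(logvar / 2) * noise."""
        if mean.shape != logvar.shape or mean.shape != np.asarray(noise).shape:
            raise ValueError("mean, logvar and noise must have identical shapes")
        eps = np.asarray(noise, dtype=mean.data.dtype)
        return mean + (logvar * 0.5).exp() * Tensor(eps)

    def decode_labels(self, z_s: Tensor) -> Tensor:
        """y_hat = D z_s + d with diagonal D."""
        return z_s * self.maps.D_diag + self.maps.d

    def labels_to_latents(self, y: np.ndarray) -> np.ndarray:
        """Inverse label map z_s = D^-1 (y - d); requires invertible D."""
        D = self.maps.D_diag.data
        if np.any(D == 0):
            raise ValueError("label map D has a zero diagonal entry; not invertible")
        return (np.asarray(y) - self.maps.d.data) / D

    def decode_frame(self, z) -> Tensor:
        """g(z): decode latents to frames in [0, 1] (logistic squashing)."""
        z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=self.dtype))
        if z.shape[-1] != self.n_mu:
            raise ValueError(f"decoder expects latent dimension {self.n_mu}, "
                             f"got {z.shape[-1]}")
        B = z.shape[0]
        h = self.dec_dense(z).relu()
        h = h.reshape(B, self._chans[-1], self.bottleneck, self.bottleneck)
        for i, deconv in enumerate(self.dec_convs):
            h = deconv(h)
            if i + 1 < len(self.dec_convs):
                h = h.relu()
        return h.sigmoid()

    # -- composite forward pass ----------------------------------------------
    def forward(self, frames, rng: np.random.Generator | None = None,
                noise_scale: float = 1.0):
        """Full pass: encode, partition, sample, decode frames and labels.

        Returns ``(partition, recon, y_hat, enc)``. With ``rng=None`` (or
        ``noise_scale=0``) the posterior means are used without sampling.
        """
        enc = self.encode(frames)
        mean_s, mean_u, mean_b = self.partition_means(enc.mu)
        Bsz = enc.mu.shape[0]

        def draw(mean, logvar):
            if mean is None:
                return None
            if rng is None or noise_scale == 0.0:
                return mean
            eps = noise_scale * rng.standard_normal(mean.shape)
            return self.sample(mean, logvar, eps)

        z_s = draw(mean_s, enc.logvar_s)
        z_u = draw(mean_u, enc.logvar_u)
        z_b = mean_b  # deterministic
        parts = [t for t in (z_s, z_u, z_b) if t is not None]
        z = nn.concat(parts, axis=1) if len(parts) > 1 else parts[0]
        part = LatentPartition(mean_s=mean_s, mean_u=mean_u, mean_b=mean_b,
                               logvar_s=enc.logvar_s, logvar_u=enc.logvar_u,
                               z_s=z_s, z_u=z_u, z_b=z_b, z=z)
        recon = self.decode_frame(z)
        y_hat = self.decode_labels(z_s) if z_s is not None else None
        return part, recon, y_hat, enc

    # -- conveniences ----------------------------------------------------------
    def config(self) -> dict:
        return {
            "frame_size": self.frame_size, "n_channels": self.n_channels,
            "n_labels": self.n_s, "n_unsupervised": self.n_u,
            "n_background": self.n_b, "variant": self.variant,
            "channel_base": self._chans[0], "max_channels": max(self._chans),
        }

    @classmethod
    def from_config(cls, cfg: dict, seed: int = 0) -> "PSVAE":
        keys = ("frame_size", "n_channels", "n_labels", "n_unsupervised",
                "n_background", "variant", "channel_base", "max_channels")
        return cls(**{k: cfg[k] for k in keys if k in cfg}, seed=seed)
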