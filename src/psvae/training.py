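"""Optimization loop: Adam, KL annealing, session pairing, per-term logging.

Training follows the published recipe: Adam at learning rate 1e-4 with no
weight decay, a fixed number of epochs (200 at full scale), and linear
annealing of the KL terms and their decompositions over the first
``anneal_epochs`` epochs (weights on KL-s/ICMI/DWKL ramp 0 -> 1, on TC
0 -> beta). The label weight alpha and the orthogonality/triplet weights are
applied at full strength from epoch 0 (they are likelihood/geometry terms,
not KL terms). A batch is one trial's block of contiguous frames.

In multi-session mode every iteration draws two batches from two different
sessions; the triplet loss is computed between their background latents and
all other terms are computed and summed across both batches.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import LabelScaler, make_splits, zscore_labels
from .model import PSVAE
from .nn import Adam
from .objective import (aggregate_triplet, frame_loglik, kl_supervised,
                        kl_unsup_decomposition, label_loglik_masked,
                        orth_penalty, total_objective)

__all__ = ["TrainConfig", "TrialDataset", "anneal_weight",
           "pair_session_batches", "train"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 200
    anneal_epochs: int = 100
    batch_size: int | None = None      # None: one trial per batch
    seed: int = 0
    variant: str = "ps-vae"
    alpha: float = 1000.0
    beta: float = 5.0
    gamma: float = 500.0
    delta: float = 50.0
    triplet_margin: float = 1.0
    likelihood_threshold: float = 0.9
    check_identity: bool = False       # assert the estimator cancellation per batch

    def __post_init__(self):
        if self.epochs <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs and learning_rate must be positive")
        if self.anneal_epochs > self.epochs:
            raise ValueError("anneal_epochs must be <= epochs")


def anneal_weight(epoch: int, anneal_epochs: int, final_value: float) -> float:
    """Linear ramp 0 -> final_value over ``anneal_epochs`` epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if anneal_epochs == 0:
        return final_value
    return final_value * min(epoch / anneal_epochs, 1.0)


class TrialDataset:
    """Trials with block splits and (per-session) z-scored labels.

    Splits follow the 8/1/1 block pattern within each session. Labels are
    individually z-scored per session, with scaler statistics computed on
    training frames only and applied to validation/test frames.
    """

    def __init__(self, trials, scale_labels: bool = True):
        self.trials = list(trials)
        self.session_ids = sorted({t.session_id for t in self.trials})
        self.splits = {}     # global trial index -> split name
        self.scalers: dict[str, LabelScaler] = {}
        by_session = {sid: [i for i, t in enumerate(self.trials)
                            if t.session_id == sid] for sid in self.session_ids}
        for sid, idxs in by_session.items():
            assignment = make_splits(len(idxs))
            for local, g in enumerate(idxs):
                self.splits[g] = assignment[local]
        if scale_labels and self.trials[0].labels.shape[1] > 0:
            for sid, idxs in by_session.items():
                train_labels = np.concatenate(
                    [self.trials[i].labels for i in idxs
                     if self.splits[i] == "train"], axis=0)
                _, scaler = zscore_labels(train_labels)
                self.scalers[sid] = scaler
                for i in idxs:
                    t = self.trials[i]
                    self.trials[i] = replace(t, labels=scaler.transform(t.labels))

    def indices(self, split: str) -> list:
        return [i for i in range(len(self.trials)) if self.splits[i] == split]

    def split_trials(self, split: str) -> list:
        return [self.trials[i] for i in self.indices(split)]

    @property
    def n_train_frames(self) -> int:
        return sum(self.trials[i].frames.shape[0] for i in self.indices("train"))


def pair_session_batches(session_to_items: dict, rng: np.random.Generator):
    """Yield (item_k, item_j) pairs with distinct session ids.

    Every item is consumed once per epoch (odd remainders borrow a partner),
    so every session appears in at least one pair. Order is seeded.
    """
    sids = sorted(session_to_items)
    if len(sids) < 2:
        raise ValueError("multi-session pairing needs >= 2 sessions")
    pool = [(sid, item) for sid in sids for item in session_to_items[sid]]
    order = rng.permutation(len(pool))
    remaining = [pool[i] for i in order]
    while remaining:
        sid_a, item_a = remaining.pop()
        partner = next((idx for idx, (s, _) in enumerate(remaining) if s != sid_a), None)
        if partner is None:
            # only same-session items left; borrow from another session
            others = [(s, it) for s, it in pool if s != sid_a]
            sid_b, item_b = others[int(rng.integers(len(others)))]
        else:
            sid_b, item_b = remaining.pop(partner)
        yield (sid_a, item_a), (sid_b, item_b)


def _batch_terms(model: PSVAE, frames, labels, likelihoods, cfg: TrainConfig,
                 n_train_frames: int, rng: np.random.Generator):
    """Forward one batch and build the per-term Tensor dict."""
    part, recon, y_hat, _ = model.forward(frames, rng=rng)
    terms = {}
    terms["frames"], terms["mse_per_pixel"] = frame_loglik(frames, recon)
    if model.variant in ("ps-vae", "msps-vae"):
        terms["labels"], terms["mse_per_label"] = label_loglik_masked(
            labels, y_hat, likelihoods, cfg.likelihood_threshold)
        terms["kl_s"] = kl_supervised(part.mean_s, part.logvar_s)
        icmi, tc, dwkl = kl_unsup_decomposition(
            part.z_u, part.mean_u, part.logvar_u, n_train_frames)
        terms["icmi"], terms["tc"], terms["dwkl"] = icmi, tc, dwkl
        if model.variant == "ps-vae":
            terms["orth"] = orth_penalty(model.maps.U())
    elif model.variant == "beta-tc-vae":
        icmi, tc, dwkl = kl_unsup_decomposition(
            part.z_u, part.mean_u, part.logvar_u, n_train_frames)
        terms["icmi"], terms["tc"], terms["dwkl"] = icmi, tc, dwkl
    else:  # vae: standard closed-form KL on the whole latent block
        terms["kl_s"] = kl_supervised(part.mean_u, part.logvar_u)
    if cfg.check_identity and "icmi" in terms:
        _assert_decomposition_identity(terms, part, n_train_frames)
    return terms, part


def _assert_decomposition_identity(terms, part, n_train_frames):
    from .objective import LOG_2PI
    z, m, lv = part.z_u.data, part.mean_u.data, part.logvar_u.data
    lq = -0.5 * (LOG_2PI + lv + (z - m) ** 2 / np.exp(lv))
    lp = -0.5 * (LOG_2PI + z ** 2)
    direct = float(np.mean(lq.sum(1) - lp.sum(1)))
    est = float(terms["icmi"].data + terms["tc"].data + terms["dwkl"].data)
    tol = 1e-6 if z.dtype == np.float64 else 5e-4  # float32 round-off
    if abs(direct - est) > tol:
        raise AssertionError(
            f"KL decomposition identity violated: {est} vs {direct}")


def _chunks(trial, batch_size):
    T = trial.frames.shape[0]
    if batch_size is None or batch_size >= T:
        yield trial.frames, trial.labels, trial.likelihoods
        return
    for lo in range(0, T, batch_size):
        hi = min(lo + batch_size, T)
        if hi - lo < 2:
            continue
        yield (trial.frames[lo:hi], trial.labels[lo:hi], trial.likelihoods[lo:hi])


def _mean_breakdown(breakdowns):
    if not breakdowns:
        return None
    from .objective import LossBreakdown
    out = LossBreakdown(weights=breakdowns[0].weights)
    n = len(breakdowns)
    for name in ("frames", "labels", "kl_s", "icmi", "tc", "dwkl", "orth",
                 "triplet", "weighted_total", "mse_per_pixel", "mse_per_label"):
        setattr(out, name, sum(getattr(b, name) for b in breakdowns) / n)
    return out


def train(model: PSVAE, dataset: TrialDataset, cfg: TrainConfig):
    """Fit the model; returns ``(model, history)`` with per-epoch train/val
    loss breakdowns. Deterministic given ``cfg.seed``."""
    if model.variant == "msps-vae" and len(dataset.session_ids) < 2:
        raise ValueError("msps-vae training requires >= 2 sessions")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n_train = dataset.n_train_frames
    train_idx = dataset.indices("train")
    history = []

    for epoch in range(cfg.epochs):
        anneal = 1.0 if cfg.anneal_epochs == 0 else min(epoch / cfg.anneal_epochs, 1.0)
        epoch_parts = []

        if model.variant == "msps-vae":
            by_session = {}
            for i in train_idx:
                by_session.setdefault(dataset.trials[i].session_id, []).append(i)
            iterator = pair_session_batches(by_session, rng)
            for (sid_a, ia), (sid_b, ib) in iterator:
                ta, tb = dataset.trials[ia], dataset.trials[ib]
                terms_a, part_a = _batch_terms(model, ta.frames, ta.labels,
                                               ta.likelihoods, cfg, n_train, rng)
                terms_b, part_b = _batch_terms(model, tb.frames, tb.labels,
                                               tb.likelihoods, cfg, n_train, rng)
                terms = {k: terms_a[k] + terms_b[k] for k in terms_a
                         if not k.startswith("mse")}
                terms["mse_per_pixel"] = 0.5 * (terms_a["mse_per_pixel"]
                                                + terms_b["mse_per_pixel"])
                terms["mse_per_label"] = 0.5 * (terms_a["mse_per_label"]
                                                + terms_b["mse_per_label"])
                # shuffled, 3-divisible subset of background latents
                M = min(part_a.z_b.shape[0], part_b.z_b.shape[0])
                M -= M % 3
                sel_a = rng.permutation(part_a.z_b.shape[0])[:M]
                sel_b = rng.permutation(part_b.z_b.shape[0])[:M]
                terms["triplet"] = aggregate_triplet(
                    part_a.z_b[sel_a], part_b.z_b[sel_b], cfg.triplet_margin,
                    session_k=sid_a, session_j=sid_b)
                total, breakdown = total_objective(
                    terms, cfg.variant, cfg.alpha, cfg.beta, cfg.gamma,
                    cfg.delta, anneal)
                _step(total, breakdown, opt, epoch)
                epoch_parts.append(breakdown)
        else:
            order = rng.permutation(len(train_idx))
            for k in order:
                trial = dataset.trials[train_idx[k]]
                for frames, labels, likes in _chunks(trial, cfg.batch_size):
                    terms, _ = _batch_terms(model, frames, labels, likes,
                                            cfg, n_train, rng)
                    total, breakdown = total_objective(
                        terms, cfg.variant, cfg.alpha, cfg.beta, cfg.gamma,
                        cfg.delta, anneal)
                    _step(total, breakdown, opt, epoch)
                    epoch_parts.append(breakdown)

        entry = {"epoch": epoch, "train": _mean_breakdown(epoch_parts)}
        entry["val"] = evaluate_split(model, dataset, cfg, "val", anneal,
                                      seed=cfg.seed + 100_000 + epoch)
        history.append(entry)
    return model, history


def _step(total, breakdown, opt, epoch):
    if not np.isfinite(total.data):
        bad = [name for name in ("frames", "labels", "kl_s", "icmi", "tc",
                                 "dwkl", "orth", "triplet")
               if not np.isfinite(getattr(breakdown, name))]
        raise FloatingPointError(
            f"non-finite loss at epoch {epoch}; offending term(s): {bad or ['total']}")
    opt.zero_grad()
    (-total).backward()
    opt.step()


def evaluate_split(model: PSVAE, dataset: TrialDataset, cfg: TrainConfig,
                   split: str, anneal: float = 1.0, seed: int = 0):
    """Per-term loss breakdown on a split (no parameter updates)."""
    rng = np.random.default_rng(seed)
    parts = []
    n_train = dataset.n_train_frames
    idxs = dataset.indices(split)
    if not idxs:
        return None
    for i in idxs:
        t = dataset.trials[i]
        terms, part = _batch_terms(model, t.frames, t.labels, t.likelihoods,
                                   cfg, n_train, rng)
        if model.variant == "msps-vae":
            # triplet needs a second session's batch; pick the next split trial
            other = next((j for j in idxs
                          if dataset.trials[j].session_id != t.session_id), None)
            if other is None:
                from .nn import Tensor
                terms["triplet"] = Tensor(np.zeros(()))
            else:
                to = dataset.trials[other]
                _, part_o = _batch_terms(model, to.frames, to.labels,
                                         to.likelihoods, cfg, n_train, rng)
                M = min(part.z_b.shape[0], part_o.z_b.shape[0])
                M -= M % 3
                terms["triplet"] = aggregate_triplet(
                    part.z_b[:M], part_o.z_b[:M], cfg.triplet_margin)
        _, breakdown = total_objective(terms, cfg.variant, cfg.alpha, cfg.beta,
                                       cfg.gamma, cfg.delta, anneal)
        parts.append(breakdown)
    return _mean_breakdown(parts)
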