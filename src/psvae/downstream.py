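"""Downstream analyses: post-hoc label decoding, ARHMM movement detectors,
latent motion energy, and neural decoding of behavioral latents.

The ARHMM is a hidden Markov model with first-order autoregressive Gaussian
emissions x_t | x_{t-1}, state k ~ N(A_k x_{t-1} + b_k, Sigma_k), fit by EM
with the documented protocol: discrete states are randomly initialized and
per-state linear regression seeds the parameters; five random restarts of
150 EM iterations each; the restart with the highest training log-likelihood
wins. State paths are Viterbi by default (posterior-marginal argmax is also
exposed).
"""
from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from . import nn
from .objective import frame_loglik

__all__ = [
    "ARHMMFit", "DecoderSpec", "fit_arhmm", "simulate_arhmm",
    "state_overlap", "motion_energy", "posthoc_label_regression",
    "neural_decode", "finetune_frame_decoder",
]

RIDGE_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0, 100000.0)


# ---------------------------------------------------------------------------
# Post-hoc label regression
# ---------------------------------------------------------------------------

def _trial_kfold_cv(train_X, train_y, make_model, grid, n_folds=5, seed=0):
    """Choose a regularization value by K-fold CV over *trials*."""
    n_trials = len(train_X)
    if n_trials < n_folds:
        raise ValueError(f"need >= {n_folds} training trials to form folds, "
                         f"got {n_trials}")
    kf = KFold(n_splits=n_folds, shuffle=False)
    scores = []
    for a in grid:
        mses = []
        for tr_idx, va_idx in kf.split(np.arange(n_trials)):
            X_tr = np.concatenate([train_X[i] for i in tr_idx])
            y_tr = np.concatenate([train_y[i] for i in tr_idx])
            X_va = np.concatenate([train_X[i] for i in va_idx])
            y_va = np.concatenate([train_y[i] for i in va_idx])
            m = make_model(a)
            m.fit(X_tr, y_tr)
            mses.append(np.mean((m.predict(X_va) - y_va) ** 2))
        scores.append(np.mean(mses))
    return grid[int(np.argmin(scores))]


def posthoc_label_regression(latents, labels, splits, kind: str = "ridge",
                             grid=RIDGE_GRID, n_folds: int = 5, seed: int = 0,
                             n_bootstrap: int = 1000, mlp_max_iter: int = 500):
    """Decode labels from latents with ridge or a small MLP (two hidden
    layers of 20 rectified units), selecting the regularization strength by
    5-fold cross-validation over training trials.

    ``latents``/``labels`` are per-trial lists; ``splits`` maps trial index
    to split name. Returns a dict with per-label test R^2, their mean, and a
    95% bootstrap interval over test trials.
    """
    train_i = [i for i in range(len(latents)) if splits[i] == "train"]
    test_i = [i for i in range(len(latents)) if splits[i] == "test"]
    train_X = [np.asarray(latents[i]) for i in train_i]
    train_y = [np.asarray(labels[i]) for i in train_i]

    if kind == "ridge":
        def make(a):
            return Ridge(alpha=a)
    elif kind == "mlp":
        def make(a):
            return MLPRegressor(hidden_layer_sizes=(20, 20), activation="relu",
                                alpha=a, max_iter=mlp_max_iter,
                                random_state=seed)
    else:
        raise ValueError(f"unknown regression kind {kind!r}")

    best_alpha = _trial_kfold_cv(train_X, train_y, make, tuple(grid),
                                 n_folds=n_folds, seed=seed)
    model = make(best_alpha)
    model.fit(np.concatenate(train_X), np.concatenate(train_y))

    per_trial_r2 = []
    y_all, yh_all = [], []
    for i in test_i:
        yh = model.predict(np.asarray(latents[i]))
        y = np.asarray(labels[i])
        y_all.append(y)
        yh_all.append(yh)
        ss_tot = np.sum((y - y.mean(0)) ** 2)
        per_trial_r2.append(1.0 - np.sum((y - yh) ** 2) / ss_tot if ss_tot else 0.0)
    y_all = np.concatenate(y_all)
    yh_all = np.concatenate(yh_all)
    per_label = 1.0 - ((y_all - yh_all) ** 2).sum(0) / \
        ((y_all - y_all.mean(0)) ** 2).sum(0)

    rng = np.random.default_rng(seed)
    boot = [np.mean([per_trial_r2[j] for j in
                     rng.integers(len(per_trial_r2), size=len(per_trial_r2))])
            for _ in range(n_bootstrap)]
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return {"r2_per_label": per_label, "r2_mean": float(np.mean(per_trial_r2)),
            "r2_ci95": ci, "alpha": best_alpha, "model": model}


# ---------------------------------------------------------------------------
# ARHMM
# ---------------------------------------------------------------------------

@dataclass
class ARHMMFit:
    n_states: int
    ar_weights: np.ndarray       # (K, D, D)
    ar_bias: np.ndarray          # (K, D)
    noise_cov: np.ndarray        # (K, D, D)
    transitions: np.ndarray      # (K, K), rows sum to 1
    initial: np.ndarray          # (K,)
    states: np.ndarray           # Viterbi path on the training series
    log_likelihoods: np.ndarray  # per-EM-iteration training log-likelihood
    train_ll: float = field(init=False)

    def __post_init__(self):
        self.train_ll = float(self.log_likelihoods[-1])


def _ar_emission_logliks(series, A, b, cov):
    """(T-1, K) log N(x_t; A_k x_{t-1} + b_k, cov_k) for t = 1..T-1."""
    x_prev, x_next = series[:-1], series[1:]
    K, D = b.shape
    out = np.empty((len(x_next), K))
    for k in range(K):
        mean = x_prev @ A[k].T + b[k]
        diff = x_next - mean
        sign, logdet = np.linalg.slogdet(cov[k])
        prec = np.linalg.inv(cov[k])
        quad = np.einsum("ti,ij,tj->t", diff, prec, diff)
        out[:, k] = -0.5 * (D * np.log(2 * np.pi) + logdet + quad)
    return out


def _weighted_ar_fit(series, weights, reg: float = 1e-6):
    """Weighted least squares x_t ~ A x_{t-1} + b; returns (A, b, cov)."""
    x_prev, x_next = series[:-1], series[1:]
    D = series.shape[1]
    X = np.concatenate([x_prev, np.ones((len(x_prev), 1))], axis=1)
    W = weights[:, None]
    XtWX = X.T @ (W * X) + reg * np.eye(D + 1)
    XtWy = X.T @ (W * x_next)
    coef = np.linalg.solve(XtWX, XtWy)     # (D+1, D)
    A, b = coef[:D].T, coef[D]
    resid = x_next - X @ coef
    wsum = weights.sum()
    cov = (resid.T @ (W * resid)) / max(wsum, 1e-12) + reg * np.eye(D)
    return A, b, cov


def _forward_backward(log_em, log_trans, log_init):
    """Scaled forward-backward; returns (gamma, expected transition counts,
    log-likelihood)."""
    Tm1, K = log_em.shape
    # per-step scaling of emissions keeps the linear-space recursions stable
    em_max = log_em.max(axis=1, keepdims=True)
    em = np.exp(log_em - em_max)
    P = np.exp(log_trans)
    alpha = np.empty((Tm1, K))
    c = np.empty(Tm1)
    a = np.exp(log_init) * em[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, Tm1):
        a = (alpha[t - 1] @ P) * em[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((Tm1, K))
    beta[-1] = 1.0
    for t in range(Tm1 - 2, -1, -1):
        beta[t] = P @ (em[t + 1] * beta[t + 1]) / c[t + 1]
    ll = float(np.log(c).sum() + em_max.sum())
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # expected transition counts, vectorized over time
    B2 = em[1:] * beta[1:] / c[1:, None]
    xi = P * (alpha[:-1].T @ B2)
    return gamma, xi, ll


def _viterbi(log_em, log_trans, log_init):
    Tm1, K = log_em.shape
    delta = log_init + log_em[0]
    back = np.zeros((Tm1, K), dtype=int)
    for t in range(1, Tm1):
        scores = delta[:, None] + log_trans
        back[t] = np.argmax(scores, axis=0)
        delta = log_em[t] + np.max(scores, axis=0)
    path = np.empty(Tm1, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(Tm1 - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def fit_arhmm(series: np.ndarray, n_states: int = 2, n_restarts: int = 5,
              n_iter: int = 150, seed: int = 0) -> ARHMMFit:
    """Fit a K-state AR(1)-HMM by EM; best of ``n_restarts`` random starts."""
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2 or series.shape[0] < 20:
        raise ValueError("series must be (time >= 20, dims)")
    if np.allclose(series.std(axis=0), 0):
        raise ValueError("series is (near-)constant; ARHMM fit is degenerate")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        fit = _fit_arhmm_once(series, n_states, n_iter, rng)
        if best is None or fit.train_ll > best.train_ll:
            best = fit
    return best


def _fit_arhmm_once(series, K, n_iter, rng):
    Tm1 = len(series) - 1
    # random state initialization, then per-state regression
    states0 = rng.integers(K, size=Tm1)
    A = np.empty((K, series.shape[1], series.shape[1]))
    b = np.empty((K, series.shape[1]))
    cov = np.empty((K, series.shape[1], series.shape[1]))
    for k in range(K):
        w = (states0 == k).astype(float)
        if w.sum() < series.shape[1] + 2:
            w = np.ones(Tm1)
        A[k], b[k], cov[k] = _weighted_ar_fit(series, w)
    trans = np.full((K, K), 1.0 / K)
    init = np.full(K, 1.0 / K)

    lls = []
    for _ in range(n_iter):
        log_em = _ar_emission_logliks(series, A, b, cov)
        gamma, xi, ll = _forward_backward(log_em, np.log(trans), np.log(init))
        lls.append(ll)
        # M-step
        for k in range(K):
            A[k], b[k], cov[k] = _weighted_ar_fit(series, gamma[:, k])
        trans = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        trans = np.maximum(trans, 1e-12)
        trans /= trans.sum(axis=1, keepdims=True)
        init = np.maximum(gamma[0], 1e-12)
        init /= init.sum()

    log_em = _ar_emission_logliks(series, A, b, cov)
    path = _viterbi(log_em, np.log(trans), np.log(init))
    return ARHMMFit(n_states=K, ar_weights=A, ar_bias=b, noise_cov=cov,
                    transitions=trans, initial=init, states=path,
                    log_likelihoods=np.asarray(lls))


def arhmm_states(fit: ARHMMFit, series: np.ndarray, method: str = "viterbi"):
    """Most-likely state path on a new series (Viterbi or marginal argmax)."""
    log_em = _ar_emission_logliks(np.asarray(series, dtype=np.float64),
                                  fit.ar_weights, fit.ar_bias, fit.noise_cov)
    if method == "viterbi":
        return _viterbi(log_em, np.log(fit.transitions), np.log(fit.initial))
    gamma, _, _ = _forward_backward(log_em, np.log(fit.transitions),
                                    np.log(fit.initial))
    return np.argmax(gamma, axis=1)


def simulate_arhmm(n_steps: int, A, b, cov, trans, seed: int = 0,
                   x0=None):
    """Simulate (series, states) from known AR-HMM parameters."""
    rng = np.random.default_rng(seed)
    A, b, cov, trans = (np.asarray(a, dtype=float) for a in (A, b, cov, trans))
    K, D = b.shape
    chol = np.linalg.cholesky(cov)
    x = np.empty((n_steps, D))
    z = np.empty(n_steps, dtype=int)
    x[0] = np.zeros(D) if x0 is None else x0
    z[0] = rng.integers(K)
    for t in range(1, n_steps):
        z[t] = rng.choice(K, p=trans[z[t - 1]])
        x[t] = A[z[t]] @ x[t - 1] + b[z[t]] + chol[z[t]] @ rng.standard_normal(D)
    return x, z


def state_overlap(states_a, states_b):
    """Percent agreement maximized over label permutations.

    Returns ``(percent, confusion)`` where the confusion matrix is counts of
    (state_a, permuted state_b) pairs. Exhaustive permutations for K <= 4,
    Hungarian assignment on the confusion matrix otherwise.
    """
    a = np.asarray(states_a, dtype=int)
    bb = np.asarray(states_b, dtype=int)
    if a.shape != bb.shape:
        raise ValueError("state sequences must have equal length")
    K = int(max(a.max(), bb.max())) + 1
    conf = np.zeros((K, K), dtype=int)
    np.add.at(conf, (a, bb), 1)
    if K <= 4:
        best_perm, best_hits = None, -1
        for perm in itertools.permutations(range(K)):
            hits = sum(conf[i, perm[i]] for i in range(K))
            if hits > best_hits:
                best_hits, best_perm = hits, perm
    else:
        row, col = linear_sum_assignment(-conf)
        best_perm = [int(col[list(row).index(i)]) for i in range(K)]
        best_hits = sum(conf[i, best_perm[i]] for i in range(K))
    conf_aligned = conf[:, list(best_perm)]
    return 100.0 * best_hits / len(a), conf_aligned


def motion_energy(traces: np.ndarray) -> np.ndarray:
    """ME_t = |x_t - x_{t-1}| per dimension; the first frame's ME is 0."""
    x = np.asarray(traces, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("motion energy needs >= 2 time points")
    me = np.zeros_like(x)
    me[1:] = np.abs(np.diff(x, axis=0))
    return me


# ---------------------------------------------------------------------------
# Neural decoding
# ---------------------------------------------------------------------------

@dataclass
class DecoderSpec:
    hidden_layers: int = 2
    hidden_units: int = 32
    lag: int = 16                 # half-window L; input is u_{t-L : t+L}
    learning_rate: float = 1e-4
    max_epochs: int = 200
    patience_window: int = 10     # running-average window for early stopping

    def __post_init__(self):
        if self.lag < 0 or self.hidden_layers < 1 or self.hidden_units < 1:
            raise ValueError("invalid decoder spec")


def _windowed(neural: np.ndarray, lag: int) -> np.ndarray:
    """Zero-padded sliding windows: (T, (2 lag + 1) * n_neurons)."""
    T, n = neural.shape
    padded = np.pad(neural, ((lag, lag), (0, 0)))
    return np.stack([padded[t:t + 2 * lag + 1].ravel() for t in range(T)])


class _MLP(nn.Module):
    def __init__(self, n_in, n_out, hidden_layers, hidden_units, rng):
        sizes = [n_in] + [hidden_units] * hidden_layers + [n_out]
        self.layers = [nn.Dense(sizes[i], sizes[i + 1], rng)
                       for i in range(len(sizes) - 1)]

    def __call__(self, x):
        h = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x))
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i + 1 < len(self.layers):
                h = h.relu()
        return h


def _train_mlp(X_tr, y_tr, X_va, y_va, spec: DecoderSpec, seed: int,
               batch_size: int = 256):
    rng = np.random.default_rng(seed)
    net = _MLP(X_tr.shape[1], y_tr.shape[1], spec.hidden_layers,
               spec.hidden_units, rng)
    opt = nn.Adam(net.parameters(), lr=spec.learning_rate)
    val_mse, run_avg = [], []
    best_state, best_avg = None, np.inf
    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(X_tr))
        for lo in range(0, len(order), batch_size):
            sel = order[lo:lo + batch_size]
            pred = net(X_tr[sel])
            loss = ((pred - nn.Tensor(y_tr[sel])) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_mse.append(float(np.mean((net(X_va).data - y_va) ** 2)))
        w = spec.patience_window
        run_avg.append(float(np.mean(val_mse[-w:])))
        if run_avg[-1] < best_avg:
            best_avg = run_avg[-1]
            best_state = net.state_arrays()
            best_state = {k: v.copy() for k, v in best_state.items()}
        # stop when the running average of validation MSE begins to increase
        if epoch >= w and run_avg[-1] > run_avg[-2]:
            break
    if best_state is not None:
        net.load_state_arrays(best_state)
    return net, val_mse


def neural_decode(neural_trials, latent_trials, splits,
                  specs=None, seed: int = 0):
    """Decode latents from windowed neural activity with a rectified MLP.

    ``specs`` is an iterable of :class:`DecoderSpec` forming the architecture
    grid (single default spec if omitted). Training stops early when the
    10-epoch running average of validation MSE increases, or at max_epochs.
    Returns per-latent test R^2, predictions for every trial, and the
    selected spec.
    """
    specs = list(specs) if specs is not None else [DecoderSpec()]
    lag = specs[0].lag
    for t_n, t_z in zip(neural_trials, latent_trials):
        if len(t_n) != len(t_z):
            raise ValueError("neural and latent trials must be aligned in time")
        if len(t_n) <= 2 * lag:
            raise ValueError(f"trial length {len(t_n)} too short for lag {lag}")

    idx = {s: [i for i in range(len(neural_trials)) if splits[i] == s]
           for s in ("train", "val", "test")}
    X = {s: np.concatenate([_windowed(np.asarray(neural_trials[i]), lag)
                            for i in idx[s]]) for s in idx}
    y = {s: np.concatenate([np.asarray(latent_trials[i]) for i in idx[s]])
         for s in idx}

    best = None
    for spec in specs:
        net, val_mse = _train_mlp(X["train"], y["train"], X["val"], y["val"],
                                  spec, seed)
        score = min(val_mse)
        if best is None or score < best[0]:
            best = (score, spec, net)
    _, spec, net = best

    yh = net(X["test"]).data
    ss_res = ((y["test"] - yh) ** 2).sum(0)
    ss_tot = ((y["test"] - y["test"].mean(0)) ** 2).sum(0)
    r2 = 1.0 - ss_res / np.maximum(ss_tot, 1e-12)
    preds = [net(_windowed(np.asarray(t), spec.lag)).data for t in neural_trials]
    return {"r2_per_latent": r2, "r2_mean": float(r2.mean()),
            "predictions": preds, "spec": spec}


# ---------------------------------------------------------------------------
# Frame-decoder fine-tuning
# ---------------------------------------------------------------------------

def finetune_frame_decoder(model, predicted_latents, frame_trials,
                           train_indices, test_indices, epochs: int = 200,
                           learning_rate: float = 1e-4, seed: int = 0):
    """Fine-tune the frame decoder g on neurally predicted latents.

    A copy of the decoder is initialized from g's weights and trained on
    (predicted latent -> true frame) pairs from training trials; returns
    ``(finetuned_model, mse_before, mse_after)`` with test-trial pixel MSE of
    the frozen and fine-tuned decoders fed the same predicted latents.
    """
    for z, f in zip(predicted_latents, frame_trials):
        if np.asarray(z).shape[1] != model.n_mu:
            raise ValueError(f"predicted latents have dimension "
                             f"{np.asarray(z).shape[1]}, decoder expects {model.n_mu}")
        if len(z) != len(f):
            raise ValueError("latent and frame trials must be aligned")

    tuned = copy.deepcopy(model)
    params = tuned.dec_dense.parameters()
    for deconv in tuned.dec_convs:
        params.extend(deconv.parameters())
    opt = nn.Adam(params, lr=learning_rate)
    rng = np.random.default_rng(seed)

    def test_mse(m):
        errs = [np.mean((m.decode_frame(np.asarray(predicted_latents[i],
                                                   dtype=m.dtype)).data
                         - frame_trials[i]) ** 2) for i in test_indices]
        return float(np.mean(errs))

    mse_before = test_mse(model)
    for _ in range(epochs):
        for i in rng.permutation(train_indices):
            z = np.asarray(predicted_latents[i], dtype=tuned.dtype)
            recon = tuned.decode_frame(z)
            L, _ = frame_loglik(frame_trials[i], recon)
            opt.zero_grad()
            (-L).backward()
            opt.step()
    mse_after = test_mse(tuned)
    return tuned, mse_before, mse_after
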