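"""Zero-inflated negative binomial variational autoencoder.

A beta-VAE whose decoder emits per-entry ZINB parameters (mean M, dispersion
Theta, zero-inflation Pi), with the decoder mean scaled by per-cell size
factors so the likelihood lives on the raw count scale.  Implemented directly
on numpy with hand-written gradients and an Adam optimizer, which keeps the
method runnable on a plain CPU stack.

Layout conventions: the public API follows genes x cells / latent x cells
matrices; internally the network computes with cells as rows for BLAS
efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import digamma, gammaln

from .data_io import CountMatrix, NormalizedMatrix

# numerical floors: sigma_x and Theta in [1e-6, 1e6], Pi in [1e-6, 1 - 1e-6]
_LOG_FLOOR = math.log(1e-6)
_LOG_CEIL = math.log(1e6)
_EPS_PI = 1e-6


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def zinb_log_pmf(x, mu, theta, pi):
    """Log pmf of the zero-inflated negative binomial distribution.

    ``log[ pi * 1{x=0} + (1 - pi) * NB(x; mu, theta) ]`` where the NB is
    parameterized by mean ``mu`` and dispersion ``theta`` (variance
    ``mu + mu^2 / theta``).  Vectorized; the zero branch is evaluated with
    log-sum-exp for stability.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if np.any(x < 0) or not np.allclose(x, np.rint(x)):
        raise ValueError("x must be a non-negative integer")
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("pi must lie strictly in (0, 1)")
    x, mu, theta, pi = np.broadcast_arrays(x, mu, theta, pi)

    log_nb = (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + x * (np.log(mu) - np.log(theta + mu))
    )
    pos = np.log1p(-pi) + log_nb
    # at x == 0: log( pi + (1-pi) * (theta/(theta+mu))^theta )
    zero = np.logaddexp(np.log(pi), np.log1p(-pi) + theta * (np.log(theta) - np.log(theta + mu)))
    out = np.where(x == 0, zero, pos)
    return out if out.ndim else float(out)


@dataclass
class Embedding:
    """Latent representation of all cells: ``z`` is latent_dim x n."""

    z: np.ndarray
    mu_x: np.ndarray
    sigma_x: np.ndarray

    def __post_init__(self) -> None:
        for name in ("z", "mu_x", "sigma_x"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"Embedding.{name}: non-finite values")
            setattr(self, name, arr)
        if np.any(self.sigma_x <= 0):
            raise ValueError("Embedding.sigma_x must be strictly positive")

    @property
    def latent_dim(self) -> int:
        return self.z.shape[0]

    @property
    def n_cells(self) -> int:
        return self.z.shape[1]


@dataclass
class VAEModel:
    """Network parameters and architecture of the ZINB beta-VAE.

    Widths must satisfy ``latent_dim < encoder_hidden_width < n_genes`` and
    ``latent_dim < decoder_hidden_width < n_genes``.
    """

    n_genes: int
    encoder_hidden_width: int = 512
    latent_dim: int = 32
    decoder_hidden_width: int = 512
    beta: float = 1.0
    seed: int = 0
    params: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    loss_history: list[dict] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        m, d1, d, d2 = (
            self.n_genes,
            self.encoder_hidden_width,
            self.latent_dim,
            self.decoder_hidden_width,
        )
        if not (d < d1 < m and d < d2 < m):
            raise ValueError(
                f"widths must satisfy d < d1 < m and d < d2 < m, got "
                f"m={m}, d1={d1}, d={d}, d2={d2}"
            )
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not self.params:
            self.params = _init_params(m, d1, d, d2, self.seed)

    def copy(self) -> "VAEModel":
        clone = VAEModel(
            self.n_genes,
            self.encoder_hidden_width,
            self.latent_dim,
            self.decoder_hidden_width,
            self.beta,
            self.seed,
            {k: v.copy() for k, v in self.params.items()},
        )
        clone.loss_history = list(self.loss_history)
        return clone

    def save(self, path: str) -> None:
        """Save a self-describing checkpoint (architecture + weights + seed)."""
        meta = dict(
            n_genes=self.n_genes,
            encoder_hidden_width=self.encoder_hidden_width,
            latent_dim=self.latent_dim,
            decoder_hidden_width=self.decoder_hidden_width,
            beta=self.beta,
            seed=self.seed,
        )
        np.savez(path, __meta__=np.array([repr(meta)]), **self.params)

    @classmethod
    def load(cls, path: str) -> "VAEModel":
        import ast

        with np.load(path, allow_pickle=False) as data:
            meta = ast.literal_eval(str(data["__meta__"][0]))
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(params=params, **meta)


def _init_params(m: int, d1: int, d: int, d2: int, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)

    def glorot(fan_in, fan_out):
        s = math.sqrt(2.0 / (fan_in + fan_out))
        return (rng.standard_normal((fan_in, fan_out)) * s).astype(np.float32)

    p = {
        "W_h": glorot(m, d1),
        "b_h": np.zeros(d1, dtype=np.float32),
        "W_mu_x": glorot(d1, d),
        "b_mu_x": np.zeros(d, dtype=np.float32),
        "W_sig_x": glorot(d1, d),
        "b_sig_x": np.zeros(d, dtype=np.float32),
        "W_d": glorot(d, d2),
        "b_d": np.zeros(d2, dtype=np.float32),
        "W_m": glorot(d2, m),
        "b_m": np.zeros(m, dtype=np.float32),
        "W_th": glorot(d2, m),
        "b_th": np.zeros(m, dtype=np.float32),
        "W_pi": glorot(d2, m),
        "b_pi": np.zeros(m, dtype=np.float32),
    }
    return p


# ---------------------------------------------------------------------------
# forward / backward passes (cells-as-rows internally)
# ---------------------------------------------------------------------------


def _encode_rows(params, X):
    """X: (n, m) -> (H, mu, log_sigma) with rows = cells."""
    H = np.maximum(X @ params["W_h"] + params["b_h"], 0.0)
    mu = H @ params["W_mu_x"] + params["b_mu_x"]
    ls = H @ params["W_sig_x"] + params["b_sig_x"]
    ls = np.clip(ls, _LOG_FLOOR, _LOG_CEIL)
    return H, mu, ls


def _decode_rows(params, Z, sf):
    """Z: (n, d), sf: (n,) -> (D, M, Theta, Pi) with rows = cells."""
    D = np.maximum(Z @ params["W_d"] + params["b_d"], 0.0)
    lm = np.clip(D @ params["W_m"] + params["b_m"], _LOG_FLOOR, _LOG_CEIL)
    lt = np.clip(D @ params["W_th"] + params["b_th"], _LOG_FLOOR, _LOG_CEIL)
    lp = D @ params["W_pi"] + params["b_pi"]
    M = sf[:, None] * np.exp(lm)
    Theta = np.exp(lt)
    Pi = np.clip(_sigmoid(lp), _EPS_PI, 1.0 - _EPS_PI)
    return D, lm, lt, lp, M, Theta, Pi


def _sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _zinb_nll_and_grads(X, M, Theta, Pi):
    """Mean (over cells) negative ZINB log-likelihood and grads wrt M, Theta, Pi.

    X, M, Theta, Pi: (n, m) with rows = cells.  Returns (nll, gM, gTh, gPi)
    where the gradients are of the *negative* mean log-likelihood.
    """
    n = X.shape[0]
    t = Theta + M
    log_t = np.log(t)
    log_th = np.log(Theta)
    x_th = X + Theta

    log_nb = (
        gammaln(x_th)
        - gammaln(Theta)
        - gammaln(X + 1.0)
        + Theta * (log_th - log_t)
        + X * (np.log(M) - log_t)
    )
    zero_mask = X == 0
    b = np.log1p(-Pi) + Theta * (log_th - log_t)
    a = np.log(Pi)
    log_zero = np.logaddexp(a, b)
    logp = np.where(zero_mask, log_zero, np.log1p(-Pi) + log_nb)
    nll = -float(logp.sum()) / n

    # gradients of log p wrt the distribution parameters
    wb = np.exp(b - log_zero)  # posterior weight of the NB component at x=0
    gM = np.where(zero_mask, -wb * Theta / t, X / M - x_th / t)
    gTh_common = log_th + 1.0 - log_t
    gTh = np.where(
        zero_mask,
        wb * (gTh_common - Theta / t),
        digamma(x_th) - digamma(Theta) + gTh_common - x_th / t,
    )
    gPi = np.where(zero_mask, (1.0 - wb) / Pi - wb / (1.0 - Pi), -1.0 / (1.0 - Pi))

    scale = -1.0 / n
    return nll, scale * gM, scale * gTh, scale * gPi


def _cluster_grads(Z, centroids, P):
    """KL(P || Q) clustering loss and grads wrt Z (n, d) and centroids (K, d)."""
    diff2 = (
        (Z * Z).sum(1)[:, None] + (centroids * centroids).sum(1)[None, :] - 2.0 * Z @ centroids.T
    )
    np.maximum(diff2, 0.0, out=diff2)
    q = 1.0 / (1.0 + diff2)
    qn = q / q.sum(1, keepdims=True)
    qn = np.clip(qn, 1e-12, None)
    loss = float(np.sum(P * (np.log(np.clip(P, 1e-12, None)) - np.log(qn))))
    G = (P - qn) * q  # (n, K)
    gZ = 2.0 * (Z * G.sum(1)[:, None] - G @ centroids)
    gC = 2.0 * (centroids * G.sum(0)[:, None] - G.T @ Z)
    return loss, gZ, gC


def _forward_backward(
    params,
    Xc,
    Xn,
    sf,
    eps,
    beta,
    P=None,
    centroids=None,
    lambda_=0.0,
):
    """One loss + gradient evaluation on a batch (rows = cells).

    Xc: raw counts (n_b, m); Xn: normalized input (n_b, m); eps: reparam noise
    (n_b, d) or None for deterministic z = mu_x.  The VAE loss is normalized
    by the batch size; the clustering loss is a plain sum over the batch
    (matching a total-sum loss when batches partition the data).
    """
    n_b = Xc.shape[0]
    H, mu, ls = _encode_rows(params, Xn)
    sig = np.exp(ls)
    Z = mu if eps is None else mu + sig * eps
    D, lm, lt, lp, M, Theta, Pi = _decode_rows(params, Z, sf)

    nll, gM, gTh, gPi = _zinb_nll_and_grads(Xc, M, Theta, Pi)
    kl = -(beta / (2.0 * n_b)) * float((1.0 + 2.0 * ls - mu * mu - sig * sig).sum())

    grads = {}
    # decoder heads; chain through exp / sigmoid (clip regions get zero grad)
    dlm = gM * M
    dlm[(lm <= _LOG_FLOOR) | (lm >= _LOG_CEIL)] = 0.0
    dlt = gTh * Theta
    dlt[(lt <= _LOG_FLOOR) | (lt >= _LOG_CEIL)] = 0.0
    dlp = gPi * Pi * (1.0 - Pi)

    grads["W_m"] = D.T @ dlm
    grads["b_m"] = dlm.sum(0)
    grads["W_th"] = D.T @ dlt
    grads["b_th"] = dlt.sum(0)
    grads["W_pi"] = D.T @ dlp
    grads["b_pi"] = dlp.sum(0)

    dD = dlm @ params["W_m"].T + dlt @ params["W_th"].T + dlp @ params["W_pi"].T
    dD[D <= 0] = 0.0
    grads["W_d"] = Z.T @ dD
    grads["b_d"] = dD.sum(0)
    dZ = dD @ params["W_d"].T

    lc = 0.0
    if lambda_ > 0.0 and centroids is not None and P is not None:
        lc, gZc, gC = _cluster_grads(Z, centroids, P)
        dZ = dZ + lambda_ * gZc
        grads["centroids"] = lambda_ * gC
    else:
        grads["centroids"] = None

    # KL gradients + reparameterization
    dmu = dZ + (beta / n_b) * mu
    dls = (beta / n_b) * (sig * sig - 1.0)
    if eps is not None:
        dls = dls + dZ * eps * sig
    clipped = (ls <= _LOG_FLOOR) | (ls >= _LOG_CEIL)
    dls[clipped] = 0.0

    grads["W_mu_x"] = H.T @ dmu
    grads["b_mu_x"] = dmu.sum(0)
    grads["W_sig_x"] = H.T @ dls
    grads["b_sig_x"] = dls.sum(0)

    dH = dmu @ params["W_mu_x"].T + dls @ params["W_sig_x"].T
    dH[H <= 0] = 0.0
    grads["W_h"] = Xn.T @ dH
    grads["b_h"] = dH.sum(0)

    total = nll + kl + lambda_ * lc
    return total, nll, kl, lc, grads


class Adam:
    """Minimal Adam optimizer over a dict of numpy parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def reset_slot(self, name, param):
        """Reinitialize one parameter's moment estimates (e.g. resized centroids)."""
        self.m[name] = np.zeros_like(param, dtype=np.float64)
        self.v[name] = np.zeros_like(param, dtype=np.float64)

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            if g is None or k not in self.m:
                continue
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            update = (self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps))
            params[k] = (params[k] - update).astype(params[k].dtype)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def encode(
    model: VAEModel,
    x_norm: NormalizedMatrix,
    sample: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Embedding:
    """Encode the normalized matrix into the latent space.

    With ``sample=False`` (inference) the embedding is the posterior mean
    ``z = mu_x``, so downstream clustering is deterministic given weights.
    """
    Xn = np.ascontiguousarray(x_norm.values.T, dtype=np.float32)
    _, mu, ls = _encode_rows(model.params, Xn)
    sig = np.exp(ls)
    if sample:
        rng = rng if rng is not None else np.random.default_rng()
        eps = rng.standard_normal(mu.shape)
        z = mu + sig * eps
    else:
        z = mu
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sig))):
        raise TrainingDivergedError("non-finite activations in encoder")
    return Embedding(z=z.T, mu_x=mu.T, sigma_x=sig.T)


def decode(model: VAEModel, emb: Embedding, size_factors: np.ndarray):
    """Decode latent vectors into ZINB parameters (M, Theta, Pi), genes x cells."""
    Z = np.ascontiguousarray(emb.z.T, dtype=np.float64)
    sf = np.asarray(size_factors, dtype=np.float64)
    if Z.shape[1] != model.latent_dim:
        raise ValueError("embedding latent dimension mismatch")
    _, _, _, _, M, Theta, Pi = _decode_rows(model.params, Z, sf)
    for name, arr in (("M", M), ("Theta", Theta), ("Pi", Pi)):
        if not np.all(np.isfinite(arr)):
            raise TrainingDivergedError(f"non-finite decoder output {name}")
    return M.T, Theta.T, Pi.T


def vae_loss(
    model: VAEModel,
    counts: CountMatrix,
    x_norm: NormalizedMatrix,
    beta: float,
) -> tuple[float, float, float]:
    """Evaluate (total, nll, kl) of the VAE loss at the posterior mean."""
    Xc = counts.counts.T.astype(np.float64)
    Xn = np.ascontiguousarray(x_norm.values.T, dtype=np.float32)
    sf = x_norm.size_factors
    n = Xc.shape[0]
    _, mu, ls = _encode_rows(model.params, Xn)
    sig = np.exp(ls)
    _, _, _, _, M, Theta, Pi = _decode_rows(model.params, mu, sf)
    nll = -float(zinb_log_pmf(Xc, M, Theta, Pi).sum()) / n
    kl = -(beta / (2.0 * n)) * float((1.0 + 2.0 * ls - mu * mu - sig * sig).sum())
    total = nll + kl
    if not math.isfinite(total):
        raise TrainingDivergedError("non-finite VAE loss")
    return total, nll, kl


def pretrain(
    model: VAEModel,
    counts: CountMatrix,
    x_norm: NormalizedMatrix,
    epochs: int = 30,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 256,
    beta: Optional[float] = None,
) -> VAEModel:
    """Pretrain the VAE; ``beta`` defaults to ``0.001 * n_genes``.

    Training is mini-batched with reparameterized sampling; fully
    reproducible under a fixed seed.  Appends per-epoch losses to
    ``model.loss_history``.
    """
    m = counts.n_genes
    if m != model.n_genes:
        raise ValueError("model was built for a different number of genes")
    beta = 0.001 * m if beta is None else beta
    model.beta = beta
    rng = np.random.default_rng(seed)
    Xc = np.ascontiguousarray(counts.counts.T, dtype=np.float64)
    Xn = np.ascontiguousarray(x_norm.values.T, dtype=np.float32)
    sf = x_norm.size_factors
    n = Xc.shape[0]
    opt = Adam(model.params, lr=lr)
    d = model.latent_dim

    for epoch in range(epochs):
        order = rng.permutation(n)
        tot = nll_sum = kl_sum = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            eps = rng.standard_normal((idx.size, d))
            total, nll, kl, _, grads = _forward_backward(
                model.params, Xc[idx], Xn[idx], sf[idx], eps, beta
            )
            if not math.isfinite(total):
                raise TrainingDivergedError(
                    f"pretraining diverged at epoch {epoch}: loss={total}"
                )
            opt.step(model.params, grads)
            w = idx.size / n
            tot += total * w
            nll_sum += nll * w
            kl_sum += kl * w
        model.loss_history.append(
            dict(phase="pretrain", epoch=epoch, total=tot, nll=nll_sum, kl=kl_sum)
        )
    return model
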