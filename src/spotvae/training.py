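"""Objective, mini-batch training and the deconvolution entry point.

The objective per real spot is the negative ELBO

    L(theta, phi; X_i) = D_KL(q_phi(Z_i|X_i) || N(0, I))
                         - E_q[log p_theta(X_i | Z_i)]

estimated with a single reparameterized Monte-Carlo sample. Pseudo-spots
contribute the same terms plus a supervised L1 penalty between the decoded
proportions and their known ground truth. Trainable parameters are the
encoder phi, decoder omega, gene scaling s and additive noise gamma (and the
ZINB dropout when that likelihood is selected); the reference signatures
u and beta stay frozen.

All gradients are computed by hand (the networks are small ReLU MLPs) and
optimized with Adam. A single seed controls initialization noise use,
batch shuffling and the reparameterization draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import likelihoods as lik
from .errors import DomainError, ShapeError
from .io import CountMatrix, ProportionMatrix
from .model import (
    SIGMA_FLOOR,
    DNNModel,
    EncoderOutput,
    VariationalModel,
    _decode_forward,
    _encode_forward,
    _sigmoid,
    _stack_forward,
    library_size_factors,
)
from .pseudospots import PseudoSpotBatch
from .sparsemax import sparsemax, sparsemax_jvp

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "LossReport",
    "kl_standard_normal",
    "supervised_loss",
    "elbo_loss",
    "train",
    "train_dnn",
    "deconvolve",
]


@dataclass
class TrainingConfig:
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 1e-3
    kl_weight: float = 1.0
    #: None = auto: use the number of genes, so the O(1) per-spot L1 term is
    #: commensurate with the reconstruction term, which sums over all genes.
    supervised_weight: float | None = None
    pseudo_ratio: float = 0.5
    seed: int = 0
    early_stopping: bool = True
    patience: int = 10
    val_fraction: float = 0.1
    pretrain_epochs: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pseudo_ratio <= 1.0:
            raise DomainError("pseudo_ratio must lie in [0, 1]")


@dataclass
class LossReport:
    """Final-epoch mean loss components plus per-epoch history."""

    total: float
    recon: float
    kl: float
    supervised: float
    history: dict[str, list[float]] = field(default_factory=dict)


def kl_standard_normal(enc: EncoderOutput) -> np.ndarray:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)) per spot (>= 0)."""
    mu, sigma = np.asarray(enc.mu_z, float), np.asarray(enc.sigma_z, float)
    if np.any(sigma <= 0):
        raise DomainError("sigma_z must be strictly positive")
    return 0.5 * (mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma)).sum(axis=-1)


def _check_simplex(v: np.ndarray, name: str) -> None:
    if np.any(v < -1e-8) or np.any(np.abs(v.sum(axis=-1) - 1.0) > 1e-5):
        raise DomainError(f"{name} rows must lie on the probability simplex")


def supervised_loss(
    pred: ProportionMatrix | np.ndarray, truth: ProportionMatrix | np.ndarray
) -> float:
    """Mean per-spot L1 distance between proportion rows; in [0, 2]."""
    p = pred.values if isinstance(pred, ProportionMatrix) else np.asarray(pred, float)
    q = truth.values if isinstance(truth, ProportionMatrix) else np.asarray(truth, float)
    if p.shape != q.shape:
        raise ShapeError(f"shapes differ: {p.shape} vs {q.shape}")
    _check_simplex(p, "pred")
    _check_simplex(q, "truth")
    return float(np.abs(p - q).sum(axis=-1).mean())


def _loglik_grad_mu(x, mu, model: VariationalModel):
    if model.likelihood == "nb":
        return lik.nb_logpmf_grad_mu(x, mu, model.beta[None, :])
    if model.likelihood == "poisson":
        return lik.poisson_logpmf_grad_mu(x, mu)
    return lik.zinb_logpmf_grad_mu(x, mu, model.beta[None, :], model.zinb_dropout[None, :])


def _loglik(x, mu, model: VariationalModel):
    if model.likelihood == "nb":
        return lik.nb_logpmf(x, mu, model.beta[None, :])
    if model.likelihood == "poisson":
        return lik.poisson_logpmf(x, mu)
    return lik.zinb_logpmf(x, mu, model.beta[None, :], model.zinb_dropout[None, :])


def _stack_backward(d_out, params, prefix, cache, grads):
    """Backward through a ReLU MLP; accumulates into grads, returns d_input."""
    acts, pres = cache
    d_h = d_out
    for l in range(len(pres) - 1, -1, -1):
        d_pre = d_h * (pres[l] > 0)
        grads[f"{prefix}.W{l}"] = acts[l].T @ d_pre
        grads[f"{prefix}.b{l}"] = d_pre.sum(axis=0)
        d_h = d_pre @ params[f"{prefix}.W{l}"].T
    return d_h


def _loss_and_grads(
    model: VariationalModel,
    X: np.ndarray,
    lib: np.ndarray,
    eps: np.ndarray,
    sup_mask: np.ndarray | None,
    Y_true: np.ndarray | None,
    kl_weight: float,
    supervised_weight: float,
):
    """One forward/backward pass over a mixed batch.

    Returns (total, recon, kl, sup, grads). ``sup_mask`` marks pseudo-spot
    rows carrying the supervised term; ``Y_true`` aligns with those rows.
    """
    n = X.shape[0]
    params = model.params
    enc, ecache = _encode_forward(model, X)
    mu_z, sigma = enc.mu_z, enc.sigma_z
    z = sigma * eps + mu_z
    Y, dcache = _decode_forward(model, z)

    s = model.s
    gamma = model.gamma
    YU = Y @ model.u
    base = s[None, :] * YU + gamma[None, :]
    mu_raw = lib[:, None] * base
    mu_x = np.maximum(mu_raw, lik.MU_FLOOR)
    floor_mask = mu_raw > lik.MU_FLOOR

    ll = _loglik(X, mu_x, model)
    recon = float(-ll.sum() / n)
    kl_vec = kl_standard_normal(enc)
    kl = float(kl_vec.mean())

    sup = 0.0
    n_sup = 0
    if sup_mask is not None and sup_mask.any():
        n_sup = int(sup_mask.sum())
        sup = float(np.abs(Y[sup_mask] - Y_true).sum(axis=1).mean())
    total = recon + kl_weight * kl + supervised_weight * sup

    grads: dict[str, np.ndarray] = {}

    # --- reconstruction path ---
    d_mu = -(1.0 / n) * _loglik_grad_mu(X, mu_x, model) * floor_mask
    B = d_mu * lib[:, None]
    grads["log_s"] = (B * YU).sum(axis=0) * s
    grads["gamma_raw"] = B.sum(axis=0) * _sigmoid(params["gamma_raw"])
    if model.likelihood == "zinb":
        grads["tau_logit"] = _tau_grad(X, mu_x, model) / n
    dY = (B * s[None, :]) @ model.u.T

    # --- supervised path ---
    if n_sup:
        dY_sup = np.sign(Y[sup_mask] - Y_true) * (supervised_weight / n_sup)
        dY[sup_mask] += dY_sup

    # --- decoder ---
    d_logits = sparsemax_jvp(Y, dY)
    grads["dec.Wout"] = dcache["h"].T @ d_logits
    grads["dec.bout"] = d_logits.sum(axis=0)
    d_h = d_logits @ params["dec.Wout"].T
    dz = _stack_backward(d_h, params, "dec", dcache["stack"], grads)

    # --- reparameterization + KL ---
    d_mu_z = dz + (kl_weight / n) * mu_z
    d_sigma = dz * eps + (kl_weight / n) * (sigma - 1.0 / sigma)
    sigma_raw = ecache["sigma_raw"]
    d_lv = d_sigma * 0.5 * sigma_raw * (sigma_raw > SIGMA_FLOOR)

    # --- encoder heads and stack ---
    h = ecache["h"]
    grads["enc.Wmu"] = h.T @ d_mu_z
    grads["enc.bmu"] = d_mu_z.sum(axis=0)
    grads["enc.Wlv"] = h.T @ d_lv
    grads["enc.blv"] = d_lv.sum(axis=0)
    d_h = d_mu_z @ params["enc.Wmu"].T + d_lv @ params["enc.Wlv"].T
    _stack_backward(d_h, params, "enc", ecache["stack"], grads)

    return total, recon, kl, sup, grads


def _tau_grad(X, mu, model: VariationalModel):
    """d(-mean loglik)/d tau_logit for the ZINB dropout, summed over spots."""
    beta = model.beta[None, :]
    tau = model.zinb_dropout[None, :]
    log_p0 = beta * (np.log(beta) - np.log(beta + mu))
    p0 = np.exp(log_p0)
    denom = tau + (1.0 - tau) * p0
    d_tau = np.where(X == 0, (1.0 - p0) / denom, -1.0 / (1.0 - tau))
    return -(d_tau * tau * (1.0 - tau)).sum(axis=0).ravel()


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def elbo_loss(
    model: VariationalModel,
    X_batch: CountMatrix | np.ndarray,
    seed: int | np.random.Generator = 0,
    library: np.ndarray | None = None,
) -> tuple[float, float]:
    """Single-sample Monte-Carlo (recon, kl) on a batch; reproducible from seed."""
    X = X_batch.values if isinstance(X_batch, CountMatrix) else np.asarray(X_batch)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if library is None:
        library = library_size_factors(X) if model.use_library else np.ones(X.shape[0])
    eps = rng.standard_normal((X.shape[0], model.latent_dim))
    total, recon, kl, _, _ = _loss_and_grads(
        model, X, library, eps, None, None, kl_weight=1.0, supervised_weight=0.0
    )
    return recon, kl


def train(
    model: VariationalModel,
    spatial: CountMatrix,
    pseudo: PseudoSpotBatch | None,
    config: TrainingConfig,
) -> tuple[VariationalModel, LossReport]:
    """Mini-batch training on real spots (ELBO) and pseudo-spots (ELBO + L1).

    Each batch mixes ``round(batch_size * pseudo_ratio)`` pseudo-spots with
    real spots. A held-out fraction of the pseudo-spots serves as a
    validation set for early stopping (patience on the validation L1); the
    best parameters are restored. ``pretrain_epochs`` optionally trains on
    pseudo-spots alone first.
    """
    if spatial.n_rows == 0:
        raise DomainError("spatial data is empty")
    if spatial.gene_ids != model.gene_ids:
        raise ShapeError("spatial genes do not match the model gene space")
    if pseudo is not None and pseudo.counts.gene_ids != model.gene_ids:
        raise ShapeError("pseudo-spot genes do not match the model gene space")

    model = model.copy()
    rng = np.random.default_rng(config.seed)
    opt = _Adam(config.learning_rate)
    sup_weight = (
        float(model.n_genes) if config.supervised_weight is None else config.supervised_weight
    )

    X_real = spatial.values
    lib_real = library_size_factors(X_real) if model.use_library else np.ones(X_real.shape[0])

    X_ps = Y_ps = lib_ps = None
    val_idx = np.array([], dtype=int)
    train_idx_ps = np.array([], dtype=int)
    if pseudo is not None and config.pseudo_ratio > 0:
        X_ps = pseudo.counts.values
        Y_ps = pseudo.true_props.values
        lib_ps = (
            library_size_factors(X_ps) if model.use_library else np.ones(X_ps.shape[0])
        )
        n_ps = X_ps.shape[0]
        n_val = int(round(config.val_fraction * n_ps)) if config.early_stopping else 0
        perm = rng.permutation(n_ps)
        val_idx, train_idx_ps = perm[:n_val], perm[n_val:]

    history: dict[str, list[float]] = {
        "total": [],
        "recon": [],
        "kl": [],
        "supervised": [],
        "val_supervised": [],
    }
    best_val = np.inf
    best_params = None
    stall = 0

    n_pseudo_batch = (
        int(round(config.batch_size * config.pseudo_ratio)) if X_ps is not None else 0
    )
    n_pseudo_batch = min(n_pseudo_batch, len(train_idx_ps))
    n_real_batch = max(config.batch_size - n_pseudo_batch, 1)

    total_epochs = config.pretrain_epochs + config.epochs
    for epoch in range(total_epochs):
        pretrain = epoch < config.pretrain_epochs
        real_order = rng.permutation(X_real.shape[0])
        ps_order = rng.permutation(train_idx_ps) if len(train_idx_ps) else train_idx_ps
        n_batches = max(int(np.ceil(len(real_order) / n_real_batch)), 1)
        ps_pos = 0
        ep = {"total": 0.0, "recon": 0.0, "kl": 0.0, "supervised": 0.0}
        for b in range(n_batches):
            parts_X, parts_lib = [], []
            if not pretrain:
                ridx = real_order[b * n_real_batch : (b + 1) * n_real_batch]
                parts_X.append(X_real[ridx])
                parts_lib.append(lib_real[ridx])
            sup_rows = None
            Yt = None
            if n_pseudo_batch:
                take = []
                for _ in range(n_pseudo_batch):
                    if ps_pos >= len(ps_order):
                        ps_order = rng.permutation(train_idx_ps)
                        ps_pos = 0
                    take.append(ps_order[ps_pos])
                    ps_pos += 1
                take = np.array(take)
                parts_X.append(X_ps[take])
                parts_lib.append(lib_ps[take])
                Yt = Y_ps[take]
            if not parts_X:
                break
            Xb = np.concatenate(parts_X, axis=0)
            libb = np.concatenate(parts_lib, axis=0)
            if Yt is not None:
                sup_rows = np.zeros(Xb.shape[0], dtype=bool)
                sup_rows[-Yt.shape[0] :] = True
            eps = rng.standard_normal((Xb.shape[0], model.latent_dim))
            total, recon, kl, sup, grads = _loss_and_grads(
                model,
                Xb,
                libb,
                eps,
                sup_rows,
                Yt,
                config.kl_weight,
                sup_weight,
            )
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b}: total={total}"
                )
            opt.step(model.params, grads)
            for k, v in zip(("total", "recon", "kl", "supervised"), (total, recon, kl, sup)):
                ep[k] += v
        for k in ep:
            history[k].append(ep[k] / n_batches)

        # validation on held-out pseudo-spots (posterior-mean forward pass)
        if len(val_idx):
            pred = _posterior_mean_props(model, X_ps[val_idx])
            val = float(np.abs(pred - Y_ps[val_idx]).sum(axis=1).mean())
            history["val_supervised"].append(val)
            if val < best_val - 1e-6:
                best_val = val
                best_params = {k: v.copy() for k, v in model.params.items()}
                stall = 0
            else:
                stall += 1
                if config.early_stopping and stall >= config.patience:
                    logger.info("early stopping at epoch %d (best val L1 %.4f)", epoch, best_val)
                    break
        else:
            history["val_supervised"].append(np.nan)

    if best_params is not None and config.early_stopping:
        model.params = best_params

    if history["total"]:
        report = LossReport(
            total=history["total"][-1],
            recon=history["recon"][-1],
            kl=history["kl"][-1],
            supervised=history["supervised"][-1],
            history=history,
        )
    else:  # epochs == 0
        report = LossReport(0.0, 0.0, 0.0, 0.0, history=history)
    return model, report


def _posterior_mean_props(model: VariationalModel, X: np.ndarray) -> np.ndarray:
    enc, _ = _encode_forward(model, X)
    Y, _ = _decode_forward(model, enc.mu_z)
    return Y


def deconvolve(
    model: VariationalModel, spatial: CountMatrix, batch_size: int = 4096
) -> ProportionMatrix:
    """Infer proportions using the posterior mean Z = E_mu(X) (no sampling).

    Deterministic: repeated calls give identical results. Processed in
    batches to bound memory on large datasets.
    """
    if spatial.gene_ids != model.gene_ids:
        if set(spatial.gene_ids) == set(model.gene_ids):
            spatial = spatial.subset_genes(model.gene_ids)
        else:
            raise ShapeError("spatial genes do not match the model gene space")
    out = np.empty((spatial.n_rows, model.n_types))
    X = spatial.values
    for start in range(0, X.shape[0], batch_size):
        out[start : start + batch_size] = _posterior_mean_props(
            model, X[start : start + batch_size]
        )
    return ProportionMatrix(out, list(spatial.row_ids), list(model.type_order))


def train_dnn(
    dnn: DNNModel,
    pseudo: PseudoSpotBatch,
    config: TrainingConfig,
) -> tuple[DNNModel, list[float]]:
    """Train the DNN ablation with the supervised L1 loss only.

    Returns the trained model and the per-epoch loss history.
    """
    rng = np.random.default_rng(config.seed)
    opt = _Adam(config.learning_rate)
    X = np.log1p(pseudo.counts.values.astype(float))
    Y_true = pseudo.true_props.values
    params = dnn.params
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(X.shape[0])
        ep_loss = 0.0
        n_batches = max(int(np.ceil(len(order) / config.batch_size)), 1)
        for b in range(n_batches):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            xb, yt = X[idx], Y_true[idx]
            h, cache = _stack_forward(xb, params, "dnn", len(dnn.hidden))
            logits = h @ params["dnn.Wout"] + params["dnn.bout"]
            Y = sparsemax(logits)
            loss = float(np.abs(Y - yt).sum(axis=1).mean())
            ep_loss += loss
            dY = np.sign(Y - yt) / xb.shape[0]
            d_logits = sparsemax_jvp(Y, dY)
            grads = {
                "dnn.Wout": h.T @ d_logits,
                "dnn.bout": d_logits.sum(axis=0),
            }
            d_h = d_logits @ params["dnn.Wout"].T
            _stack_backward(d_h, params, "dnn", cache, grads)
            opt.step(params, grads)
        history.append(ep_loss / n_batches)
    return dnn, history
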