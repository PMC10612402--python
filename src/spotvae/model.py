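"""Generative model and network components.

The generative story per spot i:

    z_i   ~ N(0, I_D)                                   (latent prior)
    Z_i   = E_sigma(X_i) * z_i + E_mu(X_i)              (reparameterization)
    Y_i   = sparsemax(D_omega(Z_i))                     (sparse proportions)
    mu_ig = l_i * (s_g * sum_t y_it u_tg + gamma_g)     (expected expression)
    X_ig  ~ NB(mu_ig, beta_g)   (or Poisson / ZINB variants)

where u_tg, beta_g are frozen at the reference-estimated signatures, s_g is
a trainable gene scaling, gamma_g a trainable additive noise, and l_i an
optional fixed per-spot library-size factor (total counts / median total).
The encoder takes log1p counts; sigma is produced as exp(0.5 * logvar) with
a small floor.

Networks are plain NumPy MLPs; forward passes cache pre-activations so the
training module can backpropagate by hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import likelihoods as lik
from .errors import DomainError, ShapeError
from .io import CountMatrix, ProportionMatrix
from .signatures import ReferenceProfile
from .sparsemax import sparsemax

SIGMA_FLOOR = 1e-4

__all__ = [
    "EncoderOutput",
    "LatentCode",
    "VariationalModel",
    "DNNModel",
    "init_model",
    "init_dnn",
    "encode",
    "reparameterize",
    "decode",
    "dnn_forward",
    "expected_expression",
    "count_log_likelihood",
    "library_size_factors",
    "save_model",
    "load_model",
]


@dataclass
class EncoderOutput:
    """Variational posterior parameters: mean and elementwise std per spot."""

    mu_z: np.ndarray
    sigma_z: np.ndarray


@dataclass
class LatentCode:
    """Standard-normal draws and the reparameterized samples z = sigma*eps + mu."""

    z_std: np.ndarray
    z: np.ndarray


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class VariationalModel:
    """All trainable parameters plus the frozen reference signatures.

    ``params`` maps names to arrays: encoder stack ``enc.W{l}``/``enc.b{l}``,
    heads ``enc.Wmu``/``enc.bmu``/``enc.Wlv``/``enc.blv``, decoder stack
    ``dec.W{l}``/``dec.b{l}`` with output ``dec.Wout``/``dec.bout``, and the
    gene parameters ``log_s`` (s = exp), ``gamma_raw`` (gamma = softplus) and
    ``tau_logit`` (tau = sigmoid, ZINB only).
    """

    params: dict[str, np.ndarray]
    u: np.ndarray
    beta: np.ndarray
    gene_ids: list[str]
    type_order: list[str]
    latent_dim: int
    hidden: tuple[int, ...] = (128, 128)
    likelihood: str = "nb"
    use_library: bool = True
    init_seed: int = 0
    _extra: dict = field(default_factory=dict, repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_order)

    @property
    def s(self) -> np.ndarray:
        return np.exp(self.params["log_s"])

    @property
    def gamma(self) -> np.ndarray:
        return _softplus(self.params["gamma_raw"])

    @property
    def zinb_dropout(self) -> np.ndarray:
        return _sigmoid(self.params["tau_logit"])

    def copy(self) -> "VariationalModel":
        return VariationalModel(
            params={k: v.copy() for k, v in self.params.items()},
            u=self.u,
            beta=self.beta,
            gene_ids=list(self.gene_ids),
            type_order=list(self.type_order),
            latent_dim=self.latent_dim,
            hidden=tuple(self.hidden),
            likelihood=self.likelihood,
            use_library=self.use_library,
            init_seed=self.init_seed,
        )


@dataclass
class DNNModel:
    """Ablation: a feed-forward map counts -> sparsemax proportions.

    Shares the decoder's hidden/output architecture but takes log1p counts
    directly — no latent variable, no sampling.
    """

    params: dict[str, np.ndarray]
    gene_ids: list[str]
    type_order: list[str]
    hidden: tuple[int, ...] = (128, 128)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def _init_stack(rng, prefix: str, dims: list[int], params: dict) -> None:
    for l in range(len(dims) - 1):
        params[f"{prefix}.W{l}"] = _glorot(rng, dims[l], dims[l + 1])
        params[f"{prefix}.b{l}"] = np.zeros(dims[l + 1])


def init_model(
    profile: ReferenceProfile,
    latent_dim: int = 10,
    hidden: tuple[int, ...] = (128, 128),
    likelihood: str = "nb",
    seed: int = 0,
    use_library: bool = True,
) -> VariationalModel:
    """Randomly initialize a model bound to the (frozen) reference signatures."""
    if likelihood not in ("nb", "poisson", "zinb"):
        raise DomainError(f"unknown likelihood {likelihood!r}")
    G, T = profile.n_genes, profile.n_types
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    _init_stack(rng, "enc", [G, *hidden], params)
    h = hidden[-1]
    params["enc.Wmu"] = _glorot(rng, h, latent_dim)
    params["enc.bmu"] = np.zeros(latent_dim)
    params["enc.Wlv"] = _glorot(rng, h, latent_dim)
    params["enc.blv"] = np.zeros(latent_dim)
    _init_stack(rng, "dec", [latent_dim, *hidden], params)
    params["dec.Wout"] = _glorot(rng, h, T)
    params["dec.bout"] = np.zeros(T)
    params["log_s"] = np.zeros(G)
    # softplus^{-1}(1e-4): start gamma near zero
    params["gamma_raw"] = np.full(G, -9.2)
    if likelihood == "zinb":
        params["tau_logit"] = np.full(G, -3.0)  # tau ~ 0.047 initial dropout
    return VariationalModel(
        params=params,
        u=profile.u.copy(),
        beta=profile.beta.copy(),
        gene_ids=list(profile.gene_ids),
        type_order=list(profile.type_order),
        latent_dim=latent_dim,
        hidden=tuple(hidden),
        likelihood=likelihood,
        use_library=use_library,
        init_seed=seed,
    )


def init_dnn(
    profile: ReferenceProfile,
    hidden: tuple[int, ...] = (128, 128),
    seed: int = 0,
) -> DNNModel:
    G, T = profile.n_genes, profile.n_types
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    _init_stack(rng, "dnn", [G, *hidden], params)
    params["dnn.Wout"] = _glorot(rng, hidden[-1], T)
    params["dnn.bout"] = np.zeros(T)
    return DNNModel(params, list(profile.gene_ids), list(profile.type_order), tuple(hidden))


# ---------------------------------------------------------------------------
# forward passes (with caches for manual backprop)


def _as_counts_array(X: CountMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, CountMatrix) else np.asarray(X)


def _stack_forward(x: np.ndarray, params: dict, prefix: str, n_layers: int):
    """ReLU MLP forward; returns output and a cache of (input, preacts)."""
    acts = [x]
    pres = []
    h = x
    for l in range(n_layers):
        pre = h @ params[f"{prefix}.W{l}"] + params[f"{prefix}.b{l}"]
        pres.append(pre)
        h = np.maximum(pre, 0.0)
        acts.append(h)
    return h, (acts, pres)


def _encode_forward(model: VariationalModel, X: np.ndarray):
    if X.shape[1] != model.n_genes:
        raise ShapeError(f"input has {X.shape[1]} genes, model expects {model.n_genes}")
    x = np.log1p(X.astype(float))
    h, cache = _stack_forward(x, model.params, "enc", len(model.hidden))
    mu = h @ model.params["enc.Wmu"] + model.params["enc.bmu"]
    lv = h @ model.params["enc.Wlv"] + model.params["enc.blv"]
    sigma_raw = np.exp(0.5 * lv)
    sigma = np.maximum(sigma_raw, SIGMA_FLOOR)
    return EncoderOutput(mu, sigma), {"stack": cache, "h": h, "lv": lv, "sigma_raw": sigma_raw}


def _decode_forward(model: VariationalModel, Z: np.ndarray):
    if Z.shape[1] != model.latent_dim:
        raise ShapeError(
            f"latent input has dim {Z.shape[1]}, model expects {model.latent_dim}"
        )
    h, cache = _stack_forward(Z, model.params, "dec", len(model.hidden))
    logits = h @ model.params["dec.Wout"] + model.params["dec.bout"]
    Y = sparsemax(logits)
    return Y, {"stack": cache, "h": h, "Y": Y}


def encode(model: VariationalModel, X: CountMatrix | np.ndarray) -> EncoderOutput:
    """Map counts to variational posterior parameters (deterministic)."""
    enc, _ = _encode_forward(model, _as_counts_array(X))
    return enc


def reparameterize(enc: EncoderOutput, seed: int | np.random.Generator = 0) -> LatentCode:
    """Draw z_std ~ N(0, I) and form z = sigma * z_std + mu."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_std = rng.standard_normal(enc.mu_z.shape)
    return LatentCode(z_std=z_std, z=enc.sigma_z * z_std + enc.mu_z)


def decode(model: VariationalModel, Z: LatentCode | np.ndarray) -> ProportionMatrix:
    """Map latent codes to sparse proportions (deterministic given Z)."""
    Zarr = Z.z if isinstance(Z, LatentCode) else np.asarray(Z)
    Y, _ = _decode_forward(model, Zarr)
    ids = [f"row_{i}" for i in range(Y.shape[0])]
    return ProportionMatrix(Y, ids, list(model.type_order))


def dnn_forward(X: CountMatrix | np.ndarray, dnn: DNNModel) -> ProportionMatrix:
    """Deterministic counts -> proportions map of the DNN ablation."""
    Xarr = _as_counts_array(X)
    if Xarr.shape[1] != len(dnn.gene_ids):
        raise ShapeError(
            f"input has {Xarr.shape[1]} genes, DNN expects {len(dnn.gene_ids)}"
        )
    x = np.log1p(Xarr.astype(float))
    h, _ = _stack_forward(x, dnn.params, "dnn", len(dnn.hidden))
    logits = h @ dnn.params["dnn.Wout"] + dnn.params["dnn.bout"]
    Y = sparsemax(logits)
    ids = [f"row_{i}" for i in range(Y.shape[0])]
    return ProportionMatrix(Y, ids, list(dnn.type_order))


def expected_expression(
    Y: ProportionMatrix | np.ndarray,
    profile: ReferenceProfile | np.ndarray,
    s: np.ndarray,
    gamma: np.ndarray,
    library: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Expected counts mu_ig = l_i * (s_g sum_t y_it u_tg + gamma_g)."""
    Yv = Y.values if isinstance(Y, ProportionMatrix) else np.asarray(Y, dtype=float)
    U = profile.u if isinstance(profile, ReferenceProfile) else np.asarray(profile, dtype=float)
    s = np.asarray(s, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(s <= 0):
        raise DomainError("gene scaling s must be positive")
    if np.any(gamma < 0):
        raise DomainError("gene additive noise gamma must be nonnegative")
    lib = np.asarray(library, dtype=float)
    if lib.ndim == 0:
        lib = np.full(Yv.shape[0], float(lib))
    return lib[:, None] * (s[None, :] * (Yv @ U) + gamma[None, :])


def count_log_likelihood(
    X: CountMatrix | np.ndarray, mu: np.ndarray, model: VariationalModel
) -> np.ndarray:
    """Per-spot log-likelihood sum over genes under the configured likelihood."""
    x = _as_counts_array(X)
    if np.any(x < 0):
        raise DomainError("counts must be nonnegative")
    if model.likelihood == "nb":
        ll = lik.nb_logpmf(x, mu, model.beta[None, :])
    elif model.likelihood == "poisson":
        ll = lik.poisson_logpmf(x, mu)
    elif model.likelihood == "zinb":
        ll = lik.zinb_logpmf(x, mu, model.beta[None, :], model.zinb_dropout[None, :])
    else:  # pragma: no cover
        raise DomainError(f"unknown likelihood {model.likelihood!r}")
    return ll.sum(axis=1)


def library_size_factors(X: CountMatrix | np.ndarray) -> np.ndarray:
    """Per-spot size factors: total counts / median total (1 if disabled)."""
    totals = _as_counts_array(X).sum(axis=1).astype(float)
    med = np.median(totals)
    if med <= 0:
        return np.ones_like(totals)
    return np.maximum(totals, 1.0) / med


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: VariationalModel, path: str | Path) -> None:
    """Serialize all parameters plus the self-describing config to one file."""
    config = {
        "gene_ids": model.gene_ids,
        "type_order": model.type_order,
        "latent_dim": model.latent_dim,
        "hidden": list(model.hidden),
        "likelihood": model.likelihood,
        "use_library": model.use_library,
        "init_seed": model.init_seed,
    }
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(config).encode(), dtype=np.uint8),
        u=model.u,
        beta=model.beta,
        **arrays,
    )


def load_model(path: str | Path) -> VariationalModel:
    with np.load(path) as data:
        config = json.loads(bytes(data["__config__"]).decode())
        params = {
            k.removeprefix("param::"): data[k] for k in data.files if k.startswith("param::")
        }
        u, beta = data["u"], data["beta"]
    return VariationalModel(
        params=params,
        u=u,
        beta=beta,
        gene_ids=config["gene_ids"],
        type_order=config["type_order"],
        latent_dim=config["latent_dim"],
        hidden=tuple(config["hidden"]),
        likelihood=config["likelihood"],
        use_library=config["use_library"],
        init_seed=config["init_seed"],
    )
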