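"""Cell-type expression signatures from a labelled scRNA-seq reference.

For each gene g the reference counts are modelled as

    X_cg ~ NB(o_c * u_{t(c),g},  beta_g)

where ``t(c)`` is the cell's type, ``o_c`` a fixed library-size offset
(total counts of cell c divided by the median total), ``u_tg`` the mean
expression of gene g in type t on the median-library scale, and ``beta_g``
a single inverse-dispersion per gene shared across types.

Estimation is joint maximum likelihood over (log u, log beta) by monotone
gradient ascent with an adaptive step: a step that would decrease the total
log-likelihood is halved and retried, so the likelihood trace is
non-decreasing by construction. Genes with zero counts in a type keep
u_tg = 0 exactly; all-zero genes get beta at the configured floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EstimationError, FormatError
from .io import CountMatrix, LabelVector
from .likelihoods import nb_logpmf, nb_logpmf_grad_beta, nb_logpmf_grad_mu

logger = logging.getLogger(__name__)

BETA_FLOOR = 1e-3
BETA_CEIL = 1e4

__all__ = ["ReferenceProfile", "estimate_signatures", "write_profile", "read_profile"]


@dataclass
class ReferenceProfile:
    """Per-type mean expression ``u`` (T x G) and per-gene inverse-dispersion ``beta``."""

    u: np.ndarray
    beta: np.ndarray
    type_order: list[str]
    gene_ids: list[str]
    loglik_history: list[float] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.u.shape != (len(self.type_order), len(self.gene_ids)):
            raise FormatError("u shape inconsistent with type_order/gene_ids")
        if self.beta.shape != (len(self.gene_ids),):
            raise FormatError("beta length inconsistent with gene_ids")
        if np.any(self.u < 0):
            raise FormatError("u entries must be nonnegative")
        if np.any(~np.isfinite(self.beta)) or np.any(self.beta <= 0):
            raise FormatError("beta entries must be positive and finite")

    @property
    def n_types(self) -> int:
        return len(self.type_order)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ReferenceProfile":
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        cols = [idx[g] for g in gene_ids]
        return ReferenceProfile(
            self.u[:, cols], self.beta[cols], list(self.type_order), list(gene_ids)
        )


def library_offsets(counts: CountMatrix) -> np.ndarray:
    """Fixed multiplicative offsets: total counts / median total counts."""
    totals = counts.total_counts().astype(float)
    med = np.median(totals)
    if med <= 0:
        return np.ones_like(totals)
    return totals / med


def _total_loglik(x, offsets, U, beta, type_idx):
    mu = offsets[:, None] * U[type_idx]
    return float(nb_logpmf(x, mu, beta).sum())


def estimate_signatures(
    reference: CountMatrix,
    labels: LabelVector,
    max_iter: int = 200,
    tol: float = 1e-6,
    offsets: np.ndarray | None = None,
) -> ReferenceProfile:
    """NB maximum-likelihood estimation of (u, beta) from labelled reference counts.

    Parameters
    ----------
    reference
        Cells x genes raw counts.
    labels
        One type label per reference cell (row order must match).
    max_iter
        Maximum accepted gradient-ascent iterations.
    tol
        Convergence on relative change of the total log-likelihood.
    offsets
        Optional fixed per-cell library offsets; computed from totals when
        omitted.
    """
    if reference.row_ids != labels.row_ids:
        raise EstimationError("reference rows and label rows do not match")
    type_idx = labels.indices()
    T = labels.n_types
    for t, name in enumerate(labels.type_order):
        if int((type_idx == t).sum()) < 2:
            raise EstimationError(f"cell type {name!r} has fewer than 2 cells")

    x = reference.values.astype(float)
    C, G = x.shape
    if offsets is None:
        offsets = library_offsets(reference)
    offsets = np.asarray(offsets, dtype=float)

    # moment initialization: offset-adjusted per-type means
    U = np.zeros((T, G))
    counts_per_type = np.zeros(T)
    adj = x / offsets[:, None]
    for t in range(T):
        sel = type_idx == t
        counts_per_type[t] = sel.sum()
        U[t] = adj[sel].mean(axis=0)
    mask = U > 0  # u_tg = 0 stays exactly 0 (no counts of gene g in type t)

    mu0 = offsets[:, None] * U[type_idx]
    resid2 = (x - mu0) ** 2
    excess = np.maximum((resid2 - mu0).sum(axis=0), 1e-12)
    beta = np.clip((mu0**2).sum(axis=0) / excess, BETA_FLOOR, BETA_CEIL)
    all_zero = ~mask.any(axis=0)
    beta[all_zero] = BETA_FLOOR

    log_u = np.where(mask, np.log(np.maximum(U, 1e-300)), 0.0)
    log_beta = np.log(beta)

    ll = _total_loglik(x, offsets, np.where(mask, np.exp(log_u), 0.0), np.exp(log_beta), type_idx)
    history = [ll]
    step = 1e-3
    converged = False
    onehot = np.zeros((C, T))
    onehot[np.arange(C), type_idx] = 1.0

    for _ in range(max_iter):
        Ucur = np.where(mask, np.exp(log_u), 0.0)
        beta = np.exp(log_beta)
        mu = offsets[:, None] * Ucur[type_idx]
        dmu = nb_logpmf_grad_mu(x, mu, beta)
        # chain rule through log u: dmu/dlog u = mu
        g_logu = onehot.T @ (dmu * mu)
        g_logu[~mask] = 0.0
        g_logbeta = beta * nb_logpmf_grad_beta(x, mu, beta).sum(axis=0)
        # normalize by dataset size so the step scale is problem-independent
        scale = 1.0 / max(C, 1)
        accepted = False
        for _ in range(40):
            cand_logu = log_u + step * scale * g_logu
            cand_logbeta = np.clip(
                log_beta + step * scale * g_logbeta, np.log(BETA_FLOOR), np.log(BETA_CEIL)
            )
            cand_ll = _total_loglik(
                x, offsets, np.where(mask, np.exp(cand_logu), 0.0), np.exp(cand_logbeta), type_idx
            )
            if cand_ll >= ll:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break  # no ascent direction at this precision: converged
        log_u, log_beta = cand_logu, cand_logbeta
        rel = abs(cand_ll - ll) / (abs(ll) + 1e-12)
        ll = cand_ll
        history.append(ll)
        step *= 1.2
        if rel < tol:
            converged = True
            break

    if not converged:
        logger.warning(
            "signature estimation did not reach tol=%.1e after %d iterations; "
            "returning last iterate",
            tol,
            max_iter,
        )

    U = np.where(mask, np.exp(log_u), 0.0)
    beta = np.clip(np.exp(log_beta), BETA_FLOOR, BETA_CEIL)
    beta[all_zero] = BETA_FLOOR
    return ReferenceProfile(
        U, beta, list(labels.type_order), list(reference.gene_ids), loglik_history=history
    )


def write_profile(profile: ReferenceProfile, prefix: str | Path) -> None:
    """Write a profile as a TSV pair: ``<prefix>.u.tsv`` and ``<prefix>.beta.tsv``."""
    prefix = Path(prefix)
    pd.DataFrame(profile.u, index=profile.type_order, columns=profile.gene_ids).to_csv(
        f"{prefix}.u.tsv", sep="\t", float_format="%.10g"
    )
    pd.DataFrame({"gene": profile.gene_ids, "beta": profile.beta}).to_csv(
        f"{prefix}.beta.tsv", sep="\t", index=False, float_format="%.10g"
    )


def read_profile(prefix: str | Path) -> ReferenceProfile:
    prefix = Path(prefix)
    u_df = pd.read_csv(f"{prefix}.u.tsv", sep="\t", index_col=0)
    b_df = pd.read_csv(f"{prefix}.beta.tsv", sep="\t")
    genes = [str(g) for g in u_df.columns]
    if [str(g) for g in b_df["gene"]] != genes:
        raise FormatError("u and beta files disagree on gene order")
    return ReferenceProfile(
        u_df.to_numpy(float), b_df["beta"].to_numpy(float), [str(t) for t in u_df.index], genes
    )
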