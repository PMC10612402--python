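"""Fully synthetic references and spatial tissues with known ground truth.

The generator emulates the data regime of cellular-resolution platforms:
low per-spot depth (mean total UMI in the tens to low hundreds), sparse
compositions (1 to k_max cell types per spot), and spatially layered tissue
(horizontal bands with soft borders, mimicking laminar structures such as
cortical layers). Reference cells follow the same NB generative process the
model assumes; tissue counts follow mu_ig = l_i * sum_t y_it u_tg with
NB(mu, beta) noise and log-normal depth heterogeneity, so the library-size
handling of the model is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .io import CountMatrix, LabelVector, ProportionMatrix, SpotCoordinates
from .metrics import MarkerSet
from .signatures import ReferenceProfile

__all__ = ["SimulationConfig", "simulate_reference", "simulate_tissue", "true_markers"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults match the regime the tool targets: T=5 types, G=300 genes,
    100 cells/type in the reference, a 50 x 40 grid of 2000 spots with mean
    total UMI 100, at most 3 cell types per spot, and gene dispersions
    log-uniform on [0.3, 10] (small beta = strong overdispersion).
    """

    n_types: int = 5
    n_genes: int = 300
    n_cells_per_type: int = 100
    grid_shape: tuple[int, int] = (50, 40)  # rows x cols; n_spots = product
    n_markers_per_type: int = 10
    marker_fold: float = 6.0
    cell_mean_umi: float = 2000.0
    mean_umi: float = 100.0
    beta_range: tuple[float, float] = (0.3, 10.0)
    k_max: int = 3
    band_softness: float = 0.6
    depth_sigma: float = 0.3  # sd of log-normal per-spot size factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise DomainError("need at least 2 cell types")
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise DomainError("more marker genes than genes")
        if self.k_max < 1:
            raise DomainError("k_max must be >= 1")
        if min(self.grid_shape) < 1:
            raise DomainError("grid must be nonempty")
        if self.marker_fold < 1:
            raise DomainError("marker_fold must be >= 1")

    @property
    def n_spots(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def gene_ids(self) -> list[str]:
        return [f"g{j:04d}" for j in range(self.n_genes)]

    def type_order(self) -> list[str]:
        return [f"type_{t}" for t in range(self.n_types)]


def true_markers(config: SimulationConfig) -> MarkerSet:
    """The marker genes the generator upregulates: genes [t*m, (t+1)*m) for type t."""
    m = config.n_markers_per_type
    genes = config.gene_ids()
    return MarkerSet(
        {
            t: genes[i * m : (i + 1) * m]
            for i, t in enumerate(config.type_order())
        }
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """NB(mu, beta) via the gamma-Poisson mixture; beta broadcast over rows."""
    lam = rng.gamma(np.broadcast_to(beta, mu.shape), mu / beta)
    return rng.poisson(lam).astype(np.int64)


def simulate_reference(
    config: SimulationConfig,
) -> tuple[CountMatrix, LabelVector, ReferenceProfile]:
    """Simulate a labelled scRNA-seq reference and return the true profile.

    Per-type means share a log-normal baseline across genes; each type's
    marker block is upregulated ``marker_fold``-fold. Cells get log-normal
    size factors (median-normalized, so the returned u is on the
    median-library scale) and counts drawn NB(u * sf, beta).
    """
    rng = np.random.default_rng(config.seed)
    T, G = config.n_types, config.n_genes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    u = np.tile(base, (T, 1))
    m = config.n_markers_per_type
    for t in range(T):
        u[t, t * m : (t + 1) * m] *= config.marker_fold
    u *= config.cell_mean_umi / u.sum(axis=1).mean()
    lo, hi = config.beta_range
    beta = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))

    n_cells = T * config.n_cells_per_type
    type_idx = np.repeat(np.arange(T), config.n_cells_per_type)
    sf = rng.lognormal(0.0, config.depth_sigma, size=n_cells)
    sf /= np.median(sf)
    mu = u[type_idx] * sf[:, None]
    x = _nb_draw(rng, mu, beta[None, :])

    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    types = config.type_order()
    labels = LabelVector(cell_ids, [types[t] for t in type_idx], list(types))
    counts = CountMatrix(x, cell_ids, config.gene_ids())
    profile = ReferenceProfile(u, beta, list(types), config.gene_ids())
    return counts, labels, profile


def simulate_tissue(
    config: SimulationConfig, profile: ReferenceProfile
) -> tuple[CountMatrix, SpotCoordinates, ProportionMatrix]:
    """Simulate a spatial tissue with banded (layered) type structure.

    Spots sit on a grid; each type occupies a horizontal band and a spot's
    type-sampling probabilities decay with distance to the band center
    (``band_softness`` widens the overlap between adjacent bands). Per spot,
    k ~ uniform{1..k_max} cells are drawn from those probabilities; the true
    proportions are the cell-count fractions. Counts follow
    NB(l_i * scale * (Y u)_ig, beta_g) with log-normal l_i and a global
    scale chosen so the expected mean total UMI equals ``mean_umi``.
    """
    rng = np.random.default_rng(config.seed + 1)
    H, W = config.grid_shape
    T = profile.n_types
    n = config.n_spots

    rows, cols = np.divmod(np.arange(n), W)
    y_frac = rows / max(H - 1, 1)
    centers = (np.arange(T) + 0.5) / T
    bandwidth = config.band_softness / T
    wgt = np.exp(-((y_frac[:, None] - centers[None, :]) / bandwidth) ** 2)
    wgt = np.maximum(wgt, 1e-12)
    probs = wgt / wgt.sum(axis=1, keepdims=True)

    ks = rng.integers(1, config.k_max + 1, size=n)
    Y = np.zeros((n, T))
    for i in range(n):
        picked = rng.choice(T, size=int(ks[i]), p=probs[i])
        Y[i] = np.bincount(picked, minlength=T) / ks[i]

    sf = rng.lognormal(0.0, config.depth_sigma, size=n)
    sf /= np.median(sf)
    mu0 = sf[:, None] * (Y @ profile.u)
    scale = config.mean_umi / mu0.sum(axis=1).mean()
    x = _nb_draw(rng, mu0 * scale, profile.beta[None, :])

    ids = [f"spot_{i:05d}" for i in range(n)]
    counts = CountMatrix(x, ids, list(profile.gene_ids))
    coords = SpotCoordinates(list(ids), np.column_stack([cols, rows]).astype(float))
    props = ProportionMatrix(Y, list(ids), list(profile.type_order))
    return counts, coords, props
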