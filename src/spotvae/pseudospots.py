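"""Pseudo-spots: labelled training spots pooled from reference cells.

A pseudo-spot pools k reference cells (k uniform on a small range, matching
the few-cells-per-spot regime of cellular-resolution platforms), sums their
counts, and optionally thins the sum binomially so the expected total UMI
matches the depth of the spatial dataset being analysed. The cell-count
fractions of the pooled cells are the known ground-truth proportions that
provide the supervised training signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .io import CountMatrix, LabelVector, ProportionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PseudoSpotBatch", "generate_pseudo_spots"]


@dataclass
class PseudoSpotBatch:
    """Pseudo-spot counts, their known proportions, and the cells pooled into each."""

    counts: CountMatrix
    true_props: ProportionMatrix
    provenance: list[list[str]]


def generate_pseudo_spots(
    reference: CountMatrix,
    labels: LabelVector,
    n_spots: int,
    cells_per_spot: tuple[int, int] = (1, 5),
    target_umi: float | None = None,
    seed: int = 0,
) -> PseudoSpotBatch:
    """Draw ``n_spots`` pseudo-spots from the reference.

    Per spot: k ~ uniform{k_min..k_max} cells drawn uniformly without
    replacement across the whole reference; counts summed; if ``target_umi``
    is set, each spot is binomially thinned with keep-probability
    ``target_umi / total`` so the expected total matches the target.
    True proportions are cell-count fractions. Fully reproducible from
    ``seed``.
    """
    k_min, k_max = cells_per_spot
    if k_min < 1:
        raise DomainError("k_min must be >= 1")
    if k_max < k_min:
        raise DomainError("cells_per_spot range is empty")
    if reference.n_rows == 0:
        raise DomainError("reference is empty")
    if k_max > reference.n_rows:
        raise DomainError(
            f"k_max={k_max} exceeds the {reference.n_rows} cells in the reference"
        )
    if reference.row_ids != labels.row_ids:
        raise DomainError("reference rows and label rows do not match")

    rng = np.random.default_rng(seed)
    type_idx = labels.indices()
    T = labels.n_types
    X = reference.values
    N, G = n_spots, reference.n_genes

    counts = np.zeros((N, G), dtype=np.int64)
    props = np.zeros((N, T))
    provenance: list[list[str]] = []
    ks = rng.integers(k_min, k_max + 1, size=N)
    for i in range(N):
        sel = rng.choice(reference.n_rows, size=int(ks[i]), replace=False)
        counts[i] = X[sel].sum(axis=0)
        tcounts = np.bincount(type_idx[sel], minlength=T)
        props[i] = tcounts / ks[i]
        provenance.append([reference.row_ids[c] for c in sel])

    if target_umi is not None:
        totals = counts.sum(axis=1)
        if np.all(totals <= target_umi):
            logger.warning(
                "target_umi=%.1f is not below any pseudo-spot total; skipping downsampling",
                target_umi,
            )
        else:
            keep = np.minimum(target_umi / np.maximum(totals, 1), 1.0)
            counts = rng.binomial(counts, keep[:, None])

    type_tally = np.bincount(type_idx, minlength=T)
    logger.info(
        "pseudo-spot type balance in reference (uniform cell sampling): %s",
        dict(zip(labels.type_order, type_tally.tolist())),
    )

    row_ids = [f"pseudo_{i}" for i in range(N)]
    return PseudoSpotBatch(
        counts=CountMatrix(counts, row_ids, list(reference.gene_ids)),
        true_props=ProportionMatrix(props, list(row_ids), list(labels.type_order)),
        provenance=provenance,
    )
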