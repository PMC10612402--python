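import numpy as np
import pytest

import spotvae as sv


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic study: reference + tissue with full ground truth."""
    cfg = sv.SimulationConfig(
        n_types=3,
        n_genes=60,
        n_cells_per_type=40,
        grid_shape=(12, 10),
        n_markers_per_type=5,
        mean_umi=80.0,
        k_max=2,
        seed=123,
    )
    ref, labels, truth = sv.simulate_reference(cfg)
    spatial, coords, props = sv.simulate_tissue(cfg, truth)
    return {
        "config": cfg,
        "reference": ref,
        "labels": labels,
        "true_profile": truth,
        "spatial": spatial,
        "coords": coords,
        "true_props": props,
    }


@pytest.fixture()
def tiny_profile():
    rng = np.random.default_rng(42)
    return sv.ReferenceProfile(
        u=rng.uniform(0.1, 5.0, size=(3, 8)),
        beta=rng.uniform(0.5, 5.0, size=8),
        type_order=["A", "B", "C"],
        gene_ids=[f"g{j}" for j in range(8)],
    )


def project_simplex_bruteforce(v: np.ndarray) -> np.ndarray:
    """Independent simplex-projection oracle: enumerate all supports.

    For each nonempty support S the candidate is v - tau on S (tau makes it
    sum to 1) and 0 elsewhere; the projection is the feasible candidate with
    the smallest Euclidean distance to v.
    """
    v = np.asarray(v, dtype=float)
    T = v.size
    best, best_d = None, np.inf
    for mask in range(1, 2**T):
        S = np.array([(mask >> i) & 1 for i in range(T)], dtype=bool)
        tau = (v[S].sum() - 1.0) / S.sum()
        p = np.where(S, v - tau, 0.0)
        if np.all(p[S] >= -1e-12):
            d = float(((p - v) ** 2).sum())
            if d < best_d:
                best, best_d = np.maximum(p, 0.0), d
    return best
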