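# spotvae

Cell-type deconvolution for **cellular-resolution spatial transcriptomics**
(Stereo-seq, Slide-seqV2, Pixel-seq and similar platforms). Spots on these
platforms are ~10 μm, capture one to a few cells and only a handful of UMIs,
and come in the hundreds of thousands — so per-spot compositions are sparse,
counts are noisy, and deconvolution has to be cheap per spot. `spotvae` is
for computational biologists who have such a spot × gene count matrix plus a
labelled scRNA-seq reference and want per-spot cell-type proportions.

## Model

A variational encoder–decoder with a count likelihood:

```
z_i  ~ N(0, I)                         latent prior (dim D)
Z_i  = E_σ(X_i) ⊙ z_i + E_μ(X_i)       reparameterized posterior sample
Y_i  = sparsemax(D_ω(Z_i))             sparse proportions on the simplex
μ_ig = l_i (s_g Σ_t y_it u_tg + γ_g)   expected expression
X_ig ~ NB(μ_ig, β_g)                   (or Poisson / ZINB)
```

Cell-type signatures `u_tg` and gene dispersions `β_g` are estimated from
the reference by direct NB maximum likelihood and frozen; the encoder φ,
decoder ω, gene scaling `s_g` and additive noise `γ_g` are trained by
minimizing `D_KL(q_φ(Z|X) ‖ N(0,I)) − E_q[log p_θ(X|Z)]` on real spots.
**Pseudo-spots** — pools of 1–5 reference cells with known cell-count
fractions, thinned to the spatial dataset's depth — are mixed into every
mini-batch and add a supervised L1 term on proportions. The **sparsemax**
output (Euclidean projection onto the simplex) produces exact zeros, so
inferred compositions are genuinely sparse rather than softmax-smoothed.
Details, parameter defaults and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

End-to-end on a synthetic layered tissue with known ground truth
(3 cell types, 120 genes, 300 spots at ~90 UMI/spot):

```python
import numpy as np
import spotvae as sv

cfg = sv.SimulationConfig(n_types=3, n_genes=120, n_cells_per_type=80,
                          grid_shape=(20, 15), mean_umi=90.0, k_max=2, seed=4)
ref, labels, _ = sv.simulate_reference(cfg)
spatial, coords, true_props = sv.simulate_tissue(cfg, sv.simulate_reference(cfg)[2])

profile = sv.estimate_signatures(ref, labels)
pseudo = sv.generate_pseudo_spots(ref, labels, n_spots=1500, cells_per_spot=(1, 2),
                                  target_umi=float(np.median(spatial.total_counts())), seed=4)
model = sv.init_model(profile, seed=4)
model, report = sv.train(model, spatial, pseudo, sv.TrainingConfig(epochs=60, seed=4))
inferred = sv.deconvolve(model, spatial)

for t, name in enumerate(inferred.type_order):
    r = np.corrcoef(inferred.values[:, t], true_props.values[:, t])[0, 1]
    print(f"{name}: Pearson r vs truth = {r:.3f}")
l1 = np.abs(inferred.values - true_props.values).sum(axis=1).mean()
print(f"mean per-spot L1 error = {l1:.3f}")
print(f"mean inferred support  = {inferred.support_sizes().mean():.2f} types/spot")

graph = sv.SpatialGraph.from_coordinates(coords, k=6)
print(f"Moran's I (type_0)     = {sv.morans_i(inferred.values[:, 0], graph):.3f}")
```

Output:

```
type_0: Pearson r vs truth = 0.936
type_1: Pearson r vs truth = 0.890
type_2: Pearson r vs truth = 0.947
mean per-spot L1 error = 0.210
mean inferred support  = 1.42 types/spot
Moran's I (type_0)     = 0.676
```

Reading it: each type's inferred proportion field tracks the truth
(r ≈ 0.9); the average L1 distance between inferred and true composition
rows is 0.21 (the metric ranges 0–2); spots carry ~1.4 nonzero types on
average, matching the k ≤ 2 cells/spot used to build the tissue; and the
inferred field of `type_0` is strongly spatially autocorrelated, as a banded
tissue should be.

The same pipeline is available from the shell:

```sh
spotvae simulate --out data --seed 4 --n-types 3 --n-genes 120 --grid 20 15
spotvae signatures --reference data/reference.tsv --labels data/labels.tsv --out-prefix sig
spotvae deconvolve --spatial data/spatial.tsv --reference data/reference.tsv \
        --labels data/labels.tsv --signatures sig --seed 4 --out props.tsv
spotvae evaluate --proportions props.tsv --spatial data/spatial.tsv \
        --coordinates data/coordinates.tsv --markers data/markers.tsv --out report.tsv
```

Accepted formats: dense TSV (header = gene ids, first column = spot ids) or
a Matrix Market triplet (`matrix.mtx` + `barcodes.tsv` + `features.tsv`);
proportions, coordinates, labels and markers are plain TSVs.

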