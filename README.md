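# spatialforces

Disentangling **intra-cellular** from **inter-cellular** gene–gene
interactions in spatially resolved transcriptomics, and generating
**counterfactual post-knockout** expression states under the learned
interactions.

A cell's expression profile mixes its intrinsic regulatory program with
the influence of its tissue neighborhood. Given a cells × genes
expression matrix with 2-D cell coordinates, `spatialforces` fits a
maximum-entropy (Ising/Potts-style) model on the spatial k-nearest-
neighbor graph whose parameters are two gene × gene force matrices:

- **G′ (intra-cellular)** couples genes within the same cell,
- **G (inter-cellular)** couples genes across neighboring cells.

The model is `p(S | G, G′) ∝ exp(H)` with

```
H = Σ_i  s_i · G′ · s_i  +  Σ_{i,j}  J_ij  s_i · G · s_j
```

where `s_i` is cell *i*'s spherically normalized (unit-L2) log
expression vector and `J` the binary kNN adjacency. The forces are the
Lagrange multipliers that pin the model's same-cell and neighbor-cell
gene–gene moments to their empirical values — analogous to partial
correlations in Gaussian graphical models, and hence deconfounded with
respect to indirect associations. Training minimizes the mean-field
surrogate of the negative log-likelihood,

```
L = Σ_i logsumexp_α(Z_iα)  −  zmft_scalar · Tr(Z Sᵀ),     Z = (J S) G + S G′,
```

whose gradient is exactly "model softmax moments − empirical moments".
Only the undirected interaction graph is identifiable from
observational data (the Markov equivalence class), so fitted matrices
are symmetric.

The same loss, with forces frozen and the state free, drives the
**generator**: projected gradient descent over non-negative unit-norm
expression rows finds the most probable tissue state, optionally with
knockout clamps (`s_j^β = 0`) held through every step — an in-silico
perturbation experiment with spatial resolution.

## Worked example

Recover known forces from a self-generated slide, then knock a gene out
and inspect how the perturbation propagates to the knocked-out cell's
neighbors:

```python
import numpy as np
from scipy.stats import spearmanr
from spatialforces import (ModelConfig, fit, generate, knockout,
                           make_fixture_slide, random_forces)
from spatialforces.preprocess import SpatialSample
from spatialforces.analysis import differential_change, neighbor_tiers
from spatialforces.energy import flatten_forces

truth = random_forces(4, seed=0)                       # ground-truth G, G'
raw = make_fixture_slide(64, 4, geometry="grid", seed=0)
gen = generate(truth, raw.adjacency, raw.expression,
               config=ModelConfig(epochs=150, learning_rate=0.05))
slide = SpatialSample(gen.final_state, raw.coords, raw.adjacency,
                      raw.gene_names, raw.cell_ids)
result = fit(slide, ModelConfig(epochs=150, learning_rate=0.02,
                                seed=104729, init="random"))
rho = spearmanr(flatten_forces(result.forces), flatten_forces(truth)).statistic
print(f"recovered-vs-truth Spearman rho: {rho:.3f}")

spec, cell = knockout(slide, "gene1", seed=0)
post = generate(truth, raw.adjacency, slide.expression, spec,
                ModelConfig(epochs=150, learning_rate=0.05))
tiers = neighbor_tiers(raw.coords, cell, r1=1.5, r2=2.5)
dc = differential_change(slide.expression, post.final_state,
                         np.flatnonzero(tiers == "first"),
                         np.flatnonzero(tiers == "other"), slide.gene_names)
print(dc.to_string(index=False))
```

Output:

```
recovered-vs-truth Spearman rho: 0.294
 gene  statistic  rank
gene2   0.019943   1.0
gene0   0.000000   2.5
gene3   0.000000   2.5
gene1  -0.021260   4.0
```

The recovered force matrices rank-correlate positively with the truth
(a random-initialization baseline centers on zero). After knocking out
`gene1` in cell 54, the per-gene change in that cell's first-tier grid
neighbors relative to distant cells shows `gene1` itself depressed and
`gene2` — the gene most negatively inter-coupled to `gene1` — relieved:
the response ranking agrees with the sign-flipped `g_inter` row of the
knocked-out gene (rho = 0.32 here; positive in ~90% of seeds).

## Command line

```bash
spatialforces fit --input sample_dir --k 6 --epochs 200 --seed 1 --out forces.h5
spatialforces perturb --forces forces.h5 --input sample_dir \
    --gene IFITM3 --cell random_positive --epochs 150 --seed 1 --out traj.h5
spatialforces simulate --n-genes 4 --n-seeds 20 --seed 7 --out report.csv
```

Samples are read from Matrix Market directories (`matrix.mtx`,
`genes.tsv`, `barcodes.tsv`, `coords.csv`), `.h5ad` files with
`obsm["spatial"]`, or CSV; forces round-trip through HDF5 or TSV.

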