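# Methods

## Model

Each spatial sample is a state `S ∈ R^{N×G}` of N cells over G genes,
with rows spherically normalized (unit L2) after a natural-log `log1p`
transform, plus the binary symmetric adjacency `J` of the k-nearest-
neighbor graph on the cell coordinates. The model is the maximum-entropy
distribution whose same-cell and neighbor-cell gene–gene moments match
the empirical ones:

```
p(S | G, G′) ∝ exp(H),    H = Σ_i s_i G′ s_iᵀ + Σ_ij J_ij s_i G s_jᵀ
```

`G′` (intra-cellular) and `G` (inter-cellular) are the Lagrange
multipliers of those moment constraints. Because `J` is symmetric and
each quadratic form only senses the symmetric part of its matrix, the
identifiable object is the pair of symmetric matrices — the undirected
interaction graph (the Markov equivalence class of any underlying
directed model). The fitting loop therefore projects both matrices to
their symmetric part after every update, and the simulation harness
verifies empirically that data generated from an asymmetric truth are
recovered as its symmetrized part.

### Mean-field loss

The exact partition function over continuous spherical states is
intractable. We replace it with a per-cell mean-field normalizer: with
the local field `Z = (J S) G + S G′`, each cell is treated as a
categorical unit over its G single-gene candidate states, giving

```
z_mft(Z) = Σ_i log Σ_α exp(Z_iα)        (stable logsumexp)
L(S, G, G′) = z_mft(Z) − zmft_scalar · Tr(Z Sᵀ)
```

This choice is made once and for a structural reason: its gradient in
the forces is exactly `softmax moments − zmft_scalar · empirical
moments`, i.e. the moment-matching stationarity the maximum-entropy
derivation demands (verified against central finite differences to
1e-5 in the test suite, and reported by the acceptance script).
`zmft_scalar ∈ (0, 1]` down-weights the energy term to keep the loss
lower-bounded when the mean-field assumption is badly violated; the
default is 1 (mean field taken as exact). Energies and partitions are
in natural-log units; there are no bias terms.

Conventions: the neighbor-aggregated term `(J S)` always carries the
inter-cellular matrix and the self term the intra-cellular matrix,
everywhere in the package. `L` is convex in `(G, G′)` for fixed data.

## Fitting (inference module)

Full-batch plain gradient descent, fixed learning rate (default 0.1),
zero initialization by default (the uniform model — and it makes fits
deterministic without any RNG); random symmetric initialization and an
Adam optimizer are opt-in. Multi-sample fits sum losses across samples
per epoch; slides at the scales this package targets make minibatching
unnecessary. Training runs exactly `epochs` epochs — no early stopping —
and reports the final gradient norm; convexity makes this auditable.
For force-matrix comparisons, matrices are flattened inter-then-intra
with diagonals included, so every correlation in the package refers to
the same vectorization.

## Generation (counterfactual module)

The generator minimizes the same loss in `S` with forces frozen,
projecting after every unconstrained step: clamp knockout entries to
zero, floor negatives at zero, renormalize rows to unit L2. A row that
projects to all-zero is re-seeded to uniform with a warning. A
halving-on-increase line search (default on, max 40 halvings) makes the
loss trajectory non-increasing to within numerical tolerance; when no
step along the projected ray descends, the state is held. Knockout
specs clamp `(cell, gene)` entries to exactly zero at every epoch, so
recorded trajectories satisfy the perturbation constraint identically,
not just at convergence. The projection scheme (rather than, say,
Riemannian descent on the sphere) was chosen because per-epoch scoring
of trajectories requires every recorded state to live in the model's
normalized domain.

De-novo generation starts from seeded uniform-random non-negative
unit-norm rows; counterfactual generation starts from the observed
sample so pre/post deltas are well defined.

## Simulation harness and study conditions

`self_consistency_experiment` runs, per seed: draw symmetric truth
forces with entries i.i.d. U(−1, 1) then symmetrized; draw a random
64-cell, 4-gene grid slide; generate the MAP slide under the truth
(150 epochs, step 0.05); refit from a random initialization (150
epochs, step 0.02, distinct seed stream from the truth draw); compare
flattened matrices to the truth by Spearman rho. Default 20 seeds. The
"generated-slide vs truth" branch is computed in moment space —
empirical moments `(Sᵀ J S, Sᵀ S)` of the generated slide correlated
against the truth forces — because correlating a count matrix with an
interaction matrix elementwise is dimensionally meaningless. Pooled
two-tailed Mann–Whitney U tests compare the rho families.

Epoch counts and learning rates are deliberately modest: recovery
quality is limited by the information content of a single MAP state
(one slide, N·G numbers constraining 2·G² parameters), not by
optimization budget — doubling the generation epochs moves the median
recovery rho by less than 0.1, which the suite checks.

The knockout-response experiment knocks out the most widely expressed
gene of each generated slide in a random positive cell, regenerates
under the clamp, and contrasts expression change between first-tier
neighbors and distant cells. Sign convention: a positive inter-cellular
force between the knocked-out gene β and gene α rewards neighbors for
expressing α; removing β's expression removes that reward, so the
expected neighbor response ranks genes like the **negated** g_inter
row of β. The reported `rho_implied` correlates against that implied
response.

### What the synthetic slides do and do not emulate

Fixture slides have uniform-random expression (before MAP shaping) on
a grid or uniform-random geometry. They exercise the model's own
generative assumptions — which is precisely what a self-consistency
experiment requires — but they do not emulate count noise, zero
inflation, segmentation error, cell-type structure, or spatial domains
of real Xenium/Visium data. Passing recovery tests therefore
demonstrates internal consistency and identifiability in practice, not
performance on tissue.

## Numerical choices

- `log1p` before spherical normalization: expression zeros are
  ubiquitous, so a plain log is undefined; base e throughout. Optional
  CPM library-size scaling precedes the log.
- kNN graph: k = 6 by default; directed k-nearest relations
  symmetrized by union; binary, unweighted, no row normalization (the
  empirical neighbor moment uses `J` as a 0/1 incidence). Distance ties
  break toward the lowest cell index (stable argsort), so duplicate
  coordinates are deterministic.
- Cropping rebuilds the adjacency from the cropped coordinates rather
  than slicing it, so boundary cells re-link inside the window.
- Spearman ties averaged; all p-values two-tailed. Shuffled-baseline
  nulls permute one flattened vector with a seeded generator.
- All seeds are plain integers; every derived seed is reduced mod
  2^31 − 1.

## Known limitations

- The mean-field normalizer is a surrogate; no claim is made about the
  exact partition function, and generation finds a MAP state, not
  samples from the full distribution.
- Pairwise forces only: multi-gene (3+) interactions are outside the
  model's degrees of freedom.
- Directionality (colliders) is not estimated; symmetric matrices are
  the ceiling of what observational data identify here.
- Rank-correlation p-values are meaningless at very small gene counts
  (with 4 genes the two-sided Spearman p cannot fall below 0.083);
  small-panel experiments should rely on effect directions aggregated
  over seeds, as the harness does.
- Gene-class contrasts take a user-supplied gene → localization
  mapping; no ontology retrieval is performed. Ranked gene lists export
  in two-column .rnk form for external enrichment tools.
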