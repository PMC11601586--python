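# rewirekit

Interpretable latent-factor analysis of exposure-driven transcriptional
rewiring in single-cell expression data.

## The scientific problem

Chronic exposures (such as cigarette smoke) do not just shift the mean
expression of individual genes — they rewire the co-expression programs
that genes participate in. Detecting that rewiring from droplet
single-cell data is hard for three reasons: the data are ~90% zeros;
co-expression programs overlap (one gene can serve several programs);
and any claim that a program is exposure-relevant needs error control
against the many programs tested.

`rewirekit` addresses this with four connected pieces:

1. **Identifiable overlapping factor estimation** (`rewirekit.love`).
   A three-step estimator of `X = Z Aᵀ + E` whose identifiability rests
   on *pure genes* — genes loading on a single factor — detected
   directly from the gene-gene correlation matrix. No orthogonality or
   sparsity-pattern assumptions; overlapping allocation rows are
   recovered by a minimum-ℓ₁ program.
2. **Protein-interaction subnetworks** (`rewirekit.networks`). Factors
   are split, re-factorized, and reduced to marker genes that seed
   OR-logic subnetworks of a protein-protein interactome, per cell type
   and exposure arm — the objects whose edge sets reveal rewiring.
3. **Knockoff-based factor selection** (`rewirekit.slide`). Model-X
   knockoffs on per-cell factor scores, iterated with fresh draws;
   factors (and factor-factor interactions) are reported only when
   their selection frequency clears a stability threshold.
4. **Cross-dataset transfer** (`rewirekit.cross_predict`). A selected
   factor's gene set is projected onto an independent, batch-shifted
   dataset and scored by AUC and a Mann-Whitney test, with permuted
   labels as the negative control.

A synthetic single-cell generator with full ground truth
(`rewirekit.synthetic`) makes every stage testable end to end; the
pipeline module wires the stages together with deterministic per-stage
seeds and run manifests. See `docs/methods.md` for the statistical
details and design decisions.

## Worked example

```python
import numpy as np
from rewirekit import (
    fit_love, make_truth, multistage_select, interaction_search,
    simulate_gaussian,
)

# a known truth: 300 genes, 6 overlapping factors, factors 0 and 1 drive
# the exposure outcome, plus a 0x1 interaction
truth = make_truth(K=6, seed=0)
X, Z, y = simulate_gaussian(truth, 1500, seed=100, label_mode="model")

# unsupervised: recover the factor structure from expression alone
model = fit_love(X, scale="covariance", seed=0)
print(model.K)                       # 6

# supervised: which factors drive the outcome?
marginals, freq = multistage_select(Z, y, iterations=100, seed=200)
pairs, _ = interaction_search(Z, y, marginals, iterations=100, seed=300)
print(marginals, pairs)              # [0, 1] [(0, 1)]
print(np.round(freq, 2))             # [1. 1. 0. 0. 0. 0.]
```

The `examples/` scripts walk the full analysis narrative; on the seeds
they ship with they print, among other things:

- `01_simulate_and_explore.py` — 2000 cells x 300 genes at zero
  fraction 0.900; the five pure genes of the signal factor occupy the
  top five DE positions (AUC 0.926–0.944).
- `02_unsupervised_networks.py` — exact pure-gene partition recovery
  (K = 4), 21 marker candidates filtered to 17, an OR-logic subnetwork
  of 35 nodes / 61 edges.
- `03_supervised_selection.py` — marginals `[0, 1]` and interaction
  `[(0, 1)]` at frequency 1.0, replicated-CV AUC 0.949, permutation
  p = 0.010 (the floor at 100 permutations).
- `04_cross_dataset_transfer.py` — transfer AUC 0.982 on a
  batch-shifted dataset (Mann-Whitney p ≈ 2e-147), permuted-label AUC
  0.492.

A thin CLI mirrors the pipeline stages:

```bash
rewirekit simulate --out-dir sim --seed 0 --n-cells 2000
rewirekit run --matrix sim/matrix.mtx --annotations sim/annotations.tsv \
    --genes sim/genes.txt --interactome sim/interactome.tsv --out-dir out
```

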