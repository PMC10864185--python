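# tcncommunity

Discovery of **tissue cellular neighborhoods (TCNs)** — spatially
coherent multicellular regions such as splenic compartments, brain
nuclei, or tumour/immune compartments — from single-cell spatial omics
maps (CODEX, MERFISH, MIBI-TOF, IMC).  The input per sample is minimal:
cell coordinates and a categorical phenotype per cell.

The method builds a k-NN cellular spatial graph with one-hot phenotype
attributes (A, F), passes it through one graph convolution
`X = ReLU(F Θ₁ᵀ + (A F) Θ₂ᵀ)` and a softmax assignment layer
`S = softmax(X Θ₃ᵀ)`, and trains the row-stochastic soft assignment
`S ∈ ℝⁿˣᶜ` with the relaxed normalized-MinCut objective

    L = − tr(SᵀAS)/tr(SᵀDS) + ‖ SᵀS/‖SᵀS‖_F − I_c/√c ‖_F .

Unsupervised mode trains an ensemble of independently seeded models per
map and consolidates their hard assignments by Hungarian label
alignment + majority vote.  Supervised mode adds differentiable graph
pooling (`X_pooled = SᵀX`, `A_pooled = SᵀAS`), a coarse-graph
convolution and a two-layer classifier, trained with
`β·L_MinCut + (1−β)·L_CE` (β = 0.9) under binary sample labels via
stratified 10-fold cross-validation — TCNs are then aligned across
samples by construction, enabling de novo discovery of
condition-specific neighborhoods.  Downstream statistics include
hypergeometric cell-type enrichment (−log10 BH-adjusted p), Spearman
within-TCN cell-type association, and permutation-tested canonical
correlation between TCN pairs.

Everything runs on numpy/scipy (the GNN trains on a small in-package
reverse-mode autodiff tape); no GPU or deep-learning framework is
required.

## Worked example

```python
import tcncommunity as tc

# a synthetic compartmentalized tissue with known ground truth
cfg = tc.SynthConfig(n_cells=1200, geometry="compartmentalized", seed=4)
cell_map, gt = tc.simulate_map(cfg)

rc = tc.RunConfig(mode="unsupervised", c=2, n_models=5, seed=0)
partition, vote_share, graph = tc.unsupervised_tcns(cell_map, rc)

print(f"k = {graph.k}, TCNs found = {partition.n_tcns}")
print(f"AMI vs ground truth = {tc.ami(gt.labels, partition.labels):.3f}")
print(f"macro-F1 vs ground truth = {tc.macro_f1(gt.labels, partition.labels).macro_f1:.3f}")
print(tc.enrichment_scores(partition, cell_map).scores.round(1))
```

prints

```
k = 35, TCNs found = 2
AMI vs ground truth = 0.842
macro-F1 vs ground truth = 0.977
     type00  type01  type02  type03
tcn
0     149.3    51.9     0.0     0.0
1       0.0     0.0   137.8    54.8
```

`k = 35` is the square-root-of-mean-cells default (√1200 ≈ 35).  The
two detected TCNs match the two simulated compartments almost cell for
cell (macro-F1 0.977; the AMI of 0.84 reflects the soft compartment
boundary).  The enrichment matrix shows each compartment's two resident
cell types strongly over-represented (scores are −log10 adjusted
p-values, capped by float precision) and the other compartment's types
at 0.

The same library drives a CLI for shell use:

```bash
tcncommunity simulate --geometry nuclei --n-cells 3000 --seed 7 --out-dir out/
tcncommunity train-unsup out/synth-nuclei-7.cells.tsv --seed 1 --out-dir out/
tcncommunity evaluate out/synth-nuclei-7.tcns.tsv out/synth-nuclei-7.gt.tsv
```

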