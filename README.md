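# editrace

A toolkit for designing, simulating and analyzing **prime-editing lineage
tracing** experiments, where cells carry cassettes of *edit sites* (ES) that
stochastically and irreversibly acquire one of S *lineage marks* (LM, short
nucleotide insertions).  The accumulated marks form a heritable character
matrix from which cell phylogenies can be reconstructed, and — because the
cassettes can also be read out in situ — linked to spatial position and
transcriptional state.

It is aimed at people building or benchmarking such recorders: how many edit
sites does a design need, how fast should editing run, how accurate are the
reconstructed trees under realistic detection, and how do lineage, space and
fitness interrelate in the resulting data.

## What it does

* **Recorder design** (`editrace.simulate`) — birth-death tree simulation
  (log-normal lifetimes, mean 1 day, σ = 0.5; death rate 0.25/day), stochastic
  LM accrual and detection dropout; closed-form and simulated saturation
  calculators.  A target edit fraction F over T days fixes the per-day rate
  `R = 1 − (1 − F)^(1/T)`; an unedited site then edits along a branch of
  duration t with probability `1 − (1 − R)^t`.  LM usage skew is modeled as
  `p_i ∝ e^(−λ i)` tuned to a target normalized entropy
  `H_norm = −Σ p_i log p_i / log S`.
* **Tree reconstruction** (`editrace.reconstruct`) — the weighted Hamming
  distance `d(i,j) = Σ_m δ(C_im, C_jm) / L` (δ = 0 on match or missing, 1
  when exactly one cell is unedited, 2 when both carry different marks; L =
  co-detected sites), neighbor joining rooted by a synthetic all-unedited
  outgroup, UPGMA, and a top-down greedy splitter.
* **Evaluation** (`editrace.evaluate`) — normalized Robinson-Foulds distance,
  depth-normalized triplets correct, and the Fowlkes-Mallows index
  `FMI = sqrt(TP/(TP+FP) · TP/(TP+FN))` between static-barcode groups and
  their best-matching tree clade; downsampling sweeps over detection rate and
  edit-site count.
* **Ancestral inference and timing** (`editrace.ancestry`) — Sankoff dynamic
  programming with asymmetric costs (install 0.6; erase or switch 1.0),
  collapse of mark-less branches, constant-rate branch-length estimation
  rescaled to the tracing duration, barcode LCA timing, extant-lineage counts
  through time, and per-site LM installation efficiencies.
* **Sequencing QC and clone calling** (`editrace.qc`) — adaptive
  mixture-model count thresholds, edit-state-aware conflict resolution,
  duplicate-integration and doublet filters, NMF/spectral clone calling with
  Jaccard doublet detection, and the greedy static-barcode grouping
  algorithm; plus a synthetic UMI-table generator with planted ground truth.
* **Editing kinetics** (`editrace.kinetics`) — bounded least-squares fits of
  `f(t) = s(1 − e^(−rt))` with s ∈ [0.8, 1], r ∈ [1e-4, 0.6].
* **Imaging decoding** (`editrace.decode`) — constant-weight error-correcting
  codebooks (21 bits, weight 6, minimum distance 4), an
  expectation-maximization intensity decoder with spot/bit normalization and
  per-bit SNR correction, per-site LM classification, and imaging QC rules.
* **Spatial-lineage statistics** (`editrace.spatial`) — phylogenetic
  (recent-common-ancestor window) and spatial (radius) neighbor graphs,
  Moran's I with permutation tests and BH correction, local LM diversity,
  the mean-neighbor-LM-distance fitness proxy, and pairwise
  phylo/character/spatial distance tables.

## Worked example

Simulate a 200-cell experiment (40 edit sites, 8 marks, 70% target edit
fraction, 80% detection), reconstruct the phylogeny, and score it:

```bash
editrace simulate --seed 7 --out-prefix run1 \
    --n-cells 200 --n-sites 40 --edit-fraction 0.7 --detection 0.8
editrace reconstruct --method nj --cm run1.cm.tsv --out tree.nwk
editrace evaluate --truth run1.nwk --recon tree.nwk --seed 0
```

prints

```json
{
  "normalized_rf": 0.39086294416243655,
  "triplets_correct": 0.7855555555555556
}
```

The observed matrix realizes 79.8% detection and a 68.2% edit fraction
(close to the targets).  `normalized_rf` counts topology splits private to
either tree over all splits in both: 0 is perfect, 1 is no shared structure —
a 200-leaf binary tree has many near-terminal splits, so 0.39 corresponds to
substantial deep structure being correct.  `triplets_correct` is easier to
read: for 78.6% of leaf triples (sampled evenly over ancestor depth) the
reconstruction places the odd-one-out correctly.  Planting three
static-barcode clades at 30% of the experiment and asking for their best
matching clades in the reconstruction gives a mean Fowlkes-Mallows index of
1.0 — the clade-level structure is recovered even where individual
near-leaf splits are not.

The same operations are available as library calls
(`editrace.simulate.simulate_experiment`,
`editrace.reconstruct.reconstruct_nj`, ...); the CLI is a thin wrapper that
adds provenance sidecar JSONs next to every output.

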