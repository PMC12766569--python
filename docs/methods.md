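# Methods

This note documents the models implemented in `editrace`, the defaults they
ship with, the numerical choices that matter, and what the synthetic
generators do and do not emulate.

## Birth-death lineage simulation

Trees grow from a single founder.  Each cell draws a lifetime from a
log-normal distribution and an independent exponential death clock; the cell
dies if the death draw is shorter than its lifetime, otherwise it divides
into two daughters.  The simulation stops when the number of living lineages
reaches the target population size (extant cells become leaves and keep
their full sampled lifetimes as branch lengths) or raises `ExtinctionError`
when every lineage dies first.  Dead lineages are pruned and pass-through
divisions contracted, summing durations.

Parameterization: "lifetime mean 1 day, sigma 0.5" is read as the
*natural-scale* mean and the *log-scale* standard deviation, i.e.
`mu = ln(mean) − sigma²/2`, which makes the distribution mean exactly 1 day
while keeping sigma the canonical log-normal shape parameter.  The death
"rate 0.25" is a hazard of 0.25 per lineage per day competing with division.
Both readings are choices — the natural alternatives (log-scale mean;
per-division death probability) change tree shape only mildly at these
values.  The founder's lifetime is kept as a stem above the root division
(`root_length`), so lineage counts through time start at one cell.

## Editing model

Editing is irreversible: an unedited site acquires exactly one lineage mark
and never changes again.  Two discretizations are used on purpose:

* **Tree overlays** use the continuous form: with per-day rate R, an
  unedited site edits along a branch of duration t days with probability
  `1 − (1 − R)^t`.  R is derived from the target end-point edit fraction F
  over the experiment duration T as `R = 1 − (1 − F)^(1/T)`; for simulated
  trees, T is the realized mean root-to-leaf time, so the mean leaf edit
  fraction converges to F across replicates.
* **Recorder-design calculators** use the simplified discrete framework:
  100 modeled root-to-leaf lineages, one division per day, no death, per-day
  per-site Bernoulli editing.  The expected saturation after T days at rate
  r is `1 − (1 − r)^T`, and the probability that division d (day d) is
  marked by at least one new edit with M sites is
  `P(d) = 1 − (1 − r(1 − r)^(d−1))^M`.

Installed marks are drawn from a fixed LM distribution, by default uniform
over S = 8 marks.  Skewed usage is modeled as `p_i ∝ e^(−λ i)` with λ found
by bisection against a target normalized entropy (monotone in λ; uniform is
returned exactly when the target is 1).

### Minimum-edit-sites search and its Monte-Carlo behavior

The minimum number of edit sites marking ≥ 90% of divisions is found by
scanning site counts and, per site count, edit rates 0–0.3 in 0.001 steps,
averaging the marked-division fraction over 10 repetitions of 100 lineages.
Two variance controls keep the 10-repetition procedure centered:

* One uniform tensor `U[lineage, day, site]` drives every (site count, rate)
  cell: a site edits on the first day its uniform falls below the rate.
  Per-rate estimates stay unbiased, and the marked-division set grows
  monotonically with the site count, so the site-count crossing is clean.
* Maximizing a noisy objective over 301 rates is biased upward by roughly
  `σ·sqrt(2 ln 301)` (σ ≈ 0.0025 here, and the crossing moves ~1 site per
  0.002 of objective), which would pull the reported minimum 2–3 sites low.
  The closed-form expectation above is therefore used to restrict the scan
  to a ±0.005 window around the analytically optimal rate (within which the
  shared-uniform estimates are strongly correlated and the maximization bias
  is negligible).  `rate_window=None` restores the full scan.

With these controls the procedure lands at the analytic crossings — 73 sites
for 20 doublings and 110 for 30 — with a spread of about ±1 site across
seeds at 10 repetitions.  At a single division (T = 1) the closed form gives
`1 − (1 − r)^M ≥ 0.9` at the grid cap r = 0.3, hence M = 7, which the
simulation reproduces exactly.

## Distances and reconstruction

The weighted Hamming distance between two cells sums per-site costs — 0 on a
match or when either state is missing, 1 when exactly one cell is unedited,
2 when both carry different marks — and divides by the number of co-detected
sites.  The 1/2 split makes a shared edit twice as informative as
presence/absence, the usual convention for irreversible recorders whose
per-site state space is dominated by the unedited state.  Optional per-site
weights multiply the cost and contribute their weight to the normalizer.
Pairs with no co-detected site receive the maximum finite distance plus one
(and are reported) rather than aborting a reconstruction.

Neighbor joining (scikit-bio) is rooted by appending a synthetic
all-unedited cell, rooting on it as an outgroup, and removing it; negative
NJ edge lengths are clipped at zero.  UPGMA uses scipy average linkage with
merge heights halved, so ultrametric inputs are recovered exactly.  The
greedy splitter recursively partitions on the (site, mark) pair carried by
the most cells that still splits the group (a flag selects least-frequent
instead; most-frequent is the default because with few distinct marks the
low-frequency choice is dominated by homoplasic singletons), sends missing
cells with the larger side, and emits a multifurcation when no informative
pair remains.  Ties break lexicographically for determinism.

## Tree comparison

Normalized Robinson-Foulds divides the symmetric difference of nontrivial
bipartitions by the total number of nontrivial bipartitions in both trees,
which keeps the range [0, 1] sensible for multifurcating trees.
Depth-normalized triplets correct samples leaf triplets evenly across the
truth-tree depth of their lowest common ancestor (the remainder goes to the
shallowest strata); a triplet counts as correct when the out-taxon agrees,
and an unresolved triplet (multifurcation) only matches an unresolved one.
When a stratum holds fewer triplets than its allocation its exact enumerated
mean is used — the limit of sampling without replacement — which also makes
the estimator exactly equal to the brute-force computation on small trees.

The Fowlkes-Mallows index between a barcode group and a clade is
`sqrt(precision × recall)` on the group/clade contingency; unbarcoded cells
are excluded.  The best-matching clade is found by scoring every internal
node's leaf set (ties prefer the deepest node, then the smaller clade; note
that a group split across the tree can tie between the root and small
clades containing single group members — the deep tie wins by rule).

## Ancestral states, branch lengths, growth

Sankoff dynamic programming runs per site over states {unedited, LM 1..S}
with costs: identity 0, install (unedited→LM) 0.6, erase or switch 1.0.
The root is constrained to all-unedited — cells start unedited at day 0 — and
the top-down backtrace breaks ties toward unedited, then the lowest mark.
Missing leaf entries contribute zero cost for every state and inherit their
parent's state in the backtrace.

Edges whose endpoints share identical state vectors are contracted (leaves
never), which is idempotent and leaves every surviving internal edge
supported by at least one mark gain.  Branch durations then come from the
constant-rate model: an edge with u unedited parent sites of which k gain a
mark has duration `−ln(max(1 − k/u, 1/(2u)))/R`; zero-edit and zero-exposure
edges share the smallest positive estimated duration, and the whole tree is
rescaled so the *mean* root-to-leaf path equals the tracing duration (the
mean, not the maximum, so one noisy deep lineage cannot stretch the clock).

Extant-lineage counts cut the timed tree at a timepoint and count edges
spanning it; leaves are extant cells and stay counted from their birth
onward, and the founder stem contributes one lineage before the first
division.  LM installation efficiency counts unedited→mark transitions per
site along all branches, divided by unedited exposures and renormalized
within the site.

## Sequencing QC and clone calling

The mixture threshold fits a two-component Gaussian mixture to log counts
and removes items assigned to the lower-mean component.  A fit is treated as
degenerate — and filtering skipped with a warning — when there are fewer
than 20 values, the variance is zero, the component means coincide within
1e-3, or a one-component fit has no worse BIC (the practical unimodality
guard; without it the mixture happily bisects a single log-normal mode).

The canonical order matters: read-count filter, per-intBC UMI filter, clone
calling, duplicate-integration removal, conflict-doublet removal, and only
then conflict resolution — the duplicate and doublet rules detect allele
conflicts that resolution would erase.  All thresholds are strict
inequalities (duplicate intBC: multi-allele UMI fraction > 0.25 clone-wide;
doublet cell: conflicted-intBC UMI fraction > 0.25 for sequencing, > 0.50
for imaging).  Conflict resolution keeps the edited allele of a
single-site edited/unedited pair when it holds > 20% of the pair's UMIs
(expression lags the genome, so fresh edits are under-represented),
otherwise the max-UMI allele with a lexicographic tie-break.

Clone calling factorizes the cell-by-intBC UMI matrix with NMF (nndsvd
initialization, Frobenius loss; spectral clustering on detection patterns is
available for imaging data), derives clone intBC sets from the >50%
detection rule, and re-assigns every cell by maximal Jaccard similarity
against single clones and clone-pair unions: pair winners are doublets, best
similarity < 0.5 is unassigned.  The number of clones is a required
parameter.  Greedy barcode grouping iterates seed → cluster (barcodes in
> 80% of the seed's cells) → assign (cluster holds > 80% of a cell's
barcode UMIs) → validate (≥ 5 cells), with lexicographic seed tie-breaks.

### The synthetic UMI generator

`synth_umi_table` plants clones whose cassettes are drawn from a finite
intBC pool (default: half the disjoint size), so distinct clones share some
intBCs with different alleles — the overlap that makes merged doublet
profiles show conflicting alleles, as with a real bounded barcode whitelist.
True alleles get Poisson-distributed UMI support around depth 30 (+10);
PCR-error and ambient records get 1–2 UMIs, giving the clean bimodality the
mixture threshold assumes.  Duplicate integrations appear in ~60% of a
clone's cells; static barcodes are clone-wide and per-round.  It does *not*
emulate: expression differences between integrations, barcode swapping,
index hopping, cells with partial cassette loss, or clone sizes differing by
orders of magnitude — recovery rates measured on it are upper bounds for
real captures.

## Kinetics

`f(t) = s(1 − e^(−rt))` is fit by bounded trust-region least squares with
s ∈ [0.8, 1] and r ∈ [1e-4, 0.6], three starts across the rate range (the
small-r corner is nearly flat), timepoints under 20 cells dropped, and a
(0, 0) anchor added when day 0 is absent (editing starts at induction).
Fits are unweighted by default; `weight_by_cells=True` weights residuals by
the square root of the cell count.

## Imaging decoding

Codebooks are built as greedy lexicodes over all weight-6 vectors, accepting
a candidate iff it keeps the minimum pairwise distance ≥ 4; the construction
is validated (constant weight, minimum distance, unique ids) and externally
supplied codebooks can be loaded from CSV.  On the tiny instance n=6, w=3,
d=4 the lexicode reaches the brute-force maximum code size.

The EM decoder alternates: normalize the intensity matrix by the outer
product of per-spot and per-bit factors (initialized from 95th percentiles),
apply the per-bit SNR correction `(Xc − 1/snr)/(1 − 1/snr)` clipped above at
1, assign each spot to the Euclidean-nearest codeword via a KD-tree, mask
assignments at distance ≥ 1.7 (2.0 in whitelist mode), and re-estimate — spot
factors from all rows, bit factors and SNR (floored at 1.05) from unmasked
spots only.  Ten iterations suffice; the mean assigned distance is monitored
and its final value never exceeds the initial one on the synthetic suite.
Near-ties in the nearest-neighbor search break to the lower barcode id.
Color normalization across laser channels is applied once, before the loop,
when a bit→channel map is supplied; without a map no equalization is done,
because the per-bit factor already absorbs arbitrary per-bit scale and
blanket equalization distorts codeword subsets with uneven bit usage (it
also breaks the exact-decode property on clean data).  Reported per-bit
intensities are returned in raw input units.

Lineage marks are decoded per edit site from row-normalized 9-bit vectors
(8 marks + unedited); argmax is the baseline and a per-site multinomial
logistic regression (L2, C=1) improves on it under cross-hybridization
bleed.  Calls with probability < 0.7 are flagged low-confidence.  Imaging QC
applies, in order: mean assignment probability ≥ 0.7, brightest-spot
deduplication of identical detections, clone-wide duplicate-integration
removal (> 40% of cells with conflicting amplicons), segmentation-doublet
removal (> 50% conflicting amplicons), and in-mask-then-brightness conflict
resolution.

The spot simulator generates
`X[i,b] = brightness_i · efficiency_b · on(i,b) + background_b · (1 − on)`
plus brightness-proportional Gaussian noise, with background set by a
per-bit SNR.  It does not emulate spot-detection failures, optical
crowding, or spatially varying illumination.

## Spatial-lineage statistics

Neighbor graphs are binary and symmetric: phylogenetic neighbors share an
LCA within a time window (default 10 days; choose a window below the tree
span, or the graph saturates), spatial neighbors lie within a radius
(default 100 µm) in the same section.  Moran's I is computed on z-scored
values as `I = N/Σw · Σ w_ij x_i x_j / Σ x_i²`; significance is a one-sided
permutation test with `p = (1 + #{I_perm ≥ I_obs})/(1 + n_perm)` (values are
permuted; permuting graph labels is equivalent) and Benjamini-Hochberg
correction across a feature batch.  Under the null the permutation p-values
are uniform and E[I] = −1/(N−1).

Local LM diversity averages pairwise weighted-Hamming distances within a
100 µm neighborhood including the focal cell (neighborhoods below two
members give NaN).  The tree-independent fitness proxy is the mean
weighted-Hamming distance of a cell to its k = 20 nearest cells *in LM
space* (ties at the k-th rank break on cell order); recently expanded
(fitter) clades have accrued fewer private marks, so lower is fitter.
Pairwise distance tables sample up to 20,000 same-section cell pairs without
replacement and report phylogenetic (path time through the LCA), LM and
spatial distances plus a shuffled-position control.  Distances are 2-D
(per-section x-y).

## Known limitations

* Fitness does not feed back into division rates; the simulator is neutral.
* Cassette silencing, re-editing, and inter-mark transitions are not
  modeled in ground truth (the Sankoff costs tolerate them only as noise).
* The branch-length estimator is a per-edge closed-form MLE with global
  rescaling, not a full maximum-likelihood optimization over the tree; it
  recovers edge-duration *rank order* well (Spearman ρ > 0.5 in the
  recovery suite) but compresses extreme durations.
* The NJ implementation is the standard O(N³) algorithm, comfortable to a
  few thousand cells; desk-scale analyses here use hundreds.
* Recovery rates quoted anywhere in the test suite are measured on the
  synthetic generators described above and should be read as upper bounds
  for real data.
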