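# Methods

`hicgat` couples a biophysical null model for Hi-C contact specificity with
a graph-attention predictor of multi-label regulatory profiles, plus
attribution and variant-effect layers on top of the trained model. This
note records the models, the defaults and why they were chosen, the design
decisions that were genuinely open, and what the synthetic benchmark does
and does not demonstrate.

## Polymer ensemble null and contact filtering

A chromatin segment modeled at 5 kb resolution is represented as a
self-avoiding chain of beads (one bead per locus, unit bond length) grown
off-lattice inside a confining sphere: each bead is placed at unit distance
from its predecessor in a uniformly random direction and rejected if it
comes within the excluded-volume diameter of any earlier bead or leaves the
sphere; on a dead end the chain unwinds a few beads and regrows, with a
bounded failure budget. Pooling over chains and positions (a homopolymer is
translation invariant) gives the null contact probability `p0(s)` for each
genomic separation `s = |i - j|`, defined as the fraction of bead pairs at
separation `s` that lie within the contact threshold.

Defaults: excluded diameter 0.8 and contact threshold 1.5 bond lengths;
confinement radius set so the bead volume fraction is 10% (for 800 beads,
radius 8 bond lengths). These values are not critical — they only need to
produce a smooth, non-degenerate `p0(s)` — and all are configurable.
The desk-scale ensemble is 2,000 chains of 800 beads (about 6 s on one
CPU); the ensemble size can be raised to the 5x10^5 used in full-scale
work without changing any interface.

Observed counts are tested against a multinomial null: the map's total
depth `N` is allocated to pairs with probabilities
`pi_ij = p0(|i-j|) / sum_kl p0(|k-l|)`, and each pair receives the
one-sided binomial upper-tail p-value `P(Binom(N, pi_ij) >= c_ij)`.
Pairs with zero counts have p-value 1 and cannot be discovered, but they
remain in the Benjamini-Hochberg family, which is all `i < j` pairs of one
modeled window (at most 4 Mb). Pairs surviving BH at `q = 0.05` form the
non-random contact set. The binomial test is exact, parameter-free and
easily checked against a direct tail-sum oracle; because the binomial tail
is discrete and conservative, the realized false discovery proportion under
the matched null sits well below the nominal level (the acceptance suite
measures it by Monte Carlo). This calibration statement applies under the
matched generative model; on real Hi-C with overdispersion it should be
read as a ranking, not a guarantee.

The diagonal is excluded everywhere (a self-contact is not an edge);
separation-1 pairs are tested like any other. Raw integer counts are
tested; balancing/normalization is deliberately left upstream.

## Signal-centered graphs

A 1 kb peak defines a 5 kb feature window (2 kb flanks), clipped and
restored to full width at chromosome edges. Contact lookup uses the grid
bin with maximal overlap with that window (ties toward the lower
coordinate), so peak-resolution features and grid-resolution contacts
coexist. The subgraph is a star: the center bin plus every locus it is
paired with in the filtered contact set; neighbor-neighbor edges are never
materialized. Message passing uses both edge directions, so two layers
give neighbor -> center -> neighbor flow.

Matched random controls preserve degree exactly: each true neighbor is
paired with a uniformly sampled bin within +/-100 kb of it, excluding the
center, all true neighbors and previously drawn controls; if a neighbor has
no candidate the window widens by one bin step (logged) before failing.
Mixed graphs take the union of real and control neighbors with provenance
flags, doubling the edge set up to logged collisions. Consensus contact
sets across cell contexts intersect pair sets and keep the per-pair
maximum p/q (conservative).

## Model

Every node is encoded by a shared locus encoder into a d-vector:

- **seq / seq+dnase**: three same-padded conv blocks (kernel 15, ReLU,
  max-pool 5) over the 4 x 5000 one-hot; each block contributes global
  average and max summaries to the projection (multi-scale readout), so
  motif-scale filter responses reach the output without traversing the
  deeper blocks, and the max path keeps a short motif's response from being
  diluted by the 5 kb window. In seq+dnase mode the accessibility row
  bypasses the convolutions and joins the projection as window mean/max:
  filters then see pure sequence. Default channels (32, 32, 64), d = 128;
  the synthetic experiments use a smaller instance (channels (16, 16, 32),
  d = 32) sized for CPU runs.
- **dense**: a two-layer perceptron projecting a precomputed 4096-vector.

The encoder supports optional motif-informed initialization
(`ModelConfig.pwm_init`): leading first-layer filters are set to
match/mismatch templates of given motifs and their reverse complements
(+1 match, -1/3 mismatch, scaled 0.3) and remain trainable. This is the
standard PWM-seeding device and stands in for the sequence vocabulary a
large pretrained encoder brings; without it, a from-scratch CNN trained on
a few hundred 5 kb windows reliably learns accessibility but not base-level
sequence features, which leaves allele-swap predictions directionless.
The synthetic experiments seed the generator's motif; applications with
real data would seed database PWMs or none.

Two graph-attention layers follow. Per head: linear projection, edge
logits `LeakyReLU(a_dst . h'_v + a_src . h'_u)` (slope 0.2), softmax over
in-edges per destination, weighted sum of projected sources, ELU, head
concatenation; then dropout (0.1, training only), a residual connection
(linear shortcut when widths differ) and layer normalization. There are no
self-loops; a node's own information travels the residual path, and
isolated nodes pass through it unchanged (up to the norm). The subgraph
representation is `z_s = [e_center || mean over nodes of the GAT output]`,
and a linear head maps `z_s` to T per-assay logits.

The loss is masked binary cross-entropy computed in logit space
(`relu(x) + log1p(exp(-|x|))` for the softplus), averaged per center over
observed assays and then over centers with at least one observed assay.

### Two-stage training

Stage 1 fits encoder + linear probe on center windows only, early stopping
on validation loss (configurable patience). Stage 2 initializes all node
encoders from stage 1, freezes the first `freeze_depth = 2` conv blocks
(the motif filters), and trains the rest end to end; the optimizer is Adam
and the published full-scale schedule (lr 3e-5, weight decay 1e-6,
ReduceLROnPlateau factor 0.5 / patience 1 / floor 1e-7) is the default
`TrainConfig`. Both stages keep the best-validation checkpoint. Data are
split by chromosome: chr9 test, chr8 validation, chrY excluded, the rest
train.

The synthetic experiments use their own schedule (stage 1: lr 3e-3, weight
decay 1e-4, 80 epochs; stage 2: lr 1e-3, 30 epochs; batch 16), because at
a few hundred training centers the full-scale learning rate cannot move the
loss. Two further choices matter at this scale: training windows are
augmented by circular shifts (+/-1 kb) and reverse complementation —
which preserve labels but defeat the window-memorization solution a small
fixed training set otherwise invites — and stage 1 runs its full budget
relying on the best-validation checkpoint, since the sequence signal
emerges late (a long plateau followed by a drop).

### Evaluation

Per-class AUPR/AUROC; F1 at per-class thresholds optimized on the
validation set and applied to the test set; macro aggregates restricted to
classes with more than `min_positives` test positives (30 by default, as
appropriate for hundreds of assays; the 8-assay synthetic runs use 5).
Classes with one label value are excluded and logged. Paired comparisons
between models bootstrap centers.

## Attribution

The softmax coefficients on center-incoming edges are read as neighbor
contributions: the default aggregation averages over all heads of both
layers and renormalizes over neighbors (alternatives: final layer only, or
a single head). Which layer the published contribution maps use is not
derivable, hence the switch. Contributions are reported for the
neighbor-to-center direction only; distances are midpoint differences.
Downstream summaries: real-contact share on provenance-flagged mixed
graphs, distance-decay profiles (bootstrap CIs over centers; empty distance
bins are reported missing, never zero), and decile comparison plus Spearman
rank correlation against an external per-locus score table (pre-binned by
max, thresholds applied by the caller).

## Variant heads

- eQTL: `z = [e_TSS || e_var]`, the TSS window through the (fine-tuned)
  encoder and the variant-centered subgraph through the graph trunk (pooled
  GAT output, length d — following the d-dimensional reading of the
  published variant embedding). The "variant-centered 5 kb locus" is the
  grid bin containing the variant.
- Pathogenicity: the variant subgraph over the consensus contact set,
  featurized with cell-averaged accessibility, pooled to a d-vector.
- The cross-validated variant head is a two-layer perceptron
  (scikit-learn), stratified k-fold, reporting AUPR/AUROC/F1/Brier,
  reliability bins and top-k precision; folds are a deterministic function
  of (seed, n).
- Allele swaps substitute the alternate allele in the one node window
  containing the variant; indels re-extract a 5000 bp window centered on
  the variant so tensor shapes stay fixed. `delta_prob` is the difference
  of two deterministic forward passes, so the reference allele gives
  exactly zero. Zero deltas are excluded from sign agreement (no sign is
  defined) and counted. Dense-embedding mode does not support swaps (it
  would require re-running the external embedding model).
- Sign agreement is reported against the majority-direction baseline and
  stratified by |slope| quantiles with bootstrap CIs; perturbation
  enrichment contrasts the top fraction of |delta-prob| records against the
  remainder with a Fisher-exact 2x2 (Haldane correction when a cell is
  empty).

## Synthetic world

The generator plants everything the pipeline consumes, with ground truth in
a ledger, fully determined by (config, seed).

- **Hi-C**: Poisson counts with power-law expected decay `|i-j|^-1`,
  normalized to depth 1e5 per 800-bin (4 Mb) window; planted pairs are
  enriched 8x. Planted pairs emulate loop-scale hubs: 20 anchor loci per
  window, each contacting a few (mean 3) partner loci 10-100 kb away, 70%
  of partners motif-bearing. Hub anchors rather than isolated pairs are
  used so that subgraphs have realistic multi-neighbor stars — attention is
  only exercised (and the mixed-graph ablation only meaningful) at degree
  >= 2. Poisson rather than negative binomial is deliberate: the FDR
  calibration statement is documented as conservative under the matched
  generative model only.
- **Genome/accessibility**: random background with homotypic motif
  clusters. Active loci carry 8-24 exact copies of a 12-mer (the "dose");
  degenerate loci carry 1-4 one-mismatch copies; accessibility is elevated
  on both ("open"), so accessibility alone cannot separate active from
  inactive open loci and sequence is load-bearing. Cluster dose rather
  than single motifs is the key desk-scale choice: a single 12-mer in 5 kb
  is not learnable from a few hundred examples by any training regime we
  tried, whereas dose is graded, compositional and learnable — and it gives
  single-copy edits a well-defined direction.
- **Labels**: assay t fires on loci with dose >= theta_t, thresholds spread
  over 1..24, with label = 1 iff the center or any contacted neighbor
  passes (so graph context is informative by construction), then 5% label
  flips and 10% mask dropout. Dose thresholds rather than per-assay random
  active subsets keep labels a deterministic function of sequence + wiring;
  random subsets inject 40% irreducible label noise that drowns the
  sequence signal at this sample size.
- **Variants**: effect variants act on whole binding-site copies — the unit
  the labels are defined on: eQTL positives delete one exact copy from a
  cluster wired to a center (negative slope) or insert one copy into a
  wired partner locus (positive slope); negatives are type-matched edits at
  unwired loci plus neutral substitutions/deletions, so local appearance
  alone cannot settle the label. Pathogenic variants disrupt clusters
  (substitutions and copy deletions); benign are type-matched neutral
  edits. Single-base eQTLs with reliable directions are out of reach of
  the desk-scale model (its dose response is grounded per copy, not per
  base), which is why effect variants are structural here.
- The default world spans three 800-bin windows named chr1/chr8/chr9 so the
  fixed chromosome split applies, with 120 centers per window: all anchors
  plus fill biased 70% toward open loci (peaks arise at accessible sites,
  and exact-vs-degenerate status is then directly supervised).

### What the synthetic benchmark shows — and does not

Passing tests demonstrate that the implementation is internally correct
(oracle equivalences, invariants, calibration under the matched null) and
that the *mechanisms* work end to end: filtered contacts recover planted
pairs; graph context improves prediction when labels genuinely depend on
neighbors; attention concentrates on informative neighbors and prefers real
contacts over matched random ones; graph embeddings transfer to variant
classification; allele-swap directions track planted effect directions.
They do not demonstrate performance on real Hi-C/ChIP-seq data, which has
overdispersion, TAD structure, correlated assays, softer motif grammars and
base-resolution effect sizes none of which the generator emulates.

## Numerical choices

Float64 throughout the tensor engine; convolution via im2col + BLAS.
Attention softmax subtracts a per-destination constant shift for stability;
the loss is computed in logit space. Ties in max-pooling send the gradient
to the first maximizer; ties in center-bin overlap break toward the lower
coordinate. Seeds flow through `numpy.random.SeedSequence` spawns, and all
training loops are bit-reproducible given a seed on one machine. Problem
sizes used by the test and acceptance runs (2,000-chain ensembles, 200
Monte-Carlo replicates, 360-center worlds, 1 Mb mini-worlds for the
five-seed ablation) were chosen as the smallest instances at which the
measured effects are stable.

## Known limitations

- The growth algorithm biases long self-avoiding chains relative to exact
  uniform sampling over conformations (no importance reweighting); for a
  separation-pooled null this bias is second order, but it is a bias.
- The binomial test ignores overdispersion; on real Hi-C a count-dispersion
  model would be needed for calibrated q-values.
- The GAT is two layers on stars by design; multi-hop context is out of
  scope.
- Dense-embedding mode consumes fixed vectors; allele swaps and any
  sequence-level attribution are undefined there.
- At desk scale the encoder needs motif-informed initialization to be
  sequence-sensitive; conclusions about from-scratch motif learning cannot
  be drawn from these runs.
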