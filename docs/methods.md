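# Methods

## Model

The predictor maps a fixed genomic window to a symmetric, log-scale
chromatin contact matrix. Inputs are a five-channel one-hot DNA
sequence (channel order A, T, C, G, N; lowercase folded; the unknown
base is a genuine fifth channel) and per-base feature tracks (CTCF
ChIP–seq and ATAC–seq coverage by default), each `ln(x+1)`-transformed
with missing data treated as zero coverage. The prediction target is
`ln(1 + x)` of ICE-normalized counts; the transform is reversible via
`expm1`, is tracked by an explicit flag on every matrix so it is applied
exactly once, and handles zero counts (plain `ln x` would not).

Architecture, one code path for all scales:

- **Encoders.** Two 1D convolutional encoders (sequence: 5 input
  channels; features: 2). Each starts with a stride-2 convolution
  header, then one module per schedule entry: a residual block (two
  same-padded kernel-5 convolutions, each followed by batch
  normalization and ReLU, with an additive skip) and a scaling block
  (kernel-5 stride-2 convolution + BN + ReLU) that halves the length
  and sets the channel width. Full scale: window 2,097,152 bp, widths
  32,32,32,32,64,64,128,128,128,128,256,256, output 256 bins × 256
  channels.
- **Fusion.** The two encoder outputs are concatenated channel-wise and
  reduced to the transformer width by a learned width-1 convolution.
  (A 1×1 convolution is the minimal shape-consistent reduction.)
- **Transformer.** Stacked post-norm attention layers (full scale:
  eight layers, eight heads) with ReLU feed-forward blocks and a
  relative key–query positional term: logits are
  `(QW_q)(KW_k)ᵀ/√d_k + Q'Rᵀ` with one learned embedding per relative
  offset, clipped at the bin count. Head dimension is d_model / heads, so the
  attention stack stays self-consistent at every scale. Softmax weights are captured per head for
  attribution.
- **Pairwise concatenation.** Grid cell (i, j) concatenates the
  features of bins i and j → a 2·d_model-channel n×n grid (512×256×256
  at full scale).
- **Decoder.** Five dilated 2D residual blocks (kernel 3, dilations
  2,4,8,16,32; 1×1-projected skip where the width changes — the first
  block also projects the 2·d_model grid down to the decoder width),
  then a 1×1 convolution to one channel. The stack's receptive field is
  1 + 4·Σdilations = 249 cells per axis, spanning essentially the whole
  256-bin grid from any cell.

The architecture does not constrain the output to be symmetric;
`predict_window` symmetrizes by averaging with the transpose (exposed
as an option).

## Training

MSE loss against the log-space target, Adam (lr 0.002), cosine
learning-rate schedule with a 200-epoch period (no warm restarts, floor
0), batch size 8 at full scale. Three augmentations, applied per
sample per epoch:

1. uniform random window shift within ±max_shift (full scale 368,640
   bp), rounded to the bin grid so the re-extracted target stays
   aligned;
2. reverse complement of the sequence with feature reversal and target
   flip along both axes, probability 0.5;
3. Gaussian noise (sd 0.1) on all input channels — including, read
   literally, the one-hot sequence (switchable off) — after the track
   transform, since that is what the model actually consumes. The
   target never receives noise.

Validation windows are never augmented; the best checkpoint is chosen
by validation loss; a non-finite loss aborts with a diagnostic.
Splits are at chromosome level (train / validation / test).

## Desk-scale configuration and problem sizes

All CPU-scale experiments use: window 65,536 bp, bin 1,024 bp (64
bins), encoder widths 8,8,8,16,16,32,32,64,64, d_model 32, two
attention layers with two heads, decoder width 16; 281,561 parameters.
Training uses batch size 2 with windows enumerated every 4,096 bp and
±8,192-bp shifts, 32 epochs. The small batch and densely overlapping
windows maximize update steps per CPU-minute: the distance-decay
component of the loss is learned within a few epochs, while the
boundary-dependent block structure emerges only after a few hundred
gradient updates (roughly 150–550 across the runs observed here), so
the number of updates — not the number of distinct windows — is the
binding resource, and batch 2 reaches it in half the epochs of batch 4.
As a safety net against initialization-dependent stalls in the
decay-only solution, the desk fit restarts with a derived
initialization seed (up to twice, analogous to k-means ``n_init``) when
the train loss has not fallen below 0.65× its epoch-2 value by epoch
20 — escaped runs cut it well below that by then, stalled runs hold
~95% of it. Residual branches (both the 1D encoder
blocks and the 2D decoder blocks) start near identity by initializing
their final batch-norm scale at 0.1; without this damping, short
training runs can stall in a decay-only solution that ignores the
feature tracks, and whether they escape is seed-dependent. (A scale of
exactly zero would be frozen by the trailing ReLU's zero gradient.)

## Synthetic genomes

The generator emulates exactly the statistical structure the model
exploits in real data, with a manifest recording the ground truth:

- **Boundary elements** on a jittered regular grid (default 8 per
  262,144-bp chromosome → ~29-kb TADs); a fixed 19-bp CTCF-like motif
  is planted at each boundary, alternating orientation so that every
  other TAD has convergent motifs (a learnable orientation signal for
  the sequence encoder).
- **Tracks**: Gaussian-shaped coverage peaks (width 600 bp, height 4,
  background 0.2) at boundaries for CTCF; ATAC additionally at random
  "enhancer" decoy sites that carry no boundary.
- **Contacts**: `scale · exp(−d/λ)` (λ = 50 kb, scale 20) times
  `tad_boost = 2` for same-TAD cells and `loop_boost = 3` for
  boundary–boundary pixels, with multiplicative log-normal noise
  (sd 0.1 in log space — additive in the log domain, matching the
  homoscedasticity assumption of the MSE loss), symmetrized, then
  `ln(1+x)`.

Deliberately not emulated: realistic base composition, A/B
compartments, replication timing, distance-dependent noise, unmappable
regions. Passing recovery tests therefore shows the pipeline can learn
and screen planted boundary structure from coverage-like inputs; it
does not certify performance on real genomes.

## Metrics

- **Insulation score** at bin i with flank f:
  `(max(mean L, mean R) + pc) / (mean C + pc)`, with L and R the f×f
  intra-domain squares on the diagonal immediately left/right of i, C
  the f×f square of contacts crossing i, and the pseudocount pc
  defaulting to the chromosome-wide mean intensity within a 2-Mb
  diagonal band (capped at the matrix span for short chromosomes).
  Under this ratio TAD boundaries are local **maxima**. The score is
  invariant to jointly scaling matrix and pseudocount. Edge bins
  without full flanks are missing. Default flank 10 bins; every
  reported correlation states its flank.
- **Distance-stratified statistics**: per-diagonal means and Pearson r,
  missing when fewer than 3 finite pairs.
- **Per-diagonal normalization** onto a target:
  `t̂ = (σ_T/σ_M)(m − μ_M) + μ_T` per diagonal; a zero-spread source
  diagonal collapses to the target mean with a warning. Idempotent, and
  exact for per-diagonal positive affine distortions.
- **Observed/expected**: counts recovered by `expm1`, divided by their
  distance-stratum mean; zero strata give missing, not infinite.
- **Region selection** between two cell types: windows above the 10th
  intensity percentile, ranked by mean absolute insulation difference;
  "differential" is the top 20% by default; the direction of the
  similarity cutoff is configurable.
- **Virtual 4C**: for 100-bp bins within ±2.5 Mb of a viewpoint, count
  pairs with one end in the viewpoint's 5-kb centered window and the
  other in the bin's, normalized by total valid pairs.

## In silico screening

Fixed-window geometry deletes each of the n_bins bin-sized segments of
one window (256 experiments at full scale). Genome geometry centers a
1-kb deletion in its own window and advances by the deletion size, so
coverage is continuous over the chromosome interior; loci whose
centered window would leave the chromosome are skipped and recorded.
Deletions remove the span from every input channel, shift content left
and pad the window end (all-N sequence, zero features) — never
re-centered, so input length is preserved. Peak score = max − min over
the centered 3-bin window (truncated at edges). Element calling takes
the top fraction (default 1%) of loci by peak score, considering only
scores strictly above the track minimum (an all-constant track selects
nothing) with ties broken by coordinate. Elements are classified by
CTCF/ATAC peak overlap (Group 1 both … Group 4 neither, with
within-group impact tertiles) and annotated with precedence
boundary > promoter > enhancer > intragenic > intergenic (boundaries
center-expanded to 50 kb, promoters −5,000/+500 bp around the TSS
strand-aware, enhancers expanded to ≥1 kb). The "normalized impact
score" is a per-chromosome z-score.

## Enrichment and downstream statistics

TF profiles with fewer than 7,000 hits (scaled to genome size on
synthetic data) or a single experiment are dropped; profiles above
20,000 hits are uniformly downsampled with a fixed seed. Each profile
is tested by a two-sided Fisher exact test on the 2×2 table of screened
loci (element vs not × overlapping vs not) over a universe defaulting
to all screened loci; q-values are Benjamini–Hochberg; zero cells get a
+0.5 continuity-corrected odds ratio, flagged. Factor clustering
min–max normalizes odds ratios within each cell type, then k-means with
six centroids (fixed seed, k-means++ with 10 restarts). Intra-TAD
analysis distance-normalizes count matrices (each cell over its
diagonal total), then per reference TAD: paired two-sided t-test over
within-TAD upper-triangle cells, mean-intensity change, log2 fold
change of the means, BH-FDR; Gain/Loss requires FDR < 0.01,
|log2fc| > 0.25 and |change| > 0.1, all strict, signed by the change.
CRISPR screens normalize guide counts to reads-per-100k, form guide
fold changes Day 4 / Day 20 (a zero Day-20 count adds a pseudocount of
1 to both days for that guide, flagged), average per gene, and test the
guide fold changes against 1 with a two-sided one-sample t-test —
performed on raw fold changes, exactly as specified.

## Numerical and design choices

- **Autodiff core.** Training and gradient attribution run on a small
  reverse-mode engine over numpy (tap-loop 1D convolution, im2col 2D
  convolution, fused batch normalization); every operator is validated
  against central finite differences in the test suite. Graph
  construction is suppressed (`no_grad`) during inference and
  screening.
- Hi-C resampling between bin grids (10 kb → 8,192 bp at full scale) is
  separable area-weighted linear interpolation, which conserves total
  counts and is exact for constant matrices.
- Window enumeration starts at multiples of the step from position 0;
  windows touching exclusion intervals (telomeres/centromeres) or the
  chromosome end are dropped. The sliding step defaults to 40,960 bp
  (five 8,192-bp bins, a "40-kb" step on the binary grid) and is
  configurable, e.g. to a decimal 40,000 bp.
- Benchmark-mode enumeration (1-Mb windows, 0.5-Mb step) keeps a window
  when its midpoint is ≥1.5 Mb from both chromosome ends; over the
  packaged hg38 primary chromosomes chr1–22 + chrX (chrY excluded)
  this enumerates 5,935 regions genome-wide.
- Stitched chromosome maps average overlapping window predictions per
  cell, count-division applied uniformly including the chromosome
  edges; never-covered cells carry an explicit missing mask, not a
  sentinel value.
- Heterozygous-allele averaging expects all maps on the fused
  coordinate system; the normal alleles' cross-breakpoint cells are
  missing (interchromosomal contacts are not counted), so the output
  there equals the fused-allele prediction alone.
- GRAM's spatial normalizer Z is the number of positions in the layer
  (the double spatial sum collapses to one axis for 1D encoder
  layers); the region defaults to the full output map. Activation maps
  are known not to be stable under window shifts or retraining; no
  stability metric is defined.
- Checkpoints are single `.npz` files embedding the model configuration
  as JSON, so a checkpoint is self-describing.

## Known limitations

The desk-scale recovery experiment uses one training chromosome of a
three-chromosome genome; its correlations are stochastic in the
training seed at the second decimal. The full-scale configuration is
exercised for architecture contracts and single forward passes, not
trained here. Trans (interchromosomal) contacts, loop significance
calling, TAD calling, peak calling and read-level processing are out of
scope; TAD lists and peak sets are consumed as inputs.
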