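# Methods

## Data model

The unit of ingestion is the frame (88 continuous acoustic features per
25 ms analysis window, 10 ms hop); the unit of diagnosis is the utterance
(one contiguous infant vocalization, labeled ASD or TD by the subject's
diagnosis and with one of five vocalization types: 0 one syllable, 1 two
syllables / canonical babbling, 2 babbling, 3 first word, 4 atypical
voice). Feature tables are delimited text with one row per frame; column
naming is configurable (`TableSchema`). The package never touches audio.

## Normalization and grouping

Per-feature mean and SD are estimated on training-partition frames only
and frozen; validation/test frames are scaled with those factors
unchanged, so distribution shift between partitions is preserved rather
than hidden. The SD uses the population convention (divide by n), the same
convention that reproduces the reference cohort's published age SD.
Zero-variance features divide by an epsilon floor (1e-8) instead of 0, so
constant/silent features stay finite. Normalization precedes grouping.

Frames are grouped into consecutive, non-overlapping 5-frame windows; a
trailing remainder shorter than one window is discarded, and utterances
shorter than 5 frames yield zero windows and are flagged (`too_short`).
Overlapping windows were a design option; non-overlap is the simplest
reading of "grouped for each five frames" and keeps window counts exactly
floor(n_frames/5).

## Feature selection

For each of the 88 features, a two-sided Mann–Whitney U test compares the
ASD and TD frame-value distributions (scipy's asymptotic normal
approximation with tie correction; U counts pairs x>y with ties as ½).
Features are ranked by ascending p-value, ties broken by larger
|U − nm/2| then by lower index, and the top k = 54 kept. Ranking with a
fixed k, rather than a significance threshold, reflects that the target
dimensionality (54) is fixed for comparability. The test is applied to
frame-level values (the larger-n reading); utterance-level aggregation
would be a one-line change upstream of `select_features`.

## Semi-supervised auto-encoder

Symmetric dense stack 88–70–54–70–88. Hidden layers apply batch
normalization then ReLU; the decoder output layer is affine with no
activation, appropriate for z-normalized real-valued targets. An auxiliary
softmax head on the 54-dim bottleneck predicts ASD/TD (ASD one-hot (0,1)).
Losses: reconstruction is mean absolute error over samples and feature
dimensions; the auxiliary loss is binary cross-entropy with probabilities
clipped to [1e-7, 1−1e-7]; the total is L_recon + α·L_aux with α = 0.3
(larger α trades reconstruction fidelity for class separation of the
bottleneck). "L2 normalization" of weights is implemented as classic L2
weight decay (coefficient 1e-4) applied to weight matrices only — not to
biases or batch-norm parameters; explicit weight renormalization is the
alternative reading and was not taken.

Unstated optimization hyperparameters default to Adam with learning rate
1e-3, batch size 256 for the AE and 128 for classifiers; all are exposed
in `TrainConfig`.

## Classifiers

* SVM: linear kernel (liblinear, C = 1.0, unadjusted class weights) on the
  row-major flattened 5×88 window (element (f, j) at index 88·f+j, 440
  dims total).
* BLSTM: one bidirectional LSTM layer, 8 hidden units per direction
  ("eight cells" read as per-direction width), forget-gate bias initialized
  to 1. The sequence readout is the concatenated final forward/backward
  hidden states (mean-over-time pooling available via config), followed by
  batch norm, dropout (rate 0.2 by default; unstated upstream), and an
  affine softmax(2) output.
* Joint model: a trainable copy of the pretrained encoder maps each of the
  5 frames to its 54-dim bottleneck; the BLSTM consumes the latent
  sequence. Encoder and BLSTM receive gradient together (joint
  optimization); `freeze_encoder=True` keeps the encoder fixed as an
  ablation.

Training uses cross-entropy, Adam, and early stopping: stop after
`patience` (default 100) consecutive epochs without strict validation-loss
improvement, restoring the best-validation-epoch parameters.

## Decision rule and metrics

Window softmax outputs are converted to class indices (1 = ASD); an
utterance is ASD iff the mean index strictly exceeds 0.5 — a tie at
exactly 0.5 is TD, per the strict reading of "over 0.5". Confusion counts
take ASD as positive. Metrics: accuracy, precision, recall, F1,
UAR = (recall_ASD + recall_TD)/2, WAR = accuracy. Ratios with zero
denominators are reported as 0 and flagged (`undefined`), so an all-TD
predictor evaluates without crashing. Cross-validated results are pooled
over the five validation folds (counts summed before metrics); per-fold
metrics are also emitted since averaging convention affects UAR-style
numbers. The held-out test set is scored with the fold model of lowest
validation loss ("best model" read as best-validation checkpoint, not
post-hoc test selection).

## Splitting

Splits are at utterance level only — windows of one utterance never
straddle partitions. 10% of utterances go to the test set, allocated
proportionally within each vocalization-type stratum (largest-remainder
rounding); the rest are dealt round-robin into five folds per stratum,
with the starting fold rotated across strata, so fold sizes within a
stratum differ by at most one. Everything is deterministic given the seed.

## Numerical core

The AE and BLSTM run on a small in-package reverse-mode autodiff engine
over float64 numpy arrays (`asdvoice.nn`), gradient-checked against
central finite differences in the test suite. Models are tiny (≤ 10^4
parameters), so this is fast, and single-threaded numpy keeps training
bit-reproducible: identical config and seed give byte-identical run
reports.

## Synthetic cohorts

The generator emulates: two groups with configurable subject counts;
per-subject utterance counts and per-utterance frame counts drawn
uniformly from ranges (defaults 8–12 utterances, 20–50 frames ≈ 0.2–0.5 s
at the 10 ms hop); frame features as stationary AR(1) noise (lag-1
autocorrelation 0.8 by default, so 5-frame windows carry exploitable
short-time structure that per-frame baselines cannot use); a group mean
shift of `delta` (in within-group SD units) on the first `n_informative`
features, split ±delta/2 around zero; vocalization-type labels drawn from
the published per-group category mix (ASD .104/.409/.043/.011/.433,
TD .250/.414/.032/.054/.249 — renormalized from rounding); ages from the
published per-group Normal(19.20, 2.52)/(14.72, 2.45) months clipped to
6–24; durations from the 25 ms window / 10 ms hop accounting.

What it does *not* emulate: the covariance structure of real eGeMAPS
features (real features are strongly cross-correlated and heavy-tailed),
speaker-level random effects beyond the group mean, label noise,
recording/channel variation, and any dependence of features on
vocalization type or age. Passing recovery tests on these cohorts
therefore demonstrates that the pipeline's machinery is correct and can
exploit planted structure — not that comparable accuracy is attainable on
clinical recordings, where the published benchmark classifiers reach
utterance UAR well below the synthetic ceiling.

Default study conditions used by the recovery runs: strong effect delta=3
on 20 of 88 features with 40 subjects (≈ 400 utterances); null cohort
delta=0 with 20 subjects (≈ 200 utterances); selection recovery at delta=2
with 500 frames per group. At these scales the bundled runs use 15/25
(AE/classifier) epochs for the strong-effect run and 8/12 for the null
run — the planted effects are far stronger than clinical signal, so
convergence is quick and the 100-epoch-patience regime never triggers;
patience semantics are verified separately at unit level.

## Known limitations

* The printed UAR row of the benchmark table and the benchmark SVM
  accuracy cell are inconsistent with their own pooled confusion matrices
  (they appear to be per-fold averages); the package recomputes all
  metrics from counts and documents, rather than reproduces, those cells.
* The decoder is only pretrained support for the encoder; after joint
  fine-tuning the encoder no longer matches it, and reconstruction quality
  is not tracked during classifier training.
* Batch-norm running statistics are momentum estimates (0.9); very short
  training runs can leave them biased toward initialization.
* `LinearSVC` (liblinear) realizes the linear-kernel SVM; its squared-hinge
  objective differs negligibly from libsvm's hinge at these scales but is
  far faster on 440-dim windows.
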