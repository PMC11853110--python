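# Methods

## Overview

`gaitpress` implements a plantar-pressure gait-recognition pipeline for a
floor-mat sensor array: raw frame streams are condensed into per-stride
average bilateral pressure maps, a compact convolutional network
identifies enrolled walkers (closed set), and a CNN–autoencoder embedding
with cosine-similarity thresholding separates authorized from
unauthorized walkers (open set). Because suitable human walking data
cannot be bundled, the package ships a synthetic pressure-mat walk
simulator that reproduces the statistical structure the pipeline assumes;
every stage is exercised end to end on simulated cohorts.

## Sensing model

The walkway is three 64 cm × 40 cm piezoresistive mat units in series:
192 × 40 sensors at 1 cm pitch (7680 cells), sampled at 40 Hz, each
sample an 8-bit value in [0, 255]. A trial is one traversal recorded as a
`T × 192 × 40` stack. Saturation is modelled by clipping, never
wrap-around, and every traversal begins with at least one all-zero frame
(walkers start ahead of the mat).

## Synthetic walk generator

The generator's defaults encode the study protocol it emulates:

- **Cohort structure.** Subjects wear one of four discrete shoe sizes
  (US 3, 4, 7, 10); the default histogram for a 60-subject cohort is
  2 / 15 / 19 / 24. Body weight (≈42–98 kg, loosely tied to shoe size)
  scales peak cell pressure linearly, so summed pre-clipping frame
  pressure is monotone in weight.
- **Footprint template.** Each foot is a pair of anisotropic Gaussian
  lobes (heel + forefoot) rasterised onto the 32 × 16 segmentation-window
  grid, rotated by a per-subject step angle (2–7° outward) and hard-cropped
  to the rotated foot box so the footprint extent is exactly the
  size-dependent foot box (20×8 up to 25×10 cells). Bimodal heel/forefoot
  structure is the minimal realistic shape for a stance-averaged plantar
  pressure image.
- **Gait phasing.** Contacts alternate left/right at half-cycle spacing
  (cadence 36–44 frames/cycle per subject); each contact stays on the mat
  for 60 % of its cycle, with a sinusoidal load envelope whose early
  weight sits on the heel lobe and late weight on the forefoot lobe
  (heel-strike → push-off progression). Consecutive cycles therefore
  overlap in double support, and the stance/cycle ratio lands in
  [0.55, 0.65].
- **Lanes.** Left feet land in the left half-width of the mat, right feet
  in the right half, advancing 14–15 cells per step along the walking
  axis. This makes side assignment and footprint disjointness testable.
- **Carried load.** The 500 g condition shifts the template one cell
  forward (centre-of-pressure displacement) and scales magnitude by 1.05.
  The shift is exact by construction, which the load-effect test exploits.
- **Noise and anomalies.** Sensor noise is integer-rounded Gaussian added
  to active cells only (default SD 2 counts); anomalies are isolated
  single-cell spikes at full scale (255), injected per frame with
  default probability 0.02.
- **Rounds and unit steps.** A "unit step" is one single-foot contact;
  a walk of `s` contacts yields `s − 1` average maps. The scheduler sizes
  each round as four 11-contact traversals (10 maps each) plus a shorter
  top-up when needed, so a round yields exactly its nominal 40 (or
  configured) unit steps. Per subject, three unloaded (Type I) rounds
  precede one loaded (Type II) round.

What the generator does **not** model: ground-reaction-force dynamics,
sole tread patterns (the protocol standardises shoes), inter-stride
temporal correlation beyond fixed cadence, fatigue or speed drift, and
cross-talk between mat cells. Synthetic subjects are considerably more
mutually distinct than real humans; passing end-to-end tests demonstrates
that the pipeline machinery is correct and learnable signal flows through
it, not that real-cohort accuracies would be reproduced.

## Preprocessing

1. **Anomaly replacement.** A cell is flagged when it deviates from its
   8-neighbourhood mean by more than `z_threshold` (default 4.0)
   neighbourhood standard deviations; the SD is floored at 4 counts so
   quantisation jitter in flat regions cannot flag. Flagged cells are
   replaced by the mean of their non-flagged neighbours.
2. **Accumulation.** All frames of a traversal are summed cell-wise into
   a wide-integer map (no 8-bit clipping).
3. **ROI segmentation.** Connected components (8-connectivity) of the
   active summed map with mass ≥ `min_mass` (default 50) become footprint
   ROIs: a 32 × 16 window centred on the component's centre of mass
   (origin = round(centre − (size−1)/2), which commutes with mirror
   imaging), the component's cell coordinates, a side label from lateral
   position, and onset/offset frames measured on the component's own
   cells (first/last frame with nonzero pressure). An alternative
   localisation refines the window by maximising enclosed mass
   (`localization="correlation"`); both sit behind the same interface and
   agree to within two cells on clean walks.
4. **Gait cycles.** N onset-sorted contacts yield N − 1 stride cycles;
   cycle *i* spans onset *i* to onset *i + 2* (the same foot's next
   touchdown). The final cycle, lacking that landmark, is capped at the
   last contact's offset — the boundary choice only affects the last map
   of each traversal.
5. **Average maps.** Each foot's 32 × 16 window is summed over the
   cycle's frames and divided by the cycle duration; the left-foot half
   occupies columns 0–15 and the right-foot half columns 16–31 of the
   32 × 32 feature image. Mass conservation (mean × duration = windowed
   sum) holds to float tolerance.
6. **Augmentation and partitioning.** Horizontal flips double the
   training set only — test data is never augmented, so no leakage.
   Closed set: train on Type I rounds 1–2 of all subjects, test on Type I
   round 3 and the Type II round separately. Open set: train only on the
   known subjects' training rounds; everything else (knowns' held-out
   rounds plus all unknown-subject maps) is test data. For a 60-subject
   cohort at 40 unit steps per round this yields 4800 closed-set training,
   3840 open-set training and 5760 open-set testing unit steps.

Average maps are kept as non-negative reals; the only input scaling
before the network is division by the training-set maximum into [0, 1].

## Models

The classifier is three 3 × 3 convolution + 2 × 2 max-pool blocks with
filter progression 32→64→128 and ReLU activations, flattened into a
256-unit hidden layer and a K-way softmax (K = 60 closed set, 48 open
set at protocol scale). The 256-dimensional hidden activation is the
identity embedding. The autoencoder is a single mirror, 256 → 64 → 64-code
(ReLU) → 256 linear, trained with mean-squared reconstruction loss.
Training uses Adam (lr 1e-3), batch size 16, a subject-stratified 10 %
validation split, and a fixed epoch budget with no early stopping
(default 50; traces show convergence around epoch 20, and the scaled test
runs therefore train 20 epochs). All layers are implemented in numpy
(im2col convolutions), float32, fully deterministic given the
configuration seed.

Unspecified hyperparameters (kernel sizes, filter counts, pooling,
optimiser) follow the smallest standard configuration consistent with a
three-block architecture and the fixed 256-unit penultimate layer.

## Open-set identification

Enrolled 64-dim codes are standardized per dimension, (x − μ)/σ, with μ
and population σ fitted over the enrolled vectors only (variance floored
at 1e-8; zero-variance dimensions standardize to 0). Queries are
standardized with the enrolment-time parameters — no test-time refitting,
avoiding leakage from unknown-subject queries. Each enrolled subject is
summarised by the mean of their standardized vectors (a per-vector
max-similarity summary is available via `FeatureDatabase(summary="max")`
and is measurably more robust to the load condition's query drift; the
centroid summary remains the default). The query's cosine similarity to
the best gallery summary decides: accept as that subject if it reaches
the decision threshold (default 0.85), otherwise reject as unknown.
Exact ties resolve to the lowest subject id and are flagged. Decisions
are per unit step; a majority vote over a trial's steps is deliberately
not applied.

## Evaluation

Open-set counting treats "accepted as authorized" as the positive event:
FRR = FN/(FN+TP), FAR = FP/(FP+TN). Whether an accepted authorized query
also names the correct identity is tracked separately
(`tp_correct_id` / identity accuracy), since acceptance accuracy and
identification accuracy answer different questions. Accuracy, precision,
recall and F1 follow the standard confusion-count formulas; closed-set
multiclass metrics are macro-averaged one-vs-rest. Undefined ratios
(zero denominators) surface as NaN, never as silent zeros.

Threshold sweeps evaluate the empirical FAR/FRR step curves on the sorted
unique scores; the EER is read off by linear interpolation across the
grid interval where FAR − FRR changes sign. AUC is the Mann–Whitney
pairwise estimator (ties ½), which equals trapezoidal ROC integration.
Misclassification attribution aggregates confused closed-set pairs and
marks shared traits: equal shoe size, and body weights within 5 kg
(a tolerance consistent with which confused pairs the study counted as
weight-similar).

## Numerical and degenerate-input choices

- 8-bit saturation by clipping; anomaly replacement rounds back to the
  integer range.
- Sweeps and EER require non-empty genuine and impostor sets; empty
  sequences, empty databases, zero vectors in cosine similarity, and
  oversized footprints raise immediately with messages.
- Stage seeds fan out from one master seed via SHA-256, so any stage can
  be re-run in isolation with identical results; every report embeds the
  configuration hash.

## Scaled test conditions

The bundled end-to-end checks run a 12-subject cohort (9 known /
3 unknown, 20 unit steps per round, 20 CNN epochs, 40 AE epochs) — small
enough for a laptop CPU, large enough to show closed-set accuracy ≥ 90 %,
open-set AUC ≥ 0.95, and an EER far below the identical-template
control's. The control clones one subject's template across the cohort,
making identity unlearnable: its closed-set accuracy sits inside the
binomial confidence band of chance and its EER near 0.5, which guards
against label leakage through any pipeline stage.

## Known limitations

- Synthetic subjects are more separable than real people; closed-set
  accuracies near 100 % on the scaled cohort say nothing about the
  accuracy achievable on a human cohort.
- Because the synthetic codes are nearly perfectly separated (raw EER
  ≈ 0–4 %), enrolment standardization has no headroom to improve the EER
  here and can slightly worsen it, particularly under the load condition
  whose queries are displaced relative to the enrolment mean. On real,
  noisier cohorts standardization is reported to help; the package keeps
  it on by default but its benefit is not asserted by the test suite.
- The anomaly detector assumes spikes are isolated single cells; clusters
  of adjacent hot cells larger than the neighbourhood would survive.
- The simulator's trial/round bookkeeping treats a "round" as the unit
  that yields a fixed number of unit steps; it does not model the
  round-trip trial structure of a live acquisition session.
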