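# Methods

This note records the models behind each stage of the pipeline, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical conventions a reader would need to
reimplement the package.

## Gaze preprocessing

**Sampling model.** Gaze is a 30 Hz stream of (t, x, y, validity) samples;
one video frame spans 1000/30 ≈ 33.33 ms, and all frame-level products use
that spacing exactly (timestamps are real milliseconds; "30 Hz" and
"33.3 ms" are the same convention).

**Gap interpolation.** A gap is a maximal run of invalid samples bounded by
valid ones. Its *span* is the missing time at the nominal rate: the distance
between the bounding valid samples minus one nominal sampling interval, so a
single lost 30 Hz sample spans 33.3 ms and two lost samples span 66.7 ms.
Gaps with span ≤ 75 ms — shorter than a normal blink — are filled by linear
interpolation in time between the bounding samples; the interpolation weight
for an inner sample is the ratio of its temporal offset to the bounding
distance, which reduces to the endpoints correctly and makes the operation
idempotent. Longer gaps and gaps touching a recording boundary are left
untouched. Valid samples are never modified.

**AOI labeling.** A valid sample is *face gaze* (`e`) when it falls inside
the interlocutor's face region — the convex hull of the 68 facial landmarks
when available, else the face bounding box — dilated by a configurable error
margin in pixels (device angular error × pixels-per-degree; default 0).
Otherwise it maps to one of the eight outer cells of a 3×3 grid whose centre
cell is the face box, lettered row-major `a b c / d e f / g h i` with the
outer cells extended to the frame edges. The rare point inside the box
corner but outside the landmark hull is assigned the outer cell nearest by
box-edge distance. Only the `e` / not-`e` distinction affects downstream
statistics, so the outer-grid convention is downstream-neutral. A manual
override table (frame → letter) takes precedence over automatic labels.

**Fixation detection (I-DT).** Left-to-right greedy dispersion grouping:
from the current start sample the window extends while bounding-box
dispersion (width + height) stays within the threshold (default 60 px,
configurable; the threshold is a free parameter of the method); the maximal
window becomes a fixation if it spans at least the minimum duration
(100 ms), measured first-to-last sample. Invalid or unlabeled samples break
windows. A fixation's direction is the majority AOI vote of its samples; an
exact tie goes to aversion (conservative toward the shorter-duration class;
configurable). Fixation end times are the last sample's timestamp, so a
fixation's span systematically underestimates the underlying stable-gaze
duration by one sampling interval on average — see *Duration estimation*.

**Frames and coverage.** Each 33.3 ms frame takes the direction of the
fixation covering its midpoint (`missing` when none). Coverage is the
fraction of samples with a non-missing AOI label; a pair is flagged for
exclusion when either recording's coverage falls below 0.70.

## Speech annotation

Speech segments carry one of 14 tags and tile the session without overlap;
boundaries are nominally on a 10 ms grid (the segmenter's resolution), which
the package enforces as a lint warning rather than an error because
synthetic boundaries are exact reals. Pauses are classed by duration: micro
pauses are at most 200 ms by definition.

Dialogue acts follow ISO 24617-2: each unit has a unique id, a dimension
(one of 9), a communicative function (the standard's inventory of 56 = 26
general-purpose + 30 dimension-specific), optional certainty/sentiment
qualifiers, ISO 24617-8 DR-Core rhetorical relations (18 labels) with an
argument number, and functional/feedback dependence references to other
units. The validator checks id uniqueness, reference resolution,
dimension-specific functions appearing only under their home dimension
(general-purpose functions are legal everywhere), and DR-Core membership;
13 functions never observed in the interview corpus the defaults model are
kept in the vocabulary but flagged. A unit's time interval is the
concatenation of its word intervals (min start to max end).

Synchronization is rigid: the offset is the difference of the two
recordings' beep timestamps, and applying it maps both beeps to the same
global time. Re-segmentation cuts both participants' segment lists at the
union of all boundary times, preserving per-tag total duration exactly.

## Frame merging and ratio statistics

The merged table has one row per frame: sender, speech attribute(s), and
both participants' gaze directions. A frame takes the segment covering its
midpoint; a midpoint exactly on a boundary belongs to the later segment
(deterministic, order-independent). For the dialogue-act scheme the
attribute bundle is the covering unit's function, dimension, qualifiers,
first rhetorical relation and argument number, and the relative offsets (in
units, capped at 20; 0 = none) of its dependence references.

For a label S, occurrences are maximal frame runs labeled S. Within an
occurrence, frames with missing gaze are excluded from both numerator and
denominator (the worked example contains none; the choice is configurable in
effect by pre-filtering). Every maximal same-direction run contributes
(run frame count) / (occurrence's gaze-labeled frame count), kept as an
exact `fractions.Fraction`; in an occurrence without missing frames the
aversion and face-gaze ratios sum to exactly 1. Frequency proportions count
runs instead of frames. Mutual face gaze is the fraction of jointly
observed frames where both directions are face gaze; episodes are maximal
mutual runs and their duration is run length × 33.3 ms.

## Gaze-direction models

**Features.** One-hot groups per frame. The speech-tag profile has 20
channels: tag (14), sender (2), sender gender (2), an is-same-person flag
(1: the sender is the participant being predicted), and the partner's gaze
(1: face gaze). The published description of the dialogue-act input gives
the attribute list and the 137-channel total but not the exact
decomposition, so the shipped profile declares one: the four shared groups
above (6) + communicative function (56) + dimension (9) + certainty (3) +
sentiment (3) + functional and feedback dependence offsets (20 each) +
rhetorical relation (18) + argument number (2) = 137; the encoder asserts
the total, and the profile is the single source of truth. An empty
attribute leaves its group all-zero; an unknown value is an error.

**Windows.** Window 9 frames (≈ 300 ms, the scale of a mean aversion),
stride 3 (≈ the 100 ms minimum fixation). A session of T frames yields
⌊(T − w)/s⌋ + 1 windows; windows never cross sessions. The label is the
predicted participant's direction (aversion = 1) at the window's last
frame; windows whose label frame is missing are dropped, not imputed. The
default prediction target is the interviewer (who appears in several
sessions, hence has the most data), configurable to either role.

**Architectures.** Both are 1D CNNs over (window × channels) with a single
sigmoid output and a classification threshold of 0.5. gazeVGG: two blocks
of two kernel-3 convolutions (batchnorm + ReLU each), channel counts f and
2f, max-pool 2 and dropout 0.2 after each block, then dense 64 → dense 1.
gazeResNet: a stem convolution, a residual unit (two conv-batchnorm pairs
with an identity shortcut added before the final ReLU), pooling/dropout, a
channel-doubling bridge convolution, a second residual unit, and the same
dense head; a 1×1 projection shortcut is inserted automatically when a
unit changes channel count. Depth (2 blocks × 2 convolutions), kernel size
3 and channel doubling are this package's defaults — the source material
fixes the block pattern, pool size 2 and first-block filters (16 or 32;
other values warn) but not depth or kernels.

**Training.** Binary cross-entropy minimized by Adam (lr 10⁻³), L2 0.001
applied as weight decay to convolution and dense weights and biases (not to
batchnorm parameters), dropout 0.2, batch 64, reference budget 100 epochs.
The stack is implemented in numpy with hand-written backprop (`dyadgaze.nn`)
and verified against finite differences in both train and eval mode; a run
is bit-reproducible given the seed, which drives initialization, shuffling
and dropout masks. Validation is either expanding-window backtesting
(n + 1 contiguous blocks; split k trains on the first k and validates on
block k + 1, so the train:validation ratio equals k) or session-shuffled
k-fold CV (whole sessions are permuted by seed and partitioned; temporal
order within a session is never disturbed).

## Evaluation

Confusion matrices are row-normalized percentages over actual classes
(face gaze, aversion). Precision/recall/F use aversion as the positive
class by default; F is the harmonic mean; zero-denominator cases are
reported as 0 with an explicit degenerate flag. Fold reports give the
arithmetic mean and the *sample* standard deviation (ddof = 1) of per-fold
accuracies. Descriptive statistics normalize fixation counts per minute of
session and average fixation durations as printed (end − start).

**Duration estimation.** When the quantity of interest is the mean duration
of the *underlying* gaze state rather than of the detected fixation, the
estimator applies two corrections: (i) end-correction — one sampling
interval added to each span, since a span runs first-to-last sample; and
(ii) truncation correction — states shorter than the minimum fixation
duration are undetectable, so the corrected durations are fitted as a gamma
distribution left-truncated at (100 + 33.3/2) ms by maximum likelihood
(Nelder–Mead on log-parameters) and the fitted untruncated mean is
reported. The gamma family is the generator's own duration model; on real
data the fit is a modeling assumption. The estimator falls back to the
corrected sample mean for fewer than 30 fixations or a failed fit.

## The synthetic dyad generator

The generator produces the statistical structure the analysis assumes, not
realistic eye movements.

* **Gaze** alternates face gaze / aversion as a two-state semi-Markov
  process with gamma durations. Means default to the role-specific values
  the analysis is calibrated around (interviewer 648.9 / 258.2 ms,
  interviewee 585.8 / 313.2 ms); only these first moments are calibrated —
  the gamma form and its shape are this package's choice. The default
  shape 6 keeps nearly all states above the 100 ms detectability floor
  (≈ 3 % of interviewer aversion states fall under it) while leaving
  visible dispersion; smaller shapes make truncation dominate.
* **Geometry.** Samples sit at the state's anchor — the face-box centre
  for face gaze, a uniformly chosen outer-cell centre for aversion — plus
  uniform jitter in a 10 px disc. Anchors of consecutive states are at
  least ~160 px apart and within-state dispersion is at most 40 px, so
  states map 1:1 onto I-DT fixations at the 60 px threshold and the
  ground-truth frame directions are exact.
* **Speech** is a turn-alternating chain over the 14 tags with
  role-specific transition weights and gamma durations (micro pauses
  rejected above 200 ms); interviewer turns centre on question-reading and
  questionnaire-filling, interviewee turns on answering and thinking. Turn
  lengths default to 7 s / 14 s means.
* **Coupling.** At each gaze-state entry the mean aversion duration is
  scaled by exp(strength × bias) and the mean face-gaze duration by
  exp(−strength × bias), where bias is the active tag's aversion bias.
  Strength 0 returns the input path unchanged (exact identity). Defaults
  encode the qualitative asymmetry the analysis expects: interviewers
  avert during on-screen tasks (Read Question, Questionnaire Filling) and
  watch the speaker otherwise; interviewees avert while thinking,
  speaking and pausing. Under these defaults the interviewee's aversion
  rate per minute robustly exceeds the interviewer's, reproducing the
  role ordering of the descriptive statistics in expectation. Biases are
  read at state entry, so tags much shorter than a gaze state blur the
  coupling — intentional, as real coupling is not instantaneous.
* **Losses and clocks.** Tracking losses start as a Poisson process
  (default 0.1/s) with lengths from a configurable distribution; the
  default (uniform 5–30 ms) emulates sub-blink single-sample dropouts,
  which the 75 ms interpolation rule repairs completely. Blink- or
  occlusion-scale losses (which split fixations and reduce coverage) are
  modeled by passing longer lengths explicitly, as the coverage-exclusion
  tests do. The two recordings run on clocks offset by a configurable
  amount; the beep marker appears in both and recovers the offset exactly.

**What passing tests do and do not show.** The generator has no saccade
kinematics, no smooth pursuit, no head movement, no face-detection failures
correlated with behaviour, and tag boundaries aligned with true behavioural
states. Tests passing on it validate the measurement chain — repair,
labeling, grouping, merging, windowing, optimization — under the assumed
statistical structure; they do not certify accuracy levels on recorded
interviews, whose models face annotation noise and weaker, participant-
specific coupling.

## Problem sizes of the shipped checks

The acceptance script and end-to-end tests use reduced problem sizes chosen
to keep the whole suite in the tens of seconds on one CPU: the worked ratio
example is the printed 95-frame table; parameter recovery uses one
30-minute session per run; the coupling-discrimination check trains
gazeResNet (16 filters) for 20 epochs on six 2-minute sessions (~6,000
windows, 5 train / 1 validation). These sizes are properties of the checks,
not of the method; the training defaults (100 epochs, 16/32 filters) remain
the reference configuration.

## Known limitations

* The dialogue-act feature decomposition is a declared reconstruction;
  alternative decompositions with the same 137 total are possible.
* The I-DT dispersion threshold (60 px) and the outer-grid lettering are
  conventions; published fixation counts cannot be checked against them.
* The truncated-gamma duration estimator assumes the gamma family; on
  heavy-tailed real durations it would misestimate the truncation mass.
* The numpy CNN stack is single-threaded and intended for the data sizes
  here (10³–10⁵ windows), not for large-scale training.
* Mixed-model significance testing of the ratio statistics is out of
  scope; the exported tables are designed to feed external statistical
  tools.
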