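# Methods

`cpactivity` implements an accelerometer-based physical-activity
classification analysis for children with cerebral palsy (CP): tri-axial
wrist/hip/ankle signals at 30 Hz are cut into 10 s non-overlapping windows,
summarized by a 49-feature vector per placement, reduced by
minimum-Redundancy-Maximum-Relevance (mRMR) selection, and classified as
sedentary (SED), standing utilitarian movement (SUM), or walking (WALK) by
Random-Forest (RF) models trained at three personalization levels — group
(G, whole cohort), group-personalized (GP, one model per GMFCS level), and
fully-personalized (FP, one model per child).  Because no raw cohort data
are distributed, the package includes a synthetic-cohort generator that
plays the role of the study population; every downstream stage is exercised
and tested against it.

## Synthetic cohort and signal model

Each subject is a parameter vector drawn from GMFCS-level-specific ranges:
step frequency (Hz), walking oscillation amplitude (g, referenced to the
vertical ankle axis), gait irregularity (0–1), residual resting-movement
amplitude (g), utilitarian-movement amplitude (g), and sitting/standing
trunk tilts (degrees).  A recording is a gravity baseline plus a
class-specific movement process plus white sensor noise (0.002 g):

* **Gravity/posture.** The device Y axis is vertical when upright; supine
  rest rotates gravity onto Z.  Sitting tilts the trunk by 2–25°, standing
  by 0–18° (per-subject draws with per-trial jitter) — overlapping ranges,
  so posture is an informative but not decisive cue.
* **SED.** Band-limited (0.3–5 Hz, 4th-order Butterworth on white noise)
  residual movement — postural sway, fidgeting, tremor — at the subject's
  resting amplitude.
* **SUM.** The same band-limited process at the subject's utilitarian
  amplitude, arm-dominant across placements (wrist 1.2, hip 0.5, ankle 0.5)
  with mild axis anisotropy, superimposed on the resting process.
* **WALK.** A quasi-periodic vertical oscillation at the instantaneous step
  frequency (fundamental plus a 0.35-weight second harmonic, and
  half-frequency medio-lateral/antero-posterior components), amplitude
  scaled per placement (ankle 1.0, hip 0.6, wrist 0.45).  Gait irregularity
  drives slow frequency wander (±40 % × irregularity), amplitude modulation,
  and broadband gait noise (0.6 × irregularity × amplitude, further scaled
  2.2/1.0/0.7 at wrist/hip/ankle — arm swing in this population is voluntary
  and irregular, while the ankle carries the cleanest rhythm), smearing the
  spectral peak for the most impaired walkers.

SED and SUM deliberately share a spectral family so that *amplitude*, not
spectral shape, separates them; within a subject the SUM amplitude is a
3.5–8× multiple of the resting amplitude (capped at step-amplitude/5.5 so
the energy ordering SED < SUM < WALK holds at every placement), while
*between* subjects the amplitude ranges overlap — one child's quiet
table-wiping resembles another's restless sitting.  The overlap, and hence
the advantage of personalized models, widens from GMFCS I to III: resting
amplitude spans 0.004–0.012 g at level I but 0.003–0.030 g at level III,
walking amplitude falls (0.70–1.00 g vs 0.45–0.70 g) and gait irregularity
rises (0.03–0.10 vs 0.20–0.45).  A `heterogeneity` dispersion factor scales
every range's half-width about its midpoint.

All three placements of one subject share an event timeline (bout
boundaries, walking phase/amplitude modulation, tilt draws) generated from
one seed stream, with placement-specific amplitude scalings and independent
noise streams, mirroring a single body observed at three sites.  Identical
(profile, seed) inputs give bit-identical recordings.

### Protocols

The structured protocol is five 6-minute trials per subject (protocol 1:
supine rest, sitting/coloring, active video game, comfortable walk, brisk
walk; protocol 2 replaces sitting with table wiping).  By default every
subject completes protocol 1: the free-living sequence contains seated
sedentary behavior, and a fully-personalized model whose training data
holds only supine rest (protocol 2) has no upright low-movement class at
all — its free-living sitting windows are routed into SUM almost
arbitrarily, which is a statement about training-data coverage rather than
about domain shift, the phenomenon the free-living comparison isolates.
`cohort.protocol_assignment: alternate` reproduces the mixed-protocol
design (and with it that FP sitting failure, worth studying in its own
right).  The brisk walk multiplies step frequency by 1.25 and amplitude by
1.15.  The free-living protocol repeats
SED → WALK → SUM → WALK for 6 minutes with bout durations drawn per bout
(defaults: sitting and standing phases 75–105 s, walks 12–20 s — a couple of
minutes at the bench or table and ~15 s of walking between them, so that
label transitions touch only a minority of the 36 windows; shorter,
sub-window bouts are reachable through configuration).

A `domain_shift` factor in [0, 1] (default 0.75) morphs the free-living SED
and SUM amplitudes toward each other (children fidget while seated — modeled
as both a raised resting amplitude and intermittent 1–3 s movement bursts —
and perform utilitarian movements with less lateral motion).  At 0 the
free-living per-class distributions match the structured trials exactly; at
the default the SED/SUM separation largely collapses, reproducing the
lab-to-free-living accuracy decline as a tunable phenomenon.

### What the generator does not emulate

Real assistive devices (walkers, crutches), biomechanically detailed gait,
non-wear and device artifacts, energy-expenditure structure, and the
open-ended activity diversity of genuine free living.  Passing tests
therefore show that the pipeline recovers the study's *patterns* under a
controlled, heterogeneous population — not that the trained models would
transfer to real children.

## Windows and features

Windows are 10 s (300 samples), non-overlapping and consecutive; trailing
samples are dropped.  Label intervals are half-open [start, end), so
adjoining bouts partition time.  Two transition policies are implemented:
`drop` (the default) labels only homogeneous windows, and `majority` labels
a mixed window with its majority class when that class covers ≥ 50 % of
samples.  `drop` is the default because a window blending two activities has
features outside every pure-class training region — its classification is
essentially arbitrary — so scoring models on such windows measures the bout
pacing of the evaluation protocol rather than the classifier; restricting
evaluation to unambiguous windows is the standard choice in activity-
recognition validation.  The majority policy remains available for
sensitivity analyses of exactly that transition effect.  Unlabeled windows
are excluded from feature tables but counted.

Per axis, 15 features: min, max, mean, variance, SD, skewness, kurtosis,
25th/50th/75th percentiles, zero-crossings, energy, dominant frequency,
dominant magnitude, entropy; plus three Pearson cross-axis correlations and
the mean vector magnitude — 49 per placement, concatenated across the
placements of a set (W, H, A, W+H, W+A, H+A, W+H+A).  Conventions (pinned by
an independent brute-force oracle in the test suite): population moments
with excess kurtosis; linear-interpolation percentiles; zero-crossings as
sign changes of the mean-centered signal with exact zeros ignored; spectral
quantities from the DFT of the mean-centered, untapered window over non-DC
bins (0.1 Hz resolution, 15 Hz Nyquist), magnitudes scaled by 2/n; energy =
mean squared scaled magnitude; entropy = normalized Shannon entropy of the
non-DC power spectrum; zero-variance axes yield skew = kurt = entropy =
domfreq = dommag = 0 and zero correlations, keeping tables free of missing
values.  No band-pass filtering is applied.

## Feature selection

mRMR with the MID (difference) criterion: greedy forward selection of the
feature maximizing I(f; class) − mean over selected s of I(f; s), with
plug-in mutual information (nats) on 10 equal-frequency bins (rank rule:
value with stable rank r of n gets bin ⌊r·B/n⌋; a constant column is one
bin).  All ties break lexicographically by feature name, making rankings
deterministic across platforms; score comparisons use a 1e-12 tolerance so
that summation order cannot flip a tie.  The selected-feature count is
constrained to {10, 15, 20} and chosen by cross-validated accuracy (ties to
the smaller k); ranking is refit inside each fold's training data so no
held-out information reaches the selection.  MID rather than MIQ avoids
division by zero for zero-redundancy candidates.

## Classifiers and cross-validation

RF = bagged decision trees (bootstrap per tree, expressed as per-row
multiplicity sample weights over scikit-learn `DecisionTreeClassifier`
inducers; `features_per_node` random candidates per split, explored range
3–11 with grid {3, 7, 11} when tuned).  Predictions aggregate per-tree hard
votes; ties break by the fixed class order SED < SUM < WALK.  Training scopes: G — all rows; GP — one scope
per GMFCS level; FP — one per subject (subjects with fewer than two classes
are skipped with a warning).  G and GP are evaluated by leave-one-subject-out
CV (GP within each level: the held-out child is predicted by their own
level's model trained on that level's remaining children); FP by 10-fold CV
within each subject, partitions redrawn (bounded retries) until every
training split holds at least two classes.

## Reporting

Confusion matrices use rows = predicted, columns = observed, fixed class
order; column-normalized percentages sum to 100 per observed class.  Overall
accuracy is window-pooled per (model type × placement set × GMFCS stratum);
per-class recalls are also reported as across-subject mean (SD, n−1
denominator).  Percentages are written to one decimal.  A long-format
accuracy table is exported for external statistical testing (repeated-
measures ANOVA itself is out of scope).

## Evaluation-scale defaults

The scientific defaults follow the study design: 38 subjects (10/20/8 at
GMFCS I–III), 6-minute trials, 500 trees, k ∈ {10, 15, 20} with
features-per-node tuned over {3, 7, 11}.  The bundled end-to-end evaluation
(`cpactivity.pipeline.study_config`, used by `scripts/acceptance.py` and the
acceptance tests) keeps the full cohort and all seven placement sets but
runs 100-tree forests with fixed k = 15 and features-per-node = 7 — the
bagging variance reduction has largely saturated at that ensemble size, and
the middle of each tuning grid is taken in place of the grid search; the
free-living deployment arm is evaluated on the three single placements.
Per-fold mRMR ranking, which can leak information if skipped, is always
refit.  Full tuning and all-placement free-living evaluation remain
available through the configuration.

## Numerical and degenerate-input choices

Equal-frequency discretization on ties follows stable sort order (documented
and hand-verified); MI uses the plug-in estimator with 0·log 0 = 0; constant
feature columns carry zero relevance.  Window labels at exactly 50 %
coverage are accepted as majority.  Recordings shorter than one window yield
an empty window list with a warning; label intervals may overhang a
recording by at most one sample period.  Seeds derive from a single master
seed via `numpy` `SeedSequence` spawning (kept below 2³¹), so every stage —
cohort draws, bout schedules, fold partitions, forests — is reproducible
end-to-end, and two runs with the same configuration and master seed produce
byte-identical report tables.

## Known limitations

* The feature conventions (spectral energy/entropy definitions among them)
  are one fixed reading of names that admit several definitions; models
  trained elsewhere under other conventions are not interchangeable.
* GP models at GMFCS III train on seven children under LOSO; their variance
  across seeds is correspondingly high.
* Under the default policy the free-living evaluation scores only
  unambiguous windows; with the `majority` policy, blended transition
  windows bound the achievable accuracy well below 100 % even without
  domain shift (they are misclassified at 50–80 % because their features
  fall outside every pure-class training region).
* Synthetic heterogeneity is expressed through a handful of amplitude and
  periodicity parameters; real CP movement heterogeneity is richer, so
  absolute accuracies here should not be read as forecasts for real cohorts.
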