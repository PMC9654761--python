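# Methods

This note documents the models, conventions and numerical choices behind
`skgait`, in the order the pipeline runs them.

## Data model and conventions

A gait cycle is 101 samples from one ipsilateral foot-strike (sample 0,
0 %GC) to the next (sample 100, 100 %GC), with hip and knee flexion and
ankle dorsiflexion positive, in degrees. Events (ipsilateral toe-off,
contralateral foot-strike, tibia-vertical instant) are stored as percent of
the cycle and may be fractional; angle values at fractional times are
obtained by linear interpolation of the sampled series, never by snapping
to the nearest sample. Patients contribute the affected side, healthy
adults the right side. Each subject carries at least one cycle; analyses
use the pointwise mean of the first five cycles (angle series, events and
cycle duration all averaged), mirroring standard clinical practice of
averaging a handful of representative cycles.

Cohort summaries report mean ± SD (ddof = 1) for continuous variables and
median [Q1–Q3] for ordinal scores. Quartiles use linear interpolation
(type 7, the numpy default); this is stated explicitly because clinical
tables rarely name their quartile convention and conventions disagree on
small ordinal samples.

The exchange format is a long CSV (`subject_id,cycle,joint,sample_index,
angle_deg`, UTF-8, `.` decimal separator) plus a `<stem>.meta.json` sidecar
for events and metadata; a self-contained JSON format is also provided.
Motion-capture processing (marker models, 3-D angle computation, event
autodetection) is upstream of this package and out of scope.

## Feature extraction

The five clustering features anchor on two events. PKF1 is the *first*
swing-phase flexion bump: within [toe-off, 100 %GC], the earliest local
maximum whose prominence is at least 0.5° (a plateau counts from its first
sample). The prominence threshold exists because "bump" is a visual notion;
0.5° was chosen to sit well above the residual noise of a five-cycle
average (≈ 0.16° SD with the default generator noise) while letting through
the smallest clinically drawn dips (several degrees). It is configurable,
as is an optional pre-detection moving-average smoothing (off by default —
peak angles read from a smoothed curve would be biased low). If no bump
exists the maximum of the window is used; for a non-increasing window this
is the toe-off instant itself, giving KFE = T1 = 0 for frozen curves by
construction. KFE ≥ 0 and T1 ≥ 0 always hold; KFM and T2 may be negative
when the detected bump falls after the tibia-vertical instant.

The tibia-vertical event is taken from the annotation when present.
Without it, the midpoint of the swing phase is used as a fallback, with a
warning — this is deliberately crude, because the event is properly a
kinematic quantity computed from shank orientation upstream.

The standard sagittal parameters (H1–H6, K1–K6, KFV, A1–A7, MAVP) use
phase windows that must be stated since phase names alone do not fix
boundaries: loading = [0, 10] %GC, stance = [0, toe-off], preswing =
[contralateral foot-strike, toe-off] (falling back to the 12 %GC before
toe-off when the contralateral event is missing), swing = (toe-off, 100].
"Maximum extension" and "maximum plantarflexion" are reported as the signed
minimum of the flexion-/dorsiflexion-positive series. KFV and MAVP are mean
angular velocities over the preswing window in deg/s, converted from %GC
using the cycle duration; MAVP is signed positive toward plantarflexion.

## Clustering and model selection

The clusterer is Lloyd k-means under squared Euclidean distance with
`replicates` = 5 independent restarts (k-means++ seeding by default, plain
random start available); the restart with the lowest total within-cluster
sum of squares wins. Iterations stop when assignments are unchanged or the
largest centroid movement falls below 1e-6, with a 300-iteration cap. An
emptied cluster is repaired by promoting the point currently farthest from
its centroid to a singleton centroid, so returned clusters are never empty.
Fixing the seed makes a fit bit-reproducible. The within-SS trace of the
winning restart is exposed and asserted non-increasing in the tests.

Features are z-scored (population SD) before clustering by default. The
five features mix degrees and %GC, and an unscaled Euclidean metric would
weight them by their accidental numeric ranges; `standardization="none"`
is provided for a literal unscaled reading, and all shipped defaults and
acceptance computations use z-scoring.

The number of clusters is selected with the gap statistic: Gap(k) =
mean_b log W*_kb − log W_k, where W is the pooled within-cluster
dispersion (equal to the k-means inertia under squared Euclidean
distance) and the B = 100 reference data sets are drawn uniformly over the
observed per-column ranges. With s_k = SD_b(log W*) · √(1 + 1/B), the
smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1} is selected, else kmax.
kmax defaults to 6, the limit of clinically interpretable severity levels;
k = 1 is reported (with a warning) when the data show no cluster
structure. Reference distribution, B and the selection rule are stated
here because gap-statistic implementations differ in all three.

## Severity labeling and classification

Labeling a 5-cluster solution uses the only quantitative boundary the
severity scheme defines: the 40° swing-peak cutoff, applied *strictly*
(40.0° is not SKG). Centroid PKF1 in raw degrees splits clusters into two
non-stiff and three stiff; any other split is an error with diagnostics
rather than a silent guess. The non-stiff pair is disambiguated by
known-healthy membership (the cluster with the larger healthy fraction is
`healthy`); without flags, the cluster with larger centroid KFE is taken
as healthy — a documented heuristic reflecting the fuller flexion
enhancement of normal gait. Stiff clusters are ordered UKG > BKG > FLG by
descending centroid PKF1, and the model invariant requires that order to
be strict.

Prospective subjects are assigned by nearest centroid (squared Euclidean)
in the model's standardized space; exact distance ties break toward the
more severe label, the conservative choice for a screening tool. How a new
patient should be assigned to a published cluster solution is genuinely
open; nearest-centroid is this package's choice and is stated as such.

A packaged reference model allows classification without refitting. Its
three stiff centroids pin PKF1 at the published cluster means (36/21/10°);
every other coordinate is reconstructed from the synthetic archetype
calibration below, and the model carries a note saying so. It is a
convenience, not a substitute for fitting on local data.

## Goldberg index and construct validity

The Goldberg parameters differ from the clustering features on purpose:
PKF is the *global* swing maximum (T its time from toe-off), KFE_g the
rise from toe-off to PKF, RKT the full-cycle flexion range. The index
awards one point per parameter abnormal in the stiff direction relative to
a healthy reference — below mean − m·SD for PKF/KFE_g/RKT, above
mean + m·SD for T — with m = 1 by default and configurable, because the
original index's exact thresholds live in its source publication and are
not restated by the severity scheme. Scores categorize as stiff (≥ 3),
borderline (= 2), not-stiff (≤ 1).

The misclassification statistics treat borderline as non-stiff: a subject
counts as misclassified when it sits in a stiff cluster (k1–k3) with a
Goldberg score ≤ 2, or in a non-stiff cluster (k4–k5) with a score ≥ 3;
analogously for CHGC, stiff clusters vs groups G0/GI and non-stiff
clusters vs GII/GIII. The borderline-as-non-stiff rule is the one under
which the packaged published cross-tabulation reproduces its printed error
counts (30/115 and 7/115) exactly, and it is flagged prominently because
the opposite convention changes the Goldberg count materially. CHGC groups
are always clinician-assigned inputs; the package never computes them.

## Statistics

Between-cluster comparisons use one-way ANOVA followed by Holm–Šidák
step-down pairwise t tests (pooled variance by default, the classical post
hoc after ANOVA; Welch optional) for continuous parameters, and
Kruskal–Wallis followed by Dunn's z tests on mean ranks with tie-corrected
variance for ordinal clinical scores. Dunn p-values are unadjusted by
default (a Holm option exists) since post-hoc adjustment conventions for
Dunn's test vary. Degenerate inputs are given explicit answers rather than
NaNs: identical data give F = 0 / H = 0 with p = 1; zero within-group
variance with different means gives p → 0 with an infinite-F guard.
Confidence intervals for means are two-sided t-based (99% by default).

Study-similarity scores: S = 100·min/max of the two studies' central
values — the mean for mean ± SD entries, the median for ordinal entries —
rounded half-up to an integer percent, with 0% if exactly one value is
zero and 100% if both are; G is the half-up-rounded mean of a block's S
scores. Half-up rounding and the central-value-only rule are the
conventions under which every packaged printed score reproduces (e.g.
74/80 → 92.5 → 93).

## Synthetic cohort generator

The generator emulates the five knee-curve morphologies seen in
hemiparetic gait: normal, near-normal (non-SKG), lowered and
delayed/flattened (mild), double-bump with a low first peak (moderate),
and frozen (severe). Each knee curve is a shape-preserving PCHIP
interpolation through event-anchored control points — initial-contact
angle, loading-phase flexion bump, stance minimum (negative under
recurvatum), preswing rise to the toe-off angle, swing peak, a post-peak
descent, the tibia-vertical anchor, and return to initial contact — plus
correlated Gaussian noise (white SD 0.8° smoothed with a 5-sample moving
average, i.e. ≈ 0.36° effective SD with a correlation length matched to
the 0.5° bump-prominence threshold). PCHIP sets zero slope at interior
extrema, so the sampled peak equals the target to well under 0.1°. The hip
is a sinusoidal flexion–extension wave with archetype-specific range; the
ankle a standard dorsi/plantar pattern shifted toward plantarflexion
(equinus) in the stiff archetypes.

Archetype swing-peak targets are the published cluster means — 36° (UKG),
21° (BKG), 10° (FLG) — with healthy subjects at 47°, the middle of the
published 44–50° healthy swing-peak band (the alternative healthy figure
of 23 ± 7° printed elsewhere in the same source is internally inconsistent
with that band and is not used). The non-SKG archetype has no published
centroid; it is this package's construction, placed just above the 40°
cutoff (43°) with reduced flexion enhancement. Morphology prevalences
follow the published description: 68% double-bump in the moderate
archetype, 35% flattened in the mild one. The default composition is
34/28/9/25/14 subjects (mild/moderate/severe/healthy-band/non-SKG), the
healthy-band archetype containing the 19 healthy adults plus 6 patients
with normal-range knee kinematics; five cycles per subject exercise the
averaging step. Metadata (velocity, ordinal clinical scores, CHGC group,
demographics) are drawn from archetype-graded distributions matched to the
published cohort medians, with recurvatum subjects mapped to the 'a' CHGC
subgroups.

The free, non-published generator parameters (event-timing SDs of
≈ 0.7 %GC, within-subject jitter, anchor angles) were calibrated once so
that the detected-feature scatter is roughly isotropic after z-scoring and
slow post-peak declines never read as plateaus; at n = 200 subjects per
archetype the extracted mean PKF1 sits within 0.5° of its target. Under
these defaults the gap statistic selects k = 5 in ≈ 95% of seeds and
cluster labels agree with the generating archetypes for ≥ 99% of subjects.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: between-subject correlation structure beyond
the archetype means, asymmetric or multimodal within-archetype
distributions, pathological curves outside the five families (e.g.
crouch), marker artefacts, and any kinetic or electromyographic signal.
Real cohorts will be messier at the cluster boundaries; the synthetic
cohort establishes that the machinery recovers the structure it is
designed for, not that five clusters exist in any given clinic's data.

## Problem sizes and reproducibility

Default analyses run a 110-subject cohort, gap statistic with B = 100
reference draws over k ∈ 1..6, and 5 k-means restarts per fit — a few
seconds per full pipeline on one CPU. The test suite's stochastic checks
use 10–20 seeds per claim and scaled reference counts (B = 40–50) for the
gap-statistic simulations; these sizes give stable pass/fail behavior at
the stated thresholds. Every random draw — cohort generation, k-means
seeding, gap references — descends from a single integer seed, and fixed
seeds give bit-identical outputs (curve math is polynomial/exponential
only, so results are stable across platforms).

## Known limitations

* Only sagittal-plane kinematics; frontal/transverse compensations (hip
  circumduction, pelvic hike) are outside the model.
* The 40° cutoff and the labeling rule assume exactly 2 + 3 clusters; a
  cohort without healthy-range subjects will (correctly) fail labeling
  rather than mislabel.
* The Goldberg reference must come from a healthy sample; the per-parameter
  m·SD parameterization is this package's reading of the index.
* The packaged reference model's non-PKF1 coordinates are reconstructions;
  classification against it is for triage, not for reporting.
* C3D import is not included; cohorts enter through the documented CSV/JSON
  dialect.
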