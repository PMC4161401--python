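# Methods

`cytoloop` is a closed-loop controller for adaptive time-lapse imaging
cytometry, exercised against a built-in virtual microscope. This note
documents the models it implements, the defaults it ships, what the
simulator does and does not emulate, and the numerical choices made where
the design was open.

## Acquisition planning

**Scan grid.** A scan region is defined by three corners (top-left,
top-right, bottom-right), each carrying its own z, so the focal surface is
the plane through the three points and z is interpolated during the scan
instead of autofocusing at every position. Grid steps equal the camera
sensor size in object space, `step = sensor_px × pixel_pitch /
magnification`; grid dimensions are `floor(extent / step)` per axis.
Binning changes image pixel counts, not the physical sensor extent, so it
does not change the grid. With a 1392×1040 sensor at 6.45 µm pitch behind
a 63× objective, a 3×3 mm region tiles into 21 × 28 = 588 positions. The
scan itself visits positions in serpentine raster order.

**FOV selection.** Positions with at least one cell but fewer than a
crowding threshold (default 20) are candidates; they are sorted by
decreasing cell count (ties keep scan order), truncated to the requested
N, and reordered into a short stage tour: nearest-neighbour construction
followed by open-path 2-opt (including endpoint-freeing prefix/suffix
reversals), restarted from each possible construction start and keeping
the first-point-anchored tour on ties. The tour is a heuristic — the
objective is stated as travel minimization, and exact TSP is unnecessary
at N ≤ a few dozen — but on small instances (≤ 8 points) it matches the
exhaustive optimum in our tests.

**Latency model and minimum period.** Every acquisition step has a cost:
autofocus `t_AF` (polynomial in image pixel count plus the focusing
exposure as an additive offset; constant within an experiment since the
camera configuration is fixed), stage moves `t_mot(x)` as a function of
travel distance, filter moves `t_filt(k)` as a function of slot distance,
exposures, and — in adaptive mode — segmentation `t_seg`, frame mapping
`t_map(n)` and feature extraction `t_ext(n)` as functions of cell count.
The minimum feasible cycle period is

    dt_min  = n_AF·t_AF + Σ_i [ t_mot(x_i) + Σ_p (t_filt(k_p) + t_exp_p) ]
    dt~_min = dt_min + N·(t_seg + t_map + t_ext)

with travel distances along the route closing the loop back to the first
FOV, and the filter wheel arriving at each FOV's first channel from the
previous FOV's last. Planning uses `t_seg = 1.15 s` and the 40-cell
operating-point constants `t_map = 3.74 s`, `t_ext = 0.53 s`, so the
chosen period remains feasible for at least one population doubling after
FOVs are seeded with ≤ 20 cells; a flag enables live recomputation from
current counts instead. Benchmark tables are fitted per term with the
lowest-degree polynomial reaching R² > 0.9 (capped at quadratic for
`t_AF`/`t_map`, linear for `t_mot`/`t_filt`/`t_ext`). Note that gently
curved increasing data is often *explained* by a line at R² > 0.9, in
which case the rule correctly returns degree 1; degree 2 is selected only
when the curvature is strong relative to the scatter. When FOVs are
dropped mid-experiment the retained set is re-routed and `dt~_min`
recomputed; with per-FOV-dominated costs the period scales as the FOV
count (30 → 22 FOVs takes a 4.6-min cycle to 3.4 min).

## Image processing

**Autofocus.** The contrast metric is the two-term autocorrelation
difference (Vollath F4), `C = Σ I(x,y)I(x+1,y) − Σ I(x,y)I(x+2,y)`,
computed along x by default (a symmetric x/y variant is available). The
search is two passes of five planes — 2 µm spacing centred on the current
z, then 0.3 µm spacing centred on the coarse argmax — exactly 10 images;
contrast ties resolve to the lowest z. On unimodal contrast-vs-z profiles
the result is within one fine step of the dense-grid argmax. The metric
assumes a structured scene; on pure noise it is not guaranteed to peak at
focus.

**Segmentation.** Yeast in phase contrast are dark interiors ringed by
bright halos, so interiors are regional minima: (1) flood-fill all minima
not connected to the image border (morphological reconstruction by
erosion from a border-anchored seed — the equivalent of MATLAB-style
hole filling); (2) background := median of the 1-px border; (3) candidate
levels := histogram bins brighter than background with frequency above
the minimum cell area (unit-width bins for integer images, 256 bins for
floating point); (4) mask := fill-raised pixels at candidate levels plus
enclosed holes, dropping components whose area after a cleanup erosion
(disk, radius 1) falls below the minimum area (default 200 px at 63×);
(5) cut necks between touching cells with a disk erosion (default radius
3), label components in raster order, and restore sizes with a
label-preserving dilation implemented as iterated 8-neighbour
minimum-label accretion — nearest label in the chamfer metric with
deterministic ties-to-lower-label — clipped to the detected mask. Cells
clipped by the image border cannot be flood-filled and are not detected;
recall guarantees apply to cells fully inside the frame.

**Tracking.** Identity is frame-to-frame Jaccard overlap
(`|A∩B| / |A∪B|`) between label regions: current cells claim previous
cells greedily in descending overlap (ties to lower current label), one
claim per previous cell, rejecting pairs below 0.3. Unclaimed current
cells are births — including budding daughters that overlap their
already-claimed mother. Features per cell are pixel area and raw mean
fluorescence under the label; the image background (border median of the
fluorescence frame) is carried separately so criteria and fits can
background-subtract.

## Closed-loop control

A protocol is an ordered list of phases, each with a media inlet, a stop
criterion, a reference timepoint (experiment start, phase start, or the
previous timepoint), a timeout, and an FOV policy. Each cycle the engine
visits the FOVs in route order, autofocuses per policy, snaps each
channel, segments, maps, extracts, then evaluates the criterion; met ⇒
advance (or finish after the last phase), applying `drop_failing` /
`drop_failing_and_rescale` policies to FOVs that failed the rule on their
own; unmet past the timeout ⇒ the experiment ends with a timeout status.
The next cycle starts no earlier than one period after the previous
cycle's start, and the period never falls below the re-planned `dt~_min`.
Exactly one notification (a pluggable callback; default structured log)
fires per experiment. Data already collected from dropped FOVs is
retained in the output.

Built-in criteria (registry-extensible): `count` (count grew by fraction
c over reference), `fluorescence` (fraction f of cells raised raw
fluorescence by ≥ c relative to reference — raw, because when expression
starts from zero the autofluorescence floor is what makes a relative
change meaningful), `fluorescence_over_background` (background-subtracted
rise ≥ c × estimated autofluorescence), `steadiness`, `doublings` (count
reached 2^d × phase start), and `elapsed` (fixed-time phases — this is
how conventional open-loop experiments are expressed in the same engine).
The autofluorescence level is estimated as the median background-
subtracted cell fluorescence over the phase preceding the first inducing
phase.

**Steadiness tolerance.** The stop rule "the last 5 points have zero
slope" is unattainable verbatim under noise: the 5-point least-squares
slope of a flat trajectory sampled every 5 min with 10% multiplicative
noise has a standard deviation of ≈ 0.63% of the level per minute. The
default tolerance is therefore |slope| ≤ 3% of the cell's current
background-subtracted level per minute — comfortably above that noise
floor, yet below the relative slope of a trajectory still rising
appreciably. Slope is computed against time in minutes, not frame index,
so the rule is invariant to adaptive period changes; the 5-point window
must lie entirely within the current phase, which also keeps the rule
from evaluating across a media switch.

## Gene-expression models

**Maturation (translation-block chase).** With translation blocked, the
pre-existing immature fluorophore pool converts to the fluorescent form
at a single rate, so the normalized population average follows
`F(t) = 1 − exp(−a t)` with t measured from the block; the rate is
reported as `T_1/2 = ln 2 / a`. The analysis pipeline is: drop cells
present for fewer than 50 time points (≈ 250 min at 5-min sampling),
average background-subtracted fluorescence over present cells per time
point, normalize the post-block window to [0, 1] by subtracting the
minimum and then dividing by the maximum of the shifted curve, and fit by
least squares. In closed-loop runs the fit is anchored at the last frame
acquired before the block (the first post-block frame lands a full period
later; normalizing *it* to zero would discard the early rise and inflate
the half-time by tens of percent).

*Known estimator property:* normalizing by the observed extremes biases
the fitted half-time upward under measurement noise, because the maximum
of a noisy plateau overestimates the amplitude. The bias is roughly
linear in the per-timepoint noise of the average — about +5% at the 10%
per-cell noise / 150–700 cell conditions used in the recovery runs, and
+15% or more when only a few dozen cells survive the length filter. It is
a property of the prescribed procedure, not of the optimizer; we document
it rather than silently switching to a free-amplitude fit.

**Logistic induction.** Sigmoid turn-on is fitted with the 4-parameter
logistic `F(t) = A + (B−A)/(1 + exp(−β(t−t0)))` — lower/upper asymptotes
A and B, maximal-rate parameter β (1/min), half-rise time t0 with
`F(t0) = (A+B)/2`. Initialization is data-driven (A := min, B := max,
t0 := first half-rise crossing, β := 4·max slope/(B−A)) with a few
perturbed restarts; a fit converging with negative β is re-expressed with
swapped asymptotes. Transcriptional memory is quantified as
`delay ratio = mean(t0, first induction) / mean(t0, second)` and
`rate ratio = mean(β, second) / mean(β, first)`.

**Replicate summaries.** `mean`, `SEM = sample SD (n−1) / √n`, and
`CV = sample SD / mean`; with fewer than two values SEM and CV are NaN.

## The virtual microscope

**What it emulates.** Budding-yeast populations in a microfluidic
chamber: Yule (pure-birth) division at rate ln 2 / doubling time, so the
expected count doubles exactly once per doubling time, halting at a
configurable carrying capacity (chamber saturation, default 10 000
cells); daughters bud tangent to their mother, preferring an angle whose
disc does not interpenetrate a neighbour (buds grow into free space), and
the fluorophore pools split in proportion to cell volume (r³). Galactose induces
transcription after a delay — the naive delay on first exposure, a
configured fraction (default 1/6) of it on re-induction, the memory flag
inherited by daughters; the sigmoid shape and its rate are not imposed,
they emerge from delay + production + maturation kinetics. Immature
protein accrues at the transcription rate while induced, matures at rate
`a` (exact exponential updates within each 0.5-min substep), and is
neither degraded nor photobleached — fluorescence falls only by dilution
through budding. Cycloheximide halts production *and* division, so under
galactose+CHX each cell's immature+mature total is exactly conserved.
Phase-contrast rendering draws bright-rim/dark-interior cells on a
mid-grey background (all interiors first, then all halos, so touching
cells keep a separating ridge) with Gaussian blur growing linearly in
defocus; fluorescence rendering fills each cell with
`(mature + autofluorescence) × exposure/75 ms` times a per-cell
multiplicative noise factor (CV default 10%). Seeding rejection-samples
positions so cell bodies never interpenetrate. All randomness flows from
the config seed; identical configs and command sequences give
bit-identical outputs, and rendering never mutates population state.

**What it does not emulate,** hence what passing tests do not show about
real data: no cell death, shape change, or cell-cycle structure (division
is memoryless); no uneven illumination, shot noise, or pixel-level noise
in phase contrast; no focus drift beyond the configured tilted plane; no
debris, no out-of-plane cells, and only mild crowding. Segmentation
recall and tracking-identity results on rendered scenes are therefore
upper bounds on real-microscope performance. The virtual camera frames
(39–52 µm across at the default pixel size) are several-fold smaller
than a real sCCD field at 63×, so count-based criteria that need room
for multiple population doublings require sparsely seeded FOVs in
simulation. A single naive induction
delay is used regardless of prior carbon source; the much longer
derepression of glucose-grown cells is represented only through the
memory mechanism, so absolute first-induction delays from glucose are
not reproduced — only the relative first/second asymmetry.

**Hardware contract.** The microscope object tracks stage position,
filter slot, medium, and a wall clock; every commanded action advances
the clock by the latency model's cost for that action. Biology is
synchronized to the clock at medium changes and explicit waits; within a
cycle's acquisition burst (seconds against minute-scale kinetics) the
population is effectively frozen. Medium changes can take effect after a
configurable perfusion lag (default 0 — the dead volume is not modeled).

## Problem sizes used in tests and the acceptance script

Chase recovery runs use the per-experiment population sizes of the study
being reproduced (333/705/167 and 342/466/470 cells) at 5-min sampling
with 10% per-cell noise; end-to-end closed-loop tests run 2–4 FOVs of
≈ 190² px frames over a few dozen cycles with faster test kinetics
(doubling 45 min, delay 15 min) — small enough to run the whole suite in
a few minutes while still exercising every stage of the loop on real
rendered images. Replicate-recovery properties use 50 seeded synthetic
trajectories per model. The bundled protocols floor the cycle period at
5 min, matching the cadence the assay was designed around; with only a
few FOVs the latency model alone would permit sub-minute cycling, which
oversamples minute-scale kinetics and shrinks the steadiness window to
the noise floor.

## Numerical choices and degenerate inputs

Histogram bin width: unit bins for integer images, 256 bins for floating
point. Border statistic: median. Label numbering: raster order of first
appearance; all tie-breaks (contrast z, route construction, greedy
overlap assignment, dilation labels) are deterministic and documented at
the definition site. Empty FOVs render background only and segment to
zero cells; an image with no candidate histogram level yields an empty
mask, not an error. Constant trajectories cannot be normalized or fitted
(named error). `overlap` of two empty sets, collinear scan corners,
unknown media, shape mismatches, an empty retained-FOV set, and `n_AF`
out of range raise named errors. Nonlinear fits are seeded and
deterministic given identical inputs.
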