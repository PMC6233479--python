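# Methods

This note documents the models, parameter choices and numerical
conventions behind `ohp`, and what the synthetic validation does and does
not establish.

## Acquisition model and coordinate conventions

Movies are single-channel 16-bit TIFF stacks with calibration supplied by
configuration, never inferred from TIFF tags (defaults: 0.22955 µm/px,
3.3 frames/s — at the nominal 512 px width this spans 117.53 µm).
Pixels are (row, col) with origin top-left; continuous positions are in
µm with x increasing rightward, y downward, and pixel index i centred at
(i + 0.5)·pixel_size. All movies are assumed stored with the distal axon
site on the left and the proximal (soma) site on the right; a `flip_x`
config flag handles mirrored acquisitions. This fixed orientation is what
gives the track-angle direction rule its meaning: a net angle of 0 points
rightward/proximal (retrograde), π leftward/distal (anterograde). The
angle is computed with the image y-axis negated so that 0 is "right" in
standard mathematical orientation; the boundary angles ±π/2 are assigned
to retrograde (a measure-zero case fixed for determinism).

## Detection

The spot detector is a difference of Gaussians tuned to an estimated
object diameter d (default 1.6 µm): σ₁ = (d/2)/√2 px and σ₂ = √2·σ₁, the
convention of the plugin family this detector emulates. Candidate spots
are strict 3×3 local maxima of the response with positive value,
suppressed greedily by descending quality with minimum separation d
(ties broken toward smaller row/col for determinism). Quality is the raw
DoG response at the maximum, in input-intensity units; the default
threshold of 45 is therefore only meaningful for comparable intensity
scales and should be adjusted per dataset (config-first). Sub-pixel
refinement is a per-axis parabolic fit in the 3×3 neighbourhood, bounded
to ±0.5 px; maxima at the image border keep their integer position.
Numerical identity with any particular GUI implementation is not claimed.

## Tracking

Linking is a frame-by-frame rectangular linear assignment problem solved
exactly (Jonker–Volgenant via `scipy.optimize.linear_sum_assignment`),
with cost = squared distance between each live track's Kalman-predicted
position and each spot, and assignments beyond the search radius
(default 2 µm) forbidden. Unassigned spots start new tracks; tracks
unmatched for at most `max_frame_gap` (default 2) frames may resume
against the prediction (gap closing), after which they terminate. The
per-track state is a constant-velocity Kalman filter over (x, y, vx, vy)
with time in frames; a one-spot track predicts its own position (zero
prior velocity with large variance, so the second observation sets the
velocity). Defaults: measurement noise 0.5 px, process (velocity) noise
0.2 µm/frame — sized to typical localization error and speed wander, and
configurable.

Track duration counts frames inclusively, duration = (last − first + 1)
× frame interval, so the 3 s filter at 3.3 fps admits exactly tracks
spanning ≥ 10 consecutive images. Link speeds are distance / (frame gap
× frame interval); a gap-closed link contributes one time-normalized
speed. Speed SD uses the N−1 denominator over link speeds (0 with a
single link).

## Morphology

Only the first frame is segmented (organelle shapes at t = 0), with an
IsoData-style intermeans auto-threshold by default (Otsu selectable) and
8-connected particle analysis; components under `min_area_px` (default 4)
are discarded as noise. Feret diameters are max/min caliper distances
over the convex hull of the component's pixel corners (corners rather
than centres so a 20 px disc measures ~20 px, the outline convention);
the minimum width uses rotating calipers over hull-edge directions.
Circularity is 4πA/P² clamped to ≤ 1, with the weighted boundary-step
perimeter estimator (naive edge counting would systematically deflate
circularity). Aspect ratio is the major/minor axis ratio of the
second-central-moment ellipse fit. The signature's single morphology
parameter is marker-specific: aspect ratio for mitochondria (elongation,
the fission/fusion readout) and outer Feret diameter for the essentially
globular lysosomes (size).

## Mining and filtering

Per-movie CSVs (`<stem>_tracks.csv`, `<stem>_morphology.csv`) are
discovered recursively; each row is joined with the condition parsed
from the file's folder levels (`Project/Experiment/Marker/Readout
position/Treatment/Disease/Line`, template configurable). Tracks with
displacement < 1.2 µm are excluded as non-processive jitter — literal
"below threshold" semantics, so exactly 1.2 µm is retained. The filter
never applies to morphology records, and the duration filter is enforced
once, at the tracking stage.

## Signature assembly

Statistics are pooled over the whole filtered population of a condition:
per track for the eight kinematic parameters, per movie for the
anterograde/retrograde count ratio (movies with zero retrograde tracks
have no defined ratio and are dropped from that parameter's pool,
reducing its N), per organelle for the morphology parameter. The Z-score
of parameter x at condition C against the baseline —  the Mock-treated
control pooled at the proximal readout of the same marker — is

    Z = (P̄xC − P̄xCtrl) / (SDxC/√NxC + SDxCtrl/√NxCtrl)

a mean difference over the *sum* of the two standard errors. A Welch-style
denominator √(SD²/N + SD²/N) is available behind `welch=True` for
sensitivity analysis; it is always ≥-in-magnitude the default, so the
default is the more conservative significance call. SDs use the N−1
denominator; pools with N < 2 are an error rather than a silent zero.
Equal means return Z = 0 even when both SDs vanish; unequal means with a
zero denominator are an error. The baseline is per marker because
mitochondrial and lysosomal parameter distributions are not comparable.
|Z| ≥ 5 is flagged significant (configurable band).

The 40 entries are ordered Mito-Distal, Mito-Proximal, Lyso-Distal,
Lyso-Proximal, each block listing duration, displacement, mean/max/min/
median/SD speed, length, the directional ratio, then the shape
parameter.

## Clustering

Signature distance is plain Euclidean over the selected entries (full
40, or the 20 distal / 20 proximal entries); no further normalization is
applied since Z-scoring already provides it. Agglomeration is UPGMA: the
pair of clusters with the smallest average inter-cluster distance merges
at that average, maintained exactly by the size-weighted update
(n_A·d_AC + n_B·d_BC)/(n_A + n_B). Ties are broken lexicographically on
the sorted leaf-label sets, so the dendrogram is invariant (up to leaf
labels) under input permutation. Heights stay in Z-distance units.
Newick export places every leaf at depth = half the root merge height
(the standard ultrametric UPGMA tree). `scipy.cluster.hierarchy` is used
as an independent oracle in the tests, never as the implementation.

## Synthetic data

The generator emulates axonal organelle traffic: each organelle is
stationary or moves at a constant per-organelle speed along ±x
(anterograde = leftward), drawn from a truncated normal, with optional
per-frame pauses and no reversals; stationary organelles jitter with SD
0.02 µm. Defaults model the observation that only a minority of axonal
mitochondria move processively: stationary fraction 0.8, anterograde
fraction 0.5, speed 0.8 ± 0.2 µm/s (typical fast organelle transport),
pause probability 0.1. Organelles are rendered as (optionally
anisotropic) Gaussian kernels whose FWHM equals the nominal diameter,
on a constant background with Gaussian or Poisson noise, clipped to 16
bits; organelles leaving the field are truncated in the ground truth,
not wrapped. Not modelled: photobleaching, axon curvature,
fission/fusion, reversals, crosstalk — so passing tests demonstrate
correctness of the measurement pipeline under its own motion model, not
robustness to every property of real movies.

The standard validation scenarios use small fields chosen for speed and
geometric cleanliness: 60-frame 128×64 px movies of twenty 0.8 µm
organelles in distinct non-crossing lanes (lane spacing must exceed the
detector's minimum-separation radius, which bounds organelle size at
this field size), half stationary, no pauses, peak/background 4000/400
with noise 40 (SNR ≈ 90). The four-condition discrimination scenario
(two control replicates, two distal-slowdown replicates at half speed,
3–4 movies per marker × readout × condition) yields pools of ~30–40
processive tracks, for which halving distal speed predicts distal
mean-speed Z ≈ −(0.4·√n)/0.3 ≈ −7 to −9, comfortably past the −5 band,
while proximal entries stay within noise (|Z| < 2).

## Known limitations

- Quality units are raw DoG response, so thresholds do not transfer
  across intensity scales.
- The tracker has no split/merge handling and assumes near-linear
  motion; heavy organelle crossing or reversals will fragment tracks.
- Morphology is single-frame; no time-resolved shape dynamics.
- The per-movie directional ratio is undefined for movies without
  retrograde tracks; such movies silently shrink that parameter's N.
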