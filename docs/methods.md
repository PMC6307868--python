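# Methods

This note documents the models, parameters and numerical choices behind
`neurorg`: what the synthetic data emulates, how each analysis stage is
defined, which defaults matter, and what a green test does and does not
establish.

## Imaging model

The simulator emulates confocal acquisitions of cultured hippocampal
neurons expressing a peroxisomal (PO) and a mitochondrial (MITO) marker:

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.08 µm/px | stated acquisition pixel size |
| frame interval | 5 s | "every 4–5 seconds" |
| session | 97 frames = 480 s | ~8 min of imaging |
| frame | 512² (tests) … 1280² (fixtures) | up to a 102 µm field of view |
| bit depth | uint16 counts | typical detector range |

Intensities: ambient background 100 counts, soma/neurite cytosolic fill
+120 counts, organelle peak 1000 counts, Gaussian read noise σ = 10.
These are calibrated, not sourced — the study reports no SNR — and were
chosen so centroid noise is well below 0.1 px, i.e. class recovery is
detection-limited, not noise-limited. Shot noise is applied as the
Gaussian approximation N(λ, λ) of Poisson counts (exact to <1 % at
λ ≥ 100), combined with read noise into a single draw N(0, λ + σ_r²);
rendering is bit-reproducible given a seed.

POs are rendered as 2-D Gaussians (σ = 0.15 µm); mitochondria as soft
capsules (cross-section σ = 0.25 µm, length 0.5–3 µm) oriented along the
local neurite tangent. Fixed-cell POs are soft-edged disks whose radius is
solved analytically from the requested count and total area.

## Neuron geometry

A soma disk (default radius 10 µm) centred in the frame, with neurites as
bounded-curvature random-walk polylines leaving the soma radially
(≥ 40 µm arc length by default; the walk steers away from the frame
boundary, so long paths serpentine inside small frames). Neurite width is
1.2 µm. Fixed-cell geometries use near-straight radial neurites
(heading noise 0.02 rad/step) because soma delineation by morphological
opening assumes arms do not fold back against the soma; this requires a
1280² frame for ~35 µm of straight neurite.

Not simulated: branching, axon/dendrite identity, z-extent (the study
analyses maximum-intensity projections), photobleaching, focus drift, and
mitochondrial fission/fusion.

## Kinetic model (ground-truth trajectories)

The study gives class fractions and speeds but no generative model. Ours:

1. Draw a motility class from the preset mixture
   (control-PO (1, 59, 30, 10) %, acbd5-PO (3, 81, 14, 2) %,
   control-MITO (75, 5, 5, 15) % for static / very-short / short / long).
2. Draw a target total path length uniformly inside the class interval
   ([0,1), [1,5), [5,10), [10,15) µm — the open "≥ 10 µm" class is capped
   at 15 µm so cohort mean distances land near the published 5.6/3.6 µm).
3. Realise the target as `1 + Poisson(2)` contiguous runs of full-speed
   steps (run speed 0.1 µm/s for POs, 0.06 µm/s for mitochondria; one step
   = speed × frame interval), plus isolated oscillation steps of exactly
   0.15 µm, plus pauses; each run and each oscillation step gets a random
   ± direction along the neurite.

Because steps are restricted to these two magnitudes, the target distance
is quantised down onto the realisable lattice (adding one oscillation step
back if quantisation would cross the class lower bound). Consequences:
every nonzero step is ≥ 0.15 µm (so the displacement floor below cannot
erase genuine motion), the planted total always lies in its class
interval, and planted max speed equals the run speed exactly for every
track containing a full run step. A small atom of planted distances sits
exactly on class boundaries (~1 % of tracks), where measurement noise
flips the class with probability ~½ — a negligible, symmetric effect at
the 3-SE tolerances used.

Motion is 1-D along the neurite path, matching kymograph-style analysis.
Tracks are packed into disjoint "territories" (trajectory extent plus
rendered half-length, separated by ≥ 1.2 µm), so no two planted organelles
ever approach within the 1 µm tracking gate: identity switches in the
ground truth are impossible by construction, and measured switch/merge
errors are attributable to the pipeline.

## Segmentation

Input: the sum over channels of the per-channel temporal **maximum**
projection. Vesselness runs on `log1p` of this image: with linear input
the per-image γ normalisation is set by bright organelle trails and the
dim neurite tube falls below any usable threshold; log compression is
intensity-scale-free and keeps both.

* **Frangi vesselness**: scale-normalised Hessian eigenvalues, bright-ridge
  polarity (λ₂ < 0), blobness β = 0.5, structureness γ = half the maximum
  Hessian norm per scale. Scales {1, 2, 3, 4, 6, 8} px: the two largest are
  matched to the 15 px tube half-width; without them the tube crest is weak
  and fragmented.
* **Non-maximal suppression** across the ridge (4-bin quantised normal),
  then **hysteresis**: seeds at `high` = Otsu of the nonzero thinned
  strengths; `low` = 8 × median nonzero strength. The median is dominated
  by noise ridges, so `low` tracks the noise floor (≥ 4× margin to both
  noise and tube in the stated world) instead of scaling with the
  brightest structures.
* The kept trace is dilated by round(width/2/pixel size) px to an analysis
  mask; trace pixels hugging the soma are removed first (the soma rim
  responds as a closed ridge).
* **Soma**: max-over-scales DoG (σ ∈ {10…40} px, ratio 1.6, computed on a
  2× decimated image — loss-free at these scales), Otsu-thresholded, holes
  filled, opened by 12 px to cut neurite-width appendages, largest
  component kept. Because the positive DoG band ends inside the intensity
  edge (~20 % area deficit), the seed is grown to the intensity half-max
  between the fill level (median inside the seed — robust to bright
  organelles) and the local background median. Recovered area is within
  ~1 % of the planted disk. The soma, dilated by 3 px, is subtracted from
  the neurite mask.

## Detection

Per frame: Gaussian blur (σ = 1 px PO, 2 px MITO), Otsu threshold over the
smoothed values inside the neurite mask only, binarise, 8-connected
components ≥ 4 px, intensity-weighted centroids (weights = smoothed excess
over threshold). Two guards handle degenerate frames: if the Otsu
foreground exceeds 15 % of the mask the cut has split the structured
background (ambient vs neurite tube) and is re-applied within the
foreground; if the final foreground mean is within 4 background-SDs of the
background mean the frame is reported empty. Constant frames inherit the
previous frame's threshold. Otsu uses a 256-bin histogram; ties across an
empty gap between modes resolve to the plateau midpoint (stable against
last-ulp noise).

## Tracking

Adjacent frames are linked by a linear assignment over centroid distances
with a hard 1 µm gate (2× the fastest planted per-frame motion), using the
augmented-matrix formulation: distance block, birth/death diagonal at the
gate cost, and a zero-cost completion block (finite exactly where a link
is feasible). The optimum minimises Σ matched distance + gate ×
(# unmatched); note this can legitimately prefer fewer, tighter matches
over a maximum matching that stretches links. No gap closing: a missed
detection splits a track, which the recovery tests measure rather than
hide. Cost is centroid distance only; ties are resolved deterministically
by the solver.

## Motility statistics

For a track with per-interval Euclidean steps d_i:

* steps < 0.1 µm (1.25 px) count as zero for distance accumulation — the
  single most consequential free parameter; it suppresses sub-resolution
  localisation jitter while passing the smallest planted real step
  (0.15 µm);
* total distance = Σ floored d_i; net distance = first-to-last straight
  line; instantaneous speed = unfloored d_i / Δt; max speed = its maximum;
  average speed = total distance / track duration (this definition
  reproduces the published pair 3.6 µm over 480 s = 0.0075 µm/s);
* class thresholds at 1, 5, 10 µm, half-open on shared endpoints
  ([1,5), [5,10), [10,∞)), consistent with the explicit "≥ 10 µm";
* "total ≥ net" is exact for unfloored accumulation (triangle
  inequality); with flooring a pathological sub-floor drift could violate
  it, so the invariant is asserted at floor = 0;
* directionality: sign and magnitude from the change of within-mask
  geodesic distance to the soma boundary (8-connected, diagonal √2)
  between first and last sample; anterograde (away from soma) positive;
* cohort summaries pool unfloored instantaneous speeds into an ECDF and
  report per-class fractions over tracks spanning ≥ 80 % of the session
  (a split track would otherwise be double counted — minimum track length
  is not specified in the source workflow);
* kymographs: one row per frame, one column per unit-pixel step along the
  polyline, value = maximum over a `width`-px segment perpendicular to the
  path (max preserves dim spots better than mean); readout converts a
  hand-drawn line on the kymograph to distances and velocities.

## Distribution and contacts

Fixed-cell morphology comes from the cytosol-fill channel (Otsu + largest
component); the soma is the DoG object intersected with it; the proximal
region is the neurite mask within a 30 µm geodesic distance of the soma
boundary. Detection for fixed-cell images thresholds the **raw** PO
channel (σ = 0) with per-compartment Otsu — the source distribution
workflow states Otsu but no blur (blurring belongs to the live pipeline),
and with a σ = 1 blur the Otsu threshold sits in the blur skirt and
inflates measured areas by ~15–25 %. Counts assign regions by centroid
membership (no double counting across the partition boundary). Measured
counts equal planted counts exactly at the default 0.5 µm edge-to-edge
spot separation; measured total areas recover within ~8 % in the soma and
~9–12 % in the proximal neurites (the smallest spots, r ≈ 0.17 µm, have
proportionally the largest threshold-placement error — the unit test
asserts 10 % for soma and 15 % for neurites).

A PO is in contact with a mitochondrion when its binarised region overlaps
the binarised mitochondria mask dilated by 1 px (8-adjacency), evaluated
on the first frame within the neurite mask. Group comparisons use the
one-tailed unpaired pooled-variance t-test with stars at
0.05/0.01/0.005/0.001; Welch's form is available via `scipy` directly if
unequal variances matter.

## What a green test establishes — and what it does not

The acceptance suite shows that the full pipeline recovers, at their
stated tolerances, quantities *planted at the published values* in
synthetic data whose geometry, kinetics and noise are idealised as above.
It does not validate against real acquisitions: real neurites branch and
cross, organelles pass each other (planted territories forbid this),
mitochondria fuse and divide, backgrounds are non-uniform, and
photobleaching shifts thresholds over time. The per-frame Otsu and the
noise-referenced hysteresis threshold address the last point in spirit but
are only exercised on stationary synthetic statistics.

## Known limitations

* Proximal-neurite PO area recovers with a ~+10 % bias (Otsu threshold
  placement on sub-diffraction spots); the soma-area and count recoveries
  are unaffected.
* No gap closing or merge/split handling in tracking; occlusion-free
  planted data makes this safe in simulation but real crossings would
  split tracks.
* Kymograph line *tracing* is manual by design: the readout takes
  user-supplied vertices.
* The abstract-level "reduced by ~70 %" style summary statistics are not
  reproduced; only quantities with an explicit operational definition are.
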