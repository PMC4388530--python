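# Methods

## Imaging model and sum-difference differencing

Frames are 8-bit intensity matrices in a fixed coordinate convention:
pixel (0,0) top-left, x rightward, y downward, 0-based. Colour input is
reduced by BT.601 luma (0.299 R + 0.587 G + 0.114 B, rounded). For a
series A₀…A_{n−1} the per-frame sum-difference image is
B_k = Σ_{j≠k} |A_k − A_j|, accumulated in int32 (a 30-frame series can
reach 29·255 per pixel, far beyond 8 bits). Any pixel whose value is
constant over the series contributes exactly zero, which is why static
debris in turbid media is invisible to the pipeline — an exact property,
tested as such on noise-free debris-only scenes. With sensor noise the
cancellation is only statistical; the denoising step handles the residue.

Denoising subtracts **twice the global pixel mean** of B (interpreted as a
global scalar — the image gives no spatial structure to justify per-row or
per-column variants), clips negatives to zero, and linearly rescales so
the maximum is 255. Normalization constants are per image, not shared
across the series. Two consequences are worth knowing:

* the noise floor of B (≈ 29·E|N(0, √2σ)| for i.i.d. noise of sd σ) sits
  well below 2·mean once any real signal is present, so clipping removes
  it almost entirely;
* a frame with *no* moving object is returned all-zero rather than as an
  error (normalizing pure residue would amplify ghost traces of bacteria
  from other frames). For the same reason, series in which every swimmer
  has left the field can surface faint "ghost stripes"; in normal use
  (several bacteria present throughout the second) these sit ~1/29 of the
  true signal and are cut by the threshold.

## Detection and the seven characteristics

Detection thresholds the normalized B at Otsu's threshold by default
(clamped ≥ 1; a fixed override is available), takes 8-connected
components — a diagonal-touching rod is one object — and discards
components below `min_area`, default 14 px², the area of a disk at the
0.4 µm optical detection limit imaged at 94.2 nm/px. Border-touching
components are kept and flagged.

Each component is reduced to: area (pixel count), unweighted centroid,
crack-boundary perimeter (count of pixel edges exposed to background; a
lone pixel has perimeter 4), orientation (principal axis of the second
central moments, degrees counterclockwise from +x, range [−90, 90)), and
length/width (full extents of the member pixels projected on the
major/minor principal axes, +1 px for pixel width). These definitions are
this package's own, chosen to be exactly reproducible; they are verified
against a brute-force double-loop oracle in the tests. Sub-pixel centroid
accuracy is meaningful because the synthetic renderer rasterizes with
coverage-weighted anti-aliasing.

## Association, gap closing, velocities

Features are made commensurate by dividing each characteristic by its
series-wide median absolute value, floored at 1 (the floor makes the
transform idempotent and keeps near-zero characteristics from exploding).
The link cost between particles of consecutive frames is the weighted L1
distance over the seven characteristics. Default weights: 1.0 on each
centroid coordinate, 0.2 on the five shape terms — at 30 fps a bacterium
moves much less than typical inter-bacterium spacing, so position should
dominate, while shape terms break ties when paths cross. Pairs whose raw
centroid displacement exceeds the gate (default 40 px ≈ 113 µm/s at
canonical optics — above any plausible swimming speed) are inadmissible.

Matching minimizes total cost as an optimal linear assignment
(`scipy.optimize.linear_sum_assignment`); a greedy nearest-neighbour rule
cannot guarantee the no-double-assignment property at crossings.
Inadmissible entries carry a prohibitive constant and any match forced
onto one is dropped to the unmatched lists. Optimality is checked against
exhaustive permutation enumeration on random matrices up to 6×6.

Tracks are chains of matches. A track that misses up to `max_gap`
(default 1) consecutive frames may re-link to an appeared particle, again
by minimal cost with the gate widened in proportion to the elapsed frames;
the record keeps a gap marker. Tracks with fewer than `min_track_len`
(default 5) detections are removed as spurious — the only "incorrect
record" filter implemented; velocity-outlier filters are left to
configuration. Each consecutive detection pair yields one velocity
vector, speed = ‖Δcm‖ · pixel size · fps; across a closed gap of g frames
the straight-line distance is divided by the elapsed time (fps/(g+1)),
consistent with the Euclidean-distance definition. A sample aggregates
all vectors (not per-track means): mean, SEM = sd/√n, n, the mean
detected-particle count per frame, and a QC flag set to `too_crowded`
strictly above 15 bacteria per image.

## Statistics

Stage contrasts use the two-sided Mann–Whitney U test: exact null for
combined n ≤ 20 without ties, tie-corrected normal approximation with
continuity correction otherwise. Calibration is verified by simulation
(type-I error at α = 0.05 within [0.03, 0.07] over 1000 null pairs of
n = 50; the continuity correction makes the observed rate mildly
conservative, ~0.04). Normality screening tests the composite hypothesis
(parameters estimated): Shapiro–Wilk and Anderson–Darling via
scipy/statsmodels, Cramér–von Mises with the small-sample-modified
statistic and the standard piecewise-exponential p approximation for the
estimated-parameter case. Velocity histograms use half-open bins [lo, hi)
of default width 5 µm/s from zero. The motile fraction is the unweighted
mean of per-sample percentages ± sample sd.

## Rheology

Laminar pipe flow: u_m = 4Q/(πD²), u(y) = 2u_m(1 − (2y/D)²) with y from
the capillary axis (so u(0) = u_max = 2u_m and u(±D/2) = 0), wall shear
rate γ̇ = 8u_m/D (magnitude), τ = ηγ̇, Re = u_m D/ν with the laminar
verdict Re < 2300 (strict). At fixed Q these scale as u_m ∝ D⁻²,
Re ∝ D⁻¹, τ ∝ D⁻³, all tested, and the profile integrates back to Q
(quadrature, < 0.1%). Shear stress is reported only when viscosity is
supplied; the CLI default fluid is η = 0.72 mPa·s, ρ = 993 kg/m³
(water-like broth at 35 °C), ν = η/ρ. The triple (η, ν, ρ) is
cross-checked to 0.1% when over-specified.

## Sample preparation

OD₆₀₀ is assumed linear in cell concentration over the working range, so
diluting to the imaging target (default 1.15) needs
factor = od/target, clipped to ≥ 1 — a thinner sample cannot be
concentrated and is flagged instead. Water to add is mass·(factor − 1) at
density 1.000 g/ml for both liquids (configurable). Gravimetric
verification passes when the measured total mass is within a symmetric
relative tolerance (default 2%) of mass·factor.

## Synthetic scenes: what they emulate, and what they do not

The generator draws solid anti-aliased ellipses for bacteria (rod shape,
orientation tied to heading), static disks for debris, and i.i.d.
Gaussian noise clipped to [0, 255]. Kinematics are a constant-speed
random-heading walk: each step turns by N(0, heading_sd) degrees
(default 10°) and advances speed/fps. Defaults: background 30/255,
noise sd 5, body 2.0 × 0.7 µm at intensity 200, canonical optics
(1280 × 960 px, 30 frames, 30 fps, 94.2 nm/px), 5–10 bacteria — the
operating optimum for tracking. Ground truth records the true sub-pixel
centre per frame while it is inside the image and the true per-step
speed; a body leaving the field is clipped at the border and its ground
truth ends, exercising the disappearance branch.

Not emulated: phase-contrast halos and defocus, flagella, 3-D motion (the
flow cell confines the sample to a ≤ 5 µm layer, so in-plane motion is
the physical regime anyway), intensity fluctuation of a swimming cell,
and structured (non-Gaussian, correlated) camera noise. Passing the
recovery benchmarks therefore demonstrates the correctness of the
*algorithmic chain* under realistic geometry and noise amplitude, not
robustness to every optical artifact of a real microscope.

## Benchmark problem sizes and numerical choices

Recovery benchmarks use ten canonical-resolution scenes per noise level
(5 bacteria, speeds uniform in 40–60 µm/s), which score recovered mean
speed within ~1.5% of truth — comfortably inside the 5%/10% bands the
package commits to. The association oracle uses 200 random matrices up to
6×6; Mann–Whitney calibration uses 1000 null pairs of n = 50. Degenerate
inputs are defined, not special-cased: empty detection lists yield empty
cost matrices and an n = 0 sample with NaN mean; an all-static series
yields zero particles. Ties in ranks switch the U test to the asymptotic
path. All randomness flows through `numpy.random.default_rng` seeds;
identical scene spec + seed reproduces output bit-for-bit.

## Known limitations

Touching bacteria merge into one particle (crowding is handled by
dilution, not watershed splitting); tracking accuracy degrades above
15 bacteria per image, hence the QC flag rather than an attempt to
recover; the gap-closing re-link is cost-greedy per frame rather than a
global multi-frame optimization; and absolute wall-shear-stress values
depend entirely on the supplied viscosity, which must be measured for
the actual medium.
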