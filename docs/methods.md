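# Methods

This note documents the models, estimators and numerical choices behind
`ringflow`, and what the synthetic scenes do and do not establish about
real microscopy data.

## Coordinate and unit conventions

Images are indexed 0-based; the image **row** is the circumferential
axis and the **column** the anterior–posterior (A–P) axis, with the
leading furrow edge at the lower column coordinate. Physical positions
are micrometres (pixel centre of pixel *k* at (k + 0.5)·pixel_size),
velocities µm/s, times seconds, intensities arbitrary units (AU).
Defaults mirror spinning-disk imaging of the *C. elegans* zygote:
5.6 s frame interval; 0.18 µm/px and SNR ≈ 20 are chosen for
testability, as the pixel size and SNR of such acquisitions vary.

## Synthetic scenes

The generator produces the two projected views the analysis consumes,
directly — no 3D rendering or optical (PSF) modelling.

**Ring kinematics.** Each furrow edge follows a piecewise-linear ramp:
stationary until its onset, then ingressing at constant speed (defaults:
leading onset 0 s, lagging onset 100 s, 0.05 µm/s per edge, R₀ = 10 µm).
This is the simplest family that spans symmetric, delayed-asymmetric and
fully unilateral closure; richer profiles (e.g. accelerating closure)
are config extensions, not defaults. Radius and centre derive exactly
from the two edges, so all closure metrics have closed forms, and
L_lead + L_lag = R_closure holds at machine precision in the truth. A
scene whose edges would cross is truncated at closure and flagged.

**Ring view.** An annulus with a Gaussian radial cross-section
(σ = `ring_thickness`, default 0.4 µm) centred on the true ring; as the
radius approaches zero the same expression degenerates to a centred
blob. Intensity may be graded between leading and lagging semicircles.

**Cortex view.** `n_foci` (default 150, enough for ≈9 per PIV window)
Gaussian spots (σ = 0.3 µm) advected through a prescribed flow — a
uniform ring-directed component toward the furrow plus a linear
circumferential sink v = −k(y − y_mid) whose exact convergence is k
(default amplitudes 0.08 µm/s and 0.005 s⁻¹, both below the 0.25 µm/s
rejection threshold). Advection is explicit per-frame Euler, justified
because the prescribed fields vary slowly relative to the 5.6 s frames;
for the linear sink the discrete map contracts by (1 − e^{−kΔt})/Δt ≈ k
per frame, a sub-percent deviation at these rates.

**Noise.** Additive Gaussian on top of the signal (σ = 5 AU on a
100 AU ring over a 10 AU background), with an optional Poisson stage.
Rendering is floating point; stacks are quantised to 16-bit on write.
All randomness derives from the config seed (per-frame child streams),
so identical configs give bit-identical truth and images.

**What the scenes do not emulate:** optical blur and attenuation with
depth, bleaching, cytoplasmic background structure, focus drift, ring
deformation away from a circle, emergent (mechanochemically coupled)
flow, and foci that appear/disappear by exchange with the cytoplasm.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated signal model, not robustness to every
microscopy artefact.

## Ring segmentation and radius estimate

Per frame: Gaussian smoothing (σ = 1 px) → Otsu threshold (the
segmentation software settings used on real data are not standardised;
Otsu is the configurable default) → morphological closing (disk 2) →
hole filling → largest connected component, with ties broken toward the
previous frame's centroid. The component is ellipse-fitted via image
moments; the radius is reported as the **mid-shell** value: the mean of
the ellipse fits of the filled outline (outer contour) and of the
interior hole. Fitting only the filled region would return the annulus
outer radius, biased high by half the shell width (≈1–2 px here); the
mid-shell estimate is unbiased for a symmetric shell and falls back to
the filled-region fit once the ring has closed into a blob. Frames with
no component ≥ 1 µm² are flagged invalid, never raised.

Closure metrics use R₀ and the reference centroid from the first valid
frame. Crossing times (alignment at 10 % closure, the Δt levels) use
frame-level first strict exceedance by default, mirroring frame-based
reporting on real data; sub-frame linear interpolation is available
behind a flag. The Δt comparator is the leading edge's own 10 %
crossing (the paired-edge reading); if the lagging edge never reaches
10 % before the series ends, Δt is reported censored with a flag rather
than dropped. The onset fit window defaults to closure ∈ [0.05, 0.25]:
below the velocity window, above the segmentation noise floor. Peak
eccentricity is taken over valid frames up to the last segmentable one.

## PIV

Windows (5.8 µm) and steps (2.9 µm) are converted to the nearest even
pixel counts. Each window is mean-subtracted and FFT cross-correlated;
the integer peak is searched within half a window; sub-pixel refinement
is a 3-point Gaussian fit independently per axis (parabolic fallback
when a neighbour is non-positive). A second pass re-correlates with the
search window offset by the first-pass integer displacement — a
multi-pass scheme that substitutes for window deformation and captures
its accuracy benefit for the smooth, low-gradient flows here.

Two validation stages follow. The primary/secondary correlation peak
ratio of the *first* pass must exceed 1.15 (re-centred second-pass
correlations always look sharp, so they carry no confidence
information). Then a normalized-median test compares each vector with
its 3×3 neighbourhood median, normalised by the neighbourhood residual
plus a 0.1 px noise floor; residuals above 2 are invalidated. On
band-limited speckle at SNR 10 this holds the mean error below 0.2 px
for rigid shifts up to 40 % of the window, with forward/reverse
antisymmetry below 0.05 px. Separately, `filter_vectors` applies the
physical speed cut (default 0.25 µm/s) to remove estimation errors.

The ring-directed flow readout is the mean A–P velocity over valid
vectors in a 6×3-cell ROI immediately anterior to the furrow (the same
footprint as the convergence block, as the flow ROI's own dimensions are
not standardised), signed so that positive means toward the ring; a
posterior ROI flips the sign accordingly.

## Convergence and strain rate

Convergence is computed per axis with the central-difference stencil at
interior points and first-order one-sided differences at boundaries,
scaled by −1/a with a the grid step: p = −(1/a)·(u_{i+1}−u_{i−1})/2,
and analogously q along rows. The scheme is exact on fields linear in
the grid coordinate and exactly invariant to constant offsets; it
matches `numpy.gradient` (used as an independent oracle in tests, never
as the implementation). Any stencil touching an invalid vector yields a
masked cell — no interpolation, to avoid fabricating gradients. The
equatorial readout averages the 6 (A–P) × 3 (circumferential) cell
block centred on the furrow; the block is specified by cell count, so
its physical footprint follows from the grid step (6 × 2.9 µm by
3 × 2.9 µm at the defaults). Sign convention: positive =
influx/compression.

The relaxation rate of a convergence series on [onset, lagging-furrow
onset] is the slope from its maximum to the subsequent minimum
(moving-average smoothing, window 3); a series with no max→min pair is
censored with a flag.

Longitudinal strain rate normalises by the reference distance —
(d(t+Δ) − d(t))/(Δ·d(t)) with Δ = 27.9 s (five frames) — i.e.
engineering strain per unit time; the unnormalised µm/s variant is
behind a flag. For a pair advected by a linear sink of rate k the
estimator returns (e^{−kΔ} − 1)/Δ exactly, which is within 7 % of −k at
the default k and horizon.

## Myosin quantification

Total ring signal is measured on raw frames: mask 1 = segmentation
dilated 4×, mask 2 = eroded 4× (3×3 cross element per iteration — an
ImageJ-like default, configurable, as the element is not standardised);
M(t) = Σ(mask 1) − Σ(mask 2), so the cytoplasm interior to the ring
cancels. If erosion annihilates the mask, M falls back to the mask-1
sum with a flag. M(t) is emitted in raw AU (optional normalisation to
the onset value).

The enrichment rate detects alternating extrema on the smoothed series
(window 3, prominence 2 % of range — unspecified upstream, so chosen
and configurable), treats the series start/end as a minimum/maximum
where the interior extrema leave a rising segment unclosed, computes
each min→max slope from the raw values at the extremum frames, and
averages. A series with no rising pair falls back to the least-squares
slope, flagged.

## Foci tracking

Detection is scale-normalised Laplacian-of-Gaussian filtering at the
expected focus scale, local maxima above a relative threshold, and
per-axis 3-point Gaussian sub-pixel refinement. Linking is greedy
nearest-neighbour per frame transition (mutually-nearest pairs first,
remainder by ascending distance) with a gate distance and optional gap
bridging. This automated tracker is a deliberate stand-in for manual
tracking: its failure modes (crossing, merging foci) are excluded by
the synthetic fixtures, and no claim of equivalence to expert manual
tracking on real data is made. Cell-body motion registration is out of
scope; synthetic scenes have a fixed frame.

## Statistics

Pearson r uses the sample formula with the two-sided p from
t = r√((n−2)/(1−r²)). "Studentized" residuals are externally
studentized (leave-one-out variance) via OLS influence measures; an
essentially exact fit reports zero residuals rather than 0/0 noise.
The conservative outlier threshold is |t| > 3. Group summaries report
mean, SD and the 95 % CI t_{0.975,n−1}·SD/√n; cross-group correlations
use unweighted group means. One-way ANOVA with Holm–Šidák-corrected
pairwise comparisons and Welch's t-test are thin pass-throughs to
scipy/statsmodels — textbook procedures, not re-derived here.

## Problem sizes and determinism

Recovery studies use 20 seeded scenes (≈40 frames of 160×160 px each)
for closure parameters, 160×160 speckle with five shifts for PIV, and
12-frame cortex scenes for convergence/strain measurements — sizes at
which every estimator's error is far from its tolerance while the whole
suite and the acceptance script each run in well under a minute of
compute. All randomness flows from explicit seeds; hypothesis-based
property tests are derandomised.

## Known limitations

- The segmentation assumes a single bright, roughly elliptical ring;
  heavily fragmented or saturated rings degrade the mid-shell estimate.
- PIV assumes locally rigid motion per window; strong in-window
  gradients (beyond the prescribed smooth fields) would need true
  window deformation.
- The tracker performs no re-identification: a focus lost longer than
  the gap allowance starts a new identity.
- Convergence reads compression only in the absence of involution or
  extrusion of cortical material; the package does not correct for
  either.
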