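# Methods

## Measurement model

A 4D flow acquisition yields three velocity components per voxel per
timeframe (cm/s, world axes, NIfTI geometry), a velocity-encoding limit
VENC beyond which stored velocities alias by multiples of 2·VENC, and
companion long-axis cine images.  `mitralflow` quantifies transmitral
inflow three ways:

**MVvel / MVflow (annulus-plane methods).**  Two annulus landmarks,
initialized at end-diastole on the long-axis cine, are tracked over the
cycle by normalized cross-correlation (NCC) template matching: a forward
and a backward pass around the (cyclic) cardiac cycle, fused per frame by
weighted averaging with weights decreasing linearly in the number of steps
from the start frame — w_f = (T−t)/T, w_b = t/T after t forward steps of T.
The landmark chord defines the annulus plane: origin at the chord midpoint,
normal the in-cine-plane unit vector perpendicular to the chord, oriented
toward the apex.  Velocities are trilinearly resampled on a 50 mm × 50 mm,
1 mm grid on this plane, projected on the normal (positive toward the
apex), the plane's own normal velocity (cyclic central differences of the
origin trajectory) is subtracted, and the map is 3×3 median-filtered with
replicated borders.  The inflow area is segmented per frame by
thresholding at max(5 cm/s, 15% of the frame's maximum positive value),
keeping the connected component containing (or nearest to) the grid
centre, and filling holes.  MVvel takes the per-frame maximum inside the
area; MVflow integrates velocity × pixel area (mL/s).

**LVvel (LV-mask method).**  The voxelwise speed √(vx²+vy²+vz²) is 3×3×3
median-filtered per frame (full volume first, then masked — a config
switch allows mask-then-filter), and the per-frame maximum inside a
supplied LV mask is taken.  The segmentation itself is an input (ground
truth for phantoms, a file for real data); no network inference is
performed here.

**Peak selection.**  Each curve is restricted to a diastolic window; in
"auto" mode the window starts at the first positive sample after cycle
fraction 0.35 (both configurable) and runs to the last frame.  Local
maxima are samples strictly greater than both neighbours, plateaus
collapsing to their first sample and window endpoints excluded; maxima
with topographic prominence below 10% of the window maximum are
discarded.  If at least two remain, the two largest are E (earlier) and A
(later); value ties break by greater prominence, then earlier time.  Fewer
than two surviving maxima flags the curve as fused (monophasic inflow) —
the E/A ratio is then undefined, mirroring the clinical exclusion of such
exams.  Pipelines are deterministic: identical inputs give bit-identical
curves and peaks.

**Preprocessing.**  Aliasing is removed temporally: anchored at frame 0
(end-diastole, where transmitral velocities are near zero and aliasing is
assumed absent), each frame is shifted per voxel/component by the multiple
of 2·VENC closest to the previous frame.  This is exact whenever true
frame-to-frame changes stay below VENC; a phantom with aliasing injected
round-trips to the clean field.  Background phase offsets are modelled as
a spatial polynomial (order 0–2, default 1) per component on world-mm
coordinates, least-squares fitted to the time-averaged velocity of static
voxels (supplied mask, or automatically: temporal-mean speed and temporal
SD both < 2 cm/s) and subtracted from every frame; order-1 offsets on
noiseless fields are recovered to 1e−6.  Concomitant-gradient correction
is assumed done on the scanner and is out of scope.

**Agreement statistics.**  For each (method, reference) pair and metric
(E/A, peak E, peak A): OLS regression y = β₁x + β₀ with R² the squared
Pearson correlation; Bland–Altman mean difference with limits of agreement
mean ± 2·SD (sample SD, n−1); per-pair percentage difference
100·(y−x)/((y+x)/2) reported as its mean; paired Student t (undefined —
reported as NaN — for zero-variance differences, e.g. identical columns);
R² association categories weak ≤ 0.25 < moderate ≤ 0.5 < strong ≤ 0.8 <
very strong ≤ 1.  Correlations are compared by Fisher r-to-z:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) with a one-sided
upper-tail normal p computed via the complementary error function.  The
independent-samples formula is the default; Steiger's dependent-sample
variant (two correlations sharing a variable) is available as
`steiger_rz_compare`.  Incomplete subjects are dropped pairwise with a
logged count.

## The synthetic phantom

The phantom emulates the structure these methods rely on, not MR physics
(no k-space, coil, or gating simulation; cine images are synthetic blob
renderings, not bSSFP).

*Geometry and motion.*  World coordinates are right-handed mm from the
NIfTI affine, LV long axis along +z (base low, apex high).  Default grid
40×40×50 voxels at 2.8 mm isotropic, 30 frames over a 1000 ms cycle,
VENC 120 cm/s — a typical clinical protocol.  The annulus plane
translates apically as z(t) = z₀ + d·(1−cos 2πt/T)/2 with peak excursion
d = 12 mm (normal mitral annular excursion; peak plane speed ≈ 3.8 cm/s,
in the range of annular tissue velocities).

*Inflow jet.*  The through-plane velocity envelope is the sum of
raised-cosine E and A pulses (defaults: 60 and 50 cm/s, half-widths 130
and 110 ms).  The default peak times, cycle fractions 13/30 and 26/30,
coincide with sample times of the 30-frame grid so that temporal
discretization does not contaminate method error; misaligned peak times
lower every method's recorded peak identically and are available by
setting the fractions.  The jet cross-section is plug flow in a 4.5 mm
core with a Gaussian shoulder (σ = 6 mm), truncated at 3σ; axially the
profile is flat for 4 mm toward the apex and decays as a Gaussian
(σ = 7.5 mm) toward the annulus.  The plug core — about 1.5 voxels —
makes the vena-contracta value invariant under the mandatory 3×3(×3)
median filters, so phantom-recovery errors measure the methods rather
than the interaction of a smooth peak with the filter; a narrow pure
Gaussian peak would be attenuated ~12% by the 3D median at this
resolution, more than the effect being studied.  The vena contracta sits
5 mm apical to the annulus plane (configurable; typical offsets are a few
mm and not reported per-subject anywhere we know of), which attenuates
the annulus-plane measurement by the axial factor α = exp(−d²/2σ²) ≈ 0.80
— reproducing the known annular-method underestimation while leaving the
E/A ratio intact.

*Annulus-attached flow.*  Blood at the moving annulus plane translates
with it: a velocity component equal to the plane's normal speed, with a
compact raised-cosine axial support that vanishes at the vena contracta,
is added near the plane.  This makes plane-motion correction consequential
— the uncorrected plane measurement is biased by the plane speed, the
corrected one is not — while preserving the envelope as the exact speed
maximum at the vena contracta.  At frames where the envelope is small
relative to the plane speed the global speed maximum can exceed the
envelope by the attached component; the envelope-equality property is
therefore exact at all frames only for a static annulus, and at the E/A
peak frames for a moving one.

*Systolic outflow.*  A base-ward jet (default 90 cm/s peaking at cycle
fraction 0.12) inside the LV mask forces LV-based peak searches to respect
the diastolic window.

*Truth.*  True peaks are the envelope amplitudes at the vena contracta;
true peak flows are envelope × α × effective jet area (closed form:
πr_c² + 2π(r_c σ√(π/2) erf(3/√2) + σ²(1−e^{−9/2}))).  The truth object
also carries the landmark trajectories, per-frame LV masks, the sampled
envelope and plane speed, and a fused flag computed from the summed
envelope (single diastolic local maximum ⇒ fused).  Gaussian noise of
configurable SD is added per component; aliasing can be injected by
wrapping stored values into [−VENC, +VENC).  Everything is
bit-reproducible from the seed.

*Synthetic cohorts.*  `make_paired_measurements` draws per-subject echo
E/A (lognormal, mean 1.0, SD 0.5, clipped 0.4–2.8 — an elderly
ischemic-cohort spread), peak A (normal, 65 ± 12 cm/s) and peak E =
ratio × peak A, then applies per-method linear models y = slope·x +
intercept + noise.  The default models reproduce the association pattern
observed between 4D-flow methods and echo in such cohorts (strong for E/A
ratios, weak for annulus-plane absolute peaks); slopes and intercepts
follow the reported regressions, and noise SDs are set so the implied R²
matches given the echo spread simulated here.

## What passing tests do and do not show

The phantom has a single smooth jet, rigid translation-only annulus
motion, no eddy-current spatial structure beyond polynomials, no
through-plane annulus tilt, and blob-rendered cine landmarks that NCC can
track almost perfectly.  Recovery within tolerance here validates the
geometry, signal processing and peak logic — not robustness to real-world
segmentation error, leaflet geometry, flow turbulence, or poor cine
contrast.  The 40-second runtime and segmentation quality of a real
deep-learning LV mask are likewise out of scope: the mask is an input.

## Numerical choices

* NCC template 21×21 px, search ±10 px, template updated each step from
  the previous combined position; subpixel peak by separate quadratic fits
  along each axis of the 3×3 neighbourhood, clipped to ±1 px.  Steps whose
  NCC peak falls below 0.3 count as failures; more than 25% fails the
  track.  The position update keeps its fractional part (re-anchoring on
  rounded pixels would accumulate rounding residuals as drift).
* Plane velocity by cyclic central differences (the cycle is periodic);
  exact for linear motion away from the wraparound, ~0.7% low for a
  30-sample sinusoid (discrete-derivative attenuation).
* Median filters use edge replication; reformatting uses trilinear
  interpolation with out-of-volume samples zeroed and excluded from masks.
* Peak prominence follows the standard topographic definition
  (scipy-compatible); the test suite cross-checks the full selection
  against an independent brute-force enumeration, including plateaus and
  ties.
* Degenerate inputs are contracts, not crashes: empty diastolic windows
  and flat curves flag fused with a warning; empty LV mask frames,
  coincident landmarks, constant regressors and zero-variance paired
  differences raise ValueError.

## Known limitations

* Temporal unwrapping assumes frame 0 is alias-free; a cycle starting
  mid-jet would need a different anchor.
* The background-phase auto mask fails when offsets themselves push static
  tissue above the 2 cm/s speed threshold; supply an explicit mask then.
* Fusion detection is binary; no attempt is made to deconvolve merged E/A
  waves.
* The Fisher comparison defaults to the independent-samples formula even
  though method-vs-reference correlations share the reference; the
  dependent-sample variant is provided but not the default, for
  comparability with common practice.
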