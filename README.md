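# mitralflow

Transmitral E/A-ratio quantification from 4D flow cardiovascular MR
velocity fields.

## The problem

The ratio between the peak early (E) and peak late (A) diastolic
transmitral inflow velocities is the first-line index for grading left
ventricular diastolic dysfunction.  It is routinely measured with Doppler
echocardiography; 4D flow CMR — time-resolved 3D phase-contrast MRI with
three-directional velocity encoding — can measure the same quantities
anywhere in the acquired volume, retrospectively, without alignment
constraints.  `mitralflow` implements three 4D-flow measurement methods and
the statistical machinery to compare them:

* **MVvel** — the maximum through-plane inflow velocity at a mitral annulus
  plane tracked over the cardiac cycle from a long-axis cine (normalized
  cross-correlation landmark tracking, forward/backward pass fusion),
  reformatted, corrected for the plane's own motion, and 3×3
  median-filtered;
* **MVflow** — the volumetric inflow rate through the same tracked plane,
  integrating through-plane velocity over a segmented inflow area;
* **LVvel** — the maximum blood speed anywhere inside a left-ventricular
  segmentation mask, 3×3×3 median-filtered; unconstrained to the annulus,
  it captures the vena contracta — the true velocity maximum of the jet,
  which sits a few millimetres apical to the annulus plane.

In each case E and A are the two highest prominent peaks of the diastolic
inflow curve (E the earlier, A the later); curves in which the two waves
have merged into a single peak ("monophasic inflow", typical at high heart
rate) are flagged as *fused* rather than quantified.

Because annular-plane methods sample the jet away from the vena contracta,
they systematically underestimate absolute peak velocities; the
underestimation is common to E and A and cancels in the ratio.  The package
makes this ordering and its cancellation testable.

Supporting modules provide velocity preprocessing (temporal phase-wrap
removal for velocities beyond the VENC limit, polynomial background
phase-offset correction), a synthetic 4D cardiac flow phantom with exact
ground truth, and method-agreement statistics: OLS regression
(y = β₁x + β₀, R² = squared Pearson r), Bland–Altman analysis with
mean ± 2 SD limits of agreement, paired t-tests, Fisher r-to-z comparison
of correlations, and the conventional R² association categories
(weak ≤ 0.25 < moderate ≤ 0.5 < strong ≤ 0.8 < very strong ≤ 1).

## Worked example

```python
import numpy as np
import mitralflow as mf

phantom = mf.generate_phantom(seed=7)          # noise-free defaults: E 60, A 50 cm/s
cine = phantom.cine
init = cine.world_to_pixel(np.asarray(phantom.init_landmarks["points_mm"]))
tracks = mf.track_landmarks(cine, init, init_frame=0)
x0, y0 = phantom.params.axis_xy
plane = mf.landmarks_to_plane(tracks, cine, np.array([x0, y0, phantom.params.apex_z]))

lv = mf.lvvel_ea(phantom.velocity, phantom.lv_mask).peaks
mv = mf.mvvel_ea(phantom.velocity, plane).peaks
print(f"true E/A  : {phantom.truth.true_ea_ratio:.3f}")
print(f"LVvel     : E = {lv.e_value:.1f} cm/s, A = {lv.a_value:.1f} cm/s, E/A = {lv.ea_ratio:.3f}")
print(f"MVvel     : E = {mv.e_value:.1f} cm/s, A = {mv.a_value:.1f} cm/s, E/A = {mv.ea_ratio:.3f}")
print(f"Fisher z=1.43 -> one-sided p = {mf.normal_upper_tail(1.43):.4f}")
```

prints

```
true E/A  : 1.200
LVvel     : E = 59.9 cm/s, A = 50.0 cm/s, E/A = 1.198
MVvel     : E = 47.2 cm/s, A = 40.0 cm/s, E/A = 1.180
Fisher z=1.43 -> one-sided p = 0.0764
```

LVvel recovers the vena-contracta peaks to within a fraction of a percent.
MVvel, measuring at the annulus plane 5 mm away from the vena contracta,
underestimates both peaks by ~20% — but its E/A ratio agrees with LVvel
and the truth to within 2%, the systematic attenuation cancelling in the
ratio.

The same pipeline is available from the shell:

```sh
mitralflow simulate --out data --seed 7
mitralflow track --cine data --landmarks data/landmarks.json --out plane.json
mitralflow mvvel --data data --plane plane.json --out mvvel.json
mitralflow lvvel --data data --mask data/lv_mask.nii.gz --out lvvel.json
mitralflow compare --table cohort.csv --out stats/
```

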