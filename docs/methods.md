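# Methods

## The diagnostic model

The screening system drives the free-hanging breast with a steady sinusoid
and tracks surface reference points in 3-D. The diagnostic rests on the
stiffness dependence of vibration frequency, ω = √(k/m): with tumour tissue
4–10× stiffer than healthy tissue and local mass comparable, response
frequencies over a lesion are elevated by √(k_tumor/k_healthy) ∈ [2, 3.16].
Rather than thresholding absolute frequencies — which would be confounded by
the large variation of breast properties across the population — the method
compares regions of one breast against each other, making every breast its
own control.

### Frequency of interest

Each point's 3-D displacement trajectory is reduced to a scalar series by
signed projection onto its first principal axis (the clinical pipeline's
choice of scalar is not knowable from the outside; the principal axis is the
projection that preserves the most signal energy and is well-posed because
the phantom's motion is dominantly axial). The one-sided amplitude spectrum
(DC and Nyquist bins removed) is searched for local maxima; peaks are ranked
by magnitude with ties broken toward lower frequency, and bins within
±2 bins of a selected peak are ineligible so that spectral leakage around a
peak is never mistaken for a second peak.

The selection flowchart: if the dominant peak differs from the actuation
frequency by more than `match_tolerance` — default max(0.5 Hz, one bin),
since "equivalent to the input frequency" needs a numeric width — the point
is *irregular* and its dominant frequency is kept as the frequency of
interest (irregular vibration can itself be caused by a stiff lesion).
Otherwise the second-dominant peak is kept, provided its magnitude reaches
15% of the dominant's (inclusive); otherwise the point is discarded.
Constant or zero trajectories are flagged degenerate, excluded and counted.

### Segmentation and run screening

The lowest and highest 5% of points by height are removed (nearest-rank:
floor(0.05·N) points at each end) — chest-wall and actuator regions are the
noisiest in the real system. The remainder is partitioned into 4 radial
quadrants × 4 height bands. Quadrants are taken about the vertical axis
through the cloud centroid with boundaries at the half-hour clock positions
(1:30/4:30/7:30/10:30), so the quadrants are centred on 12, 3, 6 and
9 o'clock; right-breast angles are mirrored through the sagittal plane so
outer/inner indices are anatomically consistent and one control
configuration applies to both sides. Height bands are equal-count quartiles
of the retained heights, not equal-extent slices: point density on a
pendant surface is strongly height-dependent, and equal-count bands keep
per-segment estimates comparably precise (which of the two the clinical
pipeline used is not stated anywhere; this is our choice).

A segment's mean *dominant* frequency should equal the actuation frequency;
if it deviates by more than 2 Hz the segment is irregular, and a run with
≥ 10% irregular segments is dropped. Only runs in the 20–23 Hz band enter
the analysis. Per-segment FoI means are averaged cell-wise across the
usable runs (a cell missing in one run takes its value from the others;
missing only if empty everywhere).

### Diagnosis

A *configuration* assigns one control quadrant per height band. For each
band whose control cell is present, every other present cell is compared to
it; the deviation is |f_s − f_c|/f_c, measured relative to the control
(matching the tolerance-band-around-the-control presentation of the
original method; a symmetric alternative |f_s − f_c|/mean is selectable).
Any deviation above the tolerance makes the breast positive. Bands with a
missing control are recorded as indeterminate; a breast whose four controls
are all missing raises an error distinct from a negative call — silently
calling such a breast healthy would hide a data-quality failure.

Twelve configurations are shipped: ids 1–4 hold a constant control quadrant,
ids 5–8 spiral it ascending across bands ((b+z) mod 4), ids 9–12 descending.
The original twelve layouts are not recoverable from any published text, so
this enumeration is a documented stand-in, replaceable verbatim from a YAML
file. Named tolerance presets 0.34 (configuration 6) and 0.33
(configuration 1) carry the clinically optimal values.

### ROC evaluation

Sweeping the tolerance over a grid (default 0 to 1 in steps of 0.05; the
original granularity is unstated) yields a monotone discrete ROC. Bootstrap
up-sampling draws 50 breasts with replacement, 200 times; each trial's sweep
contributes its (FPR, TPR) points to a pooled cloud. Trials whose resample
lacks a class contribute only their defined rate (the undefined rate is NaN
and dropped; a redraw policy would bias toward balanced resamples).

The pooled cloud is summarised by y = 1 − e^(−ax) fitted by total least
squares: a minimises the summed squared perpendicular distances to the
curve. The inner projection of each point is solved by a dense presolve
(257-point grid) plus vectorised golden-section refinement to 1e-10; the
outer problem by bounded scalar minimisation over a ∈ (0, 50]. The fit is
deterministic. One parameter deliberately spans the chance line through the
perfect square ROC; more parameters would overfit 26 breasts.

Closed forms on the fitted curve:

* AUC = 1 − (1 − e^(−a))/a. (Note: this tends to 0, not 0.5, as a → 0;
  it crosses 0.5 at a ≈ 1.594 and → 1 as a → ∞. It is verified against
  numeric quadrature to 1e-10.)
* *Optimal* operating point: the curve point closest (Euclidean) to the
  ideal corner (FPR, TPR) = (0, 1), via the stationarity condition
  x = a·e^(−2ax) (unique root, bisection). This choice — rather than the
  Youden point — analytically reproduces the published optimal
  sensitivity/specificity pairs from the published AUCs (0.85 → 81%/75%),
  so it is taken as the intended definition.
* At 80% specificity: TPR = 1 − e^(−0.2a). At 80% sensitivity:
  FPR = ln(5)/a.
* Criteria: AUC > 0.73 (strict; a boundary value fails), sensitivity ≥ 60%
  at 80% specificity, specificity ≥ 65% at 80% sensitivity.

## The phantom

`synth_recording` gives every surface point the displacement

    d_p(t) = e_p · A(z) [ sin(2π f_in t + φ₁) + m · sin(2π r(p) f_in t + φ₂) ]
             + noise,

with r(p) = ρ_h · √(1 + w(p)(k_ratio − 1)) · (1 + g(p)), where ρ_h is the
healthy secondary-to-input ratio (default 1.5), w(p) ∈ [0, 1] the lesion
footprint weight, k_ratio the tumour/healthy stiffness ratio, and g a smooth
zero-mean heterogeneity field. The secondary amplitude fraction m defaults
to 0.3, comfortably above the 15% retention rule; setting it below 0.15
produces the "filtered-out" regime. Gaussian noise (default sd 0.02 mm
against a 1 mm primary) is tripled within the outer 5% height ranges to
emulate chest-wall/actuator noise and exercise the trimming rule. Motion
directions are near-axial unit vectors with ≤ 10% off-axis jitter. Geometry
is a pendant half-ellipsoid of revolution (apex height = 1.2 × equatorial
radius) whose enclosed volume matches the breast volume; the point cloud is
a stratified-jittered area-uniform sample, bit-reproducible under its seed.
The lesion footprint has weight 1 within diameter/2 of the lesion's surface
projection (3-D chord distance — monotone in the surface geodesic at lesion
scale) and falls as a raised cosine to 0 at one diameter.

What the *secondary tone* stands for is an explicit assumption: no public
description states which physical signal the clinical second-dominant peak
is. Synthesising it as a discrete tone at ρ_h·f_in scaled by the local
stiffness factor gives the selection flowchart well-defined ground truth and
directly instantiates the √(k-ratio) elevation; real spectra may instead
carry harmonics or broadband content, so passing tests demonstrate the
pipeline's correctness on the assumed structure, not the clinical validity
of that structure.

### Population heterogeneity

A cohort in which every breast had identical tissue would be degenerate:
all segment means would coincide and any nonzero tolerance would separate
the classes perfectly. Real breast properties vary more across the
population than within one breast — that is the method's founding premise —
so `synth_cohort` draws each breast's heterogeneity scale uniformly from
(0.02, 0.20). The range is anchored to the published clinical operating
characteristics, not to any test: at the optimal 34% tolerance the clinical
specificity was 77%, so roughly a quarter of healthy breasts must carry a
maximum inter-segment deviation above 0.34, which this range reproduces
(healthy max-deviations ≈ 0.04–0.55, median ≈ 0.15). Within a breast the
field is smooth (low-order angular harmonics plus a linear height trend),
so neighbouring segments differ by a few percent, as neighbouring regions
of real tissue do.

Cohort defaults mirror the clinical cohort where values are known: volumes
200–1100 cm³, tumour diameters 7–48 mm, one lesion per cancerous breast,
stiffness ratios 4–10. `tumor_clock_positions` optionally pins lesion
angles (cycled) for controlled-placement studies — used by the acceptance
cohort, which places segment-scale lesions (40–48 mm) at quadrant centres
so the ≥ 2× elevated region lies within a single segment.

## Problem sizes

Simulated cohorts use 300–1000 points per breast rather than the clinical
~14,000. Spectral extraction is independent per point, so segment means over
n/16 ≈ 20–60 points already estimate the segment frequency to well under one
spectral bin; the reduction changes nothing structural. Recordings default
to 2 s at 250 Hz sampling (0.5 Hz resolution — the primary and secondary
tones sit ≥ 20 bins apart; Nyquist covers the highest synthesised tone,
1.5·√10·23 ≈ 109 Hz), and generation enforces both constraints explicitly.

## Numerical choices and degenerate inputs

* Peak ties break toward lower frequency; plateau maxima take the leftmost
  bin. A flat spectrum has no peaks and the point is excluded.
* Trimming uses the nearest-rank convention (counts appear in tests).
* `a_from_auc` inverts the area by bisection to 1e-10 over (0.5, 1); the
  operating-point stationarity equation is bisected to 1e-12.
* A ROC fit on points that are all at the origin is refused (the parameter
  is unidentified) rather than returned as an arbitrary value.
* All randomness flows from explicit seeds; a breast's geometry and tissue
  field are pinned by a per-breast seed shared across its runs, while
  phases and measurement noise are per-run.

## Known limitations

* The two-tone spectral model and the 12-configuration enumeration are
  stand-ins where the original system is unobservable; both are isolated
  behind explicit parameters (MaterialSpec, YAML configuration override).
* The one-parameter ROC family cannot represent asymmetric
  sensitivity/specificity trade-offs; cohorts with perfect separation
  saturate the fit at the parameter bound a = 50 (AUC ≈ 0.98).
* Deviations are control-relative and therefore asymmetric under swapping a
  segment with its control; the symmetric mode is available but the
  control-relative form is the default because it matches the original
  tolerance-band presentation.
* The phantom has no damping, no harmonics, no wave reflection and no
  concavities; irregular-dominant points arise only through noise. The run
  screening rule is therefore exercised mainly by constructed inputs in the
  tests, not by the phantom's default regime.
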