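# Methods

## Indentation model

A stress–relaxation test drives a hemispherical indenter (radius
R = 1 mm) into cartilage: a slow approach until a 0.1 N contact
threshold, a ramp of δ = 0.3 mm at 0.5 mm/s (0.6 s), then a 240 s hold.
The analysis assumes the force maximum marks the ramp-to-hold transition
(ties broken at the earliest index) and models the hold as

    F(t) = F_eq + A1 e^(−t/τ1) + A2 e^(−t/τ2) + A3 e^(−t/τ3).

Moduli are nominal: stress is force over the projected spherical-cap
area π(2Rδ − δ²) (1.60 mm² at the protocol depth), strain is δ/z with z
the cartilage height measured on the proton image. No Hertzian contact
or finite-thickness correction is applied; these are *apparent* moduli
by construction. Permeability per compartment is the poroelastic
scaling k = z²/(hτ), reported in mm² MPa⁻¹ s⁻¹ with h the apparent
equilibrium modulus. Compartments are indexed by ascending τ
(compartment 1 = fastest); any interpretation tied to a different
compartment ordering must re-map accordingly.

Two readings of the equilibrium force exist — the raw last sample and
the fitted asymptote F_eq. The fitted asymptote is used for the
equilibrium modulus because it is robust to noise in the final samples;
both values are carried in the result so the difference (which reflects
whether 240 s truly reached equilibrium) stays visible.

### Triexponential fit numerics

Nonlinear least squares (`scipy.optimize.curve_fit`, trust-region with
bounds). Initialisation: F_eq from the last sample; amplitudes as equal
thirds of the observed drop; τ at hold/100, hold/10 and hold/2 — one
guess per decade-scale compartment, no user input. Bounds: amplitudes
≥ 0 (physical decay), τ ∈ [0.01 s, 10 × hold] (prevents runaway slow
compartments). Non-convergence is returned as a flagged result, never
raised, so batch runs account for every site. For data with fewer true
compartments the surplus amplitudes shrink toward zero, which is the
intended behaviour, not a failure. Constant-force input is an exact
fixed point of the initialisation (drop = 0), returning F_eq = mean
level and zero amplitudes.

## Sodium quantification model

The conversion chain is multiplicative and order-free:

    C = line(I) × (liquid fraction / cartilage fraction) × (voxel / z) / w

* `line` — affine calibration fitted by OLS to the phantom
  (intensity, concentration) pairs; at least two distinct intensities
  required.
* Relaxation fractions — cartilage signal at echo time TE is
  0.6 e^(−TE/T2short) + 0.4 e^(−TE/T2long) with T2* = 0.8/14.8 ms
  (≈ 0.44 at TE = 1.61 ms; the short pool contributes ≈ 8 % despite
  carrying 60 % of the sodium); the liquid phantom decays
  monoexponentially with T2* = 19.8 ms (≈ 0.92). The correction factor
  is their ratio, ≈ 2.10 at full precision (2.09 from the rounded
  intermediates 0.92/0.44).
* Partial volume — thickness is the longest contiguous supra-threshold
  run in the proton column at the site (threshold = half the column
  maximum, an automated stand-in for manual segmentation), times the
  0.3 mm proton voxel. The factor voxel/z assumes uniform thickness
  within the voxel, no sodium outside the cartilage, and a negligible
  point-spread function. Thickness above the voxel size clamps the
  factor to 1 with a warning.
* Water content — the concentration is divided by the assumed 70 %
  water fraction, raising it onto the per-water-volume scale used by in
  vivo literature (~170–270 mM for degraded cartilage).

The site value is a single voxel, not an ROI mean: the 3 mm voxel
already integrates the neighbourhood around the indentation point, and
averaging further would mix in unrelated tissue.

## Association statistics

Pearson correlations with two-sided t-test p-values over all complete
sites and within the two thickness strata (severe ≤ 1.5 mm, moderate
> 1.5 mm; the boundary is inclusive on the severe side). Plateau
adjustment is a Gaussian linear model with plateau as categorical fixed
effect; a random-intercept mixed model is fitted as a companion variant
and both are reported, since either reading of "adjusted for plateau"
is defensible. No multiplicity correction is applied; p-values are
labelled raw. Sites with missing GAG are excluded listwise with a
logged count. Strata with fewer than 3 complete pairs are emitted
flagged rather than dropped.

## Synthetic-data generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is verified.

* **Population**: 4 plateaus × 16 sites (64 locations). Thickness is
  drawn uniformly on the 0.3 mm grid from 1.2 to 3.0 mm — the
  granularity at which thickness is measurable on the proton image —
  so both strata are populated. GAG is truncated-Gaussian
  (mean 3.4, SD 2.0 mg/mL, floor 0.3); tissue sodium is affine in GAG
  (default slope 25 mM per mg/mL around a 225 mM baseline, SD 30 mM);
  the apparent peak modulus is affine in GAG (slope 0.5 MPa per mg/mL
  around 3.4 MPa, SD 0.5); the equilibrium modulus is 0.24 × peak plus
  SD 0.08 MPa. Baselines match the published population means for
  degraded tibial-plateau cartilage; the coupling slopes and SDs are
  generator choices sized so the known association directions are
  detectable but not trivial at n = 64.
* **Curves**: the approach is a linear force rise to the threshold over
  0.15 mm of travel at 50 µm/s — only the threshold crossing matters
  downstream, so the within-approach force profile is not modelled.
  Forces during the hold follow the site's triexponential parameters
  exactly; τ triples are drawn on separated scales (1–4, 10–30,
  80–160 s) so the three compartments are identifiable within a 240 s
  hold. Sampling is 10 Hz: it resolves τ ≥ 1 s while keeping each
  curve ~2 400 samples. Force noise is additive Gaussian
  (default 8 mN, ~1 % of a typical peak force).
* **Volumes**: each site's slab is painted into a 0.3 mm ground-truth
  grid at intensity gain × C × water fraction × cartilage T2* fraction
  and block-averaged to the 3 mm sodium grid — partial volume arises
  from genuine averaging, not a multiplicative shortcut. Phantoms fill
  whole voxels at gain × C × liquid fraction. The proton volume marks
  the slabs at 100 intensity units. Image noise is additive Gaussian
  (default SD 1 intensity unit) on both volumes.

What the generator does **not** emulate: curved cartilage surfaces and
menisci, B0/B1 inhomogeneity, point-spread blurring, k-space sampling,
fluid signal from synovial spaces, co-registration error (volumes are
emitted aligned), and any nonlinearity in the GAG–sodium–stiffness
couplings. Passing tests therefore demonstrate that the quantification
chain is self-consistent and recovers known structure under its own
assumptions — not that those assumptions hold in real specimens.

## Problem sizes and tolerances in the test suite

Parameter-recovery statistics use 100 curves at 1 % force noise
(median τ errors < 10 %, median F_eq error < 2 %); the noiseless
partial-volume round trip covers all 64 sites (recovery within 2 %,
exact up to float error when thickness is a multiple of 0.3 mm);
calibration-slope coverage uses 200 replicates of an 8-point calibration
— with only 3 phantoms the slope-error/SE ratio has a single degree of
freedom and a ±3 SE band covers only ~80 % of replicates, so the wider
design is used for the coverage check while the 3-phantom case is
verified exactly in the noise-free limit; correlation-direction
recovery runs the full pipeline at 64 sites for 100 seeds. All
randomness is seeded; identical configuration and seed give
byte-identical pipeline outputs.

## Known limitations

* The apparent moduli are protocol-specific; they are not intrinsic
  material constants and depend on tip size, depth and hold time.
* Permeability from k = z²/(hτ) is a scaling estimate; no biphasic or
  triphasic finite-element inversion is attempted.
* The thickness threshold rule (half of column maximum) is a simple
  automated proxy for manual segmentation and will fail on columns with
  multiple disjoint tissue layers thicker than the true cartilage.
* The relaxation correction assumes fixed 60/40 pool fractions and
  literature T2* values for all sites; site-to-site T2* variation
  propagates directly into the concentration estimate.
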