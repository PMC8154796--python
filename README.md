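# cartiq

Quantification pipelines linking glycosaminoglycan (GAG) content,
compressive stiffness and tissue sodium concentration in articular
cartilage — for researchers studying whether quantitative sodium MRI can
stand in for invasive stiffness measurements in early osteoarthritis.

Cartilage owes much of its stiffness to the Donnan osmotic pressure
generated by sodium counter-ions attracted to the fixed negative charges
of GAGs. `cartiq` implements both bespoke measurement chains needed to
test that link ex vivo, plus the statistics that join them per
indentation site, plus a synthetic-data generator so the whole analysis
runs end to end without specimens.

## What it computes

**Indentation biomechanics.** A ramp-and-hold stress–relaxation curve
(0.1 N contact threshold, 0.3 mm indentation at 0.5 mm/s with a 2 mm
hemispherical tip, 240 s hold) is segmented at the force peak; the hold
phase is fitted with a third-order exponential decay

&nbsp;&nbsp;&nbsp;&nbsp;F(t) = F_eq + Σᵢ Aᵢ e^(−t/τᵢ),&nbsp;&nbsp;i = 1..3.

The apparent peak modulus is peak stress (peak force / nominal
spherical-cap contact area, π(2Rδ−δ²) = 1.6 mm² at δ = 0.3 mm) over
nominal strain (δ / cartilage height z); the apparent equilibrium modulus
uses the relaxed force F_eq. Each compartment yields a poroelastic
permeability k = z²/(hτ), in mm² MPa⁻¹ s⁻¹.

**Sodium quantification.** Sodium image intensity (3 mm isotropic voxels)
becomes tissue concentration via four corrections:
calibration against three saline phantoms (75/225/300 mM); a T2*
relaxation factor — cartilage sodium decays biexponentially
(S = 0.6·e^(−TE/0.8 ms) + 0.4·e^(−TE/14.8 ms) ≈ 0.44 at TE = 1.61 ms)
while the liquid phantoms survive at e^(−TE/19.8 ms) ≈ 0.92, a ratio of
≈ 2.1; a partial-volume factor voxel/thickness, with thickness measured
on a co-registered 0.3 mm proton volume; and division by the assumed 70%
tissue water content.

**Association statistics.** Pearson correlations among GAG, sodium,
moduli and permeability — overall and stratified into severely (≤ 1.5 mm)
and moderately (> 1.5 mm) degraded cartilage — plus plateau-adjusted
linear models (categorical fixed effect, with a random-intercept
variant).

## Worked example

```python
from cartiq import *

cfg = SimulationConfig(seed=42)          # 4 plateaus x 16 sites
geom = IndenterGeometry()
relax = RelaxationParams()

sites = generate_sites(cfg, geom)
site = sites[0]
curve = simulate_indentation_curve(site, geom, cfg)
sod, prot, layout = simulate_volumes(sites, cfg, relax)
cal = fit_calibration(extract_phantom_intensities(sod, layout.phantoms))
q = quantify_site(sod, prot, cal, relax, site.site_id,
                  layout.site_sodium_index[site.site_id],
                  layout.site_proton_column[site.site_id])
res = analyze_curve(curve, q.thickness_mm, geom)

print(f"site {site.site_id}: thickness {q.thickness_mm:.1f} mm "
      f"({stratify_by_thickness(q.thickness_mm)} stratum)")
print(f"  peak modulus      {res.apparent_peak_modulus_MPa:.2f} MPa")
print(f"  eq modulus        {res.apparent_equilibrium_modulus_MPa:.2f} MPa")
print(f"  taus              {res.taus_s.round(1)} s")
print(f"  permeability k1   {res.permeability_per_compartment[0]:.4f} mm^2/(MPa*s)")
print(f"  sodium            {q.final_concentration_mM:.1f} mM "
      f"(truth {site.true_sodium_mM:.1f} mM, pv x{q.pv_factor:.2f}, "
      f"relax x{q.relaxation_factor:.2f})")
```

prints:

```
site 1: thickness 1.2 mm (severe stratum)
  peak modulus      2.82 MPa
  eq modulus        0.53 MPa
  taus              [  1.4  19.5 110. ] s
  permeability k1   1.9062 mm^2/(MPa*s)
  sodium            160.4 mM (truth 195.5 mM, pv x2.50, relax x2.10)
```

The moduli land in the expected range for degraded cartilage (peak a few
MPa, equilibrium a few tenths). The sodium read-out underestimates the
195.5 mM ground truth by ~18%: at 1.2 mm thickness the ×2.5
partial-volume correction amplifies single-voxel image noise — exactly
the error mechanism that makes thin-cartilage sodium mapping hard.

The same chain runs from the shell:

```bash
cartiq run-all --seed 42 --outdir out/
```

which writes `site_results.csv`, `correlations.csv`, `model_fits.csv`
and a `manifest.json` whose site counts always reconcile
(`sites_in == quantified + excluded`).

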