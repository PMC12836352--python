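# wgmsense

Whispering-gallery-mode (WGM) sensing of intracellular lipid droplets.

Lipid droplets in mature adipocytes are near-perfect spheres of
triglyceride (refractive index n_LD ≈ 1.47) suspended in cytoplasm
(n_cell ≈ 1.33–1.40).  Dye emission trapped inside them by total
internal reflection forms sharp TE/TM whispering-gallery resonances.
Their positions encode the droplet diameter; their spacing (the free
spectral range, FSR = 1/(π·n_eff·d) in inverse wavelength) gives the
absolute size; their common shift between time points gives diameter
*changes* two orders of magnitude below the optical resolution limit
(Δλ/λ = Δd/d); and the TE–TM splitting encodes the refractive index of
the surrounding cytoplasm through S = √(ρ²−1)/ρ with ρ = n_LD/n_cell.

`wgmsense` is for biophotonics groups running such experiments: it
fits resonance spectra (Lorentzian superposition at high SNR, empirical
chirped / inverse-wavelength sinusoids at low SNR), converts peak
ladders into diameters d, nanometer Δd(t) tracks and n_cell(t) series,
derives lipolysis metrics (volume rate, molecules/s, molar flux,
lipolytic efficiency = (dd/dt)/2), flags viability transitions (lasing
onset, membrane rupture via n_cell drop, static-size cells), and
generates physically grounded synthetic spectra with known truth so the
whole pipeline is testable without instrument data.

Core quantities, in the field's notation:

* mode positions: π·n_LD·d/λ = ν + 2^(−1/3)α_q ν^(1/3) − P/√(ρ²−1) + …
  (first-order radial modes, ν = ℓ + ½, P = ρ for TE, 1/ρ for TM),
  with an exact Mie-root oracle for validation;
* diameter from spacing: mean Δ(1/λ) = 1/(π·n_eff·d);
* resolution: (Δd)_min = d·w_s/λ for peak scatter w_s;
* refractometry: n_cell = n_LD·√(1−S²), S from TE–TM splitting;
* flux: molecules/s = |dV/dt|/V_TG, V_TG ≈ 2 nm³ per triglyceride.

## Worked example

Simulate a lipolysis time course (60 μm droplet, −0.2 μm/h baseline
with a 30-minute burst at −1 μm/h, SNR 25), then run the full inference
chain:

```python
import numpy as np
from wgmsense import (
    SynthConfig, generate_timeseries, preprocess, fit_time_series,
    diameter_from_fsr, track_diameter_change, molecule_and_molar_flux,
)

scfg = SynthConfig(scenario="lipolysis", snr=25.0, seed=3)
spectra, truth = generate_timeseries(scfg)
psets = fit_time_series([preprocess(s) for s in spectra])
d0 = diameter_from_fsr(psets[0], n_eff=1.47)
track = track_diameter_change(
    [(s.meta.t_min, p) for s, p in zip(spectra, psets)], d0, cell_id="cell0"
)
print(f"absolute diameter: {d0.d_um:.2f} +/- {d0.sigma_um:.3f} um")
for t, dd in zip(track.times_min, track.dd_nm):
    print(f"  t = {t:5.0f} min   dd = {dd:8.1f} nm")
burst = float(np.nanmin(track.rate_um_per_h))
flux = molecule_and_molar_flux(d0.d_um, burst)
print(f"fastest interval rate: {burst:.3f} um/h")
print(f"molecules/s during burst: {flux.molecules_per_s:.2e}")
```

Output:

```
absolute diameter: 59.35 +/- 0.002 um
  t =     0 min   dd =      0.0 nm
  t =    30 min   dd =    -98.9 nm
  t =    60 min   dd =   -197.9 nm
  t =    90 min   dd =   -694.2 nm
  t =   120 min   dd =   -794.3 nm
  t =   150 min   dd =   -894.5 nm
  t =   180 min   dd =   -994.9 nm
fastest interval rate: -0.992 um/h
molecules/s during burst: 7.63e+08
```

Reading the numbers: the absolute diameter (59.35 μm for a true 60 μm
droplet) carries the ~1% bias of the n_eff = n_LD approximation, while
the *changes* are nm-accurate — the −0.2 μm/h baseline appears as
−98.9 nm per 30-minute step and the burst interval recovers
−0.992 μm/h against a true −1.  A droplet shrinking this fast exports
~8×10⁸ triglyceride molecules per second across its surface.

The same pipeline runs from the shell:

```bash
wgmsense simulate --scenario lipolysis --snr 25 --seed 3 --out-dir run/
wgmsense track    --manifest run/manifest.csv --out-dir run/
wgmsense metrics  --out-dir run/
wgmsense report   --out-dir run/
```

`simulate` writes plain-text spectra plus a manifest and truth table;
`fit`/`track`/`metrics`/`viability` consume those files unchanged and
write CSV/JSON artifacts; `report` bundles everything with the config
hash and seed.  See `docs/methods.md` for the models, conventions,
default parameters and known limitations.

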