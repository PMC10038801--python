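# p2t — pair-production tomography

`p2t` is a desk-scale simulator and reconstruction toolkit for
**pair-production tomography (P2T)**: imaging a subject from the
coincident 511 keV annihilation photons that are produced when a
megavoltage radiotherapy X-ray beam (e.g. a 10 MV bremsstrahlung source)
undergoes pair production in tissue.  P2T acquires data like PET — a ring
detector, energy and coincidence-time windows, lines of response (LORs) —
but the positrons come from the treatment beam itself rather than from a
radiotracer.  Two consequences make the modality interesting:

* after fluence correction the image intensity is proportional to
  **rho·Z_eff**, the density times the effective atomic number
  (Z_eff = Σ Z_i f_i over elemental weight fractions, by Bragg additivity
  of the pair-production cross-section) — a clean linear material signal
  that CT does not provide;
* each coincidence is localised independently, so **partial-view and
  sparse-view** acquisitions work without the angular data-sufficiency
  requirements of transmission CT, and the P2T signal tracks TERMA
  (total energy released per unit mass), making it a surrogate for
  **in-vivo dose monitoring** during radiotherapy.

The package is aimed at medical-physics researchers who want a fast,
fully scriptable model of the whole chain: voxel phantoms and material
tables, beam plans (volume excitation and scanning pencil beams, full or
partial view), a vectorised Monte Carlo of primary transport, positron
range and annihilation, a 1,440-element ring detector with a
detection-time model and the PET-style filter cascade, and the three
reconstruction methods — **FBP** (sinogram rebinning + plain ramp
filter), **SPB** (LOR × pencil-axis intersection) and **TOF**
(time-of-flight localisation, Δd = cΔt) — with attenuation and fluence
corrections and quantitative analysis (contrast, Z-linearity regression,
cumulative intensity-volume histograms).

## Worked example

```python
import numpy as np
from p2t import (RingDetector, fan_beam_plan, nanoparticle_phantom,
                 run_acquisition, geometric_efficiency, tof_resolution_cm)
from p2t.beams import pair_weighted_fluence_map
from p2t.recon import tof_reconstruct, fluence_correct
from p2t.analysis import contrast_to_water, normalize_image
from p2t.materials import insert_layout

single, pair = geometric_efficiency(RingDetector())
print(f"ring efficiency: {single:.2%} single, {pair:.2%} pair")
print(f"TOF limit at 20 ps: {tof_resolution_cm(0.02)*10:.1f} mm")

phantom = nanoparticle_phantom()           # 7 high-Z inserts + 3 water
plan = fan_beam_plan(20, mode="VE").scaled_to(4e6)
ring = RingDetector(time_resolution_ns=0.02)
acq = run_acquisition(phantom, plan, ring, rng=42)
print(f"{acq.n_primaries} primaries -> {acq.n_pair_events} pair events "
      f"-> {acq.accepted_pairs} coincidences")

img = tof_reconstruct(acq.lors, phantom)                    # sigma = 2 mm splats
img = fluence_correct(img, pair_weighted_fluence_map(plan, phantom))
lay = insert_layout("nanoparticle")
img = normalize_image(img, lay["water"], 1.2)               # water insert = 1
c, sd = contrast_to_water(img, lay["Bi"], 1.2, lay["water"], 1.2,
                          rng=np.random.default_rng(0))
print(f"TOF contrast of the 5% Bi insert vs water: {c:.2f} +/- {sd:.2f}")
```

prints

```
ring efficiency: 4.17% single, 0.17% pair
TOF limit at 20 ps: 3.0 mm
4000800 primaries -> 1775135 pair events -> 1517174 coincidences
TOF contrast of the 5% Bi insert vs water: 0.51 +/- 0.01
```

Reading the numbers: the single 10 cm detector row collects 4.17 % of
photons and hence 0.17 % of coincident pairs; a 20 ps timing detector
localises annihilations to 3 mm along the LOR.  Four million primaries
yield 1.5 M accepted coincidences, and the fluence-corrected TOF image
shows the 5 % bismuth solution at +51 % contrast over water — close to
the Bragg-additivity prediction
(ρ·Z_eff − ρ_w·Z_eff,w)/(ρ_w·Z_eff,w) = 0.645 after accounting for the
~4.6 mm median positron-range blur of the 1.75 cm inserts.

The end-to-end phantom studies (high-Z Z-linearity, partial view, dose
monitoring) are wrapped in `p2t.experiments` and in the CLI:

```bash
p2t repro fig2 --seed 1 --primaries 1e7 --out out/fig2    # Z-linearity study
p2t repro fig4 --seed 1 --out out/fig4                    # partial vs full view
p2t repro fig5 --seed 1 --out out/fig5                    # TERMA / P2T / cIVH
p2t simulate --phantom tissue --mode SPBE --primaries 1e6 --seed 0 --out out/run
p2t reconstruct --method spb --primaries 1e6 --seed 0 --out out/spb_image
```

## Layout

| module | contents |
|---|---|
| `p2t.materials` | element/material tables, Z_eff, parametric cross sections, voxel phantoms |
| `p2t.spectrum`  | binned bremsstrahlung spectra |
| `p2t.beams`     | beam plans, release timing, Siddon ray tracing, fluence maps |
| `p2t.transport` | primary MC, positron range model, annihilation, tallies, TERMA |
| `p2t.detection` | ring geometry, time model, energy window, primary discard, coincidences |
| `p2t.recon`     | sinogram rebinning, attenuation correction, FBP, SPB, TOF, fluence correction |
| `p2t.analysis`  | normalisation, contrast, Z-regression, cIVH |
| `p2t.simulate`  | the vectorised end-to-end acquisition pipeline |
| `p2t.experiments` | scaled phantom studies (Z-linearity, partial view, dose monitoring) |

See `docs/methods.md` for the model assumptions, calibration choices and
the limits of the desk-scale studies.
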