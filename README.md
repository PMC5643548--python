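# arpsim

Predictive modelling of gold-nanoparticle (GNP) radiosensitization for
kilovoltage photon therapy, at the level where the biology actually
happens: individual photoelectric absorptions in individual nanoparticles,
the Auger/photoelectron tracks they launch, and the heterogeneous
nanoscale dose they paint across the cell nucleus.

## The problem

High-Z nanoparticles boost photoelectric absorption of keV photons, but
reported radiosensitization varies wildly between experiments.  Macroscopic
absorbed dose cannot explain this: the effect depends on the interplay of
photon energy (below or above the 80.7 keV gold K edge), GNP size
(self-absorption of short-range Auger electrons), and sub-cellular
localization (whether those electrons can reach the DNA target).  This
package implements a predictive survival model for that interplay,
aimed at computational radiobiologists and medical physicists designing
GNP-enhanced irradiation strategies.

## The model

For a scenario (beam, GNP diameter, per-compartment gold concentration in
a spherical nucleus/cytoplasm/media cell), the pipeline:

1. builds the photon fluence spectrum at the cell (x-ray tube model +
   filtration + 4 mm culture medium);
2. samples photoelectric absorptions in a gold nanosphere — photon energy
   ∝ fluence × cross section, shell ∝ per-shell cross section — and emits
   the photoelectron plus the full Auger/fluorescence relaxation cascade;
3. transports each electron by straight-line CSDA through residual gold
   then water (50 eV cutoff), recording 3D energy-deposition events into
   a reusable track library with exact per-track energy bookkeeping;
4. replays Poisson-sampled absorptions from all gold-loaded compartments
   into a sparse map of 20 nm nucleus voxels, on top of the homogeneous
   photon background dose D;
5. converts local dose d to survival through a threshold-modified
   local-effect response and integrates over the nucleus volume:

       S = exp(−∫ v(D_local) dV)

       v(d) = (αd + βd²)/V_nuc                      d ≤ D_t
       v(d) = v(D_t) + S_max(d − D_t)/V_nuc         d > D_t,
       S_max = α + 2βD_t

   (PC-3 defaults α = 0.217 Gy⁻¹, β = 0.044 Gy⁻², D_t = 23.9 Gy).

Survival curves are averaged over independent Monte Carlo cell
realizations; the **mean inactivation dose** (MID) is the area under the
curve and the **sensitizer enhancement ratio** (SER) is
MID(no gold)/MID(gold).  See `docs/methods.md` for assumptions,
numerical choices and limitations.

## Worked example

```python
import numpy as np
from arpsim import (CompartmentLoading, GnpSpec, Scenario,
                    absorptions_per_gray, mid, preset_spectrum, ser,
                    survival_curve)

# deterministic: photoelectric absorptions in one 30 nm GNP per Gy
spec = preset_spectrum("gulmay_100kvp")          # at-cell spectrum
print(f"{absorptions_per_gray(GnpSpec(30.0), spec):.2e}")
# 9.02e-03        (vs 1.06e-03 for the 300 kVp preset: ~9x more)

# predictive: 1.9 nm GNPs at 2 mg/ml in media+cytoplasm+nucleus, 100 kVp
sc = Scenario(source="gulmay_100kvp", gnp_diameter_nm=1.9,
              loading=CompartmentLoading(media_mg_ml=2.0,
                                         cytoplasm_mg_ml=2.0,
                                         nucleus_mg_ml=2.0),
              n_tracks=10_000, n_repeats=30, seed=1)
res = survival_curve(sc)
ref = survival_curve(Scenario(loading=CompartmentLoading(), n_repeats=1))
print(np.round(res.surviving_fraction, 4))
# [1.     0.439  0.1791 0.066  0.0227 0.0068 0.002  0.0005 0.0001]
print(f"SER = {ser(mid(ref), mid(res)):.2f}")
# SER = 2.12
```

The survival curve falls far below the gold-free LQ curve (0.77, 0.54,
… at 1, 2 Gy): with a soft beam and full intracellular uptake the
short-range Auger electrons more than double the biological effect per
gray, while the same concentration confined to the media gives SER ≈ 1.2
and a 300 kVp beam flattens the localization dependence entirely.

A shell interface mirrors the library:

```bash
arpsim tracks --spectrum gulmay_100kvp --gnp-diameter 1.9 \
       --n-tracks 100000 --seed 42 -o lib.h5
arpsim run scenario.yaml -o out/        # survival.csv, metrics.json, manifest.json
arpsim fig2 -o grid/                    # the 2 beams x 2 sizes x 3 localizations grid
```

Every run writes a manifest (config, seed, output checksums); re-running
a manifest reproduces its outputs byte for byte.

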