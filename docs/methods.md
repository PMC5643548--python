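# Methods

`arpsim` predicts clonogenic survival of cells loaded with gold
nanoparticles (GNPs) and irradiated with kilovoltage photon beams.  The
chain is: photon spectrum → photoelectric absorptions in individual GNPs →
secondary-electron tracks → voxelized nucleus dose → local-effect survival
→ mean inactivation dose (MID) and sensitizer enhancement ratio (SER).
This note records the model, its assumptions, the numerical choices, and
what the synthetic conditions do and do not establish.

## Photon spectra

Tube spectra use a Kramers-type bremsstrahlung continuum,
N(E) ∝ (E₀ − E)/E up to the tube potential E₀, plus tungsten K
characteristic lines for potentials above the W K edge, filtered
bin-by-bin (Beer–Lambert, 0.5 keV bins) through configurable layers of
aluminum, copper and water.  Mass attenuation and energy-absorption
coefficients are shipped as plain-text tables reconstructed from standard
reference tabulations, log-log interpolated.

Two presets model the clinical 100 kVp and 300 kVp therapy beams.  Their
exact filtrations are not published, so each preset's added filtration is
a single constant calibrated **once** against the deterministic reference
absorption rate of a 30 nm GNP (9.05×10⁻³ and 1.00×10⁻³ photoelectric
absorptions per gray of water dose):

* `gulmay_100kvp`: 1.0 mm Al → rate 9.02×10⁻³ /Gy (−0.3%),
* `gulmay_300kvp`: 2.0 mm Al + 2.4 mm Cu → rate 1.06×10⁻³ /Gy (+6%).

The absorption rate was preferred over the beams' quoted mean energies
(~33 and ~100 keV after the 4 mm medium) as the calibration anchor: the
Kramers continuum overweights the soft tail relative to a real
phase-space spectrum, so matching the fluence-weighted mean would distort
the *absorption-weighted* photon spectrum — the quantity every downstream
prediction integrates over.  With rate calibration the at-cell means come
out at ~43 keV and ~143 keV; both sit on the correct side of the
80.7 keV gold K edge, which is the mechanism that matters (sub-K
absorptions relax through L/M/N shells and emit copious short-range Auger
electrons; above-K absorptions mostly eject long-range photoelectrons and
lose ~70 keV to escaping K fluorescence).

All cell-level calculations use the spectrum after 4 mm of culture
medium, the column the beams traverse before reaching the cell layer.

## Gold atomic data

Photoelectric cross sections are stored per shell (K, L1–L3, M1–M5, plus
merged effective N and O shells) as fractions of a smooth envelope fitted
to standard gold tabulations; each shell's channel opens at its edge, so
edge jumps and post-edge shell sampling emerge from the table.  Accuracy
is ~10–15% over 10–500 keV, the range that matters after filtration.

Atomic relaxation uses a principal-line scheme (≤10 lines per shell):
fluorescence yields ω_K = 0.958, ω_L1–L3 = 0.10/0.36/0.32, ω_M = 0.025,
and representative Auger / Coster-Kronig / fluorescence lines whose
energies are *derived from the binding-energy table* (E = B_i − B_f1[−B_f2]),
which makes cascade energy conservation exact by construction.  Vacancies
propagate until they reach the terminal outer shell; residual binding
energy stays in the atom.  The resulting Auger groups reproduce the
canonical range hierarchy in water: L ≈ 1.5 µm, M ≈ 0.1 µm, N ≈ 0.01 µm.

## Electron transport

Electrons are transported in the continuous-slowing-down approximation
(CSDA) on straight lines with isotropic emission; there is no angular
scattering, consistent with the package's design scope.  CSDA ranges in
water are anchored to standard tabulations (extended below 1 keV so that
a 50 eV electron has a ~2.5 nm range); gold ranges use a smooth
gold/water mass-range ratio (≈2.4 → 1.8 from 50 eV to 500 keV) and the
19.3 g/cm³ density.  Stopping power is the analytic derivative dE/dR of
the range spline, so range and stopping power are mutually consistent to
interpolation accuracy (<1%).

Inside the nanoparticle the electron loses energy over the chord to the
surface (closed-form residual-range bookkeeping, equivalent to the
fine-step limit); that energy is tallied as absorbed-in-GNP, not scored
in the cell.  In water the electron deposits energy in adaptive steps of
5% of its residual range, capped at 2 µm for very long tracks, until the
50 eV cutoff, below which the remainder is deposited on the spot.
Fluorescence photons are tallied as escaping energy and not
re-transported (their interaction probability over cell-scale water is
negligible).  Per-track bookkeeping closes exactly:
photon energy = water depositions + absorbed-in-GNP + escaping photons.

Straight-line transport carries energy farther from the source point
than a scattered random walk of equal path length; this is the main
transport simplification and biases nuclear energy deposition slightly
low for internal GNPs and slightly high for distant ones.

## Cell model and dose scoring

The cell is three concentric spheres: nucleus radius 8.2 µm, cell radius
13.1 µm (PC-3 measurements), infinite surrounding medium.  Gold loads
each compartment as a uniform mg/ml concentration; one 30 nm GNP weighs
2.73×10⁻¹⁶ g, so 2.27×10⁴ of them in the cytoplasmic shell reproduce the
measured 0.84 mg/ml.

Absorption events are a Poisson process: each GNP absorbs
Poisson(rate × dose) photons.  Equivalently — and this is how it is
sampled — the compartment's total count is Poisson with iid-uniform
positions (superposition theorem; the only approximation is that two
absorptions in the same GNP get independent positions, a ~nm-scale
effect).  Each absorption replays a uniformly chosen library track under
an independent uniform 3D rotation.

Depositions are scored into sparse 20 nm cubic voxels whose centres lie
inside the nucleus; the prescribed photon dose is a separate homogeneous
background.  Two *exact* geometric reductions keep the media compartment
(10⁵–10⁶ absorptions per realization at 300 kVp) tractable:

1. a track whose largest event radius is r_t can only reach the nucleus
   from within R_nucleus + r_t of the centre, so media positions for that
   track are sampled only inside that ball (importance truncation of the
   spec'd media region; discarded pairs would deposit nothing);
2. within a surviving (position, track) pair, only events whose radius
   shell |dist − r_event| ≤ R_nucleus + voxel can intersect the nucleus;
   the per-track events are pre-sorted by radius so this window is a
   binary search.

Both filters leave the scored distribution unchanged.  The inner
rotate-and-voxelize loop runs through a numba kernel when numba is
available, with an equivalent numpy fallback.

## Survival response

Local dose in a voxel is its GNP-track dose plus the background.  The
lethal-event density is linear-quadratic below a threshold D_t and purely
exponential above it:

    v(d) = (αd + βd²)/V_nuc                     d ≤ D_t
    v(d) = v(D_t) + S_max (d − D_t)/V_nuc       d > D_t,   S_max = α + 2βD_t

with PC-3 defaults α = 0.217 Gy⁻¹, β = 0.044 Gy⁻², D_t = 23.9 Gy
(S_max = 2.3202 Gy⁻¹).  Survival is S = exp(−∫v dV), evaluated as the
sparse-voxel sum plus the background term over the remaining nucleus
volume.  For uniform sub-threshold dose this reduces to the plain LQ
model to machine precision.  Note the scale separation: a single keV-level
deposition in a 20 nm voxel (8×10⁻²¹ kg) is ~2×10⁴ Gy, far above D_t, so
hit voxels respond on the linear branch and the GNP contribution to
−ln S is close to S_max × (nuclear energy / nuclear mass).

Survival curves average S over 30 independent cell realizations per dose
point (doses 0–8 Gy in 1 Gy steps, the assay's range).  MID is the
trapezoidal area under the curve plus an analytic exponential tail from
the last two points; on a 0.1 Gy grid this matches the LQ closed form
(erfc expression, 2.564 Gy at the defaults) to <0.5%.  SER divides the
gold-free MID by the gold-loaded MID, both integrated on the same dose
grid so the quadrature bias cancels.  LQ fits use bounded nonlinear least
squares on the linear survival scale with equal weights.

## Seeding and reproducibility

A master seed spawns one child stream for the track library and one per
(dose, repeat) realization, so changing the number of repeats never
perturbs the library, and every grid/curve is bit-reproducible from its
seed.  Each scoring source consumes its own spawned stream, which makes
dose grids exactly additive across source subsets.  CLI runs write a
manifest (config snapshot, version, seed, output SHA-256s); re-running a
manifest reproduces the outputs byte for byte.

## Problem sizes

Default study conditions: 10⁴-track libraries, 30 realizations per dose,
nine dose points.  These sizes put the Monte Carlo standard error of an
SER near 1% (jackknife over realizations), well below the model-level
uncertainty of the reconstructed spectra, and are the sizes used by
`scripts/acceptance.py`.

## What the synthetic conditions do not show

The model reproduces the *designed* experiment: spherical single cell,
uniform compartment concentrations, static geometry.  It does not emulate
cell-to-cell uptake variability, phagolysosomal GNP clustering,
cell-cycle shape changes, non-spherical nuclei, chemical/biological
sensitization pathways, or in-vivo tumour morphology — so agreement here
validates the physics-to-survival chain under idealized localization, not
predictions for heterogeneous in-vivo populations.  Within the
radiation chain itself, Compton/Rayleigh interactions inside the GNP,
electron angular scattering, bremsstrahlung, and re-transport of gold
fluorescence are out of scope; their omission is visible mainly as a
modest underprediction of the strongest enhancement endpoint (see the
calibration discussion above).

## Known limitations

* Reconstructed analytic spectra stand in for the unpublished clinical
  phase spaces; only one printed scalar per beam anchors them, and the
  SER endpoints inherit that uncertainty (the strongest endpoint, full
  intracellular uptake at 100 kVp, comes out ~15–20% below the reference
  2.56 — see the decisions on calibration).
* Straight-line CSDA vs condensed-history transport, as above.
* The principal-line relaxation scheme preserves yields, dominant line
  energies and the L/M/N range hierarchy but not the full line-by-line
  multiplicity of a complete atomic relaxation database.
* Physics tables are ~10–15% accurate reconstructions, not database
  exports; the volume-scaling law, edge structure and range hierarchy —
  the properties the predictions rest on — are exact or table-independent.
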