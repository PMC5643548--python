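"""Secondary-radiation track libraries for gold nanoparticles.

For one (photon spectrum, GNP diameter) pair this module samples
photoelectric absorptions inside the gold nanosphere, emits the
photoelectron plus the full Auger/fluorescence relaxation cascade, and
transports every electron on a straight line (continuous slowing down,
isotropic emission) first through the residual gold chord and then through
water, recording 3D energy-deposition events relative to the GNP centre.

Energy bookkeeping per absorbed photon is exact:

    photon energy = sum(water deposition events)
                  + energy absorbed in the GNP (gold slowing down,
                    sub-cutoff electrons, residual atomic binding)
                  + escaping fluorescence photon energy (tallied, not
                    re-transported)

The per-GNP photoelectric absorption rate per gray of water dose is the
deterministic spectral sum

    rate = N_atoms * sum_E w(E) sigma_PE(E) / sum_E w(E) E (muen/rho)_w(E)

which scales with the nanoparticle volume (diameter cubed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import physics_data as phys
from .physics_data import (
    GOLD_ATOMS_PER_CM3,
    GOLD_DENSITY_G_CM3,
    TRANSPORT_CUTOFF_KEV,
    electron_table,
    gold_cross_sections,
    gold_shells,
    sample_relaxation,
)
from .spectrum import PhotonSpectrum, dose_per_unit_fluence

__all__ = [
    "GnpSpec",
    "DepositionEvent",
    "SecondaryTrack",
    "TrackLibrary",
    "sample_absorption",
    "generate_track",
    "absorptions_per_gray",
    "build_library",
]

GNP_PRESET_DIAMETERS_NM = (1.9, 30.0, 100.0)

_RADIUS_KEY = 16.0e6  # nm; larger than any event radius, see radius_sorted


@dataclass(frozen=True)
class GnpSpec:
    """A spherical gold nanoparticle."""

    diameter_nm: float
    density_g_cm3: float = GOLD_DENSITY_G_CM3

    def __post_init__(self):
        if self.diameter_nm <= 0:
            raise ValueError("GNP diameter must be positive")

    @property
    def radius_nm(self) -> float:
        return self.diameter_nm / 2.0

    @property
    def volume_cm3(self) -> float:
        return np.pi / 6.0 * (self.diameter_nm * 1e-7) ** 3

    @property
    def mass_g(self) -> float:
        return self.volume_cm3 * self.density_g_cm3

    @property
    def n_atoms(self) -> float:
        return self.volume_cm3 * GOLD_ATOMS_PER_CM3 * (
            self.density_g_cm3 / GOLD_DENSITY_G_CM3
        )


@dataclass(frozen=True)
class DepositionEvent:
    """One energy deposition, offset in nm relative to the GNP centre."""

    offset_nm: np.ndarray
    energy_keV: float


@dataclass
class SecondaryTrack:
    """All depositions from one photoelectric absorption cascade."""

    offsets_nm: np.ndarray  # (n, 3)
    energies_keV: np.ndarray  # (n,)
    initiating_photon_energy_keV: float
    energy_absorbed_in_gnp_keV: float
    escaping_photon_energy_keV: float

    @property
    def events(self) -> list[DepositionEvent]:
        return [DepositionEvent(o, float(e))
                for o, e in zip(self.offsets_nm, self.energies_keV)]

    def energy_balance_error(self) -> float:
        """Relative energy-conservation error for this track."""
        tot = (float(self.energies_keV.sum())
               + self.energy_absorbed_in_gnp_keV
               + self.escaping_photon_energy_keV)
        return abs(tot - self.initiating_photon_energy_keV) / self.initiating_photon_energy_keV


# --------------------------------------------------------------------------
# Absorption sampling
# --------------------------------------------------------------------------

def _absorption_distributions(spectrum: PhotonSpectrum):
    """Per-bin absorption probability and per-bin shell probabilities."""
    xs = gold_cross_sections()
    e = spectrum.energy_bins
    sigma = np.asarray(xs.total(e))
    p_bin = spectrum.relative_fluence * sigma
    tot = p_bin.sum()
    if tot <= 0:
        raise ValueError("spectrum has zero photoelectric cross section in gold")
    p_bin = p_bin / tot
    shells = list(xs.per_shell)
    sig_shell = np.stack([np.asarray(xs.per_shell[s](e)) * (e >= xs.edges[s])
                          for s in shells], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_shell = sig_shell / sig_shell.sum(axis=1, keepdims=True)
    p_shell = np.nan_to_num(p_shell)
    return p_bin, shells, p_shell


def _uniform_points_in_sphere(radius_nm: float, n: int, rng) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius_nm * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def sample_absorption(gnp: GnpSpec, spectrum: PhotonSpectrum, rng):
    """Sample one photoelectric absorption in the nanoparticle.

    Returns ``(photon_energy_keV, interaction_point_nm, shell_id)``: the
    photon energy drawn with probability proportional to fluence times
    total photoelectric cross section, the interaction point uniform in the
    sphere, and the shell proportional to the per-shell cross section.
    """
    p_bin, shells, p_shell = _absorption_distributions(spectrum)
    i = rng.choice(len(p_bin), p=p_bin)
    e = float(spectrum.energy_bins[i])
    point = _uniform_points_in_sphere(gnp.radius_nm, 1, rng)[0]
    shell = shells[rng.choice(len(shells), p=p_shell[i])]
    return e, point, shell


# --------------------------------------------------------------------------
# Electron transport (straight-line CSDA)
# --------------------------------------------------------------------------

_WATER_STEP_FRACTION = 0.05   # adaptive step, <= 5% of residual range
_WATER_STEP_CAP_NM = 2000.0   # geometric step cap for long-range electrons


def _chord_to_surface(point_nm, direction, radius_nm) -> float:
    """Length of the ray from ``point`` (inside) to the sphere surface."""
    b = float(np.dot(point_nm, direction))
    c = float(np.dot(point_nm, point_nm)) - radius_nm**2
    return -b + np.sqrt(b * b - c)


def _transport_electron(energy_keV, start_nm, direction, gnp: GnpSpec):
    """CSDA transport through residual gold then water.

    Returns ``(offsets (n,3), deposits (n,), absorbed_in_gold_keV)``.
    Electrons below the 50 eV cutoff deposit on the spot.
    """
    if energy_keV < TRANSPORT_CUTOFF_KEV:
        return np.empty((0, 3)), np.empty(0), energy_keV
    gold = electron_table("gold")
    water = electron_table("water")
    chord = _chord_to_surface(start_nm, direction, gnp.radius_nm)
    r_gold = gold.csda_range(energy_keV)
    if r_gold <= chord:  # trapped in the nanoparticle
        return np.empty((0, 3)), np.empty(0), energy_keV
    e_exit = float(gold.energy_at_range(r_gold - chord))
    absorbed = energy_keV - e_exit
    if e_exit < TRANSPORT_CUTOFF_KEV:
        return np.empty((0, 3)), np.empty(0), energy_keV
    exit_point = start_nm + chord * direction

    r0 = water.csda_range(e_exit)
    r_cut = water.range_of_energy.value[0]  # residual range at the cutoff
    residuals = [r0]
    r = r0
    # arithmetic phase: fixed cap while 5% of residual exceeds the cap
    if r > _WATER_STEP_CAP_NM / _WATER_STEP_FRACTION:
        n_arith = int(np.ceil((r - _WATER_STEP_CAP_NM / _WATER_STEP_FRACTION)
                              / _WATER_STEP_CAP_NM))
        arith = r - _WATER_STEP_CAP_NM * np.arange(1, n_arith + 1)
        residuals.extend(arith.tolist())
        r = residuals[-1]
    # geometric phase: each step removes 5% of the residual range
    if r > r_cut:
        n_geo = int(np.ceil(np.log(r_cut / r) / np.log1p(-_WATER_STEP_FRACTION)))
        geo = r * (1.0 - _WATER_STEP_FRACTION) ** np.arange(1, n_geo + 1)
        residuals.extend(geo.tolist())
    residuals = np.array(residuals)
    residuals[-1] = min(residuals[-1], r_cut)
    energies = np.asarray(water.energy_at_range(residuals))
    energies[0] = e_exit
    deposits = -np.diff(energies, append=0.0)  # last: deposit rest locally
    s = r0 - residuals  # path length travelled at each step boundary
    s_mid = np.concatenate([(s[:-1] + s[1:]) / 2.0, s[-1:]])
    offsets = exit_point[None, :] + s_mid[:, None] * direction[None, :]
    keep = deposits > 0
    return offsets[keep], deposits[keep], absorbed


def _isotropic_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_track(photon_energy_keV, interaction_point_nm, shell_id,
                   gnp: GnpSpec, rng) -> SecondaryTrack:
    """Full secondary track for one absorption.

    The photoelectron carries ``photon_energy - binding``; relaxation
    electrons come from the sampled vacancy cascade.  Each electron is
    emitted isotropically and transported by straight-line CSDA through
    gold then water.  Fluorescence photons are tallied as escaping energy.
    """
    shells = gold_shells()
    binding = shells[shell_id].binding_energy_keV
    if photon_energy_keV <= binding:
        raise ValueError(
            f"photon energy {photon_energy_keV} keV below {shell_id} "
            f"binding energy {binding} keV"
        )
    particles, residual = sample_relaxation(shell_id, rng)
    electrons = [photon_energy_keV - binding]
    escaping_photons = 0.0
    for p in particles:
        if p.kind == "electron":
            electrons.append(p.energy_keV)
        else:
            escaping_photons += p.energy_keV
    absorbed = residual
    offs, deps = [], []
    point = np.asarray(interaction_point_nm, dtype=float)
    for e in electrons:
        o, d, a = _transport_electron(e, point, _isotropic_direction(rng), gnp)
        absorbed += a
        if len(d):
            offs.append(o)
            deps.append(d)
    offsets = np.concatenate(offs) if offs else np.empty((0, 3))
    deposits = np.concatenate(deps) if deps else np.empty(0)
    return SecondaryTrack(
        offsets_nm=offsets,
        energies_keV=deposits,
        initiating_photon_energy_keV=float(photon_energy_keV),
        energy_absorbed_in_gnp_keV=float(absorbed),
        escaping_photon_energy_keV=float(escaping_photons),
    )


# --------------------------------------------------------------------------
# Absorption rate and library
# --------------------------------------------------------------------------

def absorptions_per_gray(gnp: GnpSpec, spectrum: PhotonSpectrum) -> float:
    """Photoelectric absorptions in one GNP per gray of water dose."""
    xs = gold_cross_sections()
    sigma_cm2 = np.asarray(xs.total(spectrum.energy_bins)) * 1e-24
    mean_sigma = float(np.sum(spectrum.relative_fluence * sigma_cm2))
    return gnp.n_atoms * mean_sigma / dose_per_unit_fluence(spectrum)


@dataclass
class TrackLibrary:
    """Bank of secondary tracks for one (spectrum, GNP diameter) pair.

    Events are stored flat: ``offsets_nm[track_start[i]:track_start[i+1]]``
    are the events of track ``i``.  ``reach_nm[i]`` is the largest event
    distance from the GNP centre, used for exact media-compartment
    importance truncation.
    """

    gnp: GnpSpec
    spectrum_label: str
    offsets_nm: np.ndarray  # (M, 3) float32
    energies_keV: np.ndarray  # (M,) float64
    track_start: np.ndarray  # (n_tracks + 1,) int64
    initiating_energy_keV: np.ndarray  # (n_tracks,)
    absorbed_in_gnp_keV: np.ndarray  # (n_tracks,)
    escaping_photon_keV: np.ndarray  # (n_tracks,)
    absorptions_per_gray: float
    rng_seed: int | None = None
    reach_nm: np.ndarray = field(default=None)
    event_radius_nm: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.event_radius_nm is None:
            self.event_radius_nm = np.linalg.norm(
                self.offsets_nm.astype(np.float64), axis=1)
        if self.reach_nm is None:
            r = np.zeros(len(self), dtype=float)
            if len(self.offsets_nm):
                np.maximum.at(r, self.track_index, self.event_radius_nm)
            self.reach_nm = r

    def __len__(self) -> int:
        return len(self.track_start) - 1

    @property
    def track_index(self) -> np.ndarray:
        counts = np.diff(self.track_start)
        return np.repeat(np.arange(len(self)), counts)

    def track(self, i: int) -> SecondaryTrack:
        a, b = self.track_start[i], self.track_start[i + 1]
        return SecondaryTrack(
            offsets_nm=self.offsets_nm[a:b].astype(float),
            energies_keV=self.energies_keV[a:b],
            initiating_photon_energy_keV=float(self.initiating_energy_keV[i]),
            energy_absorbed_in_gnp_keV=float(self.absorbed_in_gnp_keV[i]),
            escaping_photon_energy_keV=float(self.escaping_photon_keV[i]),
        )

    @property
    def tracks(self) -> list[SecondaryTrack]:
        return [self.track(i) for i in range(len(self))]

    @property
    def max_reach_nm(self) -> float:
        return float(self.reach_nm.max()) if len(self) else 0.0

    def radius_sorted(self):
        """Events sorted by (track, radius) for radius-window queries.

        Returns ``(offsets, energies, key)`` where ``key = track_id * KEY +
        radius_nm`` is globally ascending, so a single ``searchsorted``
        yields, for every (track, radius interval) query, the slice of that
        track's events inside the interval.
        """
        if not hasattr(self, "_radius_sorted"):
            idx = self.track_index
            order = np.lexsort((self.event_radius_nm, idx))
            key = idx[order] * _RADIUS_KEY + self.event_radius_nm[order]
            self._radius_sorted = (
                np.ascontiguousarray(self.offsets_nm[order].astype(np.float64)),
                np.ascontiguousarray(self.energies_keV[order]),
                key,
            )
        return self._radius_sorted

    def mean_escaped_energy_fraction(self) -> float:
        """Mean fraction of absorbed photon energy leaving as electrons."""
        return float(np.mean(
            1.0 - (self.absorbed_in_gnp_keV + self.escaping_photon_keV)
            / self.initiating_energy_keV
        ))

    def self_absorbed_fraction(self) -> float:
        """Fraction of cascade electron energy absorbed inside the GNP.

        Electron energy = photon energy minus escaping fluorescence; the
        residual atomic binding is part of the absorbed tally.
        """
        electron_energy = self.initiating_energy_keV - self.escaping_photon_keV
        return float(self.absorbed_in_gnp_keV.sum() / electron_energy.sum())

    # -- persistence --------------------------------------------------------
    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            meta = f.create_group("meta")
            meta.attrs["gnp_diameter_nm"] = self.gnp.diameter_nm
            meta.attrs["gnp_density_g_cm3"] = self.gnp.density_g_cm3
            meta.attrs["spectrum_label"] = self.spectrum_label
            meta.attrs["absorptions_per_gray"] = self.absorptions_per_gray
            meta.attrs["rng_seed"] = -1 if self.rng_seed is None else self.rng_seed
            tr = f.create_group("tracks")
            tr.create_dataset("offsets", data=self.offsets_nm)
            tr.create_dataset("energies", data=self.energies_keV)
            tr.create_dataset("track_index", data=self.track_index)
            tr.create_dataset("track_start", data=self.track_start)
            tr.create_dataset("initiating_energy", data=self.initiating_energy_keV)
            tr.create_dataset("absorbed_in_gnp", data=self.absorbed_in_gnp_keV)
            tr.create_dataset("escaping_photon", data=self.escaping_photon_keV)

    @classmethod
    def from_hdf5(cls, path) -> "TrackLibrary":
        import h5py

        with h5py.File(path, "r") as f:
            meta = f["meta"].attrs
            seed = int(meta["rng_seed"])
            return cls(
                gnp=GnpSpec(float(meta["gnp_diameter_nm"]),
                            float(meta["gnp_density_g_cm3"])),
                spectrum_label=str(meta["spectrum_label"]),
                offsets_nm=f["tracks/offsets"][...],
                energies_keV=f["tracks/energies"][...],
                track_start=f["tracks/track_start"][...],
                initiating_energy_keV=f["tracks/initiating_energy"][...],
                absorbed_in_gnp_keV=f["tracks/absorbed_in_gnp"][...],
                escaping_photon_keV=f["tracks/escaping_photon"][...],
                absorptions_per_gray=float(meta["absorptions_per_gray"]),
                rng_seed=None if seed < 0 else seed,
            )


def build_library(gnp: GnpSpec, spectrum: PhotonSpectrum, n_tracks: int,
                  seed=None) -> TrackLibrary:
    """Monte Carlo bank of ``n_tracks`` absorption cascades (reproducible)."""
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    p_bin, shells, p_shell = _absorption_distributions(spectrum)
    bins = rng.choice(len(p_bin), size=n_tracks, p=p_bin)
    points = _uniform_points_in_sphere(gnp.radius_nm, n_tracks, rng)
    u = rng.random(n_tracks)
    shell_idx = (np.cumsum(p_shell[bins], axis=1) < u[:, None]).sum(axis=1)
    shell_idx = np.minimum(shell_idx, len(shells) - 1)

    offsets, energies, counts = [], [], np.zeros(n_tracks, dtype=np.int64)
    initiating = np.empty(n_tracks)
    absorbed = np.empty(n_tracks)
    escaping = np.empty(n_tracks)
    for i in range(n_tracks):
        tr = generate_track(float(spectrum.energy_bins[bins[i]]), points[i],
                            shells[shell_idx[i]], gnp, rng)
        offsets.append(tr.offsets_nm.astype(np.float32))
        energies.append(tr.energies_keV)
        counts[i] = len(tr.energies_keV)
        initiating[i] = tr.initiating_photon_energy_keV
        absorbed[i] = tr.energy_absorbed_in_gnp_keV
        escaping[i] = tr.escaping_photon_energy_keV
    track_start = np.concatenate([[0], np.cumsum(counts)])
    return TrackLibrary(
        gnp=gnp,
        spectrum_label=spectrum.label,
        offsets_nm=np.concatenate(offsets) if offsets else np.empty((0, 3), np.float32),
        energies_keV=np.concatenate(energies) if energies else np.empty(0),
        track_start=track_start,
        initiating_energy_keV=initiating,
        absorbed_in_gnp_keV=absorbed,
        escaping_photon_keV=escaping,
        absorptions_per_gray=absorptions_per_gray(gnp, spectrum),
        rng_seed=_seed_as_int(seed),
    )


def _seed_as_int(seed):
    if seed is None:
        return None
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    entropy = getattr(seed, "entropy", None)  # SeedSequence
    return int(entropy) if isinstance(entropy, (int, np.integer)) else None
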