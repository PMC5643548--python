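"""Photon fluence spectra for kilovoltage therapy beams.

Tube spectra are built from a Kramers-type bremsstrahlung continuum with
tungsten K characteristic lines, filtered through configurable layers
(Beer-Lambert per energy bin) of aluminum, copper and/or water.  The two
preset beams (``gulmay_100kvp``, ``gulmay_300kvp``) model the 100 kVp and
300 kVp x-ray therapy beams used for the cell irradiations: their added
filtrations are fixed constants calibrated once so that the deterministic
per-GNP photoelectric absorption rates of a 30 nm nanoparticle match the
reference values (9.05e-3 / 1.00e-3 per gray); after transport through the
4 mm of culture medium covering the cells the mean photon energies sit
below and above the 80.7 keV gold K edge respectively.

Spectra are discrete (0.5 keV bins), normalised to unit total fluence
weight, and carry no absolute fluence: absolute scaling enters through
:func:`dose_per_unit_fluence` (water kerma per unit fluence).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .physics_data import MATERIAL_DENSITY_G_CM3, photon_mu_rho, water_muen_rho

__all__ = [
    "PhotonSpectrum",
    "build_tube_spectrum",
    "monoenergetic",
    "attenuate",
    "dose_per_unit_fluence",
    "mean_energy",
    "preset_spectrum",
    "PRESETS",
    "KEV_TO_JOULE",
]

BIN_WIDTH_KEV = 0.5  # resolves the 80.7 keV K edge sharply
KEV_TO_JOULE = 1.602176634e-16

# Tungsten K lines (energy keV, relative strength within the K group)
_W_K_LINES = [(59.32, 0.50), (57.98, 0.29), (67.24, 0.15), (69.07, 0.06)]
_W_K_EDGE = 69.525
# Fraction of generated fluence carried by the K-line group at high overvoltage
_W_K_FRACTION = 0.08


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon fluence spectrum (bin centres, normalised weights)."""

    energy_bins: np.ndarray  # keV, ascending bin centres
    relative_fluence: np.ndarray  # nonnegative, sums to 1
    label: str = ""

    def __post_init__(self):
        e = np.asarray(self.energy_bins, dtype=float)
        w = np.asarray(self.relative_fluence, dtype=float)
        if e.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy bins must be strictly ascending")
        if np.any(w < 0):
            raise ValueError("negative fluence weight")
        tot = w.sum()
        if tot <= 0:
            raise ValueError("spectrum has zero total fluence")
        object.__setattr__(self, "energy_bins", e)
        object.__setattr__(self, "relative_fluence", w / tot)

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energy_bins * self.relative_fluence))

    def to_csv(self, path):
        pd.DataFrame(
            {"energy_keV": self.energy_bins, "relative_fluence": self.relative_fluence}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label=""):
        df = pd.read_csv(path, comment="#")
        return cls(df["energy_keV"].to_numpy(), df["relative_fluence"].to_numpy(),
                   label or str(path))


def monoenergetic(energy_keV: float, label: str | None = None) -> PhotonSpectrum:
    """Single-line spectrum (e.g. seed or synchrotron source)."""
    return PhotonSpectrum(np.array([float(energy_keV)]), np.array([1.0]),
                          label or f"mono_{energy_keV:g}keV")


def build_tube_spectrum(kvp: float, filtration: dict | None = None,
                        label: str | None = None) -> PhotonSpectrum:
    """Kramers continuum + W K lines for a tube at ``kvp``, then filtration.

    ``filtration`` maps material name -> thickness in mm, e.g.
    ``{"aluminum": 2.0}``.  Thicknesses must be nonnegative.
    """
    if not (40.0 <= kvp <= 320.0):
        raise ValueError(f"kvp {kvp} outside supported range [40, 320]")
    filtration = dict(filtration or {})
    for m, t in filtration.items():
        if t < 0:
            raise ValueError(f"negative filtration thickness for {m}: {t} mm")
    e = np.arange(BIN_WIDTH_KEV, kvp + BIN_WIDTH_KEV / 2, BIN_WIDTH_KEV)
    e = e[(e >= 1.0) & (e < kvp)]
    w = (kvp - e) / e  # Kramers photon-number continuum
    if kvp > _W_K_EDGE:
        # characteristic K lines, strength growing with overvoltage
        frac = _W_K_FRACTION * min(1.0, ((kvp / _W_K_EDGE) - 1.0) / 2.0)
        cont = w.sum()
        for el, rel in _W_K_LINES:
            i = np.argmin(np.abs(e - el))
            w[i] += frac / (1 - frac) * cont * rel
    s = PhotonSpectrum(e, w, label or f"tube_{kvp:g}kvp")
    for material, thickness in filtration.items():
        s = attenuate(s, material, thickness)
    return replace(s, label=label or f"tube_{kvp:g}kvp")


def attenuate(spectrum: PhotonSpectrum, material: str = "water",
              thickness_mm: float = 0.0) -> PhotonSpectrum:
    """Beer-Lambert filtration through ``thickness_mm`` of ``material``.

    Weights are renormalised afterwards; for water below 300 keV this
    hardens the beam (mean energy does not decrease).
    """
    if thickness_mm < 0:
        raise ValueError(f"negative thickness: {thickness_mm} mm")
    if thickness_mm == 0:
        return spectrum
    mu = photon_mu_rho(material)(spectrum.energy_bins)  # cm^2/g
    rho = MATERIAL_DENSITY_G_CM3[material]
    w = spectrum.relative_fluence * np.exp(-mu * rho * thickness_mm * 0.1)
    return PhotonSpectrum(spectrum.energy_bins, w, spectrum.label)


def dose_per_unit_fluence(spectrum: PhotonSpectrum) -> float:
    """Water kerma per unit photon fluence, Gy*cm^2.

    ``sum_i w_i * E_i * (muen/rho)_water(E_i)`` with E in joule and muen/rho
    in cm^2/kg, so that ``fluence[1/cm^2] = D[Gy] / dose_per_unit_fluence``.
    """
    muen = water_muen_rho()(spectrum.energy_bins)  # cm^2/g
    return float(np.sum(spectrum.relative_fluence * spectrum.energy_bins
                        * KEV_TO_JOULE * muen * 1e3))


def mean_energy(spectrum: PhotonSpectrum) -> float:
    return spectrum.mean_energy


# --------------------------------------------------------------------------
# Beam presets.  Added filtration values are fixed constants, calibrated
# once against the reference per-GNP photoelectric absorption rates of a
# 30 nm nanoparticle (9.05e-3 and 1.00e-3 per Gy); the resulting at-cell
# mean energies (~43 keV and ~143 keV) sit below / above the gold K edge.
# --------------------------------------------------------------------------
MEDIA_DEPTH_MM = 4.0  # culture-medium column above the cells

PRESETS = {
    # Lightly filtered beam, mean below the K edge; the aluminum thickness
    # is calibrated to the reference 30 nm GNP absorption rate.
    "gulmay_100kvp": {"kvp": 100.0, "filtration": {"aluminum": 1.0}},
    # Heavily filtered beam: mean well above the K edge; the copper
    # thickness is calibrated to the reference 300 kVp absorption rate.
    "gulmay_300kvp": {"kvp": 300.0, "filtration": {"aluminum": 2.0, "copper": 2.4}},
}


def preset_spectrum(name: str, at_cell: bool = True) -> PhotonSpectrum:
    """A named beam preset; ``at_cell`` applies the 4 mm media attenuation.

    Monoenergetic presets are accepted as ``mono_<energy>keV``.
    """
    if name.startswith("mono_") and name.endswith("keV"):
        s = monoenergetic(float(name[5:-3]), label=name)
        return s
    if name not in PRESETS:
        raise KeyError(
            f"unknown source preset {name!r}; available: "
            f"{sorted(PRESETS)} or 'mono_<E>keV'"
        )
    p = PRESETS[name]
    s = build_tube_spectrum(p["kvp"], p["filtration"], label=name)
    if at_cell:
        s = attenuate(s, "water", MEDIA_DEPTH_MM)
    return s
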