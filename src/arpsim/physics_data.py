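"""Embedded atomic and electron-transport data for gold and water.

This module loads the plain-text tables shipped under ``arpsim/data`` and
exposes:

* gold photoelectric cross sections, total and per shell, with absorption
  edges (K edge at 80.7 keV),
* water mass attenuation / mass energy-absorption coefficients and
  aluminum / copper mass attenuation for beam filtration,
* electron collision stopping power and CSDA range in water and gold,
* gold shell structure (binding energies, fluorescence yields) and a
  principal-line atomic relaxation model used to sample full Auger /
  fluorescence vacancy cascades.

Cross sections interpolate log-log linearly between grid points; per-shell
values are exactly zero below the shell's own edge.  Electron transport uses
a 50 eV cutoff below which the residual energy is deposited on the spot.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "TRANSPORT_CUTOFF_KEV",
    "GOLD_DENSITY_G_CM3",
    "GOLD_ATOMS_PER_CM3",
    "ShellData",
    "CrossSectionTable",
    "ElectronTransportTable",
    "gold_shells",
    "gold_cross_sections",
    "electron_table",
    "photoelectric_cross_section",
    "sample_relaxation",
    "csda_range",
    "EmittedParticle",
]

TRANSPORT_CUTOFF_KEV = 0.05  # electrons below 50 eV deposit locally
GOLD_DENSITY_G_CM3 = 19.3
GOLD_MOLAR_MASS = 196.96657  # g/mol
AVOGADRO = 6.02214076e23
GOLD_ATOMS_PER_CM3 = GOLD_DENSITY_G_CM3 / GOLD_MOLAR_MASS * AVOGADRO

_SHELL_ORDER = ["K", "L1", "L2", "L3", "M1", "M2", "M3", "M4", "M5", "N", "O"]


def _read_table(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("arpsim") / "data" / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


class _LogLogInterp:
    """Log-log linear interpolation on a strictly ascending energy grid."""

    def __init__(self, energy: np.ndarray, value: np.ndarray):
        if np.any(np.diff(energy) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        self.energy = np.asarray(energy, dtype=float)
        self.value = np.asarray(value, dtype=float)
        self._loge = np.log(self.energy)
        with np.errstate(divide="ignore"):
            self._logv = np.log(np.maximum(self.value, 1e-300))

    def __call__(self, e):
        e = np.asarray(e, dtype=float)
        out = np.exp(np.interp(np.log(np.maximum(e, 1e-300)), self._loge, self._logv))
        # a zero table entry (e.g. below an absorption edge) is not a point to
        # interpolate through: zero the bracketing interval exactly
        n = len(self.energy)
        right = np.clip(np.searchsorted(self.energy, e, side="left"), 0, n - 1)
        left = np.clip(right - 1, 0, n - 1)
        zero = (self.value[right] == 0.0) | (
            (self.value[left] == 0.0) & (e != self.energy[right])
        )
        out = np.where(zero, 0.0, out)
        return out if out.ndim else float(out)

    @property
    def emin(self):
        return self.energy[0]

    @property
    def emax(self):
        return self.energy[-1]


@dataclass(frozen=True)
class EmittedParticle:
    """One particle released during atomic relaxation."""

    kind: str  # "electron" | "photon"
    energy_keV: float


@dataclass
class ShellData:
    """Binding energy, fluorescence yield and principal relaxation lines."""

    shell_id: str
    binding_energy_keV: float
    fluorescence_yield: float
    # (energy_keV, probability, final vacancies)
    auger_lines: list = field(default_factory=list)
    fluor_lines: list = field(default_factory=list)


@lru_cache(maxsize=1)
def gold_shells() -> dict:
    """Load the gold shell structure with derived relaxation-line energies."""
    shells_df = _read_table("gold_shells.csv")
    lines_df = _read_table("gold_relaxation.csv").fillna("")
    binding = dict(zip(shells_df["shell"], shells_df["binding_keV"]))
    shells = {
        row.shell: ShellData(row.shell, float(row.binding_keV), float(row.fluorescence_yield))
        for row in shells_df.itertuples()
    }
    for row in lines_df.itertuples():
        b0 = binding[row.initial]
        if row.mode == "fluor":
            e = b0 - binding[row.final1]
            shells[row.initial].fluor_lines.append((e, float(row.prob), (row.final1,)))
        else:
            e = b0 - binding[row.final1] - binding[row.final2]
            shells[row.initial].auger_lines.append((e, float(row.prob), (row.final1, row.final2)))
    # normalise conditional branch probabilities
    for sh in shells.values():
        for attr in ("auger_lines", "fluor_lines"):
            lines = getattr(sh, attr)
            tot = sum(p for _, p, _ in lines)
            if tot > 0:
                setattr(sh, attr, [(e, p / tot, f) for e, p, f in lines])
    return shells


@dataclass
class CrossSectionTable:
    """Gold photoelectric cross sections (barn/atom) and water muen/rho."""

    energy_grid: np.ndarray
    total: _LogLogInterp
    per_shell: dict
    edges: dict

    def __call__(self, energy, shell=None):
        return photoelectric_cross_section(energy, shell, table=self)


@lru_cache(maxsize=1)
def gold_cross_sections() -> CrossSectionTable:
    df = _read_table("gold_photoelectric.csv")
    e = df["energy_keV"].to_numpy()
    shells = gold_shells()
    per_shell = {}
    for s in _SHELL_ORDER:
        per_shell[s] = _LogLogInterp(e, df[f"sigma_{s}"].to_numpy())
    return CrossSectionTable(
        energy_grid=e,
        total=_LogLogInterp(e, df["total"].to_numpy()),
        per_shell=per_shell,
        edges={s: shells[s].binding_energy_keV for s in _SHELL_ORDER},
    )


def photoelectric_cross_section(energy_keV, shell: str | None = None, table=None) -> float:
    """Gold photoelectric cross section in barn/atom.

    ``shell=None`` returns the total; a shell id returns that shell's
    partial cross section, which is exactly 0 below the shell edge.
    """
    table = table or gold_cross_sections()
    e = float(energy_keV)
    if not (table.energy_grid[0] <= e <= table.energy_grid[-1]):
        raise ValueError(
            f"energy {e} keV outside tabulated range "
            f"[{table.energy_grid[0]}, {table.energy_grid[-1]}] keV"
        )
    if shell is None:
        return float(table.total(e))
    if shell not in table.per_shell:
        raise KeyError(f"unknown shell {shell!r}; known: {sorted(table.per_shell)}")
    if e < table.edges[shell]:
        return 0.0
    return float(table.per_shell[shell](e))


# --------------------------------------------------------------------------
# Atomic relaxation
# --------------------------------------------------------------------------

def sample_relaxation(shell_id: str, rng: np.random.Generator):
    """Sample a full vacancy cascade starting from ``shell_id``.

    Vacancies propagate (radiatively or via Auger / Coster-Kronig emission)
    until every vacancy sits in the terminal outermost shell.  Returns
    ``(particles, residual_keV)`` where ``particles`` is a list of
    :class:`EmittedParticle` and ``residual_keV`` is the binding energy left
    in the atom (terminal-shell vacancies).  Energy is conserved exactly:
    ``sum(emitted) + residual == binding_energy(shell_id)``.
    """
    shells = gold_shells()
    if shell_id not in shells:
        raise KeyError(f"unknown shell {shell_id!r}")
    particles: list[EmittedParticle] = []
    residual = 0.0
    stack = [shell_id]
    while stack:
        sid = stack.pop()
        sh = shells[sid]
        if not sh.auger_lines and not sh.fluor_lines:  # terminal shell
            residual += sh.binding_energy_keV
            continue
        radiative = sh.fluor_lines and rng.random() < sh.fluorescence_yield
        lines = sh.fluor_lines if radiative else sh.auger_lines
        probs = np.array([p for _, p, _ in lines])
        i = rng.choice(len(lines), p=probs)
        e, _, finals = lines[i]
        particles.append(EmittedParticle("photon" if radiative else "electron", e))
        stack.extend(finals)
    return particles, residual


# --------------------------------------------------------------------------
# Electron transport tables
# --------------------------------------------------------------------------

@dataclass
class ElectronTransportTable:
    """Collision stopping power (keV/nm) and CSDA range (nm) in one medium."""

    medium: str
    energy_grid: np.ndarray
    stopping_power: _LogLogInterp
    range_of_energy: _LogLogInterp
    energy_of_range: _LogLogInterp

    def csda_range(self, energy_keV) -> float:
        """CSDA range in nm; 0 below the 50 eV transport cutoff."""
        e = float(energy_keV)
        if e < TRANSPORT_CUTOFF_KEV:
            return 0.0
        if e > self.energy_grid[-1]:
            raise ValueError(f"energy {e} keV above tabulated maximum")
        return float(self.range_of_energy(e))

    def energy_at_range(self, r_nm):
        """Inverse range-energy relation (vectorised), clipped to the grid."""
        r = np.clip(np.asarray(r_nm, dtype=float), self.range_of_energy.value[0],
                    self.range_of_energy.value[-1])
        return self.energy_of_range(r)


@lru_cache(maxsize=None)
def electron_table(medium: str) -> ElectronTransportTable:
    if medium not in ("water", "gold"):
        raise KeyError(f"unknown medium {medium!r} (water|gold)")
    df = _read_table(f"electron_{medium}.csv")
    e = df["energy_keV"].to_numpy()
    sp = df["stopping_keV_per_nm"].to_numpy()
    r = df["csda_range_nm"].to_numpy()
    return ElectronTransportTable(
        medium=medium,
        energy_grid=e,
        stopping_power=_LogLogInterp(e, sp),
        range_of_energy=_LogLogInterp(e, r),
        energy_of_range=_LogLogInterp(r, e),
    )


def csda_range(energy_keV, medium: str = "water") -> float:
    """Electron CSDA range in nm (50 eV cutoff: returns 0 below it)."""
    return electron_table(medium).csda_range(energy_keV)


# --------------------------------------------------------------------------
# Photon attenuation / energy absorption
# --------------------------------------------------------------------------

@lru_cache(maxsize=None)
def photon_mu_rho(material: str) -> _LogLogInterp:
    """Photon mass attenuation coefficient mu/rho in cm^2/g."""
    names = {"water": "photon_water.csv", "aluminum": "photon_aluminum.csv",
             "al": "photon_aluminum.csv", "copper": "photon_copper.csv",
             "cu": "photon_copper.csv"}
    if material not in names:
        raise KeyError(f"unknown filter material {material!r}; known: water, aluminum, copper")
    df = _read_table(names[material])
    return _LogLogInterp(df["energy_keV"].to_numpy(), df["mu_rho"].to_numpy())


@lru_cache(maxsize=1)
def water_muen_rho() -> _LogLogInterp:
    """Water mass energy-absorption coefficient muen/rho in cm^2/g."""
    df = _read_table("photon_water.csv")
    return _LogLogInterp(df["energy_keV"].to_numpy(), df["muen_rho"].to_numpy())


MATERIAL_DENSITY_G_CM3 = {"water": 1.0, "aluminum": 2.699, "al": 2.699,
                          "copper": 8.96, "cu": 8.96}
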