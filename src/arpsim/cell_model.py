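"""Three-compartment spherical cell model and nucleus dose scoring.

The cell is modelled as concentric spheres: a radiosensitive nucleus
(default radius 8.2 um), a cytoplasm shell (default outer radius 13.1 um)
and the surrounding culture medium.  Gold is loaded per compartment as a
mg/ml concentration; photoelectric absorption events are sampled as a
Poisson process over the gold-loaded volume and secondary tracks from a
:class:`~arpsim.gnp_source.TrackLibrary` are replayed at the sampled
locations with independent uniform 3D rotations.

Energy depositions falling inside the nucleus are scored in a sparse grid
of 20 nm cubic voxels; the prescribed photon (background) dose is stored
separately and applies homogeneously to the whole nucleus.

The media compartment is importance-truncated exactly: a track whose
largest event radius is ``r_t`` can only deposit in the nucleus when its
GNP lies within ``nucleus_radius + r_t`` of the cell centre, so positions
for that track are sampled only inside that ball.  Discarded pairs would
deposit nothing, leaving the scored dose distribution unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gnp_source import _RADIUS_KEY, GnpSpec, TrackLibrary

__all__ = [
    "VOXEL_SIZE_NM",
    "CellGeometry",
    "CompartmentLoading",
    "NucleusDoseGrid",
    "CompartmentSource",
    "ExplicitSource",
    "gnp_count",
    "concentration_from_count",
    "sample_positions",
    "score_dose",
]

VOXEL_SIZE_NM = 20.0
VOXEL_VOLUME_UM3 = (VOXEL_SIZE_NM * 1e-3) ** 3
VOXEL_MASS_KG = (VOXEL_SIZE_NM * 1e-9) ** 3 * 1000.0  # water density
KEV_TO_JOULE = 1.602176634e-16
KEV_TO_GY_PER_VOXEL = KEV_TO_JOULE / VOXEL_MASS_KG

_KEY_BITS = 11
_KEY_OFF = 1 << (_KEY_BITS - 1)  # voxel indices within +/-1023


@dataclass(frozen=True)
class CellGeometry:
    """Concentric nucleus / cell spheres centred at the origin (um)."""

    nucleus_radius_um: float = 8.2
    cell_radius_um: float = 13.1

    def __post_init__(self):
        if not (0 < self.nucleus_radius_um < self.cell_radius_um):
            raise ValueError("need 0 < nucleus radius < cell radius")

    @property
    def nucleus_volume_um3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.nucleus_radius_um**3

    @property
    def cytoplasm_volume_um3(self) -> float:
        return 4.0 / 3.0 * np.pi * (self.cell_radius_um**3 - self.nucleus_radius_um**3)


@dataclass(frozen=True)
class CompartmentLoading:
    """Gold concentration per compartment, mg/ml."""

    media_mg_ml: float = 0.0
    cytoplasm_mg_ml: float = 0.0
    nucleus_mg_ml: float = 0.0

    def __post_init__(self):
        for name in ("media_mg_ml", "cytoplasm_mg_ml", "nucleus_mg_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration: {name}")

    def concentration(self, compartment: str) -> float:
        return {"media": self.media_mg_ml, "cytoplasm": self.cytoplasm_mg_ml,
                "nucleus": self.nucleus_mg_ml}[compartment]


def gnp_count(concentration_mg_ml: float, volume_um3: float, gnp: GnpSpec) -> float:
    """Expected number of GNPs carrying the given concentration in a volume."""
    if concentration_mg_ml < 0 or volume_um3 < 0:
        raise ValueError("concentration and volume must be nonnegative")
    mass_g = concentration_mg_ml * 1e-3 * volume_um3 * 1e-12  # g
    return mass_g / gnp.mass_g


def concentration_from_count(count: float, volume_um3: float, gnp: GnpSpec) -> float:
    """Inverse of :func:`gnp_count`: concentration in mg/ml."""
    return count * gnp.mass_g / (volume_um3 * 1e-12) * 1e3


# --------------------------------------------------------------------------
# Position sampling
# --------------------------------------------------------------------------

def _uniform_shell(r_inner_um, r_outer_um, n, rng) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.random(n)
    r = (r_inner_um**3 + u * (r_outer_um**3 - r_inner_um**3)) ** (1.0 / 3.0)
    return v * r[:, None]


def sample_positions(compartment: str, count, geometry: CellGeometry,
                     loading: CompartmentLoading | None = None, rng=None,
                     media_truncation_radius_um: float | None = None) -> np.ndarray:
    """Uniform GNP positions (um) in a compartment.

    ``count`` may be fractional for the media compartment, in which case the
    actual number is Poisson-distributed about ``count``.
    """
    rng = np.random.default_rng(rng)
    if compartment == "nucleus":
        return _uniform_shell(0.0, geometry.nucleus_radius_um, int(round(count)), rng)
    if compartment == "cytoplasm":
        return _uniform_shell(geometry.nucleus_radius_um, geometry.cell_radius_um,
                              int(round(count)), rng)
    if compartment == "media":
        outer = media_truncation_radius_um or geometry.cell_radius_um * 3
        n = rng.poisson(count)  # counting statistics about density * volume
        return _uniform_shell(geometry.cell_radius_um, outer, n, rng)
    raise KeyError(f"unknown compartment {compartment!r} (nucleus|cytoplasm|media)")


# --------------------------------------------------------------------------
# Sparse nucleus dose grid
# --------------------------------------------------------------------------

@dataclass
class NucleusDoseGrid:
    """Sparse 20 nm voxel map of local GNP dose plus uniform background.

    Only voxels whose centres lie inside the nucleus sphere are stored.
    ``voxel_keys`` encodes (i, j, k) indices; ``voxel_doses`` is in Gy.
    """

    nucleus_radius_um: float
    background_dose_gy: float = 0.0
    voxel_keys: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    voxel_doses: np.ndarray = field(default_factory=lambda: np.empty(0))
    voxel_size_nm: float = VOXEL_SIZE_NM

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_keys)

    @property
    def nucleus_volume_um3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.nucleus_radius_um**3

    @property
    def total_energy_keV(self) -> float:
        return float(self.voxel_doses.sum() / KEV_TO_GY_PER_VOXEL)

    def voxel_indices(self) -> np.ndarray:
        """Decode keys to an (n, 3) integer index array."""
        k = self.voxel_keys
        mask = (1 << _KEY_BITS) - 1
        out = np.stack([(k >> (2 * _KEY_BITS)) & mask, (k >> _KEY_BITS) & mask,
                        k & mask], axis=1).astype(np.int64)
        return out - _KEY_OFF

    def add(self, other: "NucleusDoseGrid") -> "NucleusDoseGrid":
        """Voxel-wise sum of two grids over the same nucleus."""
        if other.nucleus_radius_um != self.nucleus_radius_um:
            raise ValueError("grids have different nucleus radii")
        keys = np.concatenate([self.voxel_keys, other.voxel_keys])
        doses = np.concatenate([self.voxel_doses, other.voxel_doses])
        uk, inv = np.unique(keys, return_inverse=True)
        return NucleusDoseGrid(
            nucleus_radius_um=self.nucleus_radius_um,
            background_dose_gy=self.background_dose_gy + other.background_dose_gy,
            voxel_keys=uk,
            voxel_doses=np.bincount(inv, weights=doses, minlength=len(uk)),
        )

    # -- persistence --------------------------------------------------------
    def to_hdf5(self, path):
        import h5py

        ijk = self.voxel_indices()
        with h5py.File(path, "w") as f:
            data = np.column_stack([ijk.astype(float), self.voxel_doses])
            f.create_dataset("voxels", data=data)
            meta = f.create_group("meta")
            meta.attrs["background_dose_gy"] = self.background_dose_gy
            meta.attrs["nucleus_radius_um"] = self.nucleus_radius_um
            meta.attrs["voxel_size_nm"] = self.voxel_size_nm

    @classmethod
    def from_hdf5(cls, path) -> "NucleusDoseGrid":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["voxels"][...]
            meta = f["meta"].attrs
            ijk = data[:, :3].astype(np.int64)
            keys = _encode_keys(ijk)
            order = np.argsort(keys)
            return cls(
                nucleus_radius_um=float(meta["nucleus_radius_um"]),
                background_dose_gy=float(meta["background_dose_gy"]),
                voxel_keys=keys[order],
                voxel_doses=data[order, 3],
                voxel_size_nm=float(meta["voxel_size_nm"]),
            )


def _encode_keys(ijk: np.ndarray) -> np.ndarray:
    i, j, k = (ijk + _KEY_OFF).T
    return (i.astype(np.int64) << (2 * _KEY_BITS)) | (j.astype(np.int64) << _KEY_BITS) \
        | k.astype(np.int64)


# --------------------------------------------------------------------------
# Dose sources
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentSource:
    """GNPs uniformly loaded in one compartment at a concentration."""

    library: TrackLibrary
    compartment: str  # nucleus | cytoplasm | media
    concentration_mg_ml: float

    def __post_init__(self):
        if self.compartment not in ("nucleus", "cytoplasm", "media"):
            raise KeyError(f"unknown compartment {self.compartment!r}")
        if self.concentration_mg_ml < 0:
            raise ValueError("negative concentration")


@dataclass(frozen=True)
class ExplicitSource:
    """GNPs at explicit positions (toy/test oracle configurations).

    ``n_absorptions`` fixes the number of absorptions per GNP exactly;
    ``None`` draws it Poisson with mean ``absorptions_per_gray * dose``.
    ``track_id`` optionally pins the replayed track; ``rotate=False``
    replays tracks unrotated (hand-computable geometry).
    """

    library: TrackLibrary
    positions_um: np.ndarray
    n_absorptions: int | None = None
    track_id: int | None = None
    rotate: bool = True


def _rotate_vectors(vec, quat):
    """Rotate (n,3) vectors by unit quaternions (n,4) [w, x, y, z]."""
    qw, qv = quat[:, :1], quat[:, 1:]
    t = 2.0 * np.cross(qv, vec)
    return vec + qw * t + np.cross(qv, t)


def _random_quaternions(n, rng):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


class _GridAccumulator:
    def __init__(self, nucleus_radius_um: float):
        self.r_nuc_nm = nucleus_radius_um * 1e3
        self.keys = []
        self.energies = []

    def score(self, positions_nm: np.ndarray, energies_keV: np.ndarray):
        """Score events (absolute nm coordinates) into nucleus voxels."""
        # coarse sphere cut, then exact voxel-centre membership
        r2 = np.einsum("ij,ij->i", positions_nm, positions_nm)
        coarse = r2 <= (self.r_nuc_nm + VOXEL_SIZE_NM) ** 2
        if not coarse.any():
            return
        pos = positions_nm[coarse]
        ijk = np.floor(pos / VOXEL_SIZE_NM).astype(np.int64)
        centres = (ijk + 0.5) * VOXEL_SIZE_NM
        inside = np.einsum("ij,ij->i", centres, centres) <= self.r_nuc_nm**2
        if not inside.any():
            return
        self.keys.append(_encode_keys(ijk[inside]))
        self.energies.append(energies_keV[coarse][inside])

    def score_keys(self, keys: np.ndarray, energies_keV: np.ndarray):
        """Score pre-voxelised events (key < 0 marks a discarded event)."""
        valid = keys >= 0
        if valid.any():
            self.keys.append(keys[valid])
            self.energies.append(energies_keV[valid])

    def grid(self, nucleus_radius_um, background_dose_gy) -> NucleusDoseGrid:
        if self.keys:
            keys = np.concatenate(self.keys)
            en = np.concatenate(self.energies)
            uk, inv = np.unique(keys, return_inverse=True)
            doses = np.bincount(inv, weights=en, minlength=len(uk)) * KEV_TO_GY_PER_VOXEL
        else:
            uk = np.empty(0, np.int64)
            doses = np.empty(0)
        return NucleusDoseGrid(
            nucleus_radius_um=nucleus_radius_um,
            background_dose_gy=background_dose_gy,
            voxel_keys=uk,
            voxel_doses=doses,
        )


try:  # numba accelerates the inner replay loop; numpy path is equivalent
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

_REPLAY_BATCH_EVENTS = 4_000_000


def _replay_rows_numpy(lo, hi, pos_nm, quat, offs, en, r_nuc_nm):
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0)
    off = np.concatenate([[0], np.cumsum(counts)])
    rows = np.repeat(lo, counts) + (np.arange(total) - np.repeat(off[:-1], counts))
    abs_idx = np.repeat(np.arange(len(lo)), counts)
    v = _rotate_vectors(offs[rows], quat[abs_idx]) + pos_nm[abs_idx]
    ijk = np.floor(v / VOXEL_SIZE_NM).astype(np.int64)
    centres = (ijk + 0.5) * VOXEL_SIZE_NM
    inside = np.einsum("ij,ij->i", centres, centres) <= r_nuc_nm**2
    keys = np.where(inside, _encode_keys(ijk), -1)
    return keys, en[rows]


if _numba is not None:
    @_numba.njit(cache=False)
    def _replay_rows_numba(lo, hi, pos_nm, quat, offs, en, r_nuc_nm):  # pragma: no cover
        total = 0
        for p in range(len(lo)):
            total += hi[p] - lo[p]
        keys = np.full(total, -1, np.int64)
        energies = np.empty(total, np.float64)
        r2 = r_nuc_nm * r_nuc_nm
        w = 0
        for p in range(len(lo)):
            qw, qx, qy, qz = quat[p, 0], quat[p, 1], quat[p, 2], quat[p, 3]
            px, py, pz = pos_nm[p, 0], pos_nm[p, 1], pos_nm[p, 2]
            for i in range(lo[p], hi[p]):
                ox, oy, oz = offs[i, 0], offs[i, 1], offs[i, 2]
                tx = 2.0 * (qy * oz - qz * oy)
                ty = 2.0 * (qz * ox - qx * oz)
                tz = 2.0 * (qx * oy - qy * ox)
                x = px + ox + qw * tx + (qy * tz - qz * ty)
                y = py + oy + qw * ty + (qz * tx - qx * tz)
                z = pz + oz + qw * tz + (qx * ty - qy * tx)
                i0 = int(np.floor(x / VOXEL_SIZE_NM))
                j0 = int(np.floor(y / VOXEL_SIZE_NM))
                k0 = int(np.floor(z / VOXEL_SIZE_NM))
                cx = (i0 + 0.5) * VOXEL_SIZE_NM
                cy = (j0 + 0.5) * VOXEL_SIZE_NM
                cz = (k0 + 0.5) * VOXEL_SIZE_NM
                if cx * cx + cy * cy + cz * cz <= r2:
                    keys[w] = (((i0 + _KEY_OFF) << (2 * _KEY_BITS))
                               | ((j0 + _KEY_OFF) << _KEY_BITS)
                               | (k0 + _KEY_OFF))
                    energies[w] = en[i]
                w += 1
        return keys, energies
else:  # pragma: no cover
    _replay_rows_numba = None


def _replay_tracks(accum, library: TrackLibrary, positions_um: np.ndarray,
                   track_ids: np.ndarray, rng, rotate=True):
    """Replay library tracks at GNP positions with random rotations.

    Exact geometric prefilters keep the work proportional to events that
    can actually reach the nucleus: (position, track) pairs whose track
    reach cannot span the gap are dropped, and within surviving pairs only
    events in the radius window ``|dist - r_event| <= R_nucleus + voxel``
    (the shell traced by the event under rotation intersects the nucleus)
    are rotated and scored.  Rotation quaternions are drawn once per
    surviving absorption, independent of the window contents.
    """
    if len(track_ids) == 0:
        return
    pos_nm = positions_um * 1e3
    dist = np.linalg.norm(pos_nm, axis=1)
    reach = library.reach_nm[track_ids]
    r_cut = accum.r_nuc_nm + VOXEL_SIZE_NM
    keep = dist - r_cut <= reach
    pos_nm, track_ids, dist = pos_nm[keep], track_ids[keep], dist[keep]
    n = len(track_ids)
    if n == 0:
        return
    if rotate:
        quat = _random_quaternions(n, rng)
    else:
        quat = np.zeros((n, 4))
        quat[:, 0] = 1.0
    offs, en, key = library.radius_sorted()
    tkey = track_ids.astype(np.float64) * _RADIUS_KEY
    lo = np.searchsorted(key, tkey + np.maximum(dist - r_cut, 0.0))
    hi = np.searchsorted(key, tkey + dist + r_cut)
    counts = hi - lo
    # batch absorptions so scratch buffers stay bounded
    cum = np.concatenate([[0], np.cumsum(counts)])
    kernel = _replay_rows_numba if _replay_rows_numba is not None \
        else _replay_rows_numpy
    a = 0
    while a < n:
        b = int(np.searchsorted(cum, cum[a] + _REPLAY_BATCH_EVENTS, side="left"))
        b = max(b, a + 1)
        keys, energies = kernel(lo[a:b], hi[a:b], pos_nm[a:b], quat[a:b],
                                offs, en, accum.r_nuc_nm)
        accum.score_keys(keys, energies)
        a = b


def _sample_compartment_absorptions(src: CompartmentSource, geometry: CellGeometry,
                                    dose_gy: float, rng,
                                    media_truncation_radius_um=None):
    """Absorption positions (um) and track ids for one compartment source."""
    lib = src.library
    n_tracks = len(lib)
    rate = lib.absorptions_per_gray
    if src.compartment in ("nucleus", "cytoplasm"):
        vol = (geometry.nucleus_volume_um3 if src.compartment == "nucleus"
               else geometry.cytoplasm_volume_um3)
        lam = gnp_count(src.concentration_mg_ml, vol, lib.gnp) * rate * dose_gy
        n = rng.poisson(lam)
        if src.compartment == "nucleus":
            pos = _uniform_shell(0.0, geometry.nucleus_radius_um, n, rng)
        else:
            pos = _uniform_shell(geometry.nucleus_radius_um,
                                 geometry.cell_radius_um, n, rng)
        ids = rng.integers(0, n_tracks, size=n)
        return pos, ids
    # media: per-track reach stratification
    density = gnp_count(src.concentration_mg_ml, 1.0, lib.gnp)  # per um^3
    r_cell = geometry.cell_radius_um
    r_trunc = media_truncation_radius_um
    if r_trunc is None:
        r_trunc = r_cell + lib.max_reach_nm * 1e-3
    r_out = np.minimum(geometry.nucleus_radius_um + lib.reach_nm * 1e-3
                       + VOXEL_SIZE_NM * 1e-3, r_trunc)
    vol_t = 4.0 / 3.0 * np.pi * np.clip(r_out**3 - r_cell**3, 0.0, None)
    lam_t = density * rate * dose_gy * vol_t / n_tracks
    n_t = rng.poisson(lam_t)
    ids = np.repeat(np.arange(n_tracks), n_t)
    n = len(ids)
    u = rng.random(n)
    r = (r_cell**3 + u * (np.repeat(r_out, n_t) ** 3 - r_cell**3)) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * r[:, None], ids


def score_dose(sources, geometry: CellGeometry, background_dose_gy: float,
               rng=None, media_truncation_radius_um=None,
               source_rngs=None) -> NucleusDoseGrid:
    """Score one Monte Carlo cell realization into a sparse nucleus grid.

    ``sources`` is a list of :class:`CompartmentSource` /
    :class:`ExplicitSource`; the expected number of absorptions per GNP is
    ``absorptions_per_gray * background_dose_gy``.  Each source consumes an
    independent child RNG stream (``source_rngs`` overrides them, which
    makes scoring additive across source subsets).
    """
    if not sources:
        return NucleusDoseGrid(geometry.nucleus_radius_um, background_dose_gy)
    for s in sources:
        if len(s.library) == 0:
            raise ValueError("empty track library")
    rng = np.random.default_rng(rng)
    if source_rngs is None:
        source_rngs = rng.spawn(len(sources))
    accum = _GridAccumulator(geometry.nucleus_radius_um)
    for src, srng in zip(sources, source_rngs):
        if isinstance(src, CompartmentSource):
            pos, ids = _sample_compartment_absorptions(
                src, geometry, background_dose_gy, srng,
                media_truncation_radius_um)
            _replay_tracks(accum, src.library, pos, ids, srng)
        else:
            pos = np.atleast_2d(np.asarray(src.positions_um, dtype=float))
            if src.n_absorptions is None:
                counts = srng.poisson(
                    src.library.absorptions_per_gray * background_dose_gy,
                    size=len(pos))
            else:
                counts = np.full(len(pos), src.n_absorptions)
            pos = np.repeat(pos, counts, axis=0)
            n = len(pos)
            if src.track_id is None:
                ids = srng.integers(0, len(src.library), size=n)
            else:
                ids = np.full(n, src.track_id)
            _replay_tracks(accum, src.library, pos, ids, srng,
                           rotate=src.rotate)
    return accum.grid(geometry.nucleus_radius_um, background_dose_gy)
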