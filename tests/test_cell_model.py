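"""Cell geometry, GNP loading and sparse nucleus dose scoring."""

import numpy as np
import pytest
from scipy import stats

from arpsim import (
    CellGeometry,
    CompartmentLoading,
    CompartmentSource,
    ExplicitSource,
    GnpSpec,
    gnp_count,
    sample_positions,
    score_dose,
)
from arpsim.cell_model import (
    KEV_TO_GY_PER_VOXEL,
    VOXEL_SIZE_NM,
    concentration_from_count,
)
from arpsim.cli_io import make_toy_track_library


class TestGeometryAndCounts:
    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            CellGeometry(13.1, 8.2)

    def test_zero_concentration_zero_count(self):
        assert gnp_count(0.0, 1000.0, GnpSpec(30.0)) == 0.0

    def test_cytoplasm_concentration_roundtrip(self, geometry):
        # 2.27e4 30-nm GNPs in the 8.2/13.1 um shell -> ~0.84 mg/ml
        conc = concentration_from_count(2.27e4,
                                        geometry.cytoplasm_volume_um3,
                                        GnpSpec(30.0))
        assert conc == pytest.approx(0.84, rel=0.05)

    def test_count_concentration_inverse(self, geometry):
        gnp = GnpSpec(30.0)
        v = geometry.cytoplasm_volume_um3
        n = gnp_count(0.84, v, gnp)
        assert concentration_from_count(n, v, gnp) == pytest.approx(0.84)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            CompartmentLoading(media_mg_ml=-1.0)


class TestSamplePositions:
    def test_cytoplasm_containment(self, geometry):
        pos = sample_positions("cytoplasm", 2000, geometry,
                               rng=np.random.default_rng(0))
        r = np.linalg.norm(pos, axis=1)
        assert np.all(r > geometry.nucleus_radius_um)
        assert np.all(r < geometry.cell_radius_um)

    def test_media_never_inside_cell(self, geometry):
        pos = sample_positions("media", 2000, geometry,
                               rng=np.random.default_rng(1),
                               media_truncation_radius_um=40.0)
        r = np.linalg.norm(pos, axis=1)
        assert np.all(r >= geometry.cell_radius_um)
        assert np.all(r <= 40.0)

    def test_nucleus_radial_cdf_follows_r_cubed(self, geometry):
        pos = sample_positions("nucleus", 100_000, geometry,
                               rng=np.random.default_rng(2))
        u = (np.linalg.norm(pos, axis=1) / geometry.nucleus_radius_um) ** 3
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_unknown_compartment(self, geometry):
        with pytest.raises(KeyError):
            sample_positions("membrane", 10, geometry,
                             rng=np.random.default_rng(0))


class TestScoreDose:
    def test_no_sources_background_only(self, geometry):
        grid = score_dose([], geometry, 2.0, np.random.default_rng(0))
        assert grid.n_voxels == 0
        assert grid.background_dose_gy == 2.0

    def test_zero_concentration_scores_nothing(self, geometry, lib_100_19):
        src = CompartmentSource(lib_100_19, "nucleus", 0.0)
        grid = score_dose([src], geometry, 4.0, np.random.default_rng(0))
        assert grid.n_voxels == 0

    def test_single_event_oracle(self, geometry):
        # one 1 keV deposition at the GNP position (nucleus centre) lands in
        # exactly one voxel with dose = E / (20 nm voxel water mass)
        lib = make_toy_track_library("single_event", energy_keV=1.0)
        src = ExplicitSource(lib, np.zeros((1, 3)), n_absorptions=1,
                             rotate=False)
        grid = score_dose([src], geometry, 1.0, np.random.default_rng(0))
        assert grid.n_voxels == 1
        expected = 1.602176634e-16 / ((20e-9) ** 3 * 1000.0)  # ~2.0e4 Gy
        assert grid.voxel_doses[0] == pytest.approx(expected, rel=1e-9)
        assert KEV_TO_GY_PER_VOXEL == pytest.approx(expected, rel=1e-12)

    def test_ring_total_energy(self, geometry):
        lib = make_toy_track_library("ring", energy_keV=0.5, n_events=12,
                                     radius_nm=1000.0)
        src = ExplicitSource(lib, np.zeros((1, 3)), n_absorptions=1)
        grid = score_dose([src], geometry, 1.0, np.random.default_rng(3))
        assert grid.total_energy_keV == pytest.approx(6.0, rel=1e-6)

    def test_shell_outside_nucleus_misses(self, geometry):
        lib = make_toy_track_library("isotropic_shell", radius_nm=10_000.0,
                                     n_events=64)
        src = ExplicitSource(lib, np.zeros((1, 3)), n_absorptions=1)
        grid = score_dose([src], geometry, 1.0, np.random.default_rng(4))
        assert grid.n_voxels == 0

    def test_scored_energy_bounded_by_applied(self, geometry, lib_100_19):
        n_abs = 40
        src = ExplicitSource(lib_100_19, np.array([[0.0, 0.0, 7.0]]),
                             n_absorptions=n_abs)
        grid = score_dose([src], geometry, 1.0, np.random.default_rng(5))
        max_track = lib_100_19.energies_keV.sum()  # all events of all tracks
        assert 0 < grid.total_energy_keV <= n_abs * max_track

    def test_same_seed_identical_grid(self, geometry, lib_100_19):
        sources = [CompartmentSource(lib_100_19, "nucleus", 2.0),
                   CompartmentSource(lib_100_19, "media", 2.0)]
        g1 = score_dose(sources, geometry, 4.0, np.random.default_rng(11))
        g2 = score_dose(sources, geometry, 4.0, np.random.default_rng(11))
        np.testing.assert_array_equal(g1.voxel_keys, g2.voxel_keys)
        np.testing.assert_array_equal(g1.voxel_doses, g2.voxel_doses)

    def test_additivity_over_source_sets(self, geometry, lib_100_19):
        # scoring two placement sets separately (with the same per-source
        # streams, hence the same rotations) and summing the grids equals
        # scoring them jointly, exactly
        a = CompartmentSource(lib_100_19, "nucleus", 1.0)
        b = CompartmentSource(lib_100_19, "cytoplasm", 2.0)
        r0, r1 = np.random.default_rng(21).spawn(2)
        joint = score_dose([a, b], geometry, 4.0, source_rngs=[r0, r1])
        r0, r1 = np.random.default_rng(21).spawn(2)
        ga = score_dose([a], geometry, 4.0, source_rngs=[r0])
        gb = score_dose([b], geometry, 4.0, source_rngs=[r1])
        summed = ga.add(gb)
        assert joint.n_voxels > 0
        np.testing.assert_array_equal(summed.voxel_keys, joint.voxel_keys)
        np.testing.assert_allclose(summed.voxel_doses, joint.voxel_doses,
                                   rtol=0, atol=0)

    def test_media_truncation_converged(self, geometry, lib_100_19):
        src = CompartmentSource(lib_100_19, "media", 2.0)
        default_trunc = (geometry.cell_radius_um
                         + lib_100_19.max_reach_nm * 1e-3)
        g1 = score_dose([src], geometry, 8.0, np.random.default_rng(31),
                        media_truncation_radius_um=default_trunc)
        g2 = score_dose([src], geometry, 8.0, np.random.default_rng(31),
                        media_truncation_radius_um=default_trunc * 10)
        e1, e2 = g1.total_energy_keV, g2.total_energy_keV
        assert e2 == pytest.approx(e1, rel=1e-3)

    def test_empty_library_rejected(self, geometry):
        lib = make_toy_track_library("single_event")
        lib.track_start = np.array([0], dtype=np.int64)  # zero tracks
        with pytest.raises(ValueError):
            score_dose([CompartmentSource(lib, "media", 1.0)], geometry, 1.0,
                       np.random.default_rng(0))


class TestGridContainer:
    def test_voxel_centres_inside_nucleus(self, geometry, lib_100_19):
        src = CompartmentSource(lib_100_19, "nucleus", 2.0)
        grid = score_dose([src], geometry, 8.0, np.random.default_rng(41))
        assert grid.n_voxels > 0
        centres = (grid.voxel_indices() + 0.5) * VOXEL_SIZE_NM
        r = np.linalg.norm(centres, axis=1)
        assert np.all(r <= geometry.nucleus_radius_um * 1e3)
        assert np.all(grid.voxel_doses >= 0)

    def test_hdf5_roundtrip(self, geometry, lib_100_19, tmp_path):
        src = CompartmentSource(lib_100_19, "nucleus", 2.0)
        grid = score_dose([src], geometry, 2.0, np.random.default_rng(42))
        path = tmp_path / "grid.h5"
        grid.to_hdf5(path)
        from arpsim.cell_model import NucleusDoseGrid

        back = NucleusDoseGrid.from_hdf5(path)
        np.testing.assert_array_equal(back.voxel_keys, grid.voxel_keys)
        np.testing.assert_allclose(back.voxel_doses, grid.voxel_doses)
        assert back.background_dose_gy == grid.background_dose_gy
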