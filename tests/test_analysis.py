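import numpy as np
import pytest

import minipvdr as m
from minipvdr.analysis import LateralProfile, PeakValleySet


def trilinear_oracle(src, point):
    """Independent 8-corner weighted-sum interpolation at one point."""
    coords = [src.axis_coords(a) for a in range(3)]
    idx, frac = [], []
    for a in range(3):
        c = coords[a]
        p = min(max(point[a], c[0]), c[-1])
        i = int(np.searchsorted(c, p, side="right")) - 1
        i = min(max(i, 0), len(c) - 2)
        idx.append(i)
        frac.append((p - c[i]) / (c[i + 1] - c[i]))
    out = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((frac[0] if dx else 1 - frac[0])
                     * (frac[1] if dy else 1 - frac[1])
                     * (frac[2] if dz else 1 - frac[2]))
                out += w * src.values[idx[0] + dx, idx[1] + dy, idx[2] + dz]
    return out


class TestResampleTrilinear:
    def test_constant_field_preserved(self):
        src = m.VoxelGrid3D(np.full((4, 4, 4), 3.25), spacing=(2, 2, 2))
        tgt = m.VoxelGrid3D(np.zeros((7, 7, 7)), origin=(0.3, 0.1, 0.7),
                            spacing=(0.9, 0.9, 0.9))
        out = m.resample_trilinear(src, tgt)
        assert np.allclose(out.values, 3.25, atol=1e-13)

    def test_midpoint_is_average(self):
        vals = np.zeros((2, 2, 2))
        vals[1, :, :] = 1.0
        src = m.VoxelGrid3D(vals, spacing=(2, 2, 2))
        tgt = m.VoxelGrid3D(np.zeros((1, 1, 1)), origin=(1.0, 0.0, 0.0))
        out = m.resample_trilinear(src, tgt)
        assert out.values[0, 0, 0] == pytest.approx(0.5, abs=1e-14)

    def test_matches_eight_corner_oracle(self):
        rng = np.random.default_rng(3)
        src = m.VoxelGrid3D(rng.uniform(0, 5, (4, 4, 4)),
                            origin=(-1.0, 0.5, 2.0), spacing=(1.5, 2.0, 3.0))
        pts = rng.uniform(-2.0, 8.0, (50, 3))  # includes out-of-extent points
        for p in pts:
            tgt = m.VoxelGrid3D(np.zeros((1, 1, 1)), origin=tuple(p))
            out = m.resample_trilinear(src, tgt)
            assert out.values[0, 0, 0] == pytest.approx(
                trilinear_oracle(src, p), abs=1e-12)

    def test_degenerate_axis_rejected(self):
        src = m.VoxelGrid3D(np.zeros((4, 4, 1)))
        with pytest.raises(ValueError):
            m.resample_trilinear(src, m.VoxelGrid3D(np.zeros((2, 2, 2))))


def _uniform_dataset(shape=(20, 20, 10)):
    """A laterally and axially uniform phantom for plumbing tests."""
    origin = (-4.75, -4.75, 0.5)
    dose = m.VoxelGrid3D(np.full(shape, 2.0), origin, (0.5, 0.5, 1.0),
                         "dose_Gy")
    sig = dose.like(np.full(shape, 0.02), "sigma")
    let = m.VoxelGrid3D(np.full((10, 10, 2), 1.5), (-4.5, -4.5, 2.5),
                        (1.0, 1.0, 5.0), "let_kev_per_um")
    lsig = let.like(np.full((10, 10, 2), 0.03), "sigma")
    return m.PhantomDataset(dose=dose, dose_sigma=sig, let=let,
                            let_sigma=lsig, prescription=2.0, seed=0)


class TestExtractLateralProfile:
    def test_positions_at_dose_resolution(self, ref_phantom):
        prof = m.extract_lateral_profile(ref_phantom, depth=1.0)
        assert np.allclose(np.diff(prof.positions), 0.5)

    def test_uniform_phantom_gives_constant_channels(self):
        ds = _uniform_dataset()
        prof = m.extract_lateral_profile(ds, depth=0.5)
        assert np.allclose(prof.dose, 2.0)
        assert np.allclose(prof.let, 1.5)

    def test_values_equal_direct_voxel_lookup(self, ref_phantom):
        prof = m.extract_lateral_profile(ref_phantom, depth=2.0)
        dose = ref_phantom.dose
        iy = dose.nearest_index(1, 0.0)
        iz = dose.nearest_index(2, 20.0)
        assert np.array_equal(prof.dose, dose.values[:, iy, iz])

    def test_depth_outside_grid_rejected(self, ref_phantom):
        with pytest.raises(ValueError):
            m.extract_lateral_profile(ref_phantom, depth=50.0)


def _cos2_profile():
    x = np.arange(-24.0, 24.01, 0.5)
    d = np.cos(np.pi * x / 6.0) ** 2
    z = np.zeros_like(x)
    return LateralProfile(positions=x, depth=1.0, dose=d, dose_sigma=z,
                          let=z, let_sigma=z)


class TestFindPeaksValleys:
    def test_cos2_known_extrema(self):
        prof = _cos2_profile()
        coll = m.CollimatorSpec(2.0, 6.0, field_half_width=24.0)
        pv = m.find_peaks_valleys(prof, coll, margin=10.0)
        assert list(prof.positions[pv.peak_indices]) == [-12, -6, 0, 6, 12]
        assert list(prof.positions[pv.valley_indices]) == [-9, -3, 3, 9]

    def test_peaks_and_valleys_alternate(self):
        prof = _cos2_profile()
        coll = m.CollimatorSpec(2.0, 6.0, field_half_width=24.0)
        pv = m.find_peaks_valleys(prof, coll)
        merged = sorted(pv.peak_indices + pv.valley_indices)
        kinds = ["p" if i in pv.peak_indices else "v" for i in merged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_flat_profile_rejected(self):
        x = np.arange(-24.0, 24.01, 0.5)
        z = np.zeros_like(x)
        prof = LateralProfile(x, 1.0, np.ones_like(x), z, z, z)
        coll = m.CollimatorSpec(2.0, 30.0, field_half_width=24.0)
        with pytest.raises(m.InsufficientModulationError):
            m.find_peaks_valleys(prof, coll)

    def test_reference_phantom_peaks_near_lattice(self, ref_phantom):
        prof = m.extract_lateral_profile(ref_phantom, depth=1.0)
        pv = m.find_peaks_valleys(prof, ref_phantom.collimator)
        xpk = prof.positions[pv.peak_indices]
        lattice_x = np.arange(-24, 25, 6.0)
        for x in xpk:
            assert np.min(np.abs(lattice_x - x)) <= 0.5

    def test_blind_mode_finds_same_peaks(self, quiet_phantom):
        prof = m.extract_lateral_profile(quiet_phantom, depth=1.0)
        coll = quiet_phantom.collimator
        guided = m.find_peaks_valleys(prof, coll, mode="guided")
        blind = m.find_peaks_valleys(prof, coll, mode="blind")
        assert set(guided.peak_indices) <= set(blind.peak_indices)


class TestComputePvdr:
    def _profile(self, values):
        x = np.arange(len(values), dtype=float)
        z = np.zeros_like(x)
        return LateralProfile(x, 1.0, np.asarray(values, float), z, z, z)

    def test_exact_ratio(self):
        prof = self._profile([10.0, 1.0, 10.0, 1.0, 10.0])
        pv = PeakValleySet([0, 2], [1])
        pvdr, mp, mv, sp, sv = m.compute_pvdr(prof, pv)
        assert pvdr == 10.0 and mp == 10.0 and mv == 1.0
        assert sp == 0.0 and sv == 0.0

    def test_all_equal_gives_unity(self):
        prof = self._profile([2.0, 2.0, 2.0])
        assert m.compute_pvdr(prof, PeakValleySet([0, 2], [1]))[0] == 1.0

    def test_hand_arithmetic_means(self):
        prof = self._profile([20.0, 2.0, 22.0, 2.5, 18.0])
        pvdr, mp, mv, _, _ = m.compute_pvdr(prof, PeakValleySet([0, 2, 4], [1, 3]))
        assert mp == pytest.approx(20.0) and mv == pytest.approx(2.25)
        assert pvdr == pytest.approx(20.0 / 2.25)

    def test_nonpositive_valley_rejected(self):
        prof = self._profile([10.0, 0.0, 10.0])
        with pytest.raises(m.UndefinedRatioError):
            m.compute_pvdr(prof, PeakValleySet([0, 2], [1]))


class TestPvdrReduction:
    def test_arithmetic(self):
        assert m.pvdr_reduction(25.0, 20.0) == pytest.approx(20.0)
        assert m.pvdr_reduction(7.3, 7.3) == 0.0
        assert m.pvdr_reduction(10.0, 7.35) == pytest.approx(26.5)

    def test_nonpositive_phys_rejected(self):
        with pytest.raises(ValueError):
            m.pvdr_reduction(0.0, 1.0)


class TestParameterSweep:
    def test_row_count_is_cartesian(self, sweep_df):
        # 2 holes x 1 factor x 1 gap x 3 depths x 3 models x 2 ab x 1 Rx
        assert len(sweep_df) == 2 * 3 * 3 * 2
        assert (sweep_df["error"] == "").all()

    def test_ctc_expands_with_hole_diameter(self):
        cfg = m.SweepConfig(hole_diameters=(1.0,), ctc_factors=(2.0, 3.0, 4.0))
        ctcs = sorted({h * f for h in cfg.hole_diameters
                       for f in cfg.ctc_factors})
        assert ctcs == [2.0, 3.0, 4.0]

    def test_biological_never_exceeds_physical(self, sweep_df):
        assert (sweep_df["pvdr_biol"] <= sweep_df["pvdr_phys"]).all()
        assert (sweep_df["reduction_percent"] > 0).all()

    def test_low_alpha_beta_reduces_more(self, sweep_df):
        key = ["hole_mm", "ctc_mm", "model", "depth_cm"]
        for _, grp in sweep_df.groupby(key):
            r3 = grp.loc[grp.alpha_beta == 3.0, "reduction_percent"]
            r10 = grp.loc[grp.alpha_beta == 10.0, "reduction_percent"]
            assert float(r3.iloc[0]) > float(r10.iloc[0])

    def test_pvdr_decreases_with_depth(self, sweep_df):
        key = ["hole_mm", "ctc_mm", "model", "alpha_beta"]
        for _, grp in sweep_df.groupby(key):
            seq = grp.sort_values("depth_cm")["pvdr_phys"].to_numpy()
            assert np.all(np.diff(seq) < 0)

    def test_pvdr_decreases_with_air_gap(self, gap_records):
        p = [gap_records[g]["pvdr_phys"] for g in (5.0, 10.0, 15.0)]
        b = [gap_records[g]["pvdr_biol"] for g in (5.0, 10.0, 15.0)]
        assert p[0] > p[1] > p[2]
        assert b[0] > b[1] > b[2]

    def test_summary_max_at_least_mean(self, sweep_df):
        s = m.summarize_reductions(sweep_df)
        assert (s["max_reduction_percent"]
                >= s["mean_reduction_percent"] - 1e-12).all()

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            m.SweepConfig(energies=())
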