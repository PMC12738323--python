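import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import minipvdr as m
from minipvdr.rbe import finite_difference_partials


def scalar_rbe_oracle(model, dose, ab, let):
    """Independent plain-arithmetic evaluation of the three closed forms."""
    if model == "mcnamara":
        rmax = 0.99064 + 0.35605 * let / ab
        rmin = 1.1012 + (-0.0038703) * math.sqrt(ab) * let
    elif model == "carabe":
        rmax = 0.843 + 0.154 * (2.686 / ab) * let
        rmin = 1.09 + 0.006 * (2.686 / ab) * let
    else:
        rmax = 1.0 + 0.434 * let / ab
        rmin = 1.0
    s = math.sqrt(ab * ab + 4 * dose * ab * rmax
                  + 4 * dose * dose * rmin * rmin)
    return (s - ab) / (2 * dose)


class TestRbeMaxMin:
    def test_mcnamara_zero_let_intercepts(self):
        rmax, rmin = m.rbe_max_min(m.TissueModelSpec("mcnamara", 3.0), 0.0)
        assert rmax == pytest.approx(0.99064)
        assert rmin == pytest.approx(1.1012)

    def test_wedenberg_zero_let(self):
        assert m.rbe_max_min(m.TissueModelSpec("wedenberg", 7.0), 0.0) == (1.0, 1.0)

    def test_carabe_reference_point(self):
        rmax, rmin = m.rbe_max_min(m.TissueModelSpec("carabe", 3.0), 1.0)
        assert rmax == pytest.approx(0.98088, abs=1e-5)
        assert rmin == pytest.approx(1.09537, abs=1e-5)

    def test_negative_let_rejected(self):
        with pytest.raises(ValueError):
            m.rbe_max_min(m.TissueModelSpec("mcnamara", 3.0), -0.1)


class TestRbe:
    @pytest.mark.parametrize("model,let,expected", [
        ("mcnamara", 1.0, 1.1005), ("mcnamara", 8.0, 1.3878),
        ("carabe", 1.0, 1.0482), ("wedenberg", 0.0, 1.0)])
    def test_frozen_reference_values(self, model, let, expected):
        spec = m.TissueModelSpec(model, 3.0)
        assert m.rbe(spec, 2.0, let) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("model", ["mcnamara", "carabe", "wedenberg"])
    def test_matches_independent_scalar_oracle(self, model):
        spec3 = m.TissueModelSpec(model, 3.0)
        spec10 = m.TissueModelSpec(model, 10.0)
        for dose in (0.5, 2.0, 10.0):
            for let in (0.0, 1.0, 8.0, 18.0):
                assert m.rbe(spec3, dose, let) == pytest.approx(
                    scalar_rbe_oracle(model, dose, 3.0, let), rel=1e-12)
                assert m.rbe(spec10, dose, let) == pytest.approx(
                    scalar_rbe_oracle(model, dose, 10.0, let), rel=1e-12)

    def test_zero_dose_is_a_domain_error(self):
        with pytest.raises(ValueError):
            m.rbe(m.TissueModelSpec("mcnamara", 3.0), 0.0, 1.0)

    @given(st.floats(0.05, 15.0), st.floats(1.0, 12.0))
    def test_wedenberg_unity_at_zero_let(self, dose, ab):
        r = m.rbe(m.TissueModelSpec("wedenberg", ab), dose, 0.0)
        assert abs(r - 1.0) < 1e-12

    def test_wedenberg_exactly_one_at_representative_points(self):
        for dose, ab in [(2.0, 3.0), (2.0, 10.0), (5.0, 10.0), (1.0, 3.0)]:
            assert m.rbe(m.TissueModelSpec("wedenberg", ab), dose, 0.0) == 1.0


#: monotone domain: the McNamara dRBE/dLET = (p1 + 2 D rmin p3 sqrt(ab))/S
#: changes sign near D = p1 / (2 rmin(0) |p3| sqrt(ab)) ~ 13.2 Gy for
#: alpha/beta = 10, so the dense monotonicity grids stop at 12 Gy
DENSE_DOSE = np.linspace(0.25, 12.0, 40)
DENSE_LET = np.linspace(0.0, 20.0, 60)


class TestModelInvariants:
    @pytest.mark.parametrize("model", ["mcnamara", "carabe", "wedenberg"])
    @pytest.mark.parametrize("ab", [3.0, 10.0])
    def test_rbe_strictly_increasing_in_let(self, model, ab):
        spec = m.TissueModelSpec(model, ab)
        d, l = np.meshgrid(DENSE_DOSE, DENSE_LET, indexing="ij")
        r = m.rbe(spec, d, l)
        assert np.all(np.diff(r, axis=1) > 0)

    @pytest.mark.parametrize("model", ["mcnamara", "carabe", "wedenberg"])
    @pytest.mark.parametrize("ab", [3.0, 10.0])
    def test_rbe_decreasing_in_dose_where_max_exceeds_min(self, model, ab):
        spec = m.TissueModelSpec(model, ab)
        d, l = np.meshgrid(DENSE_DOSE, DENSE_LET, indexing="ij")
        rmax, rmin = m.rbe_max_min(spec, l)
        r = m.rbe(spec, d, l)
        grad = np.diff(r, axis=0)
        cond = (rmax > rmin)[:-1, :] & (rmax > rmin)[1:, :] & (l[:-1, :] > 0)
        assert np.all(grad[cond] < 0)

    @pytest.mark.parametrize("model", ["mcnamara", "carabe", "wedenberg"])
    def test_alpha_beta_ordering(self, model):
        """Low alpha/beta (late-responding tissue) has the larger RBE."""
        d, l = np.meshgrid(DENSE_DOSE, DENSE_LET[DENSE_LET > 0],
                           indexing="ij")
        r3 = m.rbe(m.TissueModelSpec(model, 3.0), d, l)
        r10 = m.rbe(m.TissueModelSpec(model, 10.0), d, l)
        assert np.all(r3 > r10)

    def test_vectorized_equals_scalar_loop_bitwise(self):
        rng = np.random.default_rng(42)
        d = rng.uniform(0.1, 14.0, (10, 10, 10))
        l = rng.uniform(0.0, 20.0, (10, 10, 10))
        spec = m.TissueModelSpec("mcnamara", 3.0)
        vec = m.rbe(spec, d, l)
        loop = np.empty_like(vec)
        for idx in np.ndindex(d.shape):
            loop[idx] = m.rbe(spec, float(d[idx]), float(l[idx]))
        assert np.array_equal(vec, loop)


class TestMcnamaraPartials:
    def test_frozen_reference_values(self):
        dd, dl = m.mcnamara_partials(m.TissueModelSpec("mcnamara", 3.0),
                                     2.0, 1.0)
        assert dl == pytest.approx(0.0441, abs=2e-4)
        assert dd == pytest.approx(-0.0018, abs=2e-4)
        assert dd < 0

    def test_agrees_with_central_finite_differences(self):
        spec3 = m.TissueModelSpec("mcnamara", 3.0)
        spec10 = m.TissueModelSpec("mcnamara", 10.0)
        rng = np.random.default_rng(0)
        for _ in range(100):
            dose = rng.uniform(0.2, 14.0)
            let = rng.uniform(0.1, 19.0)
            spec = spec3 if rng.random() < 0.5 else spec10
            dd, dl = m.mcnamara_partials(spec, dose, let)
            h = 1e-4
            fd_d = (m.rbe(spec, dose + h, let)
                    - m.rbe(spec, dose - h, let)) / (2 * h)
            fd_l = (m.rbe(spec, dose, let + h)
                    - m.rbe(spec, dose, let - h)) / (2 * h)
            assert dd == pytest.approx(fd_d, rel=1e-6, abs=1e-10)
            assert dl == pytest.approx(fd_l, rel=1e-6)

    def test_positive_let_derivative_on_monotone_domain(self):
        d, l = np.meshgrid(np.linspace(0.1, 12, 30),
                           np.linspace(0.0, 20, 30), indexing="ij")
        for ab in (3.0, 10.0):
            _, dl = m.mcnamara_partials(m.TissueModelSpec("mcnamara", ab), d, l)
            assert np.all(dl > 0)

    def test_let_derivative_sign_flip_at_extreme_dose(self):
        """Genuine model behavior: for alpha/beta = 10 the negative p3 term
        overtakes p1 above ~13.2 Gy and RBE starts to fall with LET."""
        spec = m.TissueModelSpec("mcnamara", 10.0)
        _, dl_lo = m.mcnamara_partials(spec, 12.0, 0.5)
        _, dl_hi = m.mcnamara_partials(spec, 15.0, 0.5)
        assert dl_lo > 0 > dl_hi

    def test_other_models_unsupported(self):
        with pytest.raises(ValueError):
            m.mcnamara_partials(m.TissueModelSpec("carabe", 3.0), 2.0, 1.0)

    def test_finite_difference_fallback(self):
        spec = m.TissueModelSpec("wedenberg", 3.0)
        dd, dl = finite_difference_partials(spec, 2.0, 1.0)
        h = 1e-5
        fd_l = (m.rbe(spec, 2.0, 1.0 + h) - m.rbe(spec, 2.0, 1.0 - h)) / (2 * h)
        assert dl == pytest.approx(fd_l, rel=1e-4)


class TestBiologicalDoseGrid:
    def _uniform_dataset(self, dose_val, let_val):
        shape = (4, 4, 4)
        dose = m.VoxelGrid3D(np.full(shape, dose_val), quantity="dose_Gy")
        let = m.VoxelGrid3D(np.full(shape, let_val),
                            quantity="let_kev_per_um")
        return dose, let

    def test_wedenberg_zero_let_identity(self):
        dose, let = self._uniform_dataset(2.0, 0.0)
        bio, mask = m.biological_dose_grid(dose, let,
                                           m.TissueModelSpec("wedenberg", 3.0))
        assert np.array_equal(bio.values, dose.values)
        assert not mask.any()

    def test_mcnamara_uniform_value(self):
        dose, let = self._uniform_dataset(2.0, 1.0)
        bio, _ = m.biological_dose_grid(dose, let,
                                        m.TissueModelSpec("mcnamara", 3.0))
        assert np.allclose(bio.values, 2.201, atol=1e-3)

    def test_monotone_in_let(self):
        dose, let1 = self._uniform_dataset(2.0, 1.0)
        _, let8 = self._uniform_dataset(2.0, 8.0)
        spec = m.TissueModelSpec("mcnamara", 3.0)
        b1, _ = m.biological_dose_grid(dose, let1, spec)
        b8, _ = m.biological_dose_grid(dose, let8, spec)
        assert np.all(b8.values > b1.values)

    def test_below_floor_voxels_flagged_and_passed_through(self):
        dose, let = self._uniform_dataset(2.0, 5.0)
        dose.values[0, 0, 0] = 1e-9
        bio, mask = m.biological_dose_grid(dose, let,
                                           m.TissueModelSpec("mcnamara", 3.0))
        assert mask[0, 0, 0] and mask.sum() == 1
        assert bio.values[0, 0, 0] == dose.values[0, 0, 0]

    def test_geometry_mismatch_rejected(self):
        dose, _ = self._uniform_dataset(2.0, 0.0)
        let = m.VoxelGrid3D(np.zeros((2, 2, 2)), quantity="let_kev_per_um")
        with pytest.raises(ValueError):
            m.biological_dose_grid(dose, let, m.TissueModelSpec("mcnamara", 3.0))
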