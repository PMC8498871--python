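"""Order parameter, autocorrelation, correlation length, edge profiles, PIV."""

import numpy as np
import pytest

from monolayer_mech.errors import DegenerateFieldError, GeometryError
from monolayer_mech.synthgen import gen_speckle_pair, gen_velocity_field
from monolayer_mech.velocimetry import (
    CorrelationCurve,
    VectorField,
    correlation_length,
    edge_profile,
    largest_interior_rectangle,
    order_parameter,
    piv_displacement,
    radial_average,
    spatial_autocorrelation,
)


def uniform_field(u, v, shape=(16, 16), **kw):
    return VectorField(np.full(shape, float(u)), np.full(shape, float(v)),
                       spacing_um=12.08, **kw)


class TestOrderParameter:
    def test_parallel_is_one(self):
        assert order_parameter(uniform_field(7.0, 0.0)) == 1.0

    def test_perpendicular_is_zero(self):
        assert order_parameter(uniform_field(0.0, 5.0)) == pytest.approx(0.0, abs=1e-15)

    def test_antiparallel_is_minus_one(self):
        assert order_parameter(uniform_field(-3.0, 0.0)) == -1.0

    def test_isotropic_vectors_average_out(self):
        # CLT: |mean cos| < 3/sqrt(N) with margin -> < 0.03 at N = 1e4
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi, 10_000).reshape(100, 100)
        f = VectorField(np.cos(ang), np.sin(ang), spacing_um=1.0)
        assert abs(order_parameter(f)) < 0.03

    def test_speed_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        u, v = rng.normal(size=(2, 20, 20))
        f1 = VectorField(u, v, spacing_um=1.0)
        f2 = VectorField(10.0 * u, 10.0 * v, spacing_um=1.0)
        assert order_parameter(f1) == pytest.approx(order_parameter(f2), abs=1e-14)

    def test_zero_magnitude_vectors_excluded(self):
        u = np.zeros((8, 8)); u[0, 0] = 4.0
        f = VectorField(u, np.zeros_like(u), spacing_um=1.0)
        assert order_parameter(f) == 1.0

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateFieldError):
            order_parameter(uniform_field(0.0, 0.0))


class TestEdgeProfile:
    def test_uniform_field_flat_profile(self):
        prof = edge_profile([uniform_field(20.0, 0.0)], bin_um=12.08)
        assert np.allclose(prof.mean_speed_um_per_h, 20.0)
        assert np.allclose(prof.mean_order, 1.0)

    def test_linear_speed_gradient_recovered(self):
        # speed = 20 - 0.0075 * d (µm/h), d measured from the right edge
        sp = 12.08
        nx = 40
        cols = np.arange(nx)
        d = (nx - 1 - cols) * sp
        u = np.tile(20.0 - 0.0075 * d, (8, 1))
        f = VectorField(u, np.zeros_like(u), spacing_um=sp)
        prof = edge_profile([f], bin_um=sp)
        expected = 20.0 - 0.0075 * (prof.distance_um - sp / 2)  # node at bin lower edge
        assert np.allclose(prof.mean_speed_um_per_h, expected, atol=1e-9)

    def test_trusted_drops_flagged_bins(self):
        prof = edge_profile([uniform_field(5.0, 0.0)], bin_um=12.08, drop_first=2)
        assert prof.trusted().distance_um.size == prof.distance_um.size - 2

    def test_empty_mask_raises(self):
        f = uniform_field(5.0, 0.0, mask=np.zeros((16, 16), dtype=bool))
        with pytest.raises(DegenerateFieldError):
            edge_profile([f])


class TestSpatialAutocorrelation:
    def test_lag_negation_symmetry_exact(self):
        f, _ = gen_velocity_field((48, 48), 10.0, 25.0, 3.0, seed=2)
        ac = spatial_autocorrelation(f)
        assert np.array_equal(ac, ac[::-1, ::-1])

    def test_zero_lag_is_one(self):
        f, _ = gen_velocity_field((48, 48), 10.0, 25.0, 3.0, seed=3)
        ac = spatial_autocorrelation(f)
        assert ac[ac.shape[0] // 2, ac.shape[1] // 2] == pytest.approx(1.0)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(7)
        f = VectorField(rng.normal(size=(128, 128)), rng.normal(size=(128, 128)),
                        spacing_um=1.0)
        ac = spatial_autocorrelation(f)
        cur = radial_average(ac, 1.0)
        assert np.all(np.abs(cur.ac[1:]) < 0.05)

    def test_constant_field_raises(self):
        with pytest.raises(DegenerateFieldError):
            spatial_autocorrelation(uniform_field(5.0, 3.0))

    def test_mask_cropping_uses_inscribed_rectangle(self):
        mask = np.ones((32, 32), dtype=bool)
        mask[:, 20:] = False
        mask[:5, 15:] = False  # a finger-like bite
        sl = largest_interior_rectangle(mask)
        sub = mask[sl]
        assert sub.all() and sub.size == max(
            (32 - 5) * 20, 32 * 15
        )


class TestRadialAverage:
    def test_delta_at_zero_lag(self):
        ac = np.zeros((33, 33)); ac[16, 16] = 1.0
        cur = radial_average(ac, 1.0)
        assert cur.ac[0] == 1.0 and np.allclose(cur.ac[1:], 0.0)

    def test_radially_symmetric_input_recovered(self):
        ii, jj = np.meshgrid(np.arange(65) - 32, np.arange(65) - 32, indexing="ij")
        r = np.hypot(ii, jj)
        cur = radial_average(np.exp(-r / 10.0), 1.0)
        # bin k collects radii rounding to k; compare against direct annular sum
        for k in (2, 5, 10):
            sel = np.rint(r).astype(int) == k
            assert cur.ac[k] == pytest.approx(np.exp(-r[sel] / 10.0).mean(), rel=1e-12)

    def test_anisotropic_input_matches_bruteforce_annular_mean(self):
        ii, jj = np.meshgrid(np.arange(65) - 32, np.arange(65) - 32, indexing="ij")
        field = np.exp(-np.abs(jj) / 8.0)
        cur = radial_average(field, 1.0)
        r = np.hypot(ii, jj)
        k = np.rint(r).astype(int)
        for b in (3, 7, 12):
            oracle = field[k == b].mean()
            assert cur.ac[b] == pytest.approx(oracle, rel=1e-12)
            # bounded between the minor-axis decay and 1
            assert np.exp(-b / 8.0) <= cur.ac[b] <= 1.0


class TestCorrelationLength:
    def test_linear_decay_closed_form(self):
        r = np.linspace(0, 10, 1001)
        cur = CorrelationCurve(r, 1 - r / 10.0, np.ones_like(r))
        assert correlation_length(cur, normalize=False) == pytest.approx(100 / 6, rel=1e-4)
        assert correlation_length(cur, normalize=True) == pytest.approx(10 / 3, rel=1e-4)

    def test_exponential_decay_recovers_xi(self):
        xi = 30.0
        r = np.linspace(0, 10 * xi, 2000)
        cur = CorrelationCurve(r, np.exp(-r / xi), np.ones_like(r))
        L = correlation_length(cur)
        assert 0.9 * xi <= L <= xi

    def test_no_intercept_integrates_to_rmax(self):
        r = np.linspace(0, 8.0, 100)
        cur = CorrelationCurve(r, np.ones_like(r), np.ones_like(r))
        assert correlation_length(cur) == pytest.approx(4.0, rel=1e-9)

    def test_zero_crossing_interpolated(self):
        # AC = 1 - r/5 on a coarse grid: the crossing at r = 5 is found by
        # linear interpolation and the trapezoid value over [0, 2, 4, 5]
        # equals the hand-computed 3.6; a dense grid converges to 25/6
        r = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        cur = CorrelationCurve(r, 1 - r / 5.0, np.ones_like(r))
        assert correlation_length(cur, normalize=False) == pytest.approx(3.6, rel=1e-12)
        rd = np.linspace(0, 8, 4001)
        curd = CorrelationCurve(rd, 1 - rd / 5.0, np.ones_like(rd))
        assert correlation_length(curd, normalize=False) == pytest.approx(25 / 6, rel=1e-5)

    def test_too_few_points_raises(self):
        cur = CorrelationCurve([0.0, 1.0], [1.0, 0.5], [1, 1])
        with pytest.raises(ValueError):
            correlation_length(cur)


class TestPipelineRecovery:
    def test_grf_to_correlation_length_recovers_xi(self):
        # full-pipeline property at reduced seed count (acceptance runs 20)
        xi, sp = 30.0, 12.08
        curves = []
        for s in range(8):
            f, _ = gen_velocity_field((128, 128), sp, xi, 5.0, (10, 0), seed=s)
            curves.append(radial_average(spatial_autocorrelation(f), sp).ac)
        cur0 = radial_average(spatial_autocorrelation(f), sp)
        mean = CorrelationCurve(cur0.r_um, np.mean(curves, axis=0), cur0.n_pairs)
        assert correlation_length(mean) == pytest.approx(xi, rel=0.15)


class TestPiv:
    @pytest.mark.parametrize("shift", [0, 4, 8])
    def test_integer_shift_recovered(self, shift):
        f = VectorField(np.full((8, 8), float(shift)), np.zeros((8, 8)), spacing_um=32.0)
        a, b = gen_speckle_pair(f, dt_min=60.0, pixel_um=1.0, seed=2)
        pf = piv_displacement(a, b)
        assert pf.mask.sum() > 0.9 * pf.mask.size
        assert np.abs(pf.u[pf.mask] - shift).max() < 0.1
        assert np.abs(pf.v[pf.mask]).max() < 0.1

    def test_identical_images_zero_field(self):
        f = VectorField(np.zeros((8, 8)), np.zeros((8, 8)), spacing_um=32.0)
        a, _ = gen_speckle_pair(f, dt_min=60.0, seed=4)
        pf = piv_displacement(a, a)
        assert pf.mask.any()
        assert np.abs(pf.u[pf.mask]).max() < 1e-9
        assert np.abs(pf.v[pf.mask]).max() < 1e-9

    def test_featureless_images_all_invalid(self):
        c = np.full((64, 64), 3.0)
        assert piv_displacement(c, c).mask.sum() == 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            piv_displacement(np.zeros((64, 64)), np.zeros((64, 32)))

    def test_statistics_survive_piv_roundtrip(self):
        # order parameter measured on PIV output of an advected pair agrees
        # with the generating field's order within 10%
        f, _ = gen_velocity_field((32, 32), 16.0, 48.0, 1.0, (6.0, 2.0), seed=8)
        a, b = gen_speckle_pair(f, dt_min=60.0, pixel_um=1.0, seed=8)
        pf = piv_displacement(a, b, pixel_um=1.0, dt_min=60.0)
        assert order_parameter(pf) == pytest.approx(order_parameter(f), abs=0.1)
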