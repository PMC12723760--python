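"""Box-Cox, natural splines, atrophy residualization, tau composite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import CubicSpline
from scipy.stats import boxcox_llf

from pacctraj.errors import (
    DegenerateInputError,
    MissingDataError,
    RangeError,
    SpecificationError,
)
from pacctraj.transforms import (
    TAU_COMPOSITE_REGIONS,
    BoxCoxTransform,
    SplineBasis,
    apply_boxcox,
    build_spline_basis,
    fit_boxcox,
    inverse_boxcox,
    residualize_and_z,
    tau_composite,
)


def grid_search_lambda(y, shift, resolution=0.01):
    """Independent Box-Cox oracle: exhaustive grid over lambda."""
    lams = np.arange(-3, 3 + resolution, resolution)
    lls = [boxcox_llf(l, y + shift) for l in lams]
    return lams[int(np.argmax(lls))]


class TestBoxCox:
    def test_normal_data_lambda_near_one(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10, 1, size=10_000)
        t = fit_boxcox(y)
        assert t.shift == 0.0
        assert abs(t.lam - 1.0) < 0.15
        assert abs(t.lam - grid_search_lambda(y, t.shift)) < 0.02

    def test_lognormal_data_lambda_near_zero(self):
        rng = np.random.default_rng(2)
        y = np.exp(rng.normal(0, 1, size=10_000))
        t = fit_boxcox(y)
        assert abs(t.lam) < 0.1
        assert abs(t.lam - grid_search_lambda(y, t.shift)) < 0.02

    def test_shift_convention_for_nonpositive_data(self):
        y = np.linspace(-5, 5, 100)
        t = fit_boxcox(y)
        assert t.shift == pytest.approx(1 - (-5))

    @pytest.mark.parametrize(
        "lam,shift,y,expected",
        [
            (1.0, 0.0, [2.0, 3.0], [1.0, 2.0]),
            (0.0, 0.0, [1.0, np.e], [0.0, 1.0]),
            (0.5, 0.0, [4.0], [2.0]),
        ],
    )
    def test_closed_forms(self, lam, shift, y, expected):
        t = BoxCoxTransform(lam=lam, shift=shift)
        np.testing.assert_allclose(apply_boxcox(t, y), expected, atol=1e-12)

    @given(
        lam=st.floats(-2, 2),
        shift=st.floats(0, 10),
        y=st.lists(st.floats(0.5, 50), min_size=1, max_size=20),
    )
    @settings(max_examples=60, deadline=None)
    def test_inverse_identity(self, lam, shift, y):
        t = BoxCoxTransform(lam=round(lam, 6), shift=shift)
        z = t.apply(np.asarray(y))
        np.testing.assert_allclose(t.inverse(z), y, atol=1e-8, rtol=1e-8)

    def test_errors(self):
        with pytest.raises(DegenerateInputError):
            fit_boxcox(np.ones(100))
        with pytest.raises(DegenerateInputError):
            fit_boxcox([1.0, 2.0])
        with pytest.raises(RangeError):
            BoxCoxTransform(lam=0.5).apply([-1.0])
        with pytest.raises(RangeError):
            inverse_boxcox(BoxCoxTransform(lam=1.0), [-2.0])

    def test_serialization_roundtrip(self):
        t = BoxCoxTransform(lam=0.37, shift=12.5)
        assert BoxCoxTransform.from_dict(t.to_dict()) == t


class TestSplineBasis:
    @pytest.mark.parametrize("df", [1, 2, 3])
    def test_dimensions_and_knot_rule(self, df):
        rng = np.random.default_rng(3)
        times = rng.uniform(0, 7, size=500)
        basis = build_spline_basis(times, df)
        B = basis.evaluate(times)
        assert B.shape == (500, df)
        assert len(basis.interior_knots) == df - 1
        if df == 2:
            assert basis.interior_knots[0] == pytest.approx(np.quantile(times, 0.5))

    def test_df1_is_monotone_time(self):
        basis = build_spline_basis([0.0, 7.0], 1)
        t = np.linspace(0, 7, 50)
        col = basis.evaluate(t)[:, 0]
        assert np.all(np.diff(col) > 0)

    @pytest.mark.parametrize("df", [2, 3])
    def test_natural_constraint_zero_second_derivative_at_boundaries(self, df):
        basis = build_spline_basis(np.linspace(0, 7, 200), df)
        h = 1e-4
        for t0 in basis.boundary_knots:
            f = lambda t: basis.evaluate([t])[0]
            second = (f(t0 + h) - 2 * f(t0) + f(t0 - h)) / h**2
            scale = np.abs(basis.evaluate(np.linspace(0, 7, 50))).max(axis=0)
            assert np.all(np.abs(second) < 1e-5 * np.maximum(scale, 1.0) + 1e-4)

    def test_linear_extrapolation_beyond_boundaries(self):
        basis = build_spline_basis(np.linspace(0, 7, 100), 3)
        for ts in (np.array([7.5, 8.0, 8.5]), np.array([-1.5, -1.0, -0.5])):
            B = basis.evaluate(ts)
            second_diff = B[2] - 2 * B[1] + B[0]
            np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    def test_column_space_matches_natural_cardinal_interpolants(self):
        """Independent construction: scipy natural-BC cardinal splines span
        the same function space on the knot interval."""
        rng = np.random.default_rng(4)
        times = np.sort(rng.uniform(0, 7, size=300))
        basis = build_spline_basis(times, 2)
        t_eval = np.sort(rng.uniform(0.0, 7.0, size=200))
        B = np.column_stack([np.ones(200), basis.evaluate(t_eval)])
        knots = basis.all_knots
        cardinal = np.column_stack(
            [
                CubicSpline(knots, np.eye(len(knots))[j], bc_type="natural")(t_eval)
                for j in range(len(knots))
            ]
        )
        # each package basis column must lie in the span of the cardinal set
        proj, *_ = np.linalg.lstsq(cardinal, B, rcond=None)
        resid = B - cardinal @ proj
        assert np.abs(resid).max() < 1e-8 * np.abs(B).max()

    def test_columns_linearly_independent(self):
        times = np.linspace(0, 7, 40)
        for df in (1, 2, 3):
            B = build_spline_basis(times, df).evaluate(times)
            assert np.linalg.cond(B) < 1e6

    def test_invalid_df(self):
        with pytest.raises(SpecificationError):
            build_spline_basis([0, 1, 2], 4)
        with pytest.raises(DegenerateInputError):
            build_spline_basis([1.0, 1.0], 2)

    def test_serialization_roundtrip(self):
        basis = build_spline_basis(np.linspace(0, 7, 100), 3)
        again = SplineBasis.from_dict(basis.to_dict())
        t = np.linspace(-1, 8, 30)
        np.testing.assert_allclose(basis.evaluate(t), again.evaluate(t))


class TestResidualizeAndZ:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        icv = rng.normal(1.5e6, 1e5, 200)
        vol = 3000 + 0.002 * icv + rng.normal(0, 100, 200)
        z = residualize_and_z(vol, icv)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=0) - 1) < 1e-10

    def test_recovers_noise_term(self):
        rng = np.random.default_rng(6)
        icv = rng.normal(1.5e6, 1e5, 500)
        noise = rng.normal(0, 300, 500)
        vol = 1000 + 0.004 * icv + noise
        z = residualize_and_z(vol, icv)
        # sign flipped: more atrophy = smaller residual volume
        assert np.corrcoef(z, -noise)[0, 1] > 0.99

    def test_degenerate_inputs(self):
        icv = np.linspace(1.4e6, 1.6e6, 50)
        with pytest.raises(DegenerateInputError):
            residualize_and_z(2.0 * icv + 5.0, icv)  # exactly collinear
        with pytest.raises(DegenerateInputError):
            residualize_and_z(np.ones(50) * 7000, np.ones(50) * 1.5e6)


class TestTauComposite:
    def test_constant_and_mean(self):
        assert tau_composite({r: 1.10 for r in TAU_COMPOSITE_REGIONS}) == pytest.approx(1.10)
        vals = {r: 0.1 * (i + 1) for i, r in enumerate(TAU_COMPOSITE_REGIONS)}
        assert tau_composite(vals) == pytest.approx(0.45)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        vals = {r: float(rng.uniform(0.9, 2.0)) for r in TAU_COMPOSITE_REGIONS}
        shuffled = dict(reversed(list(vals.items())))
        assert tau_composite(vals) == pytest.approx(tau_composite(shuffled))

    def test_missing_region(self):
        vals = {r: 1.2 for r in TAU_COMPOSITE_REGIONS[:-1]}
        with pytest.raises(MissingDataError):
            tau_composite(vals)
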