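import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wkde.core_io import DensityKernel, GridSpec, KernelModel
from wkde.wkde_predictor import (
    coverage_fraction,
    density_row,
    dnam_to_row,
    fine_probability,
    joint_density_profile,
    predict_age,
    predict_samples,
    probability_vector,
    variation_score,
)

from conftest import make_matrix, make_samples, single_kernel_model


def random_model(n_cpgs, seed=0):
    rng = np.random.default_rng(seed)
    grid = GridSpec()
    kernels = [DensityKernel(f"cg{i:08d}",
                             rng.uniform(0.0, 1.0, size=(101, 101)),
                             (1.0, 1.0)) for i in range(n_cpgs)]
    weights = rng.uniform(-10, 10, size=n_cpgs)
    return KernelModel(grid, kernels, weights)


class TestDensityRow:
    def test_round_half_up_to_nearest_grid_node(self):
        assert dnam_to_row(GridSpec(), 49.6) == 50
        assert dnam_to_row(GridSpec(), 49.4) == 49
        assert dnam_to_row(GridSpec(), 49.5) == 50

    def test_boundaries(self):
        assert dnam_to_row(GridSpec(), 0.0) == 0
        assert dnam_to_row(GridSpec(), 100.0) == 100
        with pytest.raises(ValueError):
            dnam_to_row(GridSpec(), 100.6)

    def test_accessor_identity_and_missing_signal(self):
        model = random_model(1, seed=5)
        k = model.kernels[0]
        np.testing.assert_array_equal(density_row(k, 37.2), k.density[37])
        with pytest.raises(KeyError):
            density_row(k, np.nan)


class TestJointProfile:
    def test_single_cpg_profile_is_its_row(self):
        model = random_model(1, seed=1)
        profile, n = joint_density_profile(model, {"cg00000000": 42.0},
                                           use_weights=False)
        np.testing.assert_array_equal(profile, model.kernels[0].density[42])
        assert n == 1

    def test_linearity_of_weights(self):
        grid = GridSpec()
        rng = np.random.default_rng(2)
        density = rng.uniform(0, 1, size=(101, 101))
        kernels = [DensityKernel("cgA", density, (1, 1)),
                   DensityKernel("cgB", density.copy(), (1, 1))]
        model = KernelModel(grid, kernels, np.array([2.0, -1.0]))
        profile, _ = joint_density_profile(model, {"cgA": 30.0, "cgB": 30.0})
        np.testing.assert_allclose(profile, density[30], atol=1e-12)

    def test_matches_brute_force_loop_for_27_cpgs(self):
        model = random_model(27, seed=9)
        rng = np.random.default_rng(10)
        dnam = {c: rng.uniform(0, 100) for c in model.cpg_ids}
        profile, _ = joint_density_profile(model, dnam, use_weights=True)
        oracle = np.zeros(101)
        for i in range(101):
            for k, kernel in enumerate(model.kernels):
                row = int(np.floor(dnam[kernel.cpg_id] + 0.5))
                oracle[i] += model.weights[k] * kernel.density[row, i]
        np.testing.assert_allclose(profile, oracle, atol=1e-12)

    def test_missing_cpgs_skipped_and_counted(self):
        model = random_model(3, seed=3)
        profile, n = joint_density_profile(
            model, {"cg00000000": 40.0, "cg00000001": np.nan})
        assert n == 1
        with pytest.raises(ValueError, match="no signature CpG"):
            joint_density_profile(model, {})


class TestPredictAge:
    def test_argmax_and_flat_tie_rule(self):
        density = np.zeros((101, 101))
        density[50, 40] = 5.0
        density[50, 90] = 3.0
        model = single_kernel_model(density + 1e-12)
        assert predict_age(model, {"cgTOY00001": 50.0}) == 40
        flat = single_kernel_model(np.ones((101, 101)))
        assert predict_age(flat, {"cgTOY00001": 10.0}) == 0

    def test_negative_weight_flips_argmax_to_profile_minimum(self):
        # 2-age toy enumerable by hand: row densities (1, 3) over ages {0, 1}
        grid = GridSpec(age_min=0, age_max=1, dnam_min=0, dnam_max=1,
                        n_points=2)
        density = np.array([[1.0, 3.0], [1.0, 3.0]])
        k = DensityKernel("cgT", density, (1.0, 1.0))
        plus = KernelModel(grid, [k], np.array([1.0]))
        minus = KernelModel(grid, [k], np.array([-1.0]))
        assert predict_age(plus, {"cgT": 0.0}) == 1    # max of (1, 3)
        assert predict_age(minus, {"cgT": 0.0}) == 0   # max of (-1, -3)

    def test_all_ones_weights_equal_unweighted(self):
        model = random_model(5, seed=7).with_weights(np.ones(5))
        rng = np.random.default_rng(8)
        for _ in range(20):
            dnam = {c: rng.uniform(0, 100) for c in model.cpg_ids}
            assert predict_age(model, dnam, True) == predict_age(model, dnam, False)

    def test_positive_weight_scaling_changes_nothing(self):
        model = random_model(4, seed=11)
        scaled = model.with_weights(model.weights * 0.37)
        rng = np.random.default_rng(12)
        for _ in range(10):
            dnam = {c: rng.uniform(0, 100) for c in model.cpg_ids}
            assert predict_age(model, dnam) == predict_age(scaled, dnam)
            p1, _ = probability_vector(model, dnam)
            p2, _ = probability_vector(scaled, dnam)
            np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestProbabilityVector:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_sums_to_one(self, seed):
        model = random_model(3, seed=seed % 1000)
        rng = np.random.default_rng(seed)
        dnam = {c: rng.uniform(0, 100) for c in model.cpg_ids}
        p, _ = probability_vector(model, dnam, use_weights=False)
        assert abs(p.sum() - 1.0) < 1e-9
        assert np.all(p >= 0)
        pw, _ = probability_vector(model.with_weights(np.abs(model.weights)),
                                   dnam, use_weights=True)
        assert abs(pw.sum() - 1.0) < 1e-9

    def test_single_unweighted_cpg_proportional_to_row(self):
        model = random_model(1, seed=2)
        p, floored = probability_vector(model, {"cg00000000": 60.0},
                                        use_weights=False)
        row = model.kernels[0].density[60]
        np.testing.assert_allclose(p, row / row.sum(), atol=1e-12)
        assert not floored

    def test_negative_entries_floored_and_flagged(self):
        density = np.ones((101, 101))
        density[50, 10] = 5.0
        grid = GridSpec()
        kernels = [DensityKernel("cgA", density, (1, 1)),
                   DensityKernel("cgB", np.ones((101, 101)), (1, 1))]
        model = KernelModel(grid, kernels, np.array([1.0, -1.5]))
        # profile = row_A - 1.5: equals -0.5 except +3.5 at age 10
        p, floored = probability_vector(model, {"cgA": 50.0, "cgB": 50.0})
        assert floored
        assert p[0] == 0.0 and p[10] == pytest.approx(1.0)
        # argmax still works on the raw signed profile
        assert predict_age(model, {"cgA": 50.0, "cgB": 50.0}) == 10

    def test_no_positive_mass_errors(self):
        model = single_kernel_model(np.ones((101, 101)), weight=-1.0)
        with pytest.raises(ValueError, match="no positive mass"):
            probability_vector(model, {"cgTOY00001": 50.0})


class TestFineProbability:
    def test_uniform_stays_uniform(self):
        f = fine_probability(np.full(101, 1 / 101))
        np.testing.assert_allclose(f, 1 / 1001, atol=1e-15)
        assert f.size == 1001

    def test_point_mass_becomes_normalized_tent(self):
        p = np.zeros(101)
        p[40] = 1.0
        f = fine_probability(p)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(f[:390] == 0) and np.all(f[411:] == 0)
        assert np.argmax(f) == 400

    def test_values_at_knots_proportional_to_input(self):
        rng = np.random.default_rng(6)
        p = rng.dirichlet(np.ones(101))
        f = fine_probability(p)
        knots = f[::10]
        np.testing.assert_allclose(knots / knots.sum(), p, atol=1e-12)


def brute_force_moments(p, mode="consistent"):
    """Independent loop implementation of the fine-grid moments."""
    knots = np.arange(101) * 10.0
    f = np.array([np.interp(x, knots, p) for x in range(1001)])
    if mode == "consistent":
        f = f / f.sum()
        mean = sum(f[x] * x / 10 for x in range(1001))
        var = sum(f[x] * (x / 10 - mean) ** 2 for x in range(1001))
    else:
        mean = 0.1 * sum(f[x] * x for x in range(1001))
        var = 0.1 * sum(f[x] * (0.1 * x - mean) ** 2 for x in range(1001))
    return mean, var


class TestVariationScore:
    def test_point_mass_mean_exact_spread_bounded_by_interpolation(self):
        p = np.zeros(101)
        p[40] = 1.0
        v = variation_score(p, predicted_age=40)
        m, var = brute_force_moments(p)
        assert v.mean == pytest.approx(40.0, abs=1e-12)
        assert v.variance == pytest.approx(var, abs=1e-9)
        # interpolation turns the spike into a +/-1-year tent; spread stays
        # below half a year rather than exactly zero
        assert v.variation_score < 0.5

    def test_two_point_distribution(self):
        p = np.zeros(101)
        p[20] = p[60] = 0.5
        v = variation_score(p)
        m, var = brute_force_moments(p)
        assert v.mean == pytest.approx(40.0, abs=1e-12)
        assert v.variation_score == pytest.approx(20.0, abs=0.01)
        assert v.variance == pytest.approx(var, abs=1e-9)

    def test_uniform_matches_discrete_closed_form(self):
        p = np.full(101, 1 / 101)
        v = variation_score(p)
        closed = 0.1 * np.sqrt((1001 ** 2 - 1) / 12)
        m, var = brute_force_moments(p)
        assert v.variation_score == pytest.approx(closed, abs=1e-6)
        assert v.variance == pytest.approx(var, abs=1e-9)

    def test_literal_mode_reproduces_printed_arithmetic(self):
        rng = np.random.default_rng(13)
        p = rng.dirichlet(np.ones(101))
        v = variation_score(p, mode="literal")
        m, var = brute_force_moments(p, mode="literal")
        assert v.mean == pytest.approx(m, rel=1e-9)
        assert v.variance == pytest.approx(var, rel=1e-9)

    def test_interval_centered_on_predicted_age(self):
        p = np.full(101, 1 / 101)
        v = variation_score(p, predicted_age=50)
        lo, hi = v.interval
        assert lo == pytest.approx(50 - v.variation_score)
        assert hi == pytest.approx(50 + v.variation_score)
        assert lo <= hi


class TestPredictSamples:
    def test_variation_score_ignores_weights(self, toy_model):
        rng = np.random.default_rng(14)
        vals = rng.uniform(10, 90, size=(3, 8))
        matrix = make_matrix(vals, cpg_ids=toy_model.cpg_ids)
        reweighted = toy_model.with_weights(np.array([9.0, -3.0, 0.5]))
        a = predict_samples(toy_model, matrix)
        b = predict_samples(reweighted, matrix)
        np.testing.assert_allclose(a["variation_score"], b["variation_score"],
                                   atol=1e-12)

    def test_output_schema_and_delta(self, toy_model):
        matrix = make_matrix(np.full((3, 2), 50.0), cpg_ids=toy_model.cpg_ids)
        samples = make_samples([40.0, 60.0])
        out = predict_samples(toy_model, matrix, samples)
        assert set(out.columns) >= {"sample_id", "predicted_age", "delta_age",
                                    "variation_score", "interval_lo",
                                    "interval_hi", "n_cpgs_used", "floored"}
        np.testing.assert_allclose(
            out["delta_age"], out["predicted_age"] - out["chronological_age"])
        assert out["predicted_age"].between(0, 100).all()

    def test_absent_signature_cpg_named(self, toy_model):
        matrix = make_matrix(np.full((2, 2), 50.0),
                             cpg_ids=toy_model.cpg_ids[:2])
        with pytest.raises(KeyError, match=toy_model.cpg_ids[2]):
            predict_samples(toy_model, matrix)


class TestCoverage:
    @staticmethod
    def frame(deltas, scores):
        return pd.DataFrame({"delta_age": deltas, "variation_score": scores})

    def test_exact_predictions_cover_fully(self):
        assert coverage_fraction(self.frame([0.0, 0.0], [1.0, 0.0])) == 1.0

    def test_counting(self):
        f = self.frame([1.0, 5.0, -2.0, 0.0], [2.0, 2.0, 3.0, 1.0])
        assert coverage_fraction(f) == 0.75

    def test_adding_covered_sample_never_decreases_numerator(self):
        base = self.frame([5.0, 1.0], [2.0, 2.0])
        more = self.frame([5.0, 1.0, 0.0], [2.0, 2.0, 0.0])
        assert (coverage_fraction(more) * 3) >= (coverage_fraction(base) * 2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            coverage_fraction(self.frame([], []))
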