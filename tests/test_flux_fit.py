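"""Weighted least-squares estimation, profiling, sharing and Monte Carlo.

These tests run on deliberately small fit problems (FM design, 30-min
Euler steps, a handful of free parameters) so the whole file stays fast;
the full-scale parameter-recovery and coverage checks live in the
acceptance suite.
"""

import numpy as np
import pytest

from leakyflux.flux_fit import (
    DatasetSpec,
    FitProblem,
    Parameter,
    classify_reversibility,
    estimate,
    joint_fit_shared,
    monte_carlo_errors,
    profile_ci,
    weighted_ssr,
)
from leakyflux.fluxes import ratio_to_u
from leakyflux.synthetic_data import (
    ANALYTE_TO_POOL,
    PRESETS,
    central_label_input,
    central_true_fluxes,
    generate,
    load_fixture_model,
)

TRUTH = central_true_fluxes()
STEP = 30.0


def small_problem(presets=("FM",), parameters=None, seed=1, add_noise=False,
                  row_filter=None, base_fluxes=None):
    """FM-style problem with few free parameters and a coarse Euler grid."""
    model = load_fixture_model("central_carbon")
    datasets = []
    for preset in presets:
        design = PRESETS[preset]
        ms, _ = generate(design, TRUTH, seed=seed, step_min=STEP,
                         add_noise=add_noise)
        if row_filter is not None:
            ms.data = ms.data[row_filter(ms.data)].reset_index(drop=True)
        datasets.append(DatasetSpec(
            name=preset,
            measurements=ms,
            config=design.sim_config(STEP),
            label_input=central_label_input(design.glucose_labelled_fraction),
            initial_conc=dict(design.initial_conc),
            analyte_map=dict(ANALYTE_TO_POOL),
        ))
    if parameters is None:
        parameters = [
            Parameter("v_LACX", "free_flux", "LACX", (0.05, 3.0)),
            Parameter("u_LACX", "exchange_u", "LACX", (0.0, 1.0)),
        ]
    return FitProblem(model, datasets, parameters, base_fluxes or TRUTH)


def x_truth(problem):
    from conftest import true_param_vector

    return true_param_vector(problem, TRUTH)


class TestWeightedSSR:
    def test_simulation_fitted_to_itself_is_zero(self):
        prob = small_problem()
        assert weighted_ssr(x_truth(prob), prob) == pytest.approx(0.0, abs=1e-16)

    def test_single_residual_of_one_sigma_contributes_one(self):
        prob = small_problem()
        df = prob.datasets[0].measurements.data
        idx = df.index[(df["quantity"] == "M3") & (df["metabolite"] == "lactate")][2]
        df.loc[idx, "value"] += df.loc[idx, "sigma"]  # exactly one sigma off
        prob._build_alignment()
        assert weighted_ssr(x_truth(prob), prob) == pytest.approx(1.0, abs=1e-9)

    def test_doubling_sigma_quarters_contributions(self):
        prob = small_problem(add_noise=True, seed=9)
        ssr1 = weighted_ssr(x_truth(prob), prob)
        prob.datasets[0].measurements.data["sigma"] *= 2.0
        prob._build_alignment()
        ssr2 = weighted_ssr(x_truth(prob), prob)
        assert ssr2 == pytest.approx(ssr1 / 4.0, rel=1e-12)

    def test_infeasible_parameters_hit_penalty(self):
        prob = small_problem()
        x = x_truth(prob)
        x[0] = 3.0  # net lactate efflux so large the pool empties glucose
        res = prob.residuals(np.array([3.0, 0.999]))
        assert np.all(np.isfinite(res))


class TestEstimate:
    def test_recovery_and_determinism_on_noiseless_data(self):
        prob = small_problem()
        res1 = estimate(prob, n_starts=3, seed=42)
        res2 = estimate(prob, n_starts=3, seed=42)
        np.testing.assert_array_equal(res1.x, res2.x)
        np.testing.assert_allclose(res1.x, x_truth(prob), rtol=1e-5)
        assert res1.ssr == pytest.approx(0.0, abs=1e-12)

    def test_optimum_not_worse_than_truth(self):
        prob = small_problem(add_noise=True, seed=3)
        res = estimate(prob, n_starts=3, seed=0)
        assert res.ssr <= weighted_ssr(x_truth(prob), prob) + 1e-9

    def test_unidentified_parameter_is_flagged(self):
        """With the pyruvate channel removed from the data (and no pyruvate
        backflux in the model), the pyruvate pool's initial concentration
        has no leverage on the residuals and the rank check names it."""
        params = [
            Parameter("v_LACX", "free_flux", "LACX", (0.05, 3.0)),
            Parameter("c0_PYR_x", "init_conc", "PYR_x", (0.01, 2.0), shared=False),
        ]
        prob = small_problem(
            parameters=params,
            row_filter=lambda df: df["metabolite"] != "pyruvate",
            base_fluxes=central_true_fluxes(pyruvate_exchange_ratio=0.0),
        )
        with pytest.warns(UserWarning, match="weakly identified"):
            res = estimate(prob, n_starts=1, x0=x_truth(prob))
        assert any("c0_PYR_x" in n for n in res.weakly_identified)


@pytest.fixture(scope="module")
def fitted():
    prob = small_problem(add_noise=True, seed=5)
    res = estimate(prob, n_starts=1, x0=x_truth(prob))
    return prob, res


class TestProfileCI:
    def test_bounds_sit_at_the_threshold_crossing(self, fitted):
        prob, res = fitted
        ci = profile_ci(prob, res, "v_LACX", threshold=3.84, tol_rel=1e-3)
        assert ci.lower < res["v_LACX"] < ci.upper
        for bound in (ci.lower, ci.upper):
            fixed = prob.with_fixed("v_LACX", bound)
            refit = estimate(fixed, n_starts=1, identifiability_check=False)
            assert refit.ssr - res.ssr == pytest.approx(3.84, abs=0.15)

    def test_zero_threshold_degenerates_to_point(self, fitted):
        prob, res = fitted
        ci = profile_ci(prob, res, "u_LACX", threshold=0.0)
        assert ci.lower == ci.upper == res["u_LACX"]

    def test_negative_threshold_rejected(self, fitted):
        prob, res = fitted
        with pytest.raises(ValueError):
            profile_ci(prob, res, "u_LACX", threshold=-1.0)

    def test_ratio_transform_is_monotone(self, fitted):
        prob, res = fitted
        ci = profile_ci(prob, res, "u_LACX", threshold=3.84, tol_rel=5e-3)
        r = ci.to_ratio()
        assert r.lower <= r.estimate <= (np.inf if r.upper_unbounded else r.upper)


class TestJointFit:
    def test_identical_datasets_give_zero_delta(self):
        """Sharing a parameter across two copies of the same dataset cannot
        degrade the fit."""
        model = load_fixture_model("central_carbon")
        design = PRESETS["FM"]
        ms, _ = generate(design, TRUTH, seed=7, step_min=STEP, add_noise=True)
        datasets = [
            DatasetSpec(name, ms, design.sim_config(STEP),
                        central_label_input(design.glucose_labelled_fraction),
                        dict(design.initial_conc), dict(ANALYTE_TO_POOL))
            for name in ("rep1", "rep2")
        ]
        params = [
            Parameter("v_LACX", "free_flux", "LACX", (0.05, 3.0)),
            Parameter("u_LACX", "exchange_u", "LACX", (0.0, 1.0), shared=False),
        ]
        prob = FitProblem(model, datasets, params, TRUTH)
        outcome = joint_fit_shared(prob, ["u_LACX"], n_starts=2, seed=0)
        assert abs(outcome.delta_ssr) < 1e-3
        assert not outcome.different_required

    def test_unknown_parameter_rejected(self):
        prob = small_problem()
        with pytest.raises(KeyError):
            joint_fit_shared(prob, ["nonexistent"])


class TestMonteCarlo:
    def test_errors_vanish_as_sigma_vanishes(self):
        prob = small_problem(add_noise=False)
        prob.datasets[0].measurements.data["sigma"] *= 1e-6
        prob._build_alignment()
        res = estimate(prob, n_starts=1, x0=x_truth(prob))
        mc = monte_carlo_errors(prob, res, n=5, seed=0)
        assert all(se < 1e-4 for se in mc.standard_errors.values())

    def test_errors_scale_with_noise_and_are_deterministic(self):
        prob = small_problem(add_noise=True, seed=2)
        res = estimate(prob, n_starts=1, x0=x_truth(prob))
        mc1 = monte_carlo_errors(prob, res, n=8, seed=11)
        mc1b = monte_carlo_errors(prob, res, n=8, seed=11)
        assert mc1.standard_errors == mc1b.standard_errors
        # double every sigma: corrupted datasets scatter twice as much
        prob2 = small_problem(add_noise=True, seed=2)
        for ds in prob2.datasets:
            ds.measurements.data["sigma"] *= 2.0
        prob2._build_alignment()
        res2 = estimate(prob2, n_starts=1, x0=x_truth(prob2))
        mc2 = monte_carlo_errors(prob2, res2, n=8, seed=11)
        for name in mc1.standard_errors:
            ratio = mc2.standard_errors[name] / mc1.standard_errors[name]
            assert ratio == pytest.approx(2.0, rel=0.6)

    def test_corruption_is_plain_gaussian_at_each_sigma(self):
        """Monte Carlo corruption perturbs every value independently with
        its own sigma — the same error model the objective weights assume."""
        from leakyflux.flux_fit import _corrupt

        prob = small_problem(add_noise=False)
        ms = prob.datasets[0].measurements
        devs = []
        for seed in range(300):
            corrupted = _corrupt(ms, np.random.default_rng(seed))
            z = (corrupted.data["value"] - ms.data["value"]) / ms.data["sigma"]
            devs.append(z.to_numpy())
        z = np.concatenate(devs)
        assert np.std(z) == pytest.approx(1.0, rel=0.05)
        assert abs(np.mean(z)) < 0.02


class TestClassification:
    @pytest.mark.parametrize("r, lo, hi, unbounded, expected", [
        (0.01, 0.001, 0.04, False, "irreversible"),
        (312.0, 25.0, 400.0, True, "fully reversible"),
        (4.0, 2.3, 5.2, False, "partially reversible"),
        (4.0, 2.3, 30.0, False, "indeterminate"),
        (0.04, 0.01, 0.2, False, "indeterminate"),
    ])
    def test_labels(self, r, lo, hi, unbounded, expected):
        assert classify_reversibility(r, lo, hi, upper_unbounded=unbounded) == expected

    def test_figure_caption_preset(self):
        from leakyflux.flux_fit import REVERSIBILITY_PRESETS

        assert classify_reversibility(
            30.0, 22.0, 60.0, reversible_min=REVERSIBILITY_PRESETS["figure_caption"]
        ) == "indeterminate"
        assert classify_reversibility(30.0, 22.0, 60.0) == "fully reversible"

    def test_estimate_outside_ci_rejected(self):
        with pytest.raises(ValueError):
            classify_reversibility(1.0, 2.0, 3.0)
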