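"""Objective, start sampling, acceptance and identifiability diagnostics."""

import numpy as np
import pandas as pd
import pytest

from tfpi_tmdd.fitting import (
    DEFAULT_RANGES,
    OPTIMIZED_PARAMETERS,
    FitProblem,
    FitResult,
    accept_sets,
    fit_multistart,
    profile_identifiability,
    sample_starts,
    ssr,
)
from tfpi_tmdd.synthetic import generate, group_means, monkey_design


def _make_problem(monkey, thin=True, **kwargs):
    design = monkey_design(noise_cv=0.0, n_animals=1, seed=0)
    means = group_means(generate(design, monkey))
    if thin:
        # keep two informative groups and a sparse schedule: fast, still
        # well-posed enough for optimizer mechanics
        keep = means["group"].isin(["monkey_iv_17.2", "monkey_sc_68.8"])
        means = means.loc[keep & means["time_days"].isin([0.0417, 0.5, 2, 7, 21, 42])]
    regimens = {
        f"monkey_{g.route}_{g.dose_nmol_per_kg:g}": design.regimen(g)
        for g in design.groups
    }
    return FitProblem(
        observations=means.reset_index(drop=True),
        regimens=regimens,
        fixed={"BW": 3.5, "KD": 0.04665},
        **kwargs,
    )


class TestSsr:
    def test_perfect_prediction(self):
        assert ssr([1.0, 5.0], [1.0, 5.0]) == 0.0

    def test_one_decade_is_unity(self):
        assert ssr([10.0], [100.0]) == pytest.approx(1.0)

    def test_hand_computed_pairs(self):
        # two residuals of one doubling each: 2 * log10(2)^2
        assert ssr([1.0, 100.0], [2.0, 50.0]) == pytest.approx(0.18124, abs=5e-5)

    def test_order_invariance(self):
        a = ssr([1.0, 2.0, 3.0], [1.1, 2.2, 2.7])
        b = ssr([3.0, 1.0, 2.0], [2.7, 1.1, 2.2])
        assert a == pytest.approx(b)

    def test_common_rescaling_invariance(self):
        obs = np.array([1.0, 7.0, 30.0])
        pred = np.array([1.4, 6.0, 45.0])
        assert ssr(3.7 * obs, 3.7 * pred) == pytest.approx(ssr(obs, pred))

    def test_non_positive_prediction_floored_not_fatal(self):
        val = ssr([1.0], [0.0])
        assert np.isfinite(val) and val == pytest.approx(144.0)  # (log10 1e-12)^2


class TestSampleStarts:
    def test_within_ranges_and_deterministic(self, monkey):
        prob = _make_problem(monkey)
        a = sample_starts(prob, 200, seed=5)
        b = sample_starts(prob, 200, seed=5)
        assert np.array_equal(a, b)
        for j, name in enumerate(OPTIMIZED_PARAMETERS):
            lo, hi = DEFAULT_RANGES[name]
            vals = 10.0 ** a[:, j]
            assert vals.min() >= lo and vals.max() <= hi

    def test_degenerate_range_gives_constant(self, monkey):
        ranges = dict(DEFAULT_RANGES)
        ranges["V2"] = (0.1112, 0.1112)
        prob = _make_problem(monkey, ranges=ranges)
        a = sample_starts(prob, 50, seed=0)
        j = OPTIMIZED_PARAMETERS.index("V2")
        assert np.allclose(10.0 ** a[:, j], 0.1112)


class TestAcceptSets:
    def test_all_equal_all_accepted(self):
        thr, mask = accept_sets(np.full(20, 2.5))
        assert mask.all() and thr == 2.5

    def test_sharp_jump_cuts_at_cluster_boundary(self):
        ssrs = np.array([1.0, 1.0, 1.0, 1.0, 100.0, 100.0] + [100.0] * 6)
        thr, mask = accept_sets(np.sort(ssrs))
        assert mask[:4].all() and not mask[4:].any()
        assert thr == 1.0

    def test_moderate_outlier_inside_elbow_cluster_removed_by_grubbs(self):
        # the elbow keeps everything below the 100s, including a 1.3 that
        # only the Grubbs pass can remove from the tight cluster at 1.0
        ssrs = np.array([1.0] * 28 + [1.3] + [100.0] * 3)
        thr, mask = accept_sets(ssrs)
        assert not mask[-3:].any()
        assert not mask[28]
        assert mask[:28].all()
        assert thr == 1.0

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            accept_sets(np.array([3.0, 1.0] * 10))

    def test_few_sets_kept_with_warning(self):
        with pytest.warns(UserWarning):
            thr, mask = accept_sets(np.array([1.0, 2.0, 3.0]))
        assert mask.all()


class TestGaussNewtonRefinement:
    def test_refinement_reduces_ssr_and_is_deterministic(self, monkey):
        prob = _make_problem(monkey, n_starts=6, n_iterations=25, seed=3)
        fit1 = fit_multistart(prob)
        fit2 = fit_multistart(prob)
        assert np.array_equal(fit1.ssrs, fit2.ssrs)
        assert np.array_equal(fit1.log10_sets, fit2.log10_sets)
        # every terminal SSR is no worse than its start's initial SSR
        from tfpi_tmdd.fitting import _Objective

        obj = _Objective(prob)
        starts = sample_starts(prob, prob.n_starts, prob.seed)
        init_best = min(obj.ssr(x) for x in starts)
        assert fit1.ssrs[0] <= init_best

    def test_single_group_rejected(self, monkey):
        prob = _make_problem(monkey)
        single = prob.observations[prob.observations["group"] == "monkey_iv_17.2"]
        with pytest.raises(ValueError):
            fit_multistart(
                FitProblem(
                    observations=single.reset_index(drop=True),
                    regimens=prob.regimens,
                    fixed=prob.fixed,
                    n_starts=2,
                )
            )


def _synthetic_fit_result(monkey, log10_col, ssrs, threshold=None):
    """FitResult scaffold whose first column carries a constructed profile."""
    n = len(ssrs)
    sets = np.tile(np.log10([DEFAULT_RANGES[k][0] * 10 for k in OPTIMIZED_PARAMETERS]), (n, 1))
    sets[:, 0] = log10_col
    order = np.argsort(ssrs)
    prob = _make_problem(monkey, n_starts=n)
    return FitResult(
        problem=prob,
        log10_sets=sets[order],
        ssrs=np.asarray(ssrs, float)[order],
        iterations=np.zeros(n, int),
        accepted=np.ones(n, bool),
        threshold=float(threshold if threshold is not None else max(ssrs)),
        n_failed=0,
    )


class TestProfileIdentifiability:
    def test_sharp_quadratic_profile_is_identifiable(self, monkey):
        x = np.linspace(-1, 1, 60)
        fit = _synthetic_fit_result(monkey, x, 0.5 + 50 * x**2, threshold=1.0)
        _, label = profile_identifiability(fit, "CL_D")
        assert label == "identifiable"

    def test_flat_profile_over_decades_is_non_identifiable(self, monkey):
        x = np.linspace(-6, 2, 60)  # parameter value spans 8 decades
        fit = _synthetic_fit_result(monkey, x, np.full(60, 0.5), threshold=1.0)
        _, label = profile_identifiability(fit, "CL_D")
        assert label == "non-identifiable"

    def test_two_separated_minima_is_non_identifiable(self, monkey):
        x = np.linspace(-1, 1, 61)
        ssrs = 1.0 + 40 * (x**2 - 0.25) ** 2  # minima at x = +/- 0.5
        fit = _synthetic_fit_result(monkey, x, ssrs, threshold=2.0)
        _, label = profile_identifiability(fit, "CL_D")
        assert label == "non-identifiable"

    def test_unknown_parameter_rejected(self, monkey):
        fit = _synthetic_fit_result(monkey, np.zeros(10), np.ones(10))
        with pytest.raises(KeyError):
            profile_identifiability(fit, "BW")
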