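"""Decision tree and lifetime extension, checked against independent oracles
(closed-form geometric sums and a Monte-Carlo microsimulation)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffrcea.config import ParamWithSE, UtilitySchedule
from ffrcea.decision_model import (
    apply_or,
    discounted_year_sum,
    discounted_years,
    evaluate_tree,
    lifetime_extension,
    run_model,
)


class TestApplyOr:
    def test_identity_or(self):
        assert apply_or(0.09, 1.0) == pytest.approx(0.09)

    def test_hand_computed_values(self):
        assert apply_or(0.09, 3.80) == pytest.approx(0.2731629, abs=1e-6)
        assert apply_or(0.5, 2.0) == pytest.approx(2.0 / 3.0)

    def test_boundary_baselines_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                apply_or(bad, 2.0)
        with pytest.raises(ValueError):
            apply_or(0.2, 0.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=1.01, max_value=2.0),
    )
    def test_strictly_increasing_in_or_and_baseline(self, base, or_, factor):
        assert apply_or(base, or_ * factor) > apply_or(base, or_)
        if base * factor < 1.0:
            assert apply_or(base * factor, or_) > apply_or(base, or_)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(min_value=0.01, max_value=0.99), st.floats(min_value=0.1, max_value=10.0))
    def test_round_trip_through_odds(self, base, or_):
        risk = apply_or(base, or_)
        implied_or = (risk / (1 - risk)) / (base / (1 - base))
        assert implied_or == pytest.approx(or_, rel=1e-9)


class TestDiscountedYears:
    def test_zero_rate_sums_to_total(self):
        assert discounted_years(7.3, 0.0).sum() == pytest.approx(7.3)

    def test_two_years_closed_form(self):
        w = discounted_years(2.0, 0.035)
        assert w.sum() == pytest.approx(1 / 1.035 + 1.035**-2)
        assert w.sum() == pytest.approx(1.89969, abs=1e-5)

    def test_zero_years_empty(self):
        assert len(discounted_years(0.0, 0.035)) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discounted_years(5.0, -0.01)

    def test_weights_strictly_decreasing(self):
        w = discounted_years(6.0, 0.035)
        assert (np.diff(w) < 0).all()

    @pytest.mark.parametrize("years", [0.0, 0.4, 1.0, 2.5, 5.96, 10.7])
    @pytest.mark.parametrize("rate", [0.0, 0.035, 0.1])
    def test_closed_form_matches_weight_sum(self, years, rate):
        assert discounted_year_sum(years, rate) == pytest.approx(discounted_years(years, rate).sum())


def _oracle_extension(years, rate, annual, utility_fn, decrement, starting_age):
    """Independent year-by-year rollout of the post-trial tariff."""
    cost = qaly = 0.0
    remaining, t, k = years, 2, 0
    while remaining > 1e-12:
        frac = min(1.0, remaining)
        w = frac * (1 + rate) ** -(t - 1)
        cost += annual * w
        qaly += w * max(0.0, utility_fn(starting_age + 1 + k) + decrement)
        remaining -= frac
        t += 1
        k += 1
    return cost, qaly


class TestLifetimeExtension:
    def test_zero_life_expectancy(self, model_params):
        p = model_params.model_copy(
            update={
                "life_expectancy_mace": ParamWithSE(mean=0.0, se=0.0),
                "life_expectancy_no_mace": ParamWithSE(mean=0.0, se=0.0),
            }
        )
        assert lifetime_extension(True, p) == (0.0, 0.0)

    def test_no_mace_constant_utility_geometric_sum(self, model_params):
        # 5.96 years at 3.5%, GBP 423/year, utility fixed at 0.8
        p = model_params.model_copy(
            update={"utility_schedule": UtilitySchedule(base=0.8, base_age=63.0, slope_per_year=0.0)}
        )
        cost, qaly = lifetime_extension(False, p)
        v = 1 / 1.035
        s = sum(v**k for k in range(1, 6)) + 0.96 * v**6
        assert s == pytest.approx(5.29601, abs=1e-5)
        assert cost == pytest.approx(423 * s)
        assert qaly == pytest.approx(0.8 * s)

    def test_decrement_linearity(self, model_params):
        p0 = model_params.model_copy(
            update={"mace_utility_decrement": ParamWithSE(mean=0.0, se=0.0)}
        )
        p5 = model_params.model_copy(
            update={"mace_utility_decrement": ParamWithSE(mean=-0.05, se=0.0)}
        )
        _, q0 = lifetime_extension(True, p0)
        _, q5 = lifetime_extension(True, p5)
        le_mace, _ = model_params.life_expectancies()
        assert q0 - q5 == pytest.approx(0.05 * discounted_years(le_mace, 0.035).sum())

    def test_matches_independent_rollout(self, model_params):
        for mace in (True, False):
            got = lifetime_extension(mace, model_params)
            le = model_params.life_expectancies()[0 if mace else 1]
            want = _oracle_extension(
                le,
                0.035,
                model_params.annual_cost_post_year1.mean,
                lambda a: float(model_params.utility_schedule(a)),
                model_params.mace_utility_decrement.mean if mace else 0.0,
                model_params.starting_age,
            )
            assert got[0] == pytest.approx(want[0])
            assert got[1] == pytest.approx(want[1])

    def test_swap_flag_exchanges_life_expectancies(self, model_params):
        swapped = model_params.model_copy(update={"swap_life_expectancy": True})
        assert lifetime_extension(True, swapped)[0] == pytest.approx(
            _oracle_extension(5.96, 0.035, 423.0, lambda a: float(model_params.utility_schedule(a)), -0.05, 62.0)[0]
        )


def _random_params(model_params, seed):
    rng = np.random.default_rng(seed)
    probs = {}
    for arm in ("standard", "ffr"):
        v = rng.dirichlet([5, 10, 2])
        probs[arm] = tuple(v)
    cells = {
        cell: ParamWithSE(mean=float(rng.uniform(2000, 25000)), se=0.0)
        for cell in model_params.branch_costs
    }
    return model_params.model_copy(
        update={
            "treatment_probs": probs,
            "mace_mt": ParamWithSE(mean=float(rng.uniform(0.02, 0.4)), se=0.0),
            "or_pci": model_params.or_pci.model_copy(update={"mean": float(rng.uniform(0.5, 3.0))}),
            "or_cabg": model_params.or_cabg.model_copy(update={"mean": float(rng.uniform(0.5, 6.0))}),
            "branch_costs": cells,
            "wire_cost_ffr": ParamWithSE(mean=float(rng.uniform(0, 500)), se=0.0),
        }
    )


class TestEvaluateTree:
    def test_degenerate_all_mt_no_mace(self, model_params):
        p = model_params.model_copy(
            update={
                "treatment_probs": {"standard": (1.0, 0.0, 0.0), "ffr": (1.0, 0.0, 0.0)},
                "mace_mt": ParamWithSE(mean=0.0, se=0.0),
            }
        )
        cost, _, p_mace = evaluate_tree(p, "standard")
        assert cost == pytest.approx(5819.0)
        assert p_mace == 0.0

    def test_wire_only_difference(self, model_params):
        p = model_params.model_copy(
            update={
                "treatment_probs": {
                    "standard": model_params.treatment_probs["standard"],
                    "ffr": model_params.treatment_probs["standard"],
                },
                "wire_cost_ffr": ParamWithSE(mean=279.0, se=0.0),
            }
        )
        c_std, _, _ = evaluate_tree(p, "standard")
        c_ffr, _, _ = evaluate_tree(p, "ffr")
        assert c_ffr - c_std == pytest.approx(279.0)

    def test_cell_probabilities_conserve(self, model_params):
        for arm in ("standard", "ffr"):
            probs = np.array(model_params.treatment_probs[arm])
            base = model_params.mace_mt.mean
            risks = np.array(
                [base, apply_or(base, 1.01), apply_or(base, 3.80)]
            )
            cells = np.concatenate([probs * risks, probs * (1 - risks)])
            assert cells.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_tree_matches_microsimulation(self, model_params, seed):
        """Expected tree values agree with a seeded Monte-Carlo rollout."""
        p = _random_params(model_params, seed)
        n = 200_000
        rng = np.random.default_rng(1000 + seed)
        for arm in ("standard", "ffr"):
            cost_tree, _, p_mace_tree = evaluate_tree(p, arm)
            dec = rng.choice(3, n, p=np.array(p.treatment_probs[arm]))
            base = p.mace_mt.mean
            odds = base / (1 - base) * np.array([1.0, p.or_pci.mean, p.or_cabg.mean])
            risks = odds / (1 + odds)
            r = risks[dec]
            mace = rng.random(n) < r
            cell_cost = np.empty(n)
            for j, d in enumerate(("MT", "PCI", "CABG")):
                cell_cost[dec == j] = np.where(
                    mace[dec == j],
                    p.branch_costs[f"{d}_mace"].mean,
                    p.branch_costs[f"{d}_no_mace"].mean,
                )
            if arm == "ffr":
                cell_cost = cell_cost + p.wire_cost_ffr.mean
            assert abs(cost_tree - cell_cost.mean()) < 3 * cell_cost.std() / np.sqrt(n)
            assert abs(p_mace_tree - mace.mean()) < 3 * mace.std() / np.sqrt(n)


class TestRunModel:
    def test_identical_arms_give_zero_increments(self, model_params):
        p = model_params.model_copy(
            update={
                "treatment_probs": {
                    "standard": model_params.treatment_probs["standard"],
                    "ffr": model_params.treatment_probs["standard"],
                },
                "branch_qalys": {
                    "standard": ParamWithSE(mean=0.8, se=0.0),
                    "ffr": ParamWithSE(mean=0.8, se=0.0),
                },
                "wire_cost_ffr": ParamWithSE(mean=0.0, se=0.0),
            }
        )
        inc = run_model(p)["incremental"]
        assert all(v == pytest.approx(0.0) for v in inc.values())

    def test_lifetime_exceeds_trial_qalys(self, model_params):
        res = run_model(model_params)
        for arm in ("standard", "ffr"):
            assert res[arm].lifetime_qaly > res[arm].trial_qaly
            assert res[arm].lifetime_cost > res[arm].trial_cost

    def test_no_discounting_increases_lifetime_qalys(self, model_params):
        undiscounted = model_params.model_copy(update={"discount_rate": 0.0})
        assert (
            run_model(undiscounted)["ffr"].lifetime_qaly
            > run_model(model_params)["ffr"].lifetime_qaly
        )
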