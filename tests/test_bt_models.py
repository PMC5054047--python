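"""Bradley-Terry likelihood, fitting, and nested model comparison."""

import numpy as np
import pytest

from afchoice import bt_models as bt
from afchoice import synthetic_data as sd
from afchoice.trial_model import TrialRecord, ValidationError

from conftest import make_trials


def two_item_spec():
    return bt.BTSpec(items=("A", "B"), phase_structure="constant", reference_item="A")


class TestChoiceProb:
    def test_equal_worths_give_half(self):
        assert bt.choice_prob(0.0, 0.0) == 0.5

    def test_complementarity(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b = rng.normal(0, 3, size=2)
            assert bt.choice_prob(a, b) + bt.choice_prob(b, a) == pytest.approx(1.0)

    def test_log_three_gives_three_quarters(self):
        assert bt.choice_prob(np.log(3), 0.0) == pytest.approx(0.75)

    def test_numerically_stable_at_extreme_gaps(self):
        assert bt.choice_prob(700.0, 0.0) == pytest.approx(1.0)
        assert bt.choice_prob(0.0, 700.0) == pytest.approx(0.0, abs=1e-300)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bt.choice_prob(np.inf, 0.0)


class TestNegLoglik:
    def test_all_zero_worths_give_n_log_two(self):
        trials = make_trials([("A", "B", "A")] * 10)
        spec = two_item_spec()
        assert bt.neg_loglik({"A": 0.0, "B": 0.0}, trials, spec) == pytest.approx(10 * np.log(2))

    def test_saturated_worth_drives_nll_to_zero(self):
        trials = make_trials([("A", "B", "B")])
        spec = two_item_spec()
        assert bt.neg_loglik({"A": 0.0, "B": 40.0}, trials, spec) == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_trial_product_oracle(self):
        rng = np.random.default_rng(21)
        items = tuple("ABCDE")
        spec = bt.BTSpec(items=items, phase_structure="constant", reference_item="A")
        worths = {i: float(rng.normal(0, 1)) for i in items}
        rows = []
        for _ in range(200):
            a, b = rng.choice(items, size=2, replace=False)
            rows.append((a, b, a if rng.random() < 0.5 else b))
        trials = make_trials(rows)
        # oracle: explicit product of per-trial probabilities
        log_prod = 0.0
        for t in trials:
            other = t.right_item if t.chosen == t.left_item else t.left_item
            p = 1.0 / (1.0 + np.exp(worths[other] - worths[t.chosen]))
            log_prod += np.log(p)
        assert bt.neg_loglik(worths, trials, spec) == pytest.approx(-log_prod, abs=1e-10)

    def test_invariant_under_common_shift(self):
        trials = make_trials([("A", "B", "A"), ("B", "C", "C"), ("A", "C", "A")])
        spec = bt.BTSpec(items=("A", "B", "C"), phase_structure="constant")
        w = {"A": 0.3, "B": -0.2, "C": 1.1}
        shifted = {k: v + 5.7 for k, v in w.items()}
        assert bt.neg_loglik(w, trials, spec) == pytest.approx(
            bt.neg_loglik(shifted, trials, spec), rel=1e-12
        )

    def test_unresolvable_item_names_trial(self):
        trials = make_trials([("A", "Z", "Z")])
        with pytest.raises(ValidationError):
            bt.neg_loglik({"A": 0.0}, trials, two_item_spec())


class TestFit:
    def test_two_item_closed_form(self):
        # 3 wins to 1: MLE choice probability = 3/4, log-worth gap = ln 3
        trials = make_trials([("A", "B", "B")] * 3 + [("A", "B", "A")])
        fitted = bt.fit(two_item_spec(), trials)
        gap = fitted.log_worths[("B", bt.LATE)]
        assert gap == pytest.approx(np.log(3), abs=1e-5)
        assert bt.choice_prob(gap, 0.0) == pytest.approx(0.75, abs=1e-5)

    def test_symmetric_data_give_zero_worths(self):
        rows = []
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            rows += [(a, b, a), (a, b, b), (b, a, a), (b, a, b)]
        spec = bt.BTSpec(items=("A", "B", "C"), phase_structure="constant")
        fitted = bt.fit(spec, make_trials(rows))
        for v in fitted.log_worths.values():
            assert v == pytest.approx(0.0, abs=1e-6)

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(31)
        rows = []
        for _ in range(60):
            a, b = rng.choice(list("ABCD"), size=2, replace=False)
            rows.append((a, b, a if rng.random() < 0.6 else b))
        spec = bt.BTSpec(items=tuple("ABCD"), phase_structure="constant")
        f1 = bt.fit(spec, make_trials(rows))
        f2 = bt.fit(spec, make_trials(rows))
        assert f1.log_worths == f2.log_worths

    def test_fitted_point_is_global_optimum(self):
        # BT likelihood is convex in worth differences: the fit must beat
        # random parameter points and have a vanishing gradient
        rng = np.random.default_rng(32)
        rows = []
        for _ in range(150):
            a, b = rng.choice(list("ABCD"), size=2, replace=False)
            rows.append((a, b, a if rng.random() < 0.55 else b))
        trials = make_trials(rows)
        spec = bt.BTSpec(items=tuple("ABCD"), phase_structure="constant")
        fitted = bt.fit(spec, trials)
        assert fitted.converged
        best = bt.neg_loglik({k: v for k, v in fitted.log_worths.items()}, trials, spec)
        for _ in range(50):
            w = {(i, bt.LATE): float(rng.normal(0, 2)) for i in spec.items}
            assert best <= bt.neg_loglik(w, trials, spec) + 1e-9

    def test_aic_bic_identities(self):
        trials = make_trials([("A", "B", "B")] * 3 + [("A", "B", "A")] * 2)
        fitted = bt.fit(two_item_spec(), trials)
        assert fitted.aic == pytest.approx(2 * fitted.k - 2 * fitted.loglik)
        assert fitted.bic == pytest.approx(fitted.k * np.log(5) - 2 * fitted.loglik)

    def test_perfect_separation_warns_and_caps(self):
        trials = make_trials([("A", "B", "B")] * 6)
        with pytest.warns(UserWarning, match="separation"):
            fitted = bt.fit(two_item_spec(), trials)
        assert fitted.log_worths[("B", bt.LATE)] == pytest.approx(bt.WORTH_CAP)

    def test_parameter_recovery_at_moderate_n(self):
        rng = np.random.default_rng(33)
        items = tuple("ABCD")
        truth = {"A": 0.0, "B": 0.5, "C": 1.0, "D": 1.5}
        rows = []
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
        for _ in range(3000):
            a, b = pairs[rng.integers(6)]
            p = bt.choice_prob(truth[a], truth[b])
            rows.append((a, b, a if rng.random() < p else b))
        spec = bt.BTSpec(items=items, phase_structure="constant", reference_item="A")
        fitted = bt.fit(spec, make_trials(rows))
        for i in items:
            assert fitted.log_worths[(i, bt.LATE)] == pytest.approx(truth[i], abs=0.15)

    def test_split_model_separates_early_and_late_worths(self):
        # AF-test encounters 1-2 use the early slot; post-experimental trials
        # the late slot; a worth flip between them is recovered
        af_rows = [("C", "CL", "CL")] * 2  # encounters 1-2: mix preferred
        post_rows = [("C", "CL", "C")] * 8  # late: mix strongly avoided
        trials = make_trials(af_rows, phase="af_test", condition="transparent") + make_trials(
            post_rows
        )
        spec = bt.BTSpec(
            items=("C", "CL"),
            phase_structure="split_first_two",
            reference_item="C",
            phased_items=("CL",),
        )
        with pytest.warns(UserWarning, match="separation"):
            fitted = bt.fit(spec, trials)
        assert fitted.log_worths[("CL", bt.EARLY)] > 5
        assert fitted.log_worths[("CL", bt.LATE)] < -5


class TestSpecsAndComparison:
    def test_parameter_counts(self):
        items = tuple(sorted(sd.make_items()))
        mixes = tuple(sorted(i for i in items if len(i) == 2))
        a = bt.BTSpec(items=items, phase_structure="constant", reference_item="C")
        b = bt.BTSpec(
            items=items,
            phase_structure="split_first_two",
            reference_item="C",
            phased_items=mixes,
        )
        assert (a.k, b.k) == (9, 15)
        assert b.k - a.k == 6  # the likelihood-ratio df of the study's design

    def _fits(self, loglik_a, loglik_b, n=273):
        items = tuple(sorted(sd.make_items()))
        mixes = tuple(sorted(i for i in items if len(i) == 2))
        spec_a = bt.BTSpec(items=items, phase_structure="constant", reference_item="C")
        spec_b = bt.BTSpec(
            items=items, phase_structure="split_first_two", reference_item="C", phased_items=mixes
        )
        fa = bt.BTFit(spec=spec_a, log_worths={}, loglik=loglik_a, n_choices=n, converged=True)
        fb = bt.BTFit(spec=spec_b, log_worths={}, loglik=loglik_b, n_choices=n, converged=True)
        return fa, fb

    def test_identical_fits_give_null_comparison(self):
        fa, fb = self._fits(-150.0, -150.0)
        comp = bt.compare_models(fa, fb)
        assert comp.lrt_stat == 0.0
        assert comp.lrt_p == 1.0
        assert comp.preferred_by == {"aic": "A", "bic": "A", "lrt": "A"}

    def test_delta_aic_identity(self):
        fa, fb = self._fits(-152.3, -149.1)
        comp = bt.compare_models(fa, fb)
        assert comp.delta_aic == pytest.approx(2 * comp.df - comp.lrt_stat)

    def test_strong_improvement_prefers_b(self):
        fa, fb = self._fits(-170.0, -140.0)
        comp = bt.compare_models(fa, fb)
        assert comp.preferred_by == {"aic": "B", "bic": "B", "lrt": "B"}

    def test_mismatched_n_rejected(self):
        fa, _ = self._fits(-150.0, -150.0)
        _, fb = self._fits(-150.0, -150.0, n=100)
        with pytest.raises(ValueError, match="different data"):
            bt.compare_models(fa, fb)

    def test_non_nested_order_rejected(self):
        fa, fb = self._fits(-150.0, -149.0)
        with pytest.raises(ValueError):
            bt.compare_models(fb, fa)


class TestChi2Sf:
    def test_zero_statistic_gives_one(self):
        assert bt.chi2_sf(0.0, 6) == 1.0

    def test_df_two_closed_form(self):
        for x in (0.5, 1.0, 2.64, 10.0):
            assert bt.chi2_sf(x, 2) == pytest.approx(np.exp(-x / 2), rel=1e-12)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            bt.chi2_sf(-1.0, 3)


class TestEndToEndRecovery:
    def test_pure_bt_agent_worths_recovered_from_study(self):
        # with no biases, lapses, interaction noise or phase shift, the
        # simulator is exactly the BT generative model the fitter assumes
        agent = sd.AgentSpec(seed=202)
        ds, _ = sd.simulate_study(agent)
        spec_a, _ = bt.standard_specs(ds)
        trials = bt.bt_fit_scope(ds)
        fitted = bt.fit(spec_a, trials)
        items = sd.make_items()
        ref = "C"
        for iid, item in items.items():
            truth = sd.agent_worth(agent, item, "post_experimental", None) - sd.agent_worth(
                agent, items[ref], "post_experimental", None
            )
            est = fitted.log_worths[(iid, bt.LATE)]
            assert est == pytest.approx(truth, abs=0.8)  # n = 273 choices
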