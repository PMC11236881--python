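"""Prediction for new locations, MSEPD, rank correlation, CV mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metpredict as mp
from metpredict.datatypes import (
    FitResult,
    MeanSet,
    ModelSpec,
    PredictionSet,
    VarianceParams,
    stack_means,
)
from metpredict.predict import (
    leave_one_location_out,
    msepd,
    predict_new_location,
    spearman_by_location,
)

from _oracles import msepd_triple_loop, spearman_tied_ranks
from conftest import identity_vparams


def _fit_result(mu, a, beta=(), b=None, s=None, n_sc=None, genotypes=None,
                locations=("L1", "L2")):
    a = np.asarray(a, dtype=float)
    I = a.size
    q = len(beta) if n_sc is None else n_sc
    genotypes = genotypes or [f"g{i + 1}" for i in range(I)]
    spec = ModelSpec(n_sc=q)
    s = np.zeros((len(locations), I)) if s is None else np.asarray(s, float)
    return FitResult(
        spec=spec, genotypes=list(genotypes), locations=list(locations),
        params=identity_vparams(n_sc=q), mu_hat=mu,
        beta_hat=np.asarray(beta, dtype=float),
        blup_a=a, blup_b=np.zeros((I, q)) if b is None else np.asarray(b, float),
        blup_l=np.zeros(len(locations)), blup_s=s, sc=None,
        reml_loglik=0.0, aic=0.0, n_vparams=3, converged=True, n_iter=1)


class TestPredictNewLocation:
    def test_worked_example_difference(self):
        # a=(0.1,-0.1), beta=0.2, b=(0.05,-0.05), t_new=2
        # z1-z2 = (a1-a2) + t*(b1-b2) = 0.2 + 2*0.1 = 0.4
        fit = _fit_result(3.0, [0.1, -0.1], beta=[0.2],
                          b=np.array([[0.05], [-0.05]]))
        pred = predict_new_location(fit, sc_new=[2.0])
        assert pred.z[0] - pred.z[1] == pytest.approx(0.4, abs=1e-12)

    def test_no_sc_differences_equal_main_effects(self):
        fit = _fit_result(3.0, [0.3, -0.1, -0.2])
        pred = predict_new_location(fit)
        d = pred.z - pred.z[0]
        np.testing.assert_allclose(d, fit.blup_a - fit.blup_a[0], atol=1e-12)

    def test_modes_coincide_with_zero_interaction_blups(self):
        fit = _fit_result(3.0, [0.3, -0.1])
        z1 = predict_new_location(fit, mode="main_effect").z
        z2 = predict_new_location(fit, mode="main_plus_avg_interaction").z
        np.testing.assert_allclose(z1, z2)

    def test_avg_interaction_added(self):
        s = np.array([[0.1, -0.1], [0.3, 0.1]])
        fit = _fit_result(3.0, [0.0, 0.0], s=s)
        z = predict_new_location(fit, mode="main_plus_avg_interaction").z
        np.testing.assert_allclose(z, 3.0 + s.mean(axis=0))

    def test_sc_required_when_model_uses_it(self):
        fit = _fit_result(3.0, [0.1, -0.1], beta=[0.2],
                          b=np.array([[0.0], [0.0]]))
        with pytest.raises(ValueError, match="sc_new"):
            predict_new_location(fit)


class TestMSEPD:
    def _sets(self, obs, pred):
        observed = [MeanSet(loc, [f"g{i}" for i in range(len(v))], v,
                            np.ones(len(v))) for loc, v in obs.items()]
        predicted = [PredictionSet(loc, [f"g{i}" for i in range(len(v))],
                                   np.asarray(v, float), "main_effect")
                     for loc, v in pred.items()]
        return observed, predicted

    def test_perfect_predictions_zero(self):
        obs = {"L1": np.array([1.0, 2.0, 3.0]), "L2": np.array([2.0, 1.0, 0.5])}
        o, p = self._sets(obs, obs)
        assert msepd(o, p) == 0.0

    def test_per_location_shift_invariance(self, rng):
        obs = {f"L{m}": rng.standard_normal(5) for m in range(3)}
        pred = {f"L{m}": rng.standard_normal(5) for m in range(3)}
        o, p = self._sets(obs, pred)
        base = msepd(o, p)
        shifted = {loc: v + (7.7 if loc == "L1" else -2.2)
                   for loc, v in pred.items()}
        o2, p2 = self._sets(obs, shifted)
        assert msepd(o2, p2) == pytest.approx(base, rel=1e-12)

    def test_two_genotype_worked_value(self):
        # observed diff 1.0, predicted diff 0.4 -> (0.6^2 + 0.6^2)/2 = 0.36
        o, p = self._sets({"L1": np.array([2.0, 1.0])},
                          {"L1": np.array([1.7, 1.3])})
        assert msepd(o, p) == pytest.approx(0.36, abs=1e-12)

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=6),
           st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_shift_invariance_property(self, zvals, shift):
        obs = {"L1": np.arange(len(zvals), dtype=float)}
        o, p = self._sets(obs, {"L1": np.array(zvals)})
        o2, p2 = self._sets(obs, {"L1": np.array(zvals) + shift})
        assert msepd(o2, p2) == pytest.approx(msepd(o, p), rel=1e-9, abs=1e-9)

    def test_matches_triple_loop_oracle(self, rng):
        obs = {f"L{m}": rng.standard_normal(7) for m in range(2)}
        pred = {f"L{m}": rng.standard_normal(7) for m in range(2)}
        o, p = self._sets(obs, pred)
        assert msepd(o, p) == pytest.approx(msepd_triple_loop(obs, pred),
                                            rel=1e-12)

    def test_mismatched_sets_rejected(self):
        o = [MeanSet("L1", ["g1", "g2"], [1.0, 2.0], [1, 1])]
        p = [PredictionSet("L1", ["g1", "g3"], np.array([1.0, 2.0]),
                           "main_effect")]
        with pytest.raises(ValueError, match="differ"):
            msepd(o, p)


class TestSpearman:
    def _pair(self, y, z):
        I = len(y)
        o = [MeanSet("L1", [f"g{i}" for i in range(I)], y, np.ones(I))]
        p = [PredictionSet("L1", [f"g{i}" for i in range(I)],
                           np.asarray(z, float), "main_effect")]
        return o, p

    def test_identical_ranking_is_one(self):
        o, p = self._pair(np.array([1.0, 2.0, 3.0, 4.0]),
                          np.array([10.0, 20.0, 30.0, 40.0]))
        per, mean, se = spearman_by_location(o, p)
        assert mean == pytest.approx(1.0)

    def test_reversed_ranking_is_minus_one(self):
        o, p = self._pair(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0]))
        _, mean, _ = spearman_by_location(o, p)
        assert mean == pytest.approx(-1.0)

    def test_ties_match_textbook_average_rank_formula(self):
        y = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        z = np.array([1.5, 1.0, 2.5, 2.5, 3.0])
        o, p = self._pair(y, z)
        per, mean, _ = spearman_by_location(o, p)
        assert mean == pytest.approx(spearman_tied_ranks(y, z), abs=1e-12)

    def test_constant_prediction_excluded_with_warning(self):
        I = 4
        o = [MeanSet("L1", [f"g{i}" for i in range(I)],
                     np.arange(I, dtype=float), np.ones(I)),
             MeanSet("L2", [f"g{i}" for i in range(I)],
                     np.arange(I, dtype=float), np.ones(I))]
        p = [PredictionSet("L1", [f"g{i}" for i in range(I)],
                           np.full(I, 2.0), "main_effect"),
             PredictionSet("L2", [f"g{i}" for i in range(I)],
                           np.arange(I, dtype=float), "main_effect")]
        per, mean, se = spearman_by_location(o, p)
        assert np.isnan(dict(per)["L1"])
        assert mean == pytest.approx(1.0)


class TestLeaveOneLocationOut:
    def test_needs_three_locations(self):
        sets = [MeanSet(f"L{m}", ["g1", "g2", "g3"], [1, 2, 3], [1, 1, 1])
                for m in range(2)]
        with pytest.raises(ValueError, match="3 locations"):
            leave_one_location_out(sets, ModelSpec())

    def test_high_rho_without_interaction(self):
        """Strong genotype signal, no G x L: rankings are predictable."""
        vp = identity_vparams(sigma2_a=0.2, sigma2_l=0.05, sigma2_s=1e-12)
        truth = mp.simulate_genotype_location_effects(
            [f"g{i:03d}" for i in range(100)], [f"L{m}" for m in range(4)],
            ModelSpec(), vp, beta=np.zeros(0), latent_scores=np.zeros((4, 0)),
            A=None, mu=3.0, seed=21)
        ms = mp.simulate_stacked_means(truth, residual_var=0.002, seed=22)
        res = leave_one_location_out(ms, ModelSpec(), model_id="M1")
        assert res.mean_rho >= 0.9
        assert res.msepd >= 0.0

    def test_held_out_means_never_influence_training(self, tiny):
        """Mutating the held-out location's means leaves that fold's
        prediction unchanged (no leakage through PLS or REML)."""
        ms = mp.simulate_stacked_means(tiny.truth, residual_var=0.01, seed=31)
        spec = ModelSpec(n_sc=1)
        res1 = leave_one_location_out(ms, spec, ec=tiny.ec)
        held = ms[0].location
        mutated = [MeanSet(m.location, list(m.genotypes),
                           m.means + (5.0 if m.location == held else 0.0),
                           m.weights) for m in ms]
        res2 = leave_one_location_out(mutated, spec, ec=tiny.ec)
        z1 = next(p for p in res1.predictions if p.location == held).z
        z2 = next(p for p in res2.predictions if p.location == held).z
        np.testing.assert_array_equal(z1, z2)
        # but the scores for that fold do change
        assert res1.msepd != res2.msepd

    def test_cv_report_round_trip(self, tmp_path, tiny):
        ms = mp.simulate_stacked_means(tiny.truth, residual_var=0.01, seed=41)
        res = leave_one_location_out(ms, ModelSpec(), model_id="M1")
        path = tmp_path / "cv.json"
        mp.write_cv_report([res], path)
        import json
        back = json.loads(path.read_text())
        assert back[0]["model"] == "M1"
        assert back[0]["msepd"] == pytest.approx(res.msepd)
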