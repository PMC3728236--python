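"""Partial Credit Model: closed-form probabilities, JMLE vs an independent
grid-search likelihood maximiser, fit statistics vs direct summation, and
the separation/reliability identity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from absst import (
    ItemSpec,
    ResponseMatrix,
    RunConfig,
    category_probabilities,
    expected_score_and_variance,
    fit_pcm,
    fit_statistics,
    reliability_from_separation,
    separation_from_reliability,
)
from absst.data import ValidationError
from absst.pcm import PartialCreditModel, fit_by_subscale


def pcm_probs_reference(theta, steps):
    """Independent direct-summation PCM probabilities (pure python)."""
    psis = [0.0]
    for d in steps:
        psis.append(psis[-1] + (theta - d))
    exps = [math.exp(p - max(psis)) for p in psis]
    z = sum(exps)
    return [e / z for e in exps]


class TestCategoryProbabilities:
    def test_dichotomous_midpoint(self):
        p = category_probabilities(0.7, [0.7])
        assert p == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_dichotomous_closed_form(self):
        # theta - delta = ln 3  =>  P(1) = 3/4
        p = category_probabilities(math.log(3), [0.0])
        assert p == pytest.approx([0.25, 0.75], abs=1e-12)

    def test_three_category_symmetry(self):
        p = category_probabilities(0.0, [0.0, 0.0])
        assert p == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_numerically_stable_at_extremes(self):
        p = category_probabilities(300.0, [0.0])
        assert np.isfinite(p).all() and p[1] == pytest.approx(1.0)
        p = category_probabilities(-300.0, [0.0, 10.0, -5.0])
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)

    def test_rejects_nonfinite_steps(self):
        with pytest.raises(ValidationError):
            category_probabilities(0.0, [np.nan])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        theta=st.floats(-8, 8),
        steps=st.lists(st.floats(-5, 5), min_size=1, max_size=5),
    )
    def test_sums_to_one_and_matches_reference(self, theta, steps):
        p = category_probabilities(theta, steps)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(pcm_probs_reference(theta, steps), abs=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(steps=st.lists(st.floats(-3, 3), min_size=1, max_size=5))
    def test_expected_score_monotone_in_theta(self, steps):
        thetas = np.linspace(-6, 6, 25)
        e, _ = expected_score_and_variance(thetas, steps)
        assert np.all(np.diff(e) > -1e-12)


class TestExpectedScore:
    def test_uniform_three_categories(self):
        e, w = expected_score_and_variance(0.0, [0.0, 0.0])
        assert e == pytest.approx(1.0, abs=1e-12)
        assert w == pytest.approx(2 / 3, abs=1e-12)

    def test_low_theta_limit(self):
        e, w = expected_score_and_variance(-50.0, [0.0, 0.0])
        assert e == pytest.approx(0.0, abs=1e-10)
        assert w == pytest.approx(0.0, abs=1e-10)

    def test_matches_direct_sum_on_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            theta = rng.normal(0, 2)
            steps = rng.normal(0, 1.5, size=rng.integers(1, 5))
            p = pcm_probs_reference(theta, list(steps))
            e_ref = sum(x * px for x, px in enumerate(p))
            w_ref = sum((x - e_ref) ** 2 * px for x, px in enumerate(p))
            e, w = expected_score_and_variance(theta, steps)
            assert e == pytest.approx(e_ref, abs=1e-12)
            assert w == pytest.approx(w_ref, abs=1e-12)


def _toy_matrix(patterns, max_cat=1):
    items = [ItemSpec("a", max_category=max_cat), ItemSpec("b", max_category=max_cat)]
    df = pd.DataFrame(patterns, columns=["a", "b"], dtype=float,
                      index=[f"p{i}" for i in range(len(patterns))])
    return ResponseMatrix(df, items)


class TestJMLE:
    def test_identical_items_get_equal_steps(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 5, size=40)
        items = [ItemSpec("a", max_category=4), ItemSpec("b", max_category=4),
                 ItemSpec("c", max_category=4)]
        df = pd.DataFrame({"a": col, "b": col, "c": rng.integers(0, 5, size=40)},
                          dtype=float, index=[f"p{i}" for i in range(40)])
        fit = fit_pcm(ResponseMatrix(df, items), RunConfig(jmle_tol=1e-7))
        assert fit.item_steps["a"] == pytest.approx(fit.item_steps["b"], abs=1e-4)

    def test_matches_grid_search_on_dichotomous_toy(self):
        """JMLE equals an independent grid maximiser of the same joint
        likelihood (all non-extreme persons share total score 1, so the free
        parameters reduce to one theta and one centred step d)."""
        matrix = _toy_matrix([(1, 0)] * 3 + [(0, 1)] * 2 + [(1, 1)] * 2 + [(0, 0)])
        fit = fit_pcm(matrix, RunConfig(jmle_tol=1e-9))
        assert set(fit.dropped_persons) == {"p5", "p6", "p7"}

        def loglik(th, d):
            p_a = 1 / (1 + math.exp(-(th - d)))
            p_b = 1 / (1 + math.exp(-(th + d)))
            return 3 * math.log(p_a * (1 - p_b)) + 2 * math.log((1 - p_a) * p_b)

        grid = np.arange(-2, 2, 5e-4)
        best = max(((loglik(t, d), t, d) for t in (-0.02, -0.01, 0.0, 0.01, 0.02)
                    for d in grid))
        _, t_star, d_star = best
        assert fit.item_steps["a"][0] == pytest.approx(d_star, abs=1e-3)
        assert fit.item_steps["b"][0] == pytest.approx(-d_star, abs=1e-3)
        theta_hat = fit.person_measures["p0"]
        assert theta_hat == pytest.approx(t_star, abs=1e-2)

    def test_invariant_to_person_and_item_reordering(self):
        rng = np.random.default_rng(3)
        items = [ItemSpec(i, max_category=3) for i in ("a", "b", "c")]
        df = pd.DataFrame(rng.integers(0, 4, size=(30, 3)), columns=["a", "b", "c"],
                          dtype=float, index=[f"p{i}" for i in range(30)])
        fit1 = fit_pcm(ResponseMatrix(df, items), RunConfig(jmle_tol=1e-7))
        shuffled = df.iloc[::-1][["c", "a", "b"]]
        fit2 = fit_pcm(
            ResponseMatrix(shuffled, [items[2], items[0], items[1]]),
            RunConfig(jmle_tol=1e-7),
        )
        for k in ("a", "b", "c"):
            assert fit1.item_steps[k] == pytest.approx(fit2.item_steps[k], abs=1e-5)
            assert fit1.person_measures["p3"] == pytest.approx(
                fit2.person_measures["p3"], abs=1e-5
            )

    def test_identification_constraint_and_se_positive(self):
        rng = np.random.default_rng(8)
        items = [ItemSpec(f"i{k}", max_category=4) for k in range(4)]
        df = pd.DataFrame(rng.integers(0, 5, size=(60, 4)),
                          columns=[it.item_id for it in items], dtype=float,
                          index=[f"p{i}" for i in range(60)])
        fit = fit_pcm(ResponseMatrix(df, items), RunConfig())
        grand = np.mean([fit.item_steps[i].mean() for i in fit.item_steps])
        assert grand == pytest.approx(0.0, abs=1e-8)
        assert all((fit.item_se[i] > 0).all() for i in fit.item_se)
        assert (fit.person_se > 0).all()

    def test_extreme_persons_get_extrapolated_measures(self):
        matrix = _toy_matrix([(1, 0), (0, 1), (1, 0), (0, 1), (1, 1), (0, 0)])
        fit = fit_pcm(matrix, RunConfig())
        assert "p4" in fit.dropped_persons and "p5" in fit.dropped_persons
        inner = [fit.person_measures[p] for p in ("p0", "p1")]
        assert fit.person_measures["p4"] > max(inner)
        assert fit.person_measures["p5"] < min(inner)

    def test_unobserved_category_collapsed_and_reported(self):
        items = [ItemSpec("a", max_category=4), ItemSpec("b", max_category=4)]
        df = pd.DataFrame(
            {"a": [0, 1, 3, 3, 1, 0, 3, 1], "b": [0, 1, 2, 3, 4, 2, 1, 3]},
            dtype=float, index=[f"p{i}" for i in range(8)])
        fit = fit_pcm(ResponseMatrix(df, items), RunConfig())
        assert fit.rescored_items == {"a": {0: 0, 1: 1, 3: 2}}
        assert len(fit.item_steps["a"]) == 2

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(2)
        items = [ItemSpec(f"i{k}", max_category=2) for k in range(3)]
        df = pd.DataFrame(rng.integers(0, 3, size=(25, 3)),
                          columns=[it.item_id for it in items], dtype=float,
                          index=[f"p{i}" for i in range(25)])
        fit = fit_pcm(ResponseMatrix(df, items), RunConfig(jmle_max_iter=2, jmle_tol=1e-10))
        assert not fit.converged


class TestFitStatistics:
    def test_direct_sum_oracle(self):
        """Infit/outfit equal the explicit residual sums computed from the
        fitted measures with an independent probability routine."""
        items = [ItemSpec("a", max_category=2), ItemSpec("b", max_category=2)]
        df = pd.DataFrame({"a": [0, 1, 2, 1, 2, 0], "b": [1, 0, 2, 2, 1, 1]},
                          dtype=float, index=[f"p{i}" for i in range(6)])
        fit = fit_pcm(ResponseMatrix(df, items), RunConfig(jmle_tol=1e-8))
        stats = {s.item_id: s for s in fit.fit_statistics()}
        keep = [p for p in df.index if p not in fit.dropped_persons]
        for item in ("a", "b"):
            num = den = 0.0
            zsq = []
            for p in keep:
                x = df.loc[p, item]
                probs = pcm_probs_reference(fit.person_measures[p],
                                            list(fit.item_steps[item]))
                e = sum(k * pk for k, pk in enumerate(probs))
                w = sum((k - e) ** 2 * pk for k, pk in enumerate(probs))
                num += (x - e) ** 2
                den += w
                zsq.append((x - e) ** 2 / w)
            assert stats[item].infit_mnsq == pytest.approx(num / den, abs=1e-12)
            assert stats[item].outfit_mnsq == pytest.approx(np.mean(zsq), abs=1e-12)

    def test_misfit_band_flags(self, run_config):
        from absst.pcm import ItemFitStats

        assert ItemFitStats("x", 2.68, 1.0, True).misfit
        low, high = run_config.infit_band
        assert not (low <= 2.68 <= high)  # 2.68 falls outside the band
        assert low <= 1.0 <= high

    def test_null_model_mean_infit_near_one(self):
        from absst import SimulationConfig, simulate_pcm_responses

        items = [ItemSpec(f"i{k}", max_category=3) for k in range(5)]
        steps = {it.item_id: list(np.linspace(-1, 1, 3)) for it in items}
        cfg = SimulationConfig(n_persons=400, theta_mean=0, theta_sd=1.2,
                               item_steps=steps, instrument=items, seed=19)
        resp, _ = simulate_pcm_responses(cfg)
        fit = fit_pcm(resp, RunConfig())
        infits = [s.infit_mnsq for s in fit.fit_statistics()]
        assert 0.85 < np.mean(infits) < 1.15


class TestSeparationReliability:
    @pytest.mark.parametrize(
        "g,r",
        [(2.0, 0.80), (9.74, 0.99), (3.77, 0.93), (4.40, 0.95), (4.85, 0.96)],
    )
    def test_printed_anchor_pairs(self, g, r):
        assert round(reliability_from_separation(g), 2) == r

    def test_inverse_identity(self):
        assert separation_from_reliability(0.5) == pytest.approx(1.0, abs=1e-12)
        for g in (0.5, 1.0, 2.0, 4.4):
            assert separation_from_reliability(
                reliability_from_separation(g)
            ) == pytest.approx(g, abs=1e-10)

    def test_computed_stats_satisfy_identity(self):
        rng = np.random.default_rng(21)
        items = [ItemSpec(f"i{k}", max_category=4) for k in range(5)]
        theta = rng.normal(0, 1.5, size=80)
        from absst import SimulationConfig, simulate_pcm_responses

        steps = {it.item_id: list(np.linspace(-1.5, 1.5, 4) + rng.normal(0, 0.5))
                 for it in items}
        cfg = SimulationConfig(n_persons=80, theta_sd=1.5, item_steps=steps,
                               instrument=items, seed=4)
        resp, _ = simulate_pcm_responses(cfg)
        fit = fit_pcm(resp, RunConfig())
        s = fit.separation_reliability()
        for g, r in [(s.person_separation, s.person_reliability),
                     (s.item_separation, s.item_reliability)]:
            assert r == pytest.approx(g**2 / (1 + g**2), abs=1e-10)
            assert 0 <= r < 1 and g >= 0


def test_fit_by_subscale_splits_items(small_matrix, run_config):
    fits = fit_by_subscale(small_matrix, run_config)
    # only the intensity subscale has >= 2 ordinal items in the fixture
    assert list(fits) == ["symptom_intensity"]
    assert set(fits["symptom_intensity"].item_steps) == {"a", "b"}


def test_model_requires_two_items_and_persons(small_instrument):
    df = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [0.0], "h": [1.0]}, index=["p1"])
    with pytest.raises(ValidationError):
        PartialCreditModel(ResponseMatrix(df, small_instrument))


def test_from_dataframe_infers_instrument():
    df = pd.DataFrame({"x": [0.0, 1, 2], "y": [1.0, 0, 2]}, index=list("abc"))
    model = PartialCreditModel.from_dataframe(df)
    assert {it.item_id for it in model.responses.items} == {"x", "y"}


def test_summary_renders(small_matrix, run_config):
    fit = fit_by_subscale(small_matrix, run_config)["symptom_intensity"]
    text = fit.summary()
    assert "Partial Credit Model" in text and "infit" in text
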