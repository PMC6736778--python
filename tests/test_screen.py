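"""Screen statistics: AUC, Q90, interaction models, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agmacap.screen import (
    GrowthCurve,
    associate_prediction,
    enrich,
    fit_interactions,
    growth_auc,
    q90_intensity,
)
from agmacap.simulate import SimulationConfig, make_interaction_design, make_screen


def _curve(times, od, **kw):
    defaults = dict(well_id="w", nutrient_id="n", metformin_mM=0.0, replicate=0)
    defaults.update(kw)
    return GrowthCurve(times=np.asarray(times), od=np.asarray(od), **defaults)


class TestGrowthAuc:
    def test_constant_od_rectangle(self):
        curve = _curve(np.linspace(0, 18, 10), np.full(10, 0.5))
        assert growth_auc(curve) == pytest.approx(math.log2(9.0))

    def test_linear_ramp_exact_trapezoid(self):
        curve = _curve(np.linspace(0, 18, 7), np.linspace(0, 1, 7))
        assert growth_auc(curve) == pytest.approx(math.log2(9.0))

    def test_halving_od_lowers_log2_auc_by_one(self):
        t = np.linspace(0, 18, 20)
        od = 0.2 + 0.8 / (1 + np.exp(-(t - 9)))
        full = growth_auc(_curve(t, od))
        half = growth_auc(_curve(t, od / 2))
        assert full - half == pytest.approx(1.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            growth_auc(_curve([1.0], [0.5]))

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            _curve([0.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestQ90:
    def test_powers_of_two(self):
        # log2 values 1..10; interpolated 0.9-quantile = 9.1
        values = [2.0 ** k for k in range(1, 11)]
        assert q90_intensity(values) == pytest.approx(9.1)

    def test_constant_vector(self):
        assert q90_intensity([8.0, 8.0, 8.0]) == pytest.approx(3.0)

    @given(st.permutations(list(range(1, 12))))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariant(self, perm):
        base = q90_intensity([float(v) for v in range(1, 12)])
        assert q90_intensity([float(v) for v in perm]) == pytest.approx(base)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q90_intensity([])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            q90_intensity([1.0, 0.0])


def _balanced_design(delta, n=4, effects=(0.0, 0.0)):
    """One nutrient, 2x2 cells with means {0, drug, nutrient, drug+nutrient+delta}."""
    nut_eff, drug_eff = effects
    rows = []
    for nutrient in ("none", "nutA"):
        for drug in (False, True):
            mean = (nut_eff if nutrient != "none" else 0.0) + (drug_eff if drug else 0.0)
            if nutrient != "none" and drug:
                mean += delta
            rows += [
                {"nutrient_id": nutrient, "drug": drug, "response": mean}
                for _ in range(n)
            ]
    return pd.DataFrame(rows)


class TestFitInteractions:
    def test_exact_contrast_on_noiseless_cells(self):
        delta = 0.7
        out = fit_interactions(_balanced_design(delta))
        assert len(out) == 1
        assert out["interaction"].iloc[0] == pytest.approx(delta)
        assert out["effect_drug"].iloc[0] == pytest.approx(0.0)

    def test_matches_statsmodels_ols(self):
        import statsmodels.formula.api as smf

        cfg = SimulationConfig(seed=9, n_nutrients=3, n_planted=1)
        design = make_interaction_design(cfg)
        out = fit_interactions(design, pool_variance=False)
        for _, row in out.iterrows():
            sub = design[design.nutrient_id.isin(["none", row.nutrient_id])].copy()
            sub["nut"] = (sub.nutrient_id != "none").astype(int)
            sub["drg"] = sub.drug.astype(int)
            fit = smf.ols("response ~ nut * drg", data=sub).fit()
            assert row.interaction == pytest.approx(fit.params["nut:drg"], abs=1e-10)
            assert row.se_interaction == pytest.approx(fit.bse["nut:drg"], abs=1e-10)
            assert row.p_interaction == pytest.approx(fit.pvalues["nut:drg"], abs=1e-10)

    def test_missing_cell_skips_nutrient(self):
        design = _balanced_design(0.5)
        design = design[~((design.nutrient_id == "nutA") & design.drug)]
        out = fit_interactions(design)
        assert out.empty
        assert out.attrs["skipped"] == ["nutA"]

    def test_calls_follow_sign_and_fdr(self):
        cfg = SimulationConfig(seed=2, n_nutrients=40, n_planted=8, planted_effect=1.0)
        planted = {f"nut{i:03d}": (1.0 if i < 4 else -1.0) for i in range(8)}
        out = fit_interactions(make_interaction_design(cfg, planted=planted))
        calls = dict(zip(out.nutrient_id, out.call))
        assert all(calls[f"nut{i:03d}"] == "antagonistic" for i in range(4))
        assert all(calls[f"nut{i:03d}"] == "synergistic" for i in range(4, 8))
        neutral = out[out.fdr >= 0.05]
        assert (neutral.call == "neutral").all()

    def test_unbiased_over_many_balanced_designs(self):
        rng = np.random.default_rng(8)
        delta, sigma, n = 0.8, 0.3, 4
        estimates = []
        for _ in range(400):
            design = _balanced_design(delta, n=n)
            design["response"] += rng.normal(0, sigma, size=len(design))
            out = fit_interactions(design)
            estimates.append(out["interaction"].iloc[0])
        mean = float(np.mean(estimates))
        se_mean = sigma * 2 / math.sqrt(n) / math.sqrt(400)
        assert abs(mean - delta) < 2 * se_mean


class TestEnrich:
    @staticmethod
    def _exact_tail(N, K, n, k):
        """Brute-force hypergeometric upper tail P[X >= k]."""
        return sum(
            math.comb(K, i) * math.comb(N - K, n - i)
            for i in range(k, min(K, n) + 1)
        ) / math.comb(N, n)

    def test_matches_exact_enumeration(self):
        universe = [f"m{i}" for i in range(20)]
        class_map = {"acids": universe[:5]}
        hits = universe[:5] + universe[10:15]  # all 5 class members among 10 hits
        out = enrich(hits, universe, class_map)
        assert out["p"].iloc[0] == pytest.approx(self._exact_tail(20, 5, 10, 5), rel=1e-12)

    def test_sweep_against_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            N = int(rng.integers(5, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"m{i}" for i in range(N)]
            class_members = list(rng.choice(universe, size=K, replace=False))
            hits = list(rng.choice(universe, size=n, replace=False))
            out = enrich(hits, universe, {"cls": class_members})
            k = len(set(class_members) & set(hits))
            assert out["p"].iloc[0] == pytest.approx(
                self._exact_tail(N, K, n, k), rel=1e-10
            )
            assert out["k"].iloc[0] == k

    def test_hits_at_expectation_not_significant(self):
        universe = [f"m{i}" for i in range(20)]
        out = enrich(universe[:2] + universe[10:12], universe, {"cls": universe[:10]})
        assert out["p"].iloc[0] > 0.5

    def test_hit_set_equal_universe_gives_p_one(self):
        universe = [f"m{i}" for i in range(10)]
        out = enrich(universe, universe, {"a": universe[:3], "b": universe[3:]})
        assert (out["p"] == 1.0).all()

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich(["x"], ["a", "b"], {"cls": ["a"]})

    def test_bh_monotone_in_raw_p_order(self):
        rng = np.random.default_rng(23)
        universe = [f"m{i}" for i in range(25)]
        class_map = {
            f"c{j}": list(rng.choice(universe, size=int(rng.integers(2, 10)),
                                     replace=False))
            for j in range(8)
        }
        hits = list(rng.choice(universe, size=12, replace=False))
        out = enrich(hits, universe, class_map).sort_values("p")
        assert (out["fdr"].diff().dropna() >= -1e-12).all()
        assert (out["fdr"] <= 1.0).all()


class TestAssociation:
    def test_collinear_pairs_recovered(self):
        predicted = {f"n{i}": float(i) for i in range(10)}
        measured = {f"n{i}": 2.0 * i + 1.0 for i in range(10)}
        res = associate_prediction(predicted, measured)
        assert res.slope == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_slope_invariant_to_constant_shifts(self):
        rng = np.random.default_rng(4)
        predicted = {f"n{i}": float(rng.normal()) for i in range(15)}
        measured = {k: 3.0 * v + float(rng.normal(0, 0.1)) for k, v in predicted.items()}
        base = associate_prediction(predicted, measured)
        shifted = associate_prediction(
            {k: v + 100.0 for k, v in predicted.items()},
            {k: v - 7.0 for k, v in measured.items()},
        )
        assert shifted.slope == pytest.approx(base.slope)
        assert shifted.p_value == pytest.approx(base.p_value)

    def test_null_pairs_give_uniform_p(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            predicted = {f"n{i}": float(rng.normal()) for i in range(12)}
            measured = {f"n{i}": float(rng.normal()) for i in range(12)}
            pvals.append(associate_prediction(predicted, measured).p_value)
        from scipy import stats as sps

        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            associate_prediction({"a": 1.0, "b": 1.0, "c": 1.0},
                                 {"a": 1.0, "b": 2.0, "c": 3.0})


class TestSimulatedScreenRecovery:
    def test_planted_rescue_visible_in_auc(self):
        cfg = SimulationConfig(seed=3, n_nutrients=5, n_planted=2,
                               planted_effect=1.0, n_replicates=4)
        curves, worms = make_screen(cfg, od_noise=0.0)
        by = {}
        for c in curves:
            by.setdefault((c.nutrient_id, c.metformin_mM > 0), []).append(growth_auc(c))
        rescued = np.mean(by[("nut000", True)])
        unrescued = np.mean(by[("nut004", True)])
        assert rescued - unrescued == pytest.approx(1.0, abs=1e-9)

    def test_full_curve_pipeline_calls_planted_nutrients(self):
        cfg = SimulationConfig(seed=12, n_nutrients=30, n_planted=5,
                               planted_effect=1.5, n_replicates=4)
        curves, _ = make_screen(cfg, od_noise=0.02)
        rows = [
            {"nutrient_id": c.nutrient_id, "drug": c.metformin_mM > 0,
             "response": growth_auc(c)}
            for c in curves
        ]
        out = fit_interactions(pd.DataFrame(rows))
        planted = out[out.nutrient_id < "nut005"]
        assert (planted.call == "antagonistic").all()
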