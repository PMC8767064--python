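import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import embryoeffect as ee
from embryoeffect.effects import welch_t_arrays


def multi_cell_matrix(cell_means_by_feature: dict, n_reps: int = 6):
    """Noise-free endosperm matrix: feature -> {(g, t, s): mean}."""
    features = list(cell_means_by_feature)
    cells = sorted({c for m in cell_means_by_feature.values() for c in m})
    records, data = [], {}
    for (g, t, s) in cells:
        for r in range(1, n_reps + 1):
            sid = f"{g}_{t}_{s}_r{r}"
            records.append(ee.SampleRecord(sid, g, t, s, r))
            data[sid] = [cell_means_by_feature[f][(g, t, s)] for f in features]
    values = pd.DataFrame(data, index=features, dtype=float)
    values = values[[rec.sample_id for rec in records]]
    return ee.FeatureMatrix(values, "metabolome", records)


class TestWelch:
    def test_identical_samples_null(self):
        res = ee.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = ee.welch_t_test(a, b)
        # independent hand computation from the defining formulas
        se2 = 1.0 / 3 + 1.0 / 3
        t_exp = (2.0 - 3.0) / math.sqrt(se2)
        df_exp = se2**2 / ((1 / 3) ** 2 / 2 + (1 / 3) ** 2 / 2)
        p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
        assert res.statistic == pytest.approx(t_exp, rel=1e-12)
        assert res.df == pytest.approx(df_exp, rel=1e-12)
        assert res.p == pytest.approx(p_exp, rel=1e-12)

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
        st.lists(st.floats(-50, 50), min_size=3, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_scipy(self, a, b):
        if np.var(a) == 0 or np.var(b) == 0:
            return
        res = ee.welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_conventions(self):
        same = ee.welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert same.p == 1.0
        diff = ee.welch_t_test([2.0, 2.0], [3.0, 3.0])
        assert diff.p == 0.0

    def test_null_calibration_at_n6(self):
        # Welch with Satterthwaite df is mildly conservative at n=6
        # (true level ~0.046): it must never exceed nominal, and must not
        # be grossly conservative either
        rng = np.random.default_rng(29)
        A = rng.standard_normal((10_000, 6))
        B = rng.standard_normal((10_000, 6))
        _, _, p = welch_t_arrays(A, B)
        rate = float((p < 0.05).mean())
        se = math.sqrt(0.05 * 0.95 / 10_000)
        assert rate < 0.05 + 3 * se
        assert rate > 0.04


class TestDuncan:
    def test_identical_groups_nothing_significant(self):
        g = [1.0, 2.0, 3.0]
        table = ee.duncan_mrt([g, g, g])
        assert not table.significant.any()

    def test_two_groups_equal_pooled_t(self):
        rng = np.random.default_rng(31)
        mismatch = 0
        for _ in range(2000):
            a = rng.normal(0, 1, 5)
            b = rng.normal(rng.uniform(-1.5, 1.5), 1, 5)
            duncan_sig = bool(ee.duncan_mrt([a, b]).significant.iloc[0])
            t_sig = stats.ttest_ind(a, b, equal_var=True).pvalue < 0.05
            mismatch += duncan_sig != t_sig
        assert mismatch == 0

    def test_two_group_p_equals_pooled_t_p(self):
        a, b = [1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 4.5, 6.0]
        table = ee.duncan_mrt([a, b])
        ref = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert table.p.iloc[0] == pytest.approx(ref, rel=1e-9)

    def test_single_outlier_group(self):
        groups = [
            [0.01, 0.01],
            [0.03, 0.03],
            [0.05, 0.05],
            [10.0, 10.2],
        ]
        table = ee.duncan_mrt(groups)
        sig_pairs = {
            (int(r.group_i), int(r.group_j))
            for r in table.itertuples()
            if r.significant
        }
        assert sig_pairs == {(0, 3), (1, 3), (2, 3)}

    def test_no_crossing_rule(self):
        # wide span not significant -> inner pairs stay ns even if their
        # own short-span range would clear the critical value
        rng = np.random.default_rng(37)
        groups = [rng.normal(0, 5, 4) for _ in range(4)]
        table = ee.duncan_mrt(groups)
        means = [np.mean(g) for g in groups]
        order = np.argsort(means)
        full = table[
            (table.group_i == min(order[0], order[-1]))
            & (table.group_j == max(order[0], order[-1]))
        ]
        if not bool(full.significant.iloc[0]):
            assert not table.significant.any()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="group 1"):
            ee.duncan_mrt([[1.0, 2.0], [3.0]])

    def test_zero_variance_conventions(self):
        table = ee.duncan_mrt([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        by_pair = table.set_index(["group_i", "group_j"])
        assert not bool(by_pair.loc[(0, 1), "significant"])
        assert by_pair.loc[(0, 1), "p"] == 1.0
        assert bool(by_pair.loc[(0, 2), "significant"])
        assert by_pair.loc[(0, 2), "p"] == 0.0


FIG5_TRIPLE = {
    # position pi, embryo eps chosen to mimic the worked three-metabolite
    # example: maltose loses to position but gains under the embryo;
    # lysine is suppressed and PEP promoted by the embryo only.
    "maltose": {"pi": 0.5, "eps": 3.0},
    "lysine": {"pi": 1.0, "eps": 0.5},
    "PEP": {"pi": 1.0, "eps": 2.0},
}


def fig5_matrix(stage: int = 10):
    cells = {}
    for feat, eff in FIG5_TRIPLE.items():
        base = 1.0
        cells[feat] = {
            ("WT", "EnU", stage): base,
            ("WT", "EnB", stage): base * eff["pi"],
            ("NB", "EnU", stage): base,
            ("NB", "EnB", stage): base * eff["pi"] * eff["eps"],
        }
    return multi_cell_matrix(cells)


class TestEffectCalls:
    def test_planted_position_effect_noise_free(self):
        m = fig5_matrix()
        call = ee.position_effect(m, "maltose", 10)
        assert call["direction"] == "down"
        assert call["p"] < 0.05
        assert ee.position_effect(m, "lysine", 10)["direction"] == "ns"
        assert ee.position_effect(m, "PEP", 10)["direction"] == "ns"

    def test_planted_compound_effect_noise_free(self):
        m = fig5_matrix()
        assert ee.compound_effect(m, "maltose", 10)["direction"] == "up"
        assert ee.compound_effect(m, "PEP", 10)["direction"] == "up"
        assert ee.compound_effect(m, "lysine", 10)["direction"] == "down"

    def test_ratio_identities(self):
        m = fig5_matrix()
        assert ee.embryo_effect_ratio(m, "maltose", 10) == pytest.approx(3.0)
        assert ee.embryo_effect_ratio(m, "lysine", 10) == pytest.approx(0.5)
        assert ee.embryo_effect_ratio(m, "PEP", 10) == pytest.approx(2.0)

    def test_full_null_ratio_is_one(self):
        cells = {
            "f": {
                (g, t, 10): 5.0 for g in ("WT", "NB") for t in ("EnU", "EnB")
            }
        }
        m = multi_cell_matrix(cells)
        assert ee.embryo_effect_ratio(m, "f", 10) == pytest.approx(1.0)

    def test_position_effect_cancels_in_ratio(self):
        # same multiplier on EnB of both genotypes: calls move, R does not
        cells = {
            "f": {
                ("WT", "EnU", 10): 1.0,
                ("WT", "EnB", 10): 2.0,
                ("NB", "EnU", 10): 1.0,
                ("NB", "EnB", 10): 2.0,
            }
        }
        m = multi_cell_matrix(cells)
        assert ee.embryo_effect_ratio(m, "f", 10) == pytest.approx(
            1.0, abs=1e-12
        )
        assert ee.position_effect(m, "f", 10)["direction"] == "up"

    def test_ratio_undefined_on_zero_cell(self):
        cells = {
            "f": {
                ("WT", "EnU", 10): 1.0,
                ("WT", "EnB", 10): 0.0,
                ("NB", "EnU", 10): 1.0,
                ("NB", "EnB", 10): 2.0,
            }
        }
        m = multi_cell_matrix(cells)
        R = ee.embryo_effect_ratio(m, "f", 10)
        assert math.isnan(R)
        assert ee.classify_embryo_effect(R) == "undefined"


class TestClassifier:
    @pytest.mark.parametrize(
        "R,expected",
        [
            (1.05, "up"),
            (0.95, "down"),
            (1.0, "ns"),
            (0.951, "ns"),
            (1.049, "ns"),
            (0.5, "down"),
            (3.0, "up"),
        ],
    )
    def test_inclusive_boundaries(self, R, expected):
        assert ee.classify_embryo_effect(R) == expected

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            ee.classify_embryo_effect(-1.0)

    def test_threshold_invariants(self):
        with pytest.raises(ValueError):
            ee.ClassifierThresholds(tau_down=1.1)


class TestDecomposeAll:
    def test_row_count_covers_endosperm_features_by_stage(
        self, default_scaled, default_sim
    ):
        catalog, _, _, _ = default_sim
        calls = ee.decompose_all(default_scaled)
        n_endo = sum(1 for c in catalog if "endosperm" in c.tissue_presence)
        assert len(calls) == n_endo * 3
        assert set(calls.stage) == {10, 20, 30}

    def test_matches_per_feature_operations(self, default_scaled):
        calls = ee.decompose_all(default_scaled)
        sample = calls.sample(12, random_state=41)
        for row in sample.itertuples():
            pos = ee.position_effect(default_scaled, row.feature_id, row.stage)
            cmpd = ee.compound_effect(default_scaled, row.feature_id, row.stage)
            R = ee.embryo_effect_ratio(default_scaled, row.feature_id, row.stage)
            assert row.position_dir == pos["direction"]
            assert row.position_p == pytest.approx(pos["p"], rel=1e-9)
            assert row.compound_dir == cmpd["direction"]
            assert row.R == pytest.approx(R, rel=1e-12)

    def test_noise_free_null_everything_ns(self):
        cfg = ee.GeneratorConfig.with_counts(
            25, 5, 5, seed=13, noise_sigma=0.0
        ).null()
        matrix, _, _ = ee.simulate_metabolome(cfg)
        calls = ee.decompose_all(ee.median_scale(matrix))
        assert (calls.embryo_class == "ns").all()
        assert (calls.position_dir == "ns").all()
        assert (calls.compound_dir == "ns").all()

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=10, deadline=None)
    def test_stage_scale_invariance_of_r(self, factor):
        m = fig5_matrix()
        scaled_vals = m.values * factor
        m2 = ee.FeatureMatrix(scaled_vals, "metabolome", m.samples)
        for feat in FIG5_TRIPLE:
            assert ee.embryo_effect_ratio(m2, feat, 10) == pytest.approx(
                ee.embryo_effect_ratio(m, feat, 10), rel=1e-12
            )

    def test_genotype_swap_inverts_r(self):
        m = fig5_matrix()
        swapped_records = [
            ee.SampleRecord(
                r.sample_id,
                "NB" if r.genotype == "WT" else "WT",
                r.tissue,
                r.stage,
                r.replicate,
            )
            for r in m.samples
        ]
        m2 = ee.FeatureMatrix(m.values, "metabolome", swapped_records)
        for feat in FIG5_TRIPLE:
            assert ee.embryo_effect_ratio(m2, feat, 10) == pytest.approx(
                1.0 / ee.embryo_effect_ratio(m, feat, 10), rel=1e-12
            )


class TestParameterRecoveryNoiseFree:
    def test_planted_epsilon_recovered_exactly(self):
        cfg = ee.GeneratorConfig.with_counts(
            40, 0, 0, seed=19, noise_sigma=0.0
        )
        cfg = dataclasses.replace(cfg, position_effect_fraction=0.5)
        matrix, truth, _ = ee.simulate_metabolome(cfg)
        calls = ee.decompose_all(ee.median_scale(matrix))
        merged = calls.merge(truth, on=["feature_id", "stage"])
        np.testing.assert_allclose(
            merged.R.to_numpy(), merged.epsilon.to_numpy(), rtol=1e-9
        )
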