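"""Derived features and the composite multi-statistic importance score."""

import numpy as np
import pandas as pd
import pytest

from sdml.config import FeatureConfig
from sdml.data import FeatureTable
from sdml.features import (
    STAT_NAMES,
    _raw_stats,
    derive_features,
    score_features,
    select_features,
)
from tests.conftest import make_table


def _chem_table(n=30, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "MW": rng.uniform(214, 714, n),
        "logKow": rng.uniform(2, 7, n),
        "pKa": rng.uniform(-1, 5, n),
        "TPSA": rng.uniform(0, 80, n),
        "ExposureTime": rng.uniform(1, 60, n),
        "logRCF": rng.normal(size=n),
    })
    return FeatureTable(df, target_name="logRCF")


class TestDeriveFeatures:
    def test_named_formulas(self):
        df = pd.DataFrame({
            "MW": [100.0, 100.0], "logKow": [0.0, 0.0], "pKa": [1.0, 1.0],
            "TPSA": [0.0, 50.0], "ExposureTime": [0.0, 60.0], "logRCF": [0.0, 0.0],
        })
        t = FeatureTable(df, target_name="logRCF")
        out = derive_features(t)
        wsi = out.data["water_solubility_index"]
        assert wsi.iloc[0] == 0.0                       # zero numerator
        assert wsi.iloc[1] == pytest.approx(0.5)        # 50 / (100 * 1)
        kin = out.data["absorption_kinetics"]
        assert kin.iloc[0] == 0.0                       # 1 - e^0
        assert kin.iloc[1] == pytest.approx(1 - np.exp(-0.3))

    def test_kinetics_monotone_and_saturating(self):
        df = pd.DataFrame({"ExposureTime": np.linspace(0, 2000, 50), "logRCF": np.zeros(50)})
        out = derive_features(FeatureTable(df, target_name="logRCF"))
        kin = out.data["absorption_kinetics"].to_numpy()
        assert np.all(np.diff(kin) > 0) and kin[-1] < 1 and kin[-1] > 0.99

    def test_degenerate_denominator_is_missing(self):
        df = pd.DataFrame({"MW": [100.0], "logKow": [-2.0], "TPSA": [50.0],
                           "ExposureTime": [1.0], "logRCF": [0.0]})
        out = derive_features(FeatureTable(df, target_name="logRCF"))
        assert np.isnan(out.data["water_solubility_index"].iloc[0])

    def test_generic_transforms_and_products_added(self):
        out = derive_features(_chem_table())
        for col in ("MW^2", "sqrt|MW|", "ln|MW|", "MW*logKow", "pKa*TPSA"):
            assert col in out.data.columns


class TestScoreFeatures:
    def test_informative_beats_noise(self, linear_table):
        scores = score_features(linear_table, n_bootstrap=20, seed=0)
        by_name = {s.feature: s for s in scores}
        assert by_name["x1"].composite > by_name["x2"].composite
        assert scores[0].feature == "x1"

    def test_duplicated_feature_penalized_by_vif(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        z = rng.normal(size=200)
        y = 2 * x + rng.normal(0, 0.1, 200)
        dup = make_table(np.column_stack([x, x, z]), y, names=["a", "a_copy", "b"])
        solo = make_table(np.column_stack([x, z]), y, names=["a", "b"])
        s_dup = {s.feature: s for s in score_features(dup, n_bootstrap=0, seed=0)}
        s_solo = {s.feature: s for s in score_features(solo, n_bootstrap=0, seed=0)}
        assert s_dup["a"].vif > 1e6 and s_dup["a_copy"].vif > 1e6
        assert s_dup["a"].composite < 0.01 * max(s_solo["a"].composite, 1e-12) + 0.01
        assert s_dup["a"].composite < s_solo["a"].composite

    def test_f_only_weights_match_squared_pearson_ranking(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 4))
        y = 3 * X[:, 0] + 2 * X[:, 1] + 1 * X[:, 2] + rng.normal(0, 0.5, 300)
        t = make_table(X, y)
        scores = score_features(t, n_bootstrap=0, seed=0,
                                weights={"f_stat": 1.0, "mutual_info": 0, "dist_corr": 0,
                                         "mic": 0, "relieff": 0})
        ranked = [s.feature for s in scores]
        r2 = [np.corrcoef(X[:, j], y)[0, 1] ** 2 for j in range(4)]
        expected = [f"x{j + 1}" for j in np.argsort(r2)[::-1]]
        assert ranked == expected

    def test_constant_feature_flagged_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 2))
        X[:, 1] = 7.0
        t = make_table(X, X[:, 0] + rng.normal(0, 0.1, 50))
        scores = {s.feature: s for s in score_features(t, n_bootstrap=5, seed=0)}
        assert scores["x2"].constant and scores["x2"].composite == 0.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 3))
        y = X[:, 0] + 0.5 * X[:, 1] ** 2 + rng.normal(0, 0.2, 150)
        base = score_features(make_table(X, y), n_bootstrap=0, seed=0)
        X2 = X.copy()
        X2[:, 0] = -1000.0 * X2[:, 0] + 5.0
        scaled = score_features(make_table(X2, y), n_bootstrap=0, seed=0)
        for s_b, s_s in zip(sorted(base, key=lambda s: s.feature),
                            sorted(scaled, key=lambda s: s.feature)):
            assert s_s.composite == pytest.approx(s_b.composite, abs=0.05)

    def test_pairwise_stats_unchanged_by_extra_noise_columns(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 2))
        y = 2 * X[:, 0] + rng.normal(0, 0.3, 120)
        cfg = FeatureConfig()
        small = _raw_stats(X, y, cfg, seed=0)
        X_wide = np.column_stack([X, rng.normal(size=(120, 3))])
        wide = _raw_stats(X_wide, y, cfg, seed=0)
        # F, MI, dCor and MIC are target-pair statistics: adding pure-noise
        # columns cannot change them for the informative feature
        for row in range(4):
            assert wide[row, 0] == pytest.approx(small[row, 0], rel=1e-9)

    def test_requires_target_and_enough_rows(self):
        t = make_table(np.zeros((10, 2)), np.zeros(10))
        with pytest.raises(ValueError):
            score_features(t, n_bootstrap=0)


class TestSelectFeatures:
    def test_top_k_and_ties(self, linear_table):
        scores = score_features(linear_table, n_bootstrap=10, seed=0)
        assert select_features(scores, 2) == [s.feature for s in scores[:2]]
        assert select_features(scores, 1) == ["x1"]
        with pytest.raises(ValueError):
            select_features(scores, 0)
        with pytest.raises(ValueError):
            select_features(scores, 99)

    def test_tie_broken_lexicographically(self):
        from sdml.features import FeatureScore

        mk = lambda name: FeatureScore(name, 0, 0, 0, 0, 0, 1.0, 1.0, 0.5)
        assert select_features([mk("b"), mk("a")], 1) == ["a"]
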