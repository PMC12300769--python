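"""Imputation, 1.5-IQR trimming, skew transforms and categorical encoding."""

import numpy as np
import pandas as pd
import pytest

from sdml.data import CATEGORICAL, FeatureTable, InsufficientDataError
from sdml.preprocess import (
    UnimputableError,
    decode_categories,
    encode_categories,
    impute_missing,
    preprocess_table,
    sample_skewness,
    transform_skewed,
    trim_outliers,
)
from tests.conftest import make_table


class TestImpute:
    def test_clean_table_unchanged(self):
        t = make_table(np.arange(20.0).reshape(10, 2), np.arange(10.0))
        out, rep = impute_missing(t)
        assert out.data.equals(t.data)
        assert all(c.n_imputed == 0 for c in rep.columns.values())

    def test_linear_relationship_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, 60)
        y = 2 * x
        df = pd.DataFrame({"x": x, "y": y})
        df.loc[30, "y"] = np.nan
        t = FeatureTable(df)
        out, rep = impute_missing(t, seed=0)
        expected = 2 * x[30]
        assert abs(out.data["y"].iloc[30] - expected) <= 0.1 * expected
        assert rep.columns["y"].n_imputed == 1

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        df.iloc[5, 0] = np.nan
        df.iloc[7, 1] = np.nan
        a, _ = impute_missing(FeatureTable(df.copy()), seed=3)
        b, _ = impute_missing(FeatureTable(df.copy()), seed=3)
        assert a.data.equals(b.data)

    def test_fully_missing_column_raises(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [np.nan] * 3})
        with pytest.raises(UnimputableError):
            impute_missing(FeatureTable(df))


class TestTrim:
    def test_symmetric_data_untouched(self):
        t = make_table(np.zeros((9, 1)), np.arange(1.0, 10.0))
        out, rep = trim_outliers(t)
        assert out.n_rows == 9 and rep.n_trimmed == 0

    def test_gross_outlier_removed(self):
        y = np.array([1.0, 2, 3, 4, 100])
        # brute-force fences via linearly interpolated quartiles
        q1, q3 = np.percentile(y, [25, 75])
        assert 100 > q3 + 1.5 * (q3 - q1)
        t = make_table(np.zeros((5, 1)), y)
        out, rep = trim_outliers(t)
        assert out.n_rows == 4 and 100 not in out.y.tolist()
        assert rep.n_trimmed == 1

    def test_constant_target_keeps_everything(self):
        t = make_table(np.zeros((6, 1)), np.full(6, 2.5))
        out, _ = trim_outliers(t)
        assert out.n_rows == 6

    def test_too_few_rows(self):
        t = make_table(np.zeros((3, 1)), np.arange(3.0))
        with pytest.raises(InsufficientDataError):
            trim_outliers(t)

    def test_retrim_after_removal_may_remove_more(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(0, 1, 50), [40.0, 80.0]])
        t = make_table(np.zeros((52, 1)), y)
        once, rep1 = trim_outliers(t)
        twice, rep2 = trim_outliers(once)
        assert rep1.n_trimmed > 0
        assert rep2.n_trimmed >= 0  # re-trimming is not idempotent in general
        clean = make_table(np.zeros((9, 1)), np.arange(1.0, 10.0))
        _, rep3 = trim_outliers(trim_outliers(clean)[0])
        assert rep3.n_trimmed == 0  # when nothing was removed, retrim is identity


class TestTransform:
    def test_symmetric_column_untouched(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(300, 1))
        t = make_table(x, rng.normal(size=300))
        out, rep = transform_skewed(t)
        assert rep.columns["x1"].transform_applied == "none"
        assert np.array_equal(out.data["x1"], t.data["x1"])

    def test_lognormal_column_symmetrized(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(0, 1.2, size=(500, 1)))
        t = make_table(x, rng.normal(size=500))
        before = sample_skewness(x[:, 0])
        assert before > 1
        out, rep = transform_skewed(t)
        assert rep.columns["x1"].transform_applied == "log10"
        assert abs(sample_skewness(out.data["x1"].to_numpy())) < before

    def test_infinite_threshold_is_identity(self):
        rng = np.random.default_rng(6)
        x = np.exp(rng.normal(0, 2, size=(100, 2)))
        t = make_table(x, rng.normal(size=100))
        out, _ = transform_skewed(t, skew_threshold=np.inf)
        assert out.data.equals(t.data)

    def test_shift_protects_nonpositive_columns(self):
        x = np.concatenate([[-1.0, 0.0], np.exp(np.random.default_rng(7).normal(2, 1.5, 98))])
        t = make_table(x.reshape(-1, 1), np.zeros(100))
        out, rep = transform_skewed(t)
        if rep.columns["x1"].transform_applied == "log10":
            assert np.isfinite(out.data["x1"]).all()


class TestEncode:
    def test_first_appearance_coding(self):
        df = pd.DataFrame({"species": ["lettuce", "maize", "lettuce"], "y": [1.0, 2, 3]})
        t = FeatureTable(df, target_name="y", column_kinds={"species": CATEGORICAL})
        out, rep = encode_categories(t)
        assert out.data["species"].tolist() == [0, 1, 0]
        assert rep.columns["species"].encoding == ["lettuce", "maize"]

    def test_integer_codes_left_alone(self):
        df = pd.DataFrame({"species": [0, 1, 0], "y": [1.0, 2, 3]})
        t = FeatureTable(df, target_name="y", column_kinds={"species": CATEGORICAL})
        out, _ = encode_categories(t)
        assert out.data["species"].tolist() == [0, 1, 0]

    def test_decode_inverts_encode(self):
        df = pd.DataFrame({"species": ["a", "c", "b", "c"], "y": [1.0, 2, 3, 4]})
        t = FeatureTable(df, target_name="y", column_kinds={"species": CATEGORICAL})
        out, _ = encode_categories(t)
        back = decode_categories(out)
        assert back.data["species"].tolist() == ["a", "c", "b", "c"]


class TestPipeline:
    def test_stage_counts_reconcile(self):
        rng = np.random.default_rng(9)
        n = 80
        df = pd.DataFrame({
            "MW": rng.uniform(200, 700, n),
            "species": rng.integers(0, 3, n),
            "y": np.concatenate([rng.normal(0, 1, n - 2), [30.0, -30.0]]),
        })
        df.loc[4, "MW"] = np.nan
        t = FeatureTable(df, target_name="y", column_kinds={"species": CATEGORICAL})
        clean, reports = preprocess_table(t, seed=0)
        trim_report = reports[1]
        assert trim_report.n_rows_out == trim_report.n_rows_in - trim_report.n_trimmed
        assert clean.n_rows == trim_report.n_rows_out
        assert not clean.data.isna().any().any()
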