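"""Adaptive binning, quota planning, SMOTER, VAE and the augmentation loop."""

import numpy as np
import pandas as pd
import pytest

from sdml.augment import (
    BinPartition,
    SmoteParams,
    adaptive_bin_count,
    augment_dataset,
    make_bins,
    plan_quotas,
    smote_generate,
    vae_fit,
    vae_generate,
)
from sdml.config import AugmentConfig
from sdml.data import CATEGORICAL, InsufficientDataError, PROVENANCE, FeatureTable
from sdml.vae import TabularVAE, TrainingDivergenceError, VaeSpec
from tests.conftest import make_table


def _table(n, seed=0, skewed=False, species=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "a": rng.normal(size=n),
        "b": rng.uniform(0, 10, n),
    })
    y = np.exp(rng.normal(0, 1, n)) if skewed else rng.normal(0, 1, n)
    kinds = {}
    if species:
        df["species"] = rng.integers(0, 3, n)
        kinds["species"] = CATEGORICAL
        y = y + df["species"] * 1.5
    df["y"] = y
    return FeatureTable(df, target_name="y", column_kinds=kinds)


class TestMakeBins:
    @pytest.mark.parametrize("n_train,expected", [(462, 12), (60, 6), (24, 6), (144, 12), (100, 8)])
    def test_adaptive_bin_count(self, n_train, expected):
        assert adaptive_bin_count(n_train) == expected
        t = _table(n_train)
        bins = make_bins(t.y.to_numpy(), n_train)
        assert bins.n_bins == expected

    def test_counts_sum_and_range_coverage(self):
        t = _table(200, seed=1)
        y = t.y.to_numpy()
        bins = make_bins(y, 200)
        assert bins.n_samples.sum() == 200
        assert bins.edges[0] <= y.min() and bins.edges[-1] >= y.max()

    def test_strategy_follows_skewness(self):
        sym = make_bins(_table(120, seed=2).y.to_numpy(), 120)
        assert sym.strategy == "equal_width"
        skw = make_bins(_table(120, seed=2, skewed=True).y.to_numpy(), 120)
        assert skw.strategy == "equal_frequency"

    def test_too_small_raises(self):
        with pytest.raises(InsufficientDataError):
            make_bins(np.arange(23.0), 23)


class TestPlanQuotas:
    def test_factor_one_is_noop(self):
        bins = make_bins(_table(60).y.to_numpy(), 60)
        bins = plan_quotas(bins, 1.0)
        assert bins.quota.sum() == 0

    def test_symmetric_deficit_splits_evenly(self):
        bins = BinPartition(
            edges=np.array([0.0, 1.0, 2.0]), n_samples=np.array([10, 10]),
            mean=np.zeros(2), std=np.zeros(2), min=np.zeros(2), max=np.zeros(2),
            quota=np.zeros(2, int), strategy="equal_width", n_train=20,
        )
        bins = plan_quotas(bins, 2.0)
        assert bins.quota.tolist() == [10, 10]

    def test_sparse_bin_gets_largest_share(self):
        bins = BinPartition(
            edges=np.linspace(0, 3, 4), n_samples=np.array([30, 10, 20]),
            mean=np.zeros(3), std=np.zeros(3), min=np.zeros(3), max=np.zeros(3),
            quota=np.zeros(3, int), strategy="equal_width", n_train=60,
        )
        bins = plan_quotas(bins, 2.0)
        # brute-force largest-remainder apportionment of T=60 over weights
        # deficit+1 = (1, 21, 11): shares (1.818, 38.182, 20.0)
        assert bins.quota.tolist() == [2, 38, 20]
        assert bins.quota.sum() == 60
        assert bins.quota[1] == bins.quota.max()


class TestSmote:
    def test_replay_oracle_verifies_every_row(self):
        t = _table(120, seed=3, species=True)
        y = t.y.to_numpy()
        bins = plan_quotas(make_bins(y, 120), 2.0)
        params = SmoteParams(k_neighbors=5, noise_scale=0.0, seed=9)
        out, draws = smote_generate(t, bins, params, 80)
        assert out.n_rows == 80 and len(draws) == 80
        cont = t.continuous_features
        X = t.data[cont].to_numpy()
        for row, d in zip(range(80), draws):
            xi, xnn = X[d.seed_row], X[d.neighbor_row]
            expected = xi + d.mu * (xnn - xi) + d.delta
            np.testing.assert_allclose(out.data[cont].iloc[row].to_numpy(), expected,
                                       atol=1e-12)
            y_exp = y[d.seed_row] + d.mu * (y[d.neighbor_row] - y[d.seed_row])
            assert out.y.iloc[row] == pytest.approx(y_exp, abs=1e-12)
            # categorical copied from the seed row
            assert out.data["species"].iloc[row] == t.data["species"].iloc[d.seed_row]

    def test_neighbors_come_from_same_bin(self):
        t = _table(120, seed=4)
        y = t.y.to_numpy()
        bins = plan_quotas(make_bins(y, 120), 2.0)
        out, draws = smote_generate(t, bins, SmoteParams(seed=1), 50)
        assign = bins.assign(y)
        for d in draws:
            assert assign[d.seed_row] == assign[d.neighbor_row] == d.bin_index

    def test_noise_scale_zero_stays_on_segment(self):
        t = _table(100, seed=5)
        bins = plan_quotas(make_bins(t.y.to_numpy(), 100), 2.0)
        out, draws = smote_generate(t, bins, SmoteParams(noise_scale=0.0, seed=2), 40)
        X = t.data[t.continuous_features].to_numpy()
        for row, d in enumerate(draws):
            lo = np.minimum(X[d.seed_row], X[d.neighbor_row]) - 1e-12
            hi = np.maximum(X[d.seed_row], X[d.neighbor_row]) + 1e-12
            v = out.data[t.continuous_features].iloc[row].to_numpy()
            assert np.all(v >= lo) and np.all(v <= hi)

    def test_negative_n_rejected(self):
        t = _table(60)
        bins = make_bins(t.y.to_numpy(), 60)
        with pytest.raises(ValueError):
            smote_generate(t, bins, SmoteParams(), -1)


class TestVae:
    def test_untrained_state_samples_finite(self):
        t = _table(60, seed=6)
        state = vae_fit(t, VaeSpec(epochs=0, seed=0))
        bins = make_bins(t.y.to_numpy(), 60)
        out, idx = vae_generate(state, bins, 20, seed=1)
        assert out.n_rows == 20
        assert np.isfinite(out.data.to_numpy(float)).all()

    def test_zero_samples_gives_empty_table(self):
        t = _table(60, seed=6)
        state = vae_fit(t, VaeSpec(epochs=0, seed=0))
        bins = make_bins(t.y.to_numpy(), 60)
        out, idx = vae_generate(state, bins, 0, seed=1)
        assert out.n_rows == 0 and len(idx) == 0

    def test_point_mass_reconstruction_converges(self):
        X = np.zeros((100, 3))
        vae = TabularVAE(3, VaeSpec(epochs=100, seed=0)).fit(X)
        assert np.abs(vae.reconstruct(X)).max() < 0.1

    def test_loss_decreases_and_is_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 4))
        a = TabularVAE(4, VaeSpec(epochs=40, seed=3)).fit(X)
        b = TabularVAE(4, VaeSpec(epochs=40, seed=3)).fit(X)
        assert a.loss_history_[-1] < a.loss_history_[0]
        assert a.loss_history_ == b.loss_history_

    def test_prior_samples_match_standard_normal_mean(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(500, 2))
        vae = TabularVAE(2, VaeSpec(epochs=100, seed=0)).fit(X)
        S = vae.sample(1000, np.random.default_rng(1))
        assert np.all(np.abs(S.mean(axis=0)) < 0.2)

    def test_decoded_targets_respect_range_margin(self):
        t = _table(120, seed=9)
        state = vae_fit(t, VaeSpec(epochs=50, seed=0))
        bins = make_bins(t.y.to_numpy(), 120)
        out, _ = vae_generate(state, bins, 200, seed=2, range_margin=0.05)
        y = t.y.to_numpy()
        span = y.max() - y.min()
        decoded = out.data["y"].to_numpy()
        assert decoded.min() >= y.min() - 0.05 * span - 1e-9
        assert decoded.max() <= y.max() + 0.05 * span + 1e-9

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 3))
        vae = TabularVAE(3, VaeSpec(epochs=10, seed=1)).fit(X)
        back = TabularVAE.from_dict(vae.to_dict())
        r = np.random.default_rng(0)
        r2 = np.random.default_rng(0)
        np.testing.assert_allclose(vae.sample(7, r), back.sample(7, r2))


class TestAugmentDataset:
    def test_factor_one_identity(self):
        t = _table(60, seed=12)
        out, report = augment_dataset(t, AugmentConfig(expansion_factor=1.0), seed=0)
        assert out.n_rows == 60
        assert report.n_synthetic == 0
        assert (out.data[PROVENANCE] == "original").all()
        pd.testing.assert_frame_equal(out.data.drop(columns=[PROVENANCE]), t.data)

    def test_conservation_and_provenance_accounting(self):
        t = _table(120, seed=13, species=True)
        cfg = AugmentConfig(expansion_factor=3.0, vae_epochs=30)
        out, report = augment_dataset(t, cfg, seed=0)
        counts = out.data[PROVENANCE].value_counts()
        assert counts["original"] == 120
        assert report.n_synthetic == out.n_rows - 120
        assert counts.get("smote", 0) == report.n_smote
        assert counts.get("vae", 0) == report.n_vae

    def test_synthetic_targets_stay_in_their_bins(self):
        t = _table(120, seed=14)
        cfg = AugmentConfig(expansion_factor=3.0, vae_epochs=30)
        out, report = augment_dataset(t, cfg, seed=0)
        y = t.y.to_numpy()
        bins = make_bins(y, 120, skew_threshold=cfg.bin_skew_threshold)
        synth = out.data[out.data[PROVENANCE] != "original"]
        idx = bins.assign(synth["y"].to_numpy())
        w = bins.widths[idx]
        lo = bins.edges[idx] - 0.1 * w - 1e-9
        hi = bins.edges[idx + 1] + 0.1 * w + 1e-9
        ys = synth["y"].to_numpy()
        assert np.all(ys >= lo) and np.all(ys <= hi)

    def test_balance_strictly_improves(self):
        t = _table(150, seed=15)
        cfg = AugmentConfig(expansion_factor=3.0, vae_epochs=30)
        out, report = augment_dataset(t, cfg, seed=0)
        before = np.array(report.counts_before, float)
        after = np.array(report.counts_after, float)
        assert after.min() / after.max() > before.min() / before.max()

    def test_deterministic_for_fixed_seed(self):
        t = _table(100, seed=16)
        cfg = AugmentConfig(expansion_factor=2.0, vae_epochs=20)
        a, _ = augment_dataset(t, cfg, seed=4)
        b, _ = augment_dataset(t, cfg, seed=4)
        pd.testing.assert_frame_equal(a.data, b.data)
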