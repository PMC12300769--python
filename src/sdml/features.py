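"""Derived-feature construction and composite multi-statistic feature ranking.

Two named derived features are always built when their inputs are present:

* ``water_solubility_index = TPSA / (MW * (1 + 0.5 * logKow))`` — a composite
  solubility descriptor; high values mean polar, low-mass, hydrophilic
  compounds.
* ``absorption_kinetics = 1 - exp(-0.005 * ExposureTime)`` — a saturating
  first-order uptake term in exposure time.

Feature relevance is scored by five complementary statistics against the
target — the univariate F statistic (linear signal), k-NN mutual information
(general dependence), distance correlation, an equi-partition maximal
information coefficient, and regression ReliefF (local, instance-based) —
each min–max normalized across features and combined with user weights. A
bootstrap stability factor (fraction of resamples in which the feature ranks
in the top half) and a variance-inflation-factor penalty for redundancy
multiply the combined score, keeping the composite in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_regression

from .config import FeatureConfig
from .data import CONTINUOUS, FeatureTable

logger = logging.getLogger("sdml")

_EPS = 1e-6
STAT_NAMES = ("f_stat", "mutual_info", "dist_corr", "mic", "relieff")


@dataclass
class FeatureScore:
    feature: str
    f_stat: float
    mutual_info: float
    dist_corr: float
    mic: float
    relieff: float
    stability: float
    vif: float
    composite: float
    constant: bool = False

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "f_stat": self.f_stat,
            "mutual_info": self.mutual_info,
            "dist_corr": self.dist_corr,
            "mic": self.mic,
            "relieff": self.relieff,
            "stability": self.stability,
            "vif": self.vif,
            "composite": self.composite,
        }


# ----------------------------------------------------------- derived features

def derive_features(table: FeatureTable, config: FeatureConfig | None = None) -> FeatureTable:
    """Append named and generic derived features to the table.

    Rows where ``|MW * (1 + 0.5*logKow)| < 1e-12`` get a NaN water-solubility
    index. Generic transforms (square, sqrt(|x|), ln(|x|+eps)) and pairwise
    products are built only over the configured base features to bound
    dictionary growth.
    """
    config = config or FeatureConfig()
    df = table.data.copy()
    kinds = dict(table.column_kinds)

    mw, lk = config.mw_column, config.log_kow_column
    tp, et = config.tpsa_column, config.exposure_time_column
    if mw in df.columns and lk in df.columns and tp in df.columns:
        denom = df[mw].to_numpy(float) * (1.0 + 0.5 * df[lk].to_numpy(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            wsi = np.where(np.abs(denom) < 1e-12, np.nan, df[tp].to_numpy(float) / denom)
        df["water_solubility_index"] = wsi
        kinds["water_solubility_index"] = CONTINUOUS
    if et in df.columns:
        df["absorption_kinetics"] = 1.0 - np.exp(-0.005 * df[et].to_numpy(float))
        kinds["absorption_kinetics"] = CONTINUOUS

    base = [c for c in config.base_features if c in df.columns]
    if config.generic_transforms:
        for c in base:
            x = df[c].to_numpy(float)
            df[f"{c}^2"] = x * x
            df[f"sqrt|{c}|"] = np.sqrt(np.abs(x))
            df[f"ln|{c}|"] = np.log(np.abs(x) + _EPS)
            for name in (f"{c}^2", f"sqrt|{c}|", f"ln|{c}|"):
                kinds[name] = CONTINUOUS
    if config.pairwise_products:
        for i, a in enumerate(base):
            for b in base[i + 1:]:
                df[f"{a}*{b}"] = df[a].to_numpy(float) * df[b].to_numpy(float)
                kinds[f"{a}*{b}"] = CONTINUOUS

    out = table.with_data(df)
    out.column_kinds = kinds
    logger.info("derive_features: %d -> %d columns", table.data.shape[1], df.shape[1])
    return out


# ------------------------------------------------------------- raw statistics

def _pearson_f(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (sx * sy)
    r = np.nan_to_num(np.clip(r, -0.999999, 0.999999))
    return r**2 / (1 - r**2) * max(n - 2, 1)


def _dist_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Distance correlation of each column of X with y (O(n^2) per column)."""
    n = len(y)
    dy = np.abs(y[:, None] - y[None, :])
    B = dy - dy.mean(axis=0) - dy.mean(axis=1)[:, None] + dy.mean()
    dvar_y = (B * B).mean()
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        dx = np.abs(X[:, j][:, None] - X[:, j][None, :])
        A = dx - dx.mean(axis=0) - dx.mean(axis=1)[:, None] + dx.mean()
        dcov2 = (A * B).mean()
        dvar_x = (A * A).mean()
        denom = np.sqrt(dvar_x * dvar_y)
        out[j] = np.sqrt(max(dcov2, 0.0) / denom) if denom > 0 else 0.0
    return out


def _grid_list(n: int) -> list[tuple[int, int]]:
    cap = max(4, int(n**0.6))
    grids = []
    for i in range(2, cap // 2 + 1):
        for j in range(2, cap // i + 1):
            grids.append((i, j))
    return grids


def _quantile_codes(x: np.ndarray, sizes: list[int]) -> dict[int, np.ndarray]:
    codes = {}
    for k in sizes:
        edges = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
        codes[k] = np.searchsorted(edges, x, side="right")
    return codes


def _mic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Equi-partition MIC approximation with a B = n^0.6 grid cap."""
    n = len(y)
    grids = _grid_list(n)
    sizes = sorted({g for ij in grids for g in ij})
    ycodes = _quantile_codes(y, sizes)
    out = np.zeros(X.shape[1])
    for jcol in range(X.shape[1]):
        xcodes = _quantile_codes(X[:, jcol], sizes)
        best = 0.0
        for i, j in grids:
            joint = np.bincount(xcodes[i] * j + ycodes[j], minlength=i * j).astype(float)
            joint /= n
            px = joint.reshape(i, j).sum(axis=1)
            py = joint.reshape(i, j).sum(axis=0)
            outer = np.outer(px, py).ravel()
            nz = joint > 0
            mi = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
            best = max(best, mi / np.log(min(i, j)))
        out[jcol] = min(best, 1.0)
    return out


def _relieff(X: np.ndarray, y: np.ndarray, k: int = 10) -> np.ndarray:
    """Regression ReliefF: contrast of feature vs target differences among
    each instance's k nearest neighbors (standardized Euclidean metric)."""
    n, p = X.shape
    rng_x = np.ptp(X, axis=0)
    rng_x[rng_x == 0] = 1.0
    Z = (X - X.min(axis=0)) / rng_x
    rng_y = np.ptp(y)
    dy_scale = rng_y if rng_y > 0 else 1.0
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2) if n <= 400 else None
    if d2 is None:
        from scipy.spatial.distance import squareform, pdist

        d2 = squareform(pdist(Z, "sqeuclidean"))
    np.fill_diagonal(d2, np.inf)
    k = min(k, n - 1)
    nbrs = np.argpartition(d2, k - 1, axis=1)[:, :k]
    n_dc = 0.0
    n_df = np.zeros(p)
    n_dcdf = np.zeros(p)
    for i in range(n):
        js = nbrs[i]
        dyij = np.abs(y[i] - y[js]) / dy_scale
        dfij = np.abs(Z[i][None, :] - Z[js])
        n_dc += dyij.sum()
        n_df += dfij.sum(axis=0)
        n_dcdf += (dyij[:, None] * dfij).sum(axis=0)
    m = n * k
    if n_dc <= 0 or m - n_dc <= 0:
        return np.zeros(p)
    return n_dcdf / n_dc - (n_df - n_dcdf) / (m - n_dc)


def _raw_stats(X: np.ndarray, y: np.ndarray, config: FeatureConfig, seed: int) -> np.ndarray:
    """Stack of the five raw statistics, shape (5, n_features); constant
    features get zero everywhere."""
    const = np.ptp(X, axis=0) == 0
    stats_ = np.zeros((5, X.shape[1]))
    if (~const).any():
        Xv = X[:, ~const]
        stats_[0, ~const] = _pearson_f(Xv, y)
        stats_[1, ~const] = mutual_info_regression(
            Xv, y, n_neighbors=config.mi_neighbors, random_state=seed
        )
        stats_[2, ~const] = _dist_corr(Xv, y)
        stats_[3, ~const] = _mic(Xv, y)
        stats_[4, ~const] = _relieff(Xv, y, k=config.relieff_neighbors)
    return stats_


def _composite_raw(stats_: np.ndarray, weights: np.ndarray) -> np.ndarray:
    lo = stats_.min(axis=1, keepdims=True)
    hi = stats_.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(span > 0, (stats_ - lo) / span, 0.0)
    return weights @ norm


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF of each column regressed (with intercept) on all the others."""
    n, p = X.shape
    out = np.ones(p)
    if p < 2:
        return out
    for j in range(p):
        xj = X[:, j]
        if np.ptp(xj) == 0:
            out[j] = np.inf
            continue
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ beta
        ss_tot = np.sum((xj - xj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        out[j] = 1.0 / (1.0 - r2) if r2 < 1.0 - 1e-12 else 1e12
    return out


# ------------------------------------------------------------------- scoring

def score_features(
    table: FeatureTable,
    n_bootstrap: int | None = None,
    weights: dict[str, float] | None = None,
    seed: int = 0,
    config: FeatureConfig | None = None,
) -> list[FeatureScore]:
    """Rank every feature against the target by the composite score.

    ``composite = composite_raw * stability * vif_penalty`` where
    ``composite_raw`` is the weighted sum of the five min–max-normalized
    statistics, ``stability`` the fraction of bootstrap resamples in which the
    feature ranks in the top half by ``composite_raw``, and the VIF penalty is
    ``1 / (1 + max(0, vif - cap)/cap)`` with cap 10. Results are sorted by
    descending composite (name order breaks ties).
    """
    config = config or FeatureConfig()
    if n_bootstrap is None:
        n_bootstrap = config.n_bootstrap
    if table.target_name is None:
        raise ValueError("score_features requires a target column")
    if table.n_rows < 20:
        raise ValueError("score_features requires at least 20 rows")
    names = table.feature_names
    X = table.X.to_numpy(float)
    y = table.y.to_numpy(float)
    finite = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[finite], y[finite]

    wmap = dict(config.weights)
    if weights:
        wmap.update(weights)
    wvec = np.array([wmap.get(s, 0.0) for s in STAT_NAMES], dtype=float)
    if wvec.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    wvec = wvec / wvec.sum()

    raw = _raw_stats(X, y, config, seed)
    composite_raw = _composite_raw(raw, wvec)

    # bootstrap stability of the composite_raw ranking
    rng = np.random.default_rng(seed)
    p = len(names)
    top_counts = np.zeros(p)
    n_res = max(int(round(config.bootstrap_fraction * len(y))), 20)
    for b in range(n_bootstrap):
        idx = rng.integers(0, len(y), size=n_res)
        cb = _composite_raw(_raw_stats(X[idx], y[idx], config, seed + 1 + b), wvec)
        order = np.argsort(-cb, kind="stable")
        top_counts[order[: max(p // 2, 1)]] += 1
    stability = top_counts / n_bootstrap if n_bootstrap > 0 else np.ones(p)

    vif = _vif(X)
    cap = config.vif_cap
    penalty = 1.0 / (1.0 + np.maximum(0.0, vif - cap) / cap)
    const = np.ptp(X, axis=0) == 0
    composite = np.where(const, 0.0, composite_raw * stability * penalty)

    scores = [
        FeatureScore(
            feature=names[j],
            f_stat=float(raw[0, j]),
            mutual_info=float(raw[1, j]),
            dist_corr=float(raw[2, j]),
            mic=float(raw[3, j]),
            relieff=float(raw[4, j]),
            stability=float(stability[j]),
            vif=float(vif[j]),
            composite=float(composite[j]),
            constant=bool(const[j]),
        )
        for j in range(p)
    ]
    scores.sort(key=lambda s: (-s.composite, s.feature))
    return scores


def select_features(scores: list[FeatureScore], k: int) -> list[str]:
    """Top-k feature names by composite score; ties broken by name order."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored features")
    ordered = sorted(scores, key=lambda s: (-s.composite, s.feature))
    return [s.feature for s in ordered[:k]]


def scores_to_frame(scores: list[FeatureScore]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in scores])
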