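"""Stratified variational regression augmentation.

The training target (log RCF) is partitioned into 6–12 adaptive bins —
``n_bins = max(6, min(12, n_train // 12))`` — using equal-frequency cuts when
the target is strongly skewed and equal-width cuts otherwise. Each bin's
synthetic-sample quota is apportioned in proportion to its deficit against
the largest bin, so sparse target regions receive the most new samples.

Two generation pipelines fill the quotas:

* SMOTER interpolation within a bin: ``x_new = x_i + mu * (x_nn - x_i) +
  delta`` with ``mu ~ U(0,1)``, ``x_nn`` one of the seed row's k nearest
  same-bin neighbors, and ``delta`` per-feature Gaussian noise proportional to
  the feature's scale. The target interpolates the same way.
* A variational autoencoder trained jointly on the standardized features and
  target; prior samples are decoded, de-standardized, and assigned to the bin
  containing their decoded target.

Generation is iterative and self-monitored: every candidate must pass a
quality-control envelope (continuous features within the donor bin's observed
range +/- 5%, target within the bin edges +/- 10% of the bin width) before it
is credited against a quota. Unmet quotas after the round budget produce a
warning and a partial augmentation, never an exception.

All random draws (seed row, neighbor, mu, delta, latent z) are made from a
single seeded generator, and SMOTER draws are logged so a replay oracle can
verify every synthetic row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AugmentConfig, RunConfig
from .data import FeatureTable, InsufficientDataError, PROVENANCE
from .preprocess import sample_skewness
from .vae import TabularVAE, VaeSpec

logger = logging.getLogger("sdml")

EQUAL_FREQUENCY = "equal_frequency"
EQUAL_WIDTH = "equal_width"


# ------------------------------------------------------------------- binning

@dataclass
class BinPartition:
    edges: np.ndarray                  # length n_bins + 1, ascending
    n_samples: np.ndarray              # per-bin counts of the training target
    mean: np.ndarray
    std: np.ndarray
    min: np.ndarray
    max: np.ndarray
    quota: np.ndarray                  # synthetic samples to generate per bin
    strategy: str
    n_train: int

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def assign(self, y: np.ndarray) -> np.ndarray:
        """Bin index of each target value (clipped to the outer bins)."""
        idx = np.searchsorted(self.edges, y, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def adaptive_bin_count(n_train: int, min_bins: int = 6, max_bins: int = 12,
                       rows_per_bin: int = 12) -> int:
    """``max(6, min(12, floor(n_train / 12)))`` with the defaults."""
    return max(min_bins, min(max_bins, n_train // rows_per_bin))


def make_bins(
    target: np.ndarray,
    n_train: int | None = None,
    skew_threshold: float = 1.0,
    min_bins: int = 6,
    max_bins: int = 12,
    rows_per_bin: int = 12,
) -> BinPartition:
    """Partition the observed target range into adaptive bins with statistics."""
    y = np.asarray(target, dtype=float)
    if n_train is None:
        n_train = len(y)
    if n_train != len(y):
        raise ValueError("n_train must equal len(target)")
    if n_train < 2 * min_bins * 2:
        raise InsufficientDataError(
            f"need at least {4 * min_bins} training rows for binning, got {n_train}"
        )
    n_bins = adaptive_bin_count(n_train, min_bins, max_bins, rows_per_bin)
    skew = sample_skewness(y)
    strategy = EQUAL_FREQUENCY if abs(skew) > skew_threshold else EQUAL_WIDTH
    if strategy == EQUAL_FREQUENCY:
        edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        if len(edges) < n_bins + 1:      # heavy ties: fall back to equal width
            edges = np.linspace(y.min(), y.max(), n_bins + 1)
            strategy = EQUAL_WIDTH
    else:
        edges = np.linspace(y.min(), y.max(), n_bins + 1)
    if edges[-1] <= edges[0]:            # constant target: degenerate single span
        edges = np.linspace(edges[0] - 0.5, edges[0] + 0.5, n_bins + 1)

    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    mean = np.zeros(n_bins)
    std = np.zeros(n_bins)
    mn = np.zeros(n_bins)
    mx = np.zeros(n_bins)
    for b in range(n_bins):
        yb = y[idx == b]
        if len(yb):
            mean[b], std[b] = yb.mean(), yb.std()
            mn[b], mx[b] = yb.min(), yb.max()
        else:
            mean[b] = mn[b] = mx[b] = 0.5 * (edges[b] + edges[b + 1])
    return BinPartition(
        edges=edges, n_samples=counts, mean=mean, std=std, min=mn, max=mx,
        quota=np.zeros(n_bins, dtype=int), strategy=strategy, n_train=n_train,
    )


def plan_quotas(bins: BinPartition, expansion_factor: float) -> BinPartition:
    """Apportion the synthetic total over bins by deficit toward the largest.

    ``T = round((factor - 1) * n_train)``; per-bin weights are
    ``deficit_b + 1`` with ``deficit_b = max_b'(n_b') - n_b``; quotas are the
    largest-remainder apportionment of T over the weights (ties to the lower
    bin index), so they sum exactly to T.
    """
    if expansion_factor < 1:
        raise ValueError("expansion_factor must be >= 1")
    T = int(round((expansion_factor - 1) * bins.n_train))
    deficit = bins.n_samples.max() - bins.n_samples
    weights = (deficit + 1).astype(float)
    shares = T * weights / weights.sum()
    quotas = np.floor(shares).astype(int)
    remainder = T - quotas.sum()
    if remainder > 0:
        frac = shares - np.floor(shares)
        order = np.lexsort((np.arange(len(frac)), -frac))
        quotas[order[:remainder]] += 1
    bins.quota = quotas
    return bins


# ------------------------------------------------------------------- SMOTER

@dataclass(frozen=True)
class SmoteParams:
    k_neighbors: int = 5
    noise_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class SmoteDraw:
    """One logged interpolation, sufficient to replay the synthetic row."""

    bin_index: int
    seed_row: int                      # positional index into the training table
    neighbor_row: int
    mu: float
    delta: np.ndarray                  # per continuous feature, 0 for categorical


def _bin_members(table: FeatureTable, bins: BinPartition) -> list[np.ndarray]:
    idx = bins.assign(table.y.to_numpy(float))
    return [np.flatnonzero(idx == b) for b in range(bins.n_bins)]


def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n over non-negative weights."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0 or n <= 0:
        return np.zeros(len(weights), dtype=int)
    shares = n * weights / weights.sum()
    counts = np.floor(shares).astype(int)
    rem = n - counts.sum()
    if rem > 0:
        frac = shares - np.floor(shares)
        order = np.lexsort((np.arange(len(frac)), -frac))
        counts[order[:rem]] += 1
    return counts


def smote_generate(
    train: FeatureTable,
    bins: BinPartition,
    params: SmoteParams,
    n: int,
    bin_counts: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureTable, list[SmoteDraw]]:
    """Generate ``n`` SMOTER rows, allocated over bins by quota by default.

    Neighbors are found within the seed row's own bin under a standardized
    Euclidean metric on continuous features. Mixed data is handled the way
    regression SMOTE variants handle nominal columns: when the bin contains
    another row with the seed's exact categorical profile, neighbor candidates
    are restricted to that profile, so interpolation never blends across
    species unless a species is alone in its bin. Categorical columns are
    copied from the seed row; the target interpolates with the same ``mu``.
    Bins with fewer than 2 donors are excluded and their allocation
    reassigned. Returns the synthetic table and the draw log for replay
    verification.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cont = train.continuous_features
    cat = train.categorical_features
    members = _bin_members(train, bins)
    eligible = np.array([len(m) >= 2 for m in members])
    if bin_counts is None:
        weights = np.where(eligible, np.maximum(bins.quota, 0), 0).astype(float)
        if weights.sum() == 0:
            weights = eligible.astype(float)
        bin_counts = _apportion(n, weights)
    else:
        bin_counts = np.asarray(bin_counts, dtype=int)

    Xc = train.data[cont].to_numpy(float)
    sd = Xc.std(axis=0)
    sd_safe = np.where(sd > 1e-12, sd, 1.0)
    y = train.y.to_numpy(float)

    rows = []
    draws: list[SmoteDraw] = []
    for b, count in enumerate(bin_counts):
        if count <= 0:
            continue
        m = members[b]
        if len(m) < 2:
            continue
        Zb = Xc[m] / sd_safe
        d2 = ((Zb[:, None, :] - Zb[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        if cat:
            profiles = train.data[cat].to_numpy()[m]
            same = (profiles[:, None, :] == profiles[None, :, :]).all(axis=2)
            np.fill_diagonal(same, False)
            # restrict to the seed's categorical profile where possible
            has_mate = same.any(axis=1)
            d2 = np.where(has_mate[:, None] & ~same, np.inf, d2)
        order = np.argsort(d2, axis=1)
        n_cand = np.sum(np.isfinite(d2), axis=1)
        for _ in range(count):
            si = rng.integers(0, len(m))
            k = max(1, min(params.k_neighbors, int(n_cand[si])))
            nn = order[si][rng.integers(0, k)]
            i_row, nn_row = m[si], m[nn]
            mu = rng.uniform(0.0, 1.0)
            delta = rng.normal(0.0, params.noise_scale * sd)
            x_new = Xc[i_row] + mu * (Xc[nn_row] - Xc[i_row]) + delta
            y_new = y[i_row] + mu * (y[nn_row] - y[i_row])
            row = dict(zip(cont, x_new))
            for c in cat:
                row[c] = train.data[c].iloc[i_row]
            row[train.target_name] = y_new
            rows.append(row)
            draws.append(SmoteDraw(b, int(i_row), int(nn_row), float(mu), delta))
    df = pd.DataFrame(rows, columns=list(train.data.columns))
    out = train.with_data(df)
    return out, draws


# ------------------------------------------------------------- VAE pipeline

@dataclass
class VaeState:
    """Trained generator plus the column layout it was fitted on."""

    vae: TabularVAE
    columns: list[str]                 # continuous features + categoricals + target
    cat_codes: dict[str, np.ndarray]   # observed codes per categorical column
    target_name: str
    y_min: float
    y_max: float


def vae_fit(train: FeatureTable, spec: VaeSpec | None = None) -> VaeState:
    """Train the VAE on standardized continuous features + target jointly.

    Categorical code columns are included as numeric inputs and snapped back
    to observed codes at generation time.
    """
    spec = spec or VaeSpec()
    if spec.epochs > 0 and train.n_rows < 50:
        raise InsufficientDataError("VAE training requires at least 50 rows")
    cols = train.continuous_features + train.categorical_features + [train.target_name]
    X = train.data[cols].to_numpy(float)
    vae = TabularVAE(len(cols), spec)
    if spec.epochs > 0:
        vae.fit(X)
    else:
        vae.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        vae.sd_ = np.where(sd > 1e-12, sd, 1.0)
    cat_codes = {
        c: np.unique(train.data[c].to_numpy(float)) for c in train.categorical_features
    }
    y = train.y.to_numpy(float)
    return VaeState(vae, cols, cat_codes, train.target_name, float(y.min()), float(y.max()))


def vae_generate(
    state: VaeState,
    bins: BinPartition,
    n: int,
    seed: int = 0,
    range_margin: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureTable, np.ndarray]:
    """Decode ``n`` prior samples; returns the table and per-row bin indices.

    Decoded targets outside the observed global range +/- ``range_margin`` of
    the range are rejected and resampled (clipped after 50 attempts).
    Categorical columns are snapped to the nearest observed code.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tcol = state.columns.index(state.target_name)
    span = state.y_max - state.y_min
    lo = state.y_min - range_margin * span
    hi = state.y_max + range_margin * span
    samples = np.empty((0, len(state.columns)))
    attempts = 0
    while len(samples) < n and attempts < 50:
        batch = state.vae.sample(max(n - len(samples), 1), rng)
        keep = (batch[:, tcol] >= lo) & (batch[:, tcol] <= hi)
        samples = np.vstack([samples, batch[keep]])
        attempts += 1
    if len(samples) < n:
        extra = state.vae.sample(n - len(samples), rng)
        extra[:, tcol] = np.clip(extra[:, tcol], lo, hi)
        samples = np.vstack([samples, extra])
    samples = samples[:n]
    df = pd.DataFrame(samples, columns=state.columns)
    for c, codes in state.cat_codes.items():
        vals = df[c].to_numpy(float)
        snapped = codes[np.argmin(np.abs(vals[:, None] - codes[None, :]), axis=1)]
        df[c] = snapped.astype(int)
    bin_idx = bins.assign(df[state.target_name].to_numpy(float)) if n else np.empty(0, int)
    return FeatureTable(df, target_name=state.target_name), bin_idx


# --------------------------------------------------------------- QC + loop

@dataclass
class AugmentReport:
    n_original: int = 0
    n_synthetic: int = 0
    n_smote: int = 0
    n_vae: int = 0
    rounds_used: int = 0
    quotas_met: bool = True
    strategy: str = ""
    counts_before: list[int] = field(default_factory=list)
    counts_after: list[int] = field(default_factory=list)
    quota: list[int] = field(default_factory=list)
    acceptance_rate_smote: float = 1.0
    acceptance_rate_vae: float = 1.0
    mean_drift: list[float] = field(default_factory=list)    # per-bin |after - before|
    std_before: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()}


class _QC:
    """Per-bin acceptance envelopes over the original training rows."""

    def __init__(self, train: FeatureTable, bins: BinPartition,
                 envelope_margin: float, target_margin: float):
        self.cont = train.continuous_features
        self.bins = bins
        members = _bin_members(train, bins)
        X = train.data[self.cont].to_numpy(float)
        n_bins = bins.n_bins
        self.f_lo = np.zeros((n_bins, len(self.cont)))
        self.f_hi = np.zeros((n_bins, len(self.cont)))
        for b, m in enumerate(members):
            ref = X[m] if len(m) else X
            lo, hi = ref.min(axis=0), ref.max(axis=0)
            margin = envelope_margin * np.maximum(hi - lo, 1e-12)
            self.f_lo[b], self.f_hi[b] = lo - margin, hi + margin
        w = bins.widths
        self.t_lo = bins.edges[:-1] - target_margin * w
        self.t_hi = bins.edges[1:] + target_margin * w

    def accept(self, df: pd.DataFrame, bin_idx: np.ndarray, target_name: str) -> np.ndarray:
        X = df[self.cont].to_numpy(float)
        y = df[target_name].to_numpy(float)
        ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
        ok &= (X >= self.f_lo[bin_idx]).all(axis=1) & (X <= self.f_hi[bin_idx]).all(axis=1)
        ok &= (y >= self.t_lo[bin_idx]) & (y <= self.t_hi[bin_idx])
        return ok


def augment_dataset(
    train: FeatureTable,
    config: RunConfig | AugmentConfig | None = None,
    seed: int | None = None,
) -> tuple[FeatureTable, AugmentReport]:
    """Expand the training set to ``expansion_factor`` times its size.

    Runs the dual SMOTER/VAE pipeline with per-round quality control until all
    bin quotas are met or ``max_rounds`` is exhausted; the output carries a
    provenance column with values ``original``/``smote``/``vae``.
    """
    if config is None:
        cfg = AugmentConfig()
    elif isinstance(config, RunConfig):
        cfg = config.augment
    else:
        cfg = config
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    base = train.copy()
    base.data[PROVENANCE] = "original"
    n_train = train.n_rows
    y = train.y.to_numpy(float)
    bins = make_bins(y, n_train, skew_threshold=cfg.bin_skew_threshold,
                     min_bins=cfg.min_bins, max_bins=cfg.max_bins,
                     rows_per_bin=cfg.rows_per_bin)
    bins = plan_quotas(bins, cfg.expansion_factor)
    report = AugmentReport(
        n_original=n_train,
        strategy=bins.strategy,
        counts_before=bins.n_samples.tolist(),
        quota=bins.quota.tolist(),
        std_before=bins.std.tolist(),
    )
    if bins.quota.sum() == 0:
        report.counts_after = bins.n_samples.tolist()
        report.mean_drift = [0.0] * bins.n_bins
        logger.info("augment_dataset: expansion factor 1, no synthetic rows")
        return base, report

    members = _bin_members(train, bins)
    smoteable = np.array([len(m) >= 2 for m in members])
    use_vae = cfg.smote_share < 1.0 and n_train >= 50
    state = None
    if use_vae:
        spec = VaeSpec(
            latent_dim=cfg.vae_latent_dim, hidden_dims=tuple(cfg.vae_hidden_dims),
            epochs=cfg.vae_epochs, batch_size=cfg.vae_batch_size,
            kl_weight=cfg.vae_kl_weight, seed=seed,
        )
        state = vae_fit(train, spec)

    qc = _QC(train, bins, cfg.qc_envelope_margin, cfg.qc_target_margin)
    params = SmoteParams(cfg.smote_k_neighbors, cfg.smote_noise_scale, seed)
    remaining = bins.quota.copy()
    accepted_frames: list[pd.DataFrame] = []
    tried = {"smote": 0, "vae": 0}
    taken = {"smote": 0, "vae": 0}
    rounds = 0
    while remaining.sum() > 0 and rounds < cfg.max_rounds:
        rounds += 1
        late = rounds > cfg.max_rounds // 2
        # ---- SMOTER leg: generate directly inside each needy, donor-rich bin
        share = 1.0 if (not use_vae or late) else cfg.smote_share
        smote_counts = np.where(smoteable, np.ceil(remaining * share), 0).astype(int)
        if smote_counts.sum() > 0:
            cand, _ = smote_generate(train, bins, params, int(smote_counts.sum()),
                                     bin_counts=smote_counts, rng=rng)
            bidx = bins.assign(cand.y.to_numpy(float))
            ok = qc.accept(cand.data, bidx, train.target_name)
            tried["smote"] += len(cand.data)
            _credit(cand.data, bidx, ok, remaining, accepted_frames, "smote", taken)
        # ---- VAE leg: decode a batch, route by decoded target
        if use_vae and remaining.sum() > 0:
            batch = int(min(max(2 * remaining.sum(), 32), 4 * n_train))
            cand, bidx = vae_generate(state, bins, batch,
                                      range_margin=cfg.qc_envelope_margin, rng=rng)
            cand.data = cand.data[list(train.data.columns)]
            cand.column_kinds = dict(train.column_kinds)
            ok = qc.accept(cand.data, bidx, train.target_name)
            tried["vae"] += len(cand.data)
            _credit(cand.data, bidx, ok, remaining, accepted_frames, "vae", taken)

    report.rounds_used = rounds
    report.quotas_met = bool(remaining.sum() == 0)
    if not report.quotas_met:
        logger.warning(
            "augment_dataset: %d of %d quota rows unmet after %d rounds",
            int(remaining.sum()), int(bins.quota.sum()), rounds,
        )
    for key in ("smote", "vae"):
        rate = taken[key] / tried[key] if tried[key] else 1.0
        setattr(report, f"acceptance_rate_{key}", rate)
    report.n_smote, report.n_vae = taken["smote"], taken["vae"]
    report.n_synthetic = taken["smote"] + taken["vae"]

    if accepted_frames:
        synth = pd.concat(accepted_frames, ignore_index=True)
        out_df = pd.concat([base.data, synth], ignore_index=True)
    else:
        out_df = base.data
    out = base.with_data(out_df)

    y_after = out.data[train.target_name].to_numpy(float)
    idx_after = bins.assign(y_after)
    counts_after, drift = [], []
    for b in range(bins.n_bins):
        yb = y_after[idx_after == b]
        counts_after.append(int(len(yb)))
        drift.append(float(abs(yb.mean() - bins.mean[b])) if len(yb) else 0.0)
    report.counts_after = counts_after
    report.mean_drift = drift
    logger.info(
        "augment_dataset: %d -> %d rows (%d smote, %d vae, %d rounds)",
        n_train, out.n_rows, taken["smote"], taken["vae"], rounds,
    )
    return out, report


def _credit(df: pd.DataFrame, bidx: np.ndarray, ok: np.ndarray,
            remaining: np.ndarray, frames: list, tag: str, taken: dict) -> None:
    """Credit QC-passing candidates against bin quotas, bin by bin."""
    keep_rows = []
    for b in range(len(remaining)):
        if remaining[b] <= 0:
            continue
        rows = np.flatnonzero(ok & (bidx == b))[: remaining[b]]
        remaining[b] -= len(rows)
        keep_rows.extend(rows.tolist())
    if keep_rows:
        sub = df.iloc[keep_rows].copy()
        sub[PROVENANCE] = tag
        frames.append(sub)
        taken[tag] += len(keep_rows)
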