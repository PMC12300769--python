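"""PFAS-like synthetic data with a known sparse ground truth.

The study-scale dataset of chemical–plant exposure records is not public, so
every stage of the workflow is exercised on simulated tables that emulate its
structure: molecular weight (g/mol), log Kow, pKa, TPSA (Å²), exposure time
(days), an integer plant-species code, and a log10 root concentration factor
target. The target is a known sparse function of the features — a positive
molecular-weight effect, a saturating exposure-time kinetics term, a negative
water-solubility-index effect, per-species offsets (which make the target
marginal multi-modal) and one interaction — plus Gaussian noise, so recovery
tests can check any stage against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CATEGORICAL, CONTINUOUS, FeatureTable

__all__ = ["GeneratorSpec", "TruthRecord", "simulate_dataset", "make_worked_example"]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic chemical–plant exposure generator.

    Defaults give a learnable-but-noisy regression task: molecular weight and
    species dominate, exposure kinetics and one interaction contribute, and
    independent noise features carry nothing.
    """

    n: int = 616
    seed: int = 0
    noise_sd: float = 0.4
    n_noise_features: int = 0
    species_levels: int = 3
    species_offsets: tuple | None = None     # default: evenly spans [-3, 0]
    missing_rate: float = 0.0
    betas: tuple = (1.0, 0.8, 1.2, 0.5)      # MW, kinetics, WSI(-), MW x kinetics
    mw_range: tuple = (214.0, 714.0)         # short- to long-chain PFAS masses
    logkow_slope: float = 1.0                # logKow ~ slope * MW/100 + noise
    logkow_noise_sd: float = 0.6
    target_name: str = "logRCF"

    def resolved_offsets(self) -> np.ndarray:
        if self.species_offsets is not None:
            return np.asarray(self.species_offsets, dtype=float)
        return np.linspace(-3.0, 0.0, self.species_levels)


@dataclass
class TruthRecord:
    """The planted response surface, reusable as an oracle in recovery tests."""

    betas: tuple
    species_offsets: np.ndarray
    noise_sd: float
    terms: list[str] = field(default_factory=list)

    def evaluate(self, df: pd.DataFrame) -> np.ndarray:
        """Noise-free target for rows with the generator's feature columns."""
        b1, b2, b3, b4 = self.betas
        mw = df["MW"].to_numpy(float) / 100.0
        kin = 1.0 - np.exp(-0.005 * df["ExposureTime"].to_numpy(float))
        denom = df["MW"].to_numpy(float) * (1.0 + 0.5 * df["logKow"].to_numpy(float))
        wsi = df["TPSA"].to_numpy(float) / denom
        sp = df["species"].to_numpy(int)
        return (
            b1 * mw
            + b2 * kin
            - b3 * wsi
            + b4 * mw * kin
            + self.species_offsets[sp]
        )


def simulate_dataset(spec: GeneratorSpec) -> tuple[FeatureTable, TruthRecord]:
    """Draw a synthetic exposure table and return it with its ground truth.

    Feature marginals: MW uniform on ``mw_range``; logKow positively
    correlated with MW; pKa uniform on [-1, 5]; TPSA uniform on [0, 80];
    exposure time uniform on [1, 60] days; species uniform over its levels.
    ``noise_sd = 0`` and ``missing_rate = 0`` make the target exactly equal to
    the truth function.
    """
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    mw = rng.uniform(*spec.mw_range, size=n)
    logkow = spec.logkow_slope * mw / 100.0 + rng.normal(0.0, spec.logkow_noise_sd, size=n)
    pka = rng.uniform(-1.0, 5.0, size=n)
    tpsa = rng.uniform(0.0, 80.0, size=n)
    time = rng.uniform(1.0, 60.0, size=n)
    species = rng.integers(0, spec.species_levels, size=n)

    df = pd.DataFrame(
        {
            "MW": mw,
            "logKow": logkow,
            "pKa": pka,
            "TPSA": tpsa,
            "ExposureTime": time,
            "species": species,
        }
    )
    for j in range(spec.n_noise_features):
        df[f"noise_{j + 1}"] = rng.normal(0.0, 1.0, size=n)

    truth = TruthRecord(
        betas=spec.betas,
        species_offsets=spec.resolved_offsets(),
        noise_sd=spec.noise_sd,
        terms=[
            "MW/100",
            "1 - exp(-0.005 * ExposureTime)",
            "-TPSA / (MW * (1 + 0.5*logKow))",
            "(MW/100) * (1 - exp(-0.005 * ExposureTime))",
            "species offset",
        ],
    )
    df[spec.target_name] = truth.evaluate(df) + rng.normal(0.0, spec.noise_sd, size=n)

    if spec.missing_rate > 0:
        feature_cols = [c for c in df.columns if c != spec.target_name]
        mask = rng.random((n, len(feature_cols))) < spec.missing_rate
        for j, col in enumerate(feature_cols):
            if col == "species":
                continue  # the categorical code stays observed
            df.loc[mask[:, j], col] = np.nan

    kinds = {c: CONTINUOUS for c in df.columns if c != spec.target_name}
    kinds["species"] = CATEGORICAL
    table = FeatureTable(df, target_name=spec.target_name, column_kinds=kinds)
    return table, truth


def make_worked_example() -> FeatureTable:
    """A frozen 24-row table, small enough for hand-checked quartiles and bins.

    Deterministically regenerated (fixed seed, values rounded to 4 decimals)
    so it is identical on every run.
    """
    spec = GeneratorSpec(n=24, seed=42, noise_sd=0.3)
    table, _ = simulate_dataset(spec)
    table.data[:] = table.data.round(4)
    table.data["species"] = table.data["species"].astype(int)
    return table
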