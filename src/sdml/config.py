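"""Run configuration: every tunable stage parameter in one serializable object.

The configuration nests one dataclass per stage and round-trips losslessly
through YAML. A short hash of the canonical serialization is logged by each
stage so runs can be matched to their exact settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import yaml


@dataclass
class SplitConfig:
    train_fraction: float = 0.75
    seed: int = 0


@dataclass
class PreprocessConfig:
    skew_threshold: float = 1.0          # transform columns with skewness above this
    log_shift_epsilon: float = 1e-6      # shift = max(0, eps - min(x)) before log10
    imputer_trees: int = 100
    imputer_tol: float = 1e-3
    imputer_max_rounds: int = 10
    one_hot: bool = False                # ordinal integer codes by default


@dataclass
class FeatureConfig:
    base_features: list[str] = field(
        default_factory=lambda: ["MW", "logKow", "pKa", "TPSA", "ExposureTime"]
    )
    mw_column: str = "MW"
    log_kow_column: str = "logKow"
    tpsa_column: str = "TPSA"
    exposure_time_column: str = "ExposureTime"
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "f_stat": 0.2, "mutual_info": 0.2, "dist_corr": 0.2, "mic": 0.2, "relieff": 0.2,
        }
    )
    n_bootstrap: int = 100
    bootstrap_fraction: float = 0.8
    vif_cap: float = 10.0
    mi_neighbors: int = 3
    relieff_neighbors: int = 10
    generic_transforms: bool = True      # square, sqrt(|x|), ln(|x|+eps) of base features
    pairwise_products: bool = True


@dataclass
class AugmentConfig:
    expansion_factor: float = 9.0        # final size = factor x original train size
    min_bins: int = 6
    max_bins: int = 12
    rows_per_bin: int = 12               # n_bins = max(min, min(max, n_train // rows_per_bin))
    bin_skew_threshold: float = 1.0
    smote_share: float = 0.5
    smote_k_neighbors: int = 5
    smote_noise_scale: float = 0.02
    vae_hidden_dims: list[int] = field(default_factory=lambda: [32, 16])
    vae_latent_dim: int = 8
    vae_epochs: int = 200
    vae_batch_size: int = 32
    vae_kl_weight: float = 1.0
    qc_envelope_margin: float = 0.05     # fraction of per-bin feature range
    qc_target_margin: float = 0.1        # fraction of bin width
    max_rounds: int = 20
    seed: int = 0


@dataclass
class ModelConfig:
    n_folds: int = 5
    hpo_budget: int = 50
    seed: int = 0
    deterministic: bool = True           # single-thread boosters for exact reproducibility


@dataclass
class SymregConfig:
    gp_population: int = 2000
    gp_generations: int = 100
    gp_parsimony: float = 0.001
    gp_tournament: int = 20
    mftec_top_m: int = 8
    hsie_max_order: int = 3
    seed: int = 0


@dataclass
class RunConfig:
    split: SplitConfig = field(default_factory=SplitConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    models: ModelConfig = field(default_factory=ModelConfig)
    symreg: SymregConfig = field(default_factory=SymregConfig)

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            sub = d.get(f.name, {})
            kwargs[f.name] = f.default_factory().__class__(**sub)  # type: ignore[misc]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            d = yaml.safe_load(path_or_text)
        else:
            with open(path_or_text, encoding="utf-8") as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d or {})

    def hash(self) -> str:
        """Short stable hash of the canonical YAML serialization."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
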