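"""Configuration objects for the synthetic county generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; the message names the field."""


@dataclass(frozen=True)
class CountyConfig:
    """Study-design parameters for a synthetic county.

    The defaults describe a mid-sized urban county: a 24x24 grid of square
    1-km tracts (576 tracts) nested in 36 subregional areas (SRAs) of 4x4
    tracts, log-normal tract populations averaging ~5 000 residents, an AAPI
    population share with mean ~0.11, food-outlet intensity tracking
    population, and a spatial-lag disease-rate process observed for 7 years
    with small-cell suppression at counts below 11.
    """

    n_rows: int = 24
    n_cols: int = 24
    tract_side: float = 1000.0  # metres
    sra_block: int = 4
    seed: int = 0
    pop_log_mean: float = 8.45
    pop_log_sd: float = 0.35
    aapi_beta_a: float = 2.0
    aapi_beta_b: float = 16.4
    outlet_rate_per_1k: float = 3.7
    supermarket_rate_per_10k: float = 0.6
    aapi_outlet_affinity: float = 3.0
    true_rho: float = 0.5
    true_beta: Sequence[float] = (36.0, 24.0, 18.0)
    covariate_cols: Sequence[str] = ("pop_density", "pct_obese", "pct_over65")
    noise_sd: float = 24.0
    suppression_threshold: int = 11
    n_years: int = 7
    pop_points_per_tract: int = 25

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "sra_block", "pop_points_per_tract"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_rows % self.sra_block or self.n_cols % self.sra_block:
            raise ConfigurationError("sra_block must divide n_rows and n_cols")
        if not abs(self.true_rho) < 1:
            raise ConfigurationError("true_rho must satisfy |true_rho| < 1")
        if self.tract_side <= 0:
            raise ConfigurationError("tract_side must be positive")
        if self.suppression_threshold < 0:
            raise ConfigurationError("suppression_threshold must be >= 0")
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.outlet_rate_per_1k < 0:
            raise ConfigurationError("outlet_rate_per_1k must be >= 0")
        if len(self.true_beta) != len(self.covariate_cols):
            raise ConfigurationError(
                "true_beta length must match covariate_cols length"
            )

    @property
    def n_tracts(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_sras(self) -> int:
        return (self.n_rows // self.sra_block) * (self.n_cols // self.sra_block)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_beta"] = list(self.true_beta)
        d["covariate_cols"] = list(self.covariate_cols)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CountyConfig":
        d = dict(d)
        if "true_beta" in d:
            d["true_beta"] = tuple(d["true_beta"])
        if "covariate_cols" in d:
            d["covariate_cols"] = tuple(d["covariate_cols"])
        return cls(**d)
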