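"""Configuration objects for the synthetic-data generators and the pipeline.

A single integer seed drives everything; each generator derives its own child
seed from ``(seed, generator-name)`` so that adding a new generator never
perturbs the random streams of existing ones.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

__all__ = ["SyntheticConfig", "ConfigError", "child_rng", "child_seed"]


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


FractionSpec = Union[float, Mapping[str, float]]

# Default secondary-structure transition matrix, row/column order (H, E, C).
# Strong self-transitions give DSSP-like run lengths (mean helix ~10 residues).
_DEFAULT_SS_TRANSITION = (
    (0.90, 0.02, 0.08),
    (0.02, 0.85, 0.13),
    (0.08, 0.10, 0.82),
)


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-generator seed below 2**31 from a master seed.

    Uses CRC32 of the generator name so the mapping is independent of the
    order in which generators are invoked.
    """
    return (int(seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31 - 1)


def child_rng(seed: int, name: str) -> np.random.Generator:
    """A numpy Generator seeded from the master seed and a generator name."""
    return np.random.default_rng(child_seed(seed, name))


def _check_prob(name: str, value: float) -> None:
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1]; got {value!r}")


def _check_positive_int(name: str, value: int) -> None:
    if not isinstance(value, (int, np.integer)) or value <= 0:
        raise ConfigError(f"{name} must be a positive integer; got {value!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters controlling every synthetic generator.

    Fractions planted per condition (``planted_ip_fraction``,
    ``planted_len_fraction``) accept either a single float (applied to every
    condition) or a mapping from treatment label to float.
    """

    seed: int = 0
    # --- peptidome ---
    n_samples_per_group: int = 4
    n_peptides: int = 2000
    planted_ip_fraction: FractionSpec = 0.78
    planted_len_fraction: FractionSpec = 0.60
    intensity_logmean: float = 14.0   # natural-log scale of raw precursor intensity
    intensity_logsd: float = 1.2
    charge_duplicate_rate: float = 0.2  # fraction of peptides emitted at two charges
    # --- intensity matrix ---
    n_features: int = 1000
    n_de: int = 100
    de_log2fc: float = 2.0
    noise_sd: float = 0.5             # log2-scale replicate noise (prior scale)
    noise_prior_df: float = 6.0       # df of the inverse-chi2 variance prior
    missing_rate: float = 0.05
    missing_mode: str = "mcar"        # "mcar" or "censor" (intensity-dependent)
    # --- structures ---
    n_proteins: int = 60
    protein_len_lo: int = 150
    protein_len_hi: int = 400
    ss_transition: tuple = _DEFAULT_SS_TRANSITION
    exposure_alpha: float = 1.6
    exposure_beta: float = 3.0
    acidic_enrichment_delta: float = 0.08
    # --- embeddings ---
    embedding_dim: int = 16
    embedding_signal: float = 10.0
    embedding_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_samples_per_group", "n_peptides", "n_features",
                     "n_proteins", "embedding_dim", "protein_len_lo",
                     "protein_len_hi"):
            _check_positive_int(name, getattr(self, name))
        if self.n_de < 0 or self.n_de > self.n_features:
            raise ConfigError(
                f"n_de must satisfy 0 <= n_de <= n_features; got {self.n_de}")
        if self.protein_len_lo > self.protein_len_hi:
            raise ConfigError("protein_len_lo must not exceed protein_len_hi")
        for name in ("missing_rate", "charge_duplicate_rate"):
            _check_prob(name, getattr(self, name))
        for name, value in self._fraction_items("planted_ip_fraction"):
            _check_prob(name, value)
        for name, value in self._fraction_items("planted_len_fraction"):
            _check_prob(name, value)
        for name in ("intensity_logmean", "intensity_logsd", "de_log2fc",
                     "exposure_alpha", "exposure_beta",
                     "acidic_enrichment_delta", "embedding_signal",
                     "embedding_noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.exposure_alpha <= 0 or self.exposure_beta <= 0:
            raise ConfigError("beta-distribution parameters must be positive")
        if not (math.isfinite(self.noise_sd) and self.noise_sd > 0):
            raise ConfigError("noise_sd must be finite and positive")
        if math.isnan(self.noise_prior_df) or self.noise_prior_df <= 0:
            raise ConfigError("noise_prior_df must be positive (inf allowed)")
        if self.missing_mode not in ("mcar", "censor"):
            raise ConfigError("missing_mode must be 'mcar' or 'censor'")
        T = np.asarray(self.ss_transition, dtype=float)
        if T.shape != (3, 3) or (T < 0).any():
            raise ConfigError("ss_transition must be a non-negative 3x3 matrix")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigError("ss_transition rows must sum to 1 within 1e-9")

    def _fraction_items(self, name: str):
        spec = getattr(self, name)
        if isinstance(spec, Mapping):
            return [(f"{name}[{k}]", v) for k, v in spec.items()]
        return [(name, spec)]

    def fraction_for(self, name: str, treatment: str) -> float:
        """Resolve a per-condition fraction for a treatment label."""
        spec = getattr(self, name)
        if isinstance(spec, Mapping):
            if treatment not in spec:
                raise ConfigError(f"{name} has no entry for treatment {treatment!r}")
            return float(spec[treatment])
        return float(spec)

    def rng(self, name: str) -> np.random.Generator:
        return child_rng(self.seed, name)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["planted_ip_fraction"], Mapping):
            d["planted_ip_fraction"] = dict(d["planted_ip_fraction"])
        if isinstance(d["planted_len_fraction"], Mapping):
            d["planted_len_fraction"] = dict(d["planted_len_fraction"])
        d["ss_transition"] = [list(row) for row in np.asarray(self.ss_transition)]
        return d
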