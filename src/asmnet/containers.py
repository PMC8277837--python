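"""In-memory containers shared across pipeline stages.

Counts and expression values live in pandas DataFrames (genes as rows,
samples as columns); sample metadata (condition, optional age/sex) lives in a
parallel DataFrame indexed by sample id. ``condition`` is always one of
``"case"`` / ``"control"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONDITIONS = ("case", "control")


class AsmnetError(Exception):
    """Base class for user-facing errors."""


class ConfigurationError(AsmnetError):
    """Invalid configuration or malformed input."""


def _check_samples(values: pd.DataFrame, samples: pd.DataFrame) -> None:
    if values.columns.duplicated().any():
        raise ConfigurationError("duplicate sample ids")
    if values.index.duplicated().any():
        raise ConfigurationError("duplicate gene ids")
    missing = set(values.columns) - set(samples.index)
    if missing:
        raise ConfigurationError(f"samples missing from sample sheet: {sorted(missing)}")
    bad = set(samples["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ConfigurationError(f"unknown condition labels: {sorted(bad)} (expected {CONDITIONS})")


@dataclass
class CountMatrix:
    """Raw integer counts (genes x samples) plus the sample sheet."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index: sample_id; columns: condition [, age, sex]

    def __post_init__(self) -> None:
        _check_samples(self.counts, self.samples)
        if (self.counts.to_numpy() < 0).any():
            raise ConfigurationError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.loc[list(self.counts.columns)]
        return list(sel.index[sel["condition"] == condition])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[gene_ids], self.samples)


@dataclass
class ExpressionMatrix:
    """Normalized log2-CPM expression values with the same sample sheet."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_samples(self.values, self.samples)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.loc[list(self.values.columns)]
        return list(sel.index[sel["condition"] == condition])

    def condition_values(self, condition: str) -> pd.DataFrame:
        return self.values[self.condition_samples(condition)]


@dataclass
class SimTruth:
    """Ground truth emitted by the synthetic generator."""

    de_genes: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1 (sign of lfc)
    module_map: dict[str, int] = field(default_factory=dict)
    rewired_modules: set[int] = field(default_factory=set)
    regulator_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.rewired_modules:
            if m not in self.regulator_of:
                raise ConfigurationError(f"rewired module {m} has no regulator")
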