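"""Core tabular domain types shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionTable", "FormatError", "DesignError"]


class FormatError(ValueError):
    """Malformed input file content."""


class DesignError(ValueError):
    """Sample/condition design inconsistency."""


@dataclass
class ExpressionTable:
    """Gene x sample matrix of nonnegative abundances plus the design.

    ``values`` is indexed by gene with one column per sample;
    ``design`` maps each sample name to its condition label.
    """

    values: pd.DataFrame
    design: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
            bad = np.argwhere(~np.isfinite(arr) | (arr < 0))[0]
            raise FormatError(
                f"non-finite or negative value at gene "
                f"{self.values.index[bad[0]]!r}, sample "
                f"{self.values.columns[bad[1]]!r}")
        unknown = [s for s in self.values.columns if s not in self.design]
        if unknown:
            raise DesignError(f"samples without condition assignment: {unknown}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.design[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.design[s] == condition]
        if not out:
            raise DesignError(f"condition {condition!r} has no samples")
        return out

    def condition_values(self, gene: str, condition: str) -> np.ndarray:
        return self.values.loc[gene, self.condition_samples(condition)].to_numpy(
            dtype=float)

    def condition_means(self, condition: str) -> pd.Series:
        return self.values[self.condition_samples(condition)].mean(axis=1)

    def equals(self, other: "ExpressionTable") -> bool:
        return self.values.equals(other.values) and self.design == other.design
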