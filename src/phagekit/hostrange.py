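"""Efficiency-of-plating (EOP) host-range analysis.

EOP is the titer a phage reaches on a test strain divided by its titer on
its isolation (reference) host. Values above 1 are possible — some strains
plate a phage better than its own host — so EOP is a ratio, not a
probability. Values are classified into four tiers:

* high: EOP >= 0.5
* medium: 0.1 <= EOP < 0.5
* poor: 0.001 <= EOP < 0.1
* inefficient: EOP < 0.001

The published tier wording overlaps at 0.001 ("poor 0.001-0.1" vs
"inefficient <= 0.001"); this module resolves it with half-open intervals so
every nonnegative EOP maps to exactly one tier, 0.001 falling in "poor".
Host-range *breadth* is the percentage of tested strains a phage infects at
all (EOP > 0 by default), reported half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import require, round_half_up

__all__ = [
    "TIER_ORDER",
    "compute_eop",
    "classify_eop",
    "breadth_percent",
    "HostRangeMatrix",
    "summarize_matrix",
    "read_titer_csv",
    "read_reference_csv",
]

#: Tiers from least to most productive infection.
TIER_ORDER = ("inefficient", "poor", "medium", "high")

_DEFAULT_BOUNDS = (0.5, 0.1, 0.001)  # high / medium / poor lower bounds


def compute_eop(test_titer: float, reference_titer: float) -> float:
    """Efficiency of plating: test-strain titer over reference-host titer."""
    require(reference_titer > 0, "reference_titer must be positive")
    require(test_titer >= 0, "test_titer must be nonnegative")
    return test_titer / reference_titer


def classify_eop(
    eop: float, bounds: tuple[float, float, float] = _DEFAULT_BOUNDS
) -> str:
    """Map an EOP value to its tier.

    ``bounds`` are the inclusive lower bounds of (high, medium, poor);
    anything below the poor bound is inefficient.
    """
    require(eop >= 0, "EOP must be nonnegative")
    high, medium, poor = bounds
    require(high > medium > poor > 0, "tier bounds must be strictly decreasing")
    if eop >= high:
        return "high"
    if eop >= medium:
        return "medium"
    if eop >= poor:
        return "poor"
    return "inefficient"


def breadth_percent(
    eops: Sequence[float] | np.ndarray, threshold: float = 0.0
) -> float:
    """Percent of strains with EOP strictly above *threshold*, half-up 1 dp.

    The default threshold 0 counts any plaque formation as susceptibility,
    the convention behind spot-test breadth percentages like 20/21 -> 95.2.
    """
    values = np.asarray(eops, dtype=float)
    require(values.size > 0, "breadth requires at least one strain")
    require(bool(np.all(values >= 0)), "EOP values must be nonnegative")
    return round_half_up(100.0 * float(np.sum(values > threshold)) / values.size, 1)


@dataclass(frozen=True)
class HostRangeMatrix:
    """Complete phage x strain grid of EOP values.

    ``eop`` is a DataFrame with phage ids as the index and strain ids as
    columns; every cell must be present (0 means no plaques).
    """

    eop: pd.DataFrame

    def __post_init__(self) -> None:
        missing = self.eop.isna()
        if missing.to_numpy().any():
            row, col = np.argwhere(missing.to_numpy())[0]
            raise ValueError(
                "host-range grid is incomplete: missing cell "
                f"(phage={self.eop.index[row]!r}, strain={self.eop.columns[col]!r})"
            )
        require(bool((self.eop.to_numpy() >= 0).all()), "EOP values must be nonnegative")
        require(self.eop.index.is_unique, "duplicate phage ids")
        require(self.eop.columns.is_unique, "duplicate strain ids")

    @classmethod
    def from_titers(
        cls, titers: pd.DataFrame, reference_titers: pd.Series
    ) -> "HostRangeMatrix":
        """Build an EOP grid from raw test titers and per-phage reference titers."""
        require(
            set(titers.index) <= set(reference_titers.index),
            "every phage needs a reference titer",
        )
        refs = reference_titers.loc[titers.index]
        require(bool((refs > 0).all()), "reference titers must be positive")
        return cls(titers.div(refs, axis=0))

    @property
    def phages(self) -> list[str]:
        return list(self.eop.index)

    @property
    def strains(self) -> list[str]:
        return list(self.eop.columns)

    def tiers(self) -> pd.DataFrame:
        """Tier label for every cell."""
        return self.eop.map(classify_eop)

    def breadths(self, threshold: float = 0.0) -> pd.Series:
        """Per-phage breadth percentage."""
        return pd.Series(
            {p: breadth_percent(self.eop.loc[p].to_numpy(), threshold) for p in self.phages},
            name="breadth_percent",
        )


def summarize_matrix(matrix: HostRangeMatrix, threshold: float = 0.0) -> dict:
    """Per-phage and per-strain host-range report.

    For each phage: breadth percentage, tier counts over strains, and the
    strain with the highest EOP. For each strain: the number of phages that
    infect it (EOP above *threshold*).
    """
    tiers = matrix.tiers()
    breadths = matrix.breadths(threshold)
    per_phage = {}
    for p in matrix.phages:
        row = matrix.eop.loc[p]
        counts = tiers.loc[p].value_counts().to_dict()
        per_phage[p] = {
            "breadth_percent": float(breadths[p]),
            "tier_counts": {t: int(counts.get(t, 0)) for t in TIER_ORDER},
            "max_eop_strain": str(row.idxmax()),
            "max_eop": float(row.max()),
        }
    per_strain = {
        s: int((matrix.eop[s] > threshold).sum()) for s in matrix.strains
    }
    return {"per_phage": per_phage, "per_strain_infecting_phages": per_strain}


def read_titer_csv(path: str | Path) -> pd.DataFrame:
    """Read a titer matrix CSV: first column phage ids, header strain ids."""
    return pd.read_csv(path, index_col=0)


def read_reference_csv(path: str | Path) -> pd.Series:
    """Read per-phage reference titers: CSV with columns phage_id, reference_titer."""
    df = pd.read_csv(path)
    require(
        {"phage_id", "reference_titer"} <= set(df.columns),
        "reference CSV needs columns phage_id, reference_titer",
    )
    return df.set_index("phage_id")["reference_titer"]
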