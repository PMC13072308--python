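"""Phage adsorption kinetics.

Free-phage counts :math:`P_t` from an adsorption assay are reduced to four
per-time statistics plus two whole-series estimates:

* adsorption capacity ``P0 - Pt`` (PFU/mL bound),
* adsorption rate constant ``K = (P0 - Pt) / (P0 * B * t)`` (mL/min), the
  per-time first-order binding constant given bacterial density ``B``,
* adsorption velocity ``nu = K * B`` (1/min),
* adsorption efficiency ``(P0 - P60) / P0 * 100`` (percent at the final
  sampling time),

together with the normalized progress curve ``(P0 - Pt)/P0 * 100``, an OLS
regression of ``nu`` on ``K`` (a first-order consistency check; within one
series ``nu`` is an exact multiple of ``K``, so R² = 1 unless the pipeline is
broken — pooling series with different ``B`` makes it a real regression), and
a whole-series rate-constant estimator from the slope of ``ln(Pt/P0)`` vs t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._util import require, round_half_up

__all__ = [
    "AdsorptionSeries",
    "AdsorptionParams",
    "RegressionResult",
    "adsorption_capacity",
    "adsorption_rate_constant",
    "adsorption_velocity",
    "adsorption_efficiency",
    "normalized_progress",
    "fit_k_v_regression",
    "estimate_rate_constant",
    "analyze_series",
    "read_adsorption_tsv",
    "write_adsorption_tsv",
]

DEFAULT_TIMES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@dataclass(frozen=True)
class AdsorptionSeries:
    """Timed free-phage counts with the assay's bacterial density.

    ``free_phage[0]`` at ``times[0] == 0`` is the initial titer P0.
    ``B`` is the bacterial concentration in CFU/mL.
    """

    times: np.ndarray
    free_phage: np.ndarray
    B: float
    moi: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "free_phage", np.asarray(self.free_phage, dtype=float))
        require(len(self.times) == len(self.free_phage), "times and counts must align")
        require(len(self.times) >= 2, "need at least two time points")
        require(self.times[0] == 0, "series must start at t=0")
        require(bool(np.all(np.diff(self.times) > 0)), "times must be strictly increasing")
        require(bool(np.all(self.free_phage >= 0)), "counts must be nonnegative")
        require(self.B > 0, "bacterial concentration B must be positive")

    @property
    def P0(self) -> float:
        """Free phage at t=0 (PFU/mL)."""
        return float(self.free_phage[0])


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of velocity on rate constant with Pearson R²."""

    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


@dataclass(frozen=True)
class AdsorptionParams:
    """Full per-series report.

    ``table`` has one row per positive time point with columns
    ``time_min, free_phage, capacity, rate_constant, velocity, progress_pct``.
    The t=0 row is excluded from the table (K is undefined there) but its
    progress value, 0, anchors :func:`normalized_progress`.
    """

    table: pd.DataFrame
    efficiency_pct: float
    max_rate_time_min: float
    max_rate_constant: float
    fitted_K: float
    regression: RegressionResult
    flags: tuple[str, ...] = ()


def adsorption_capacity(P0: float, Pt: float) -> float:
    """Bound phage ``P0 - Pt`` (PFU/mL); negative differences clamp to 0.

    Upward count noise can make Pt exceed P0; the capacity is then reported
    as 0 with a ``UserWarning`` rather than a negative count.
    """
    require(P0 > 0, "P0 must be positive")
    require(Pt >= 0, "Pt must be nonnegative")
    capacity = P0 - Pt
    if capacity < 0:
        warnings.warn("Pt exceeds P0; capacity clamped to 0", stacklevel=2)
        return 0.0
    return capacity


def adsorption_rate_constant(P0: float, Pt: float, B: float, t: float) -> float:
    """Per-time first-order rate constant ``(P0 - Pt)/(P0 * B * t)`` in mL/min."""
    require(P0 > 0, "P0 must be positive")
    require(B > 0, "B must be positive")
    if t <= 0:
        raise ValueError("rate constant is undefined at t <= 0; exclude the t=0 row")
    return adsorption_capacity(P0, Pt) / (P0 * B * t)


def adsorption_velocity(K: float, B: float) -> float:
    """Adsorption velocity ``nu = K * B`` (1/min)."""
    require(K >= 0, "K must be nonnegative")
    require(B > 0, "B must be positive")
    return K * B


def adsorption_efficiency(P0: float, P_final: float) -> float:
    """Percent of input phage adsorbed by the final time point, in [0, 100]."""
    require(P0 > 0, "P0 must be positive")
    frac = adsorption_capacity(P0, P_final) / P0
    return min(100.0, 100.0 * frac)


def normalized_progress(series: AdsorptionSeries) -> np.ndarray:
    """Percent adsorbed ``(P0 - Pt)/P0 * 100`` at every time point.

    Starts at exactly 0; the last entry equals the adsorption efficiency.
    Negative excursions (noise) are clamped to 0 consistently with
    :func:`adsorption_capacity`.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        caps = np.array([adsorption_capacity(series.P0, p) for p in series.free_phage])
    return np.minimum(100.0, 100.0 * caps / series.P0)


def fit_k_v_regression(
    k_values: np.ndarray, velocities: np.ndarray
) -> RegressionResult:
    """OLS of velocity on rate constant; R² is the squared Pearson correlation.

    Pairs may come from one series (then ``nu = K*B`` exactly and R² = 1 —
    the first-order consistency identity) or pooled across series with
    different bacterial densities, where the fit is informative. Zero
    variance in K makes the correlation undefined; the result is flagged
    degenerate with ``r_squared = nan``.
    """
    k = np.asarray(k_values, dtype=float)
    v = np.asarray(velocities, dtype=float)
    require(len(k) == len(v), "K and velocity arrays must align")
    require(len(k) >= 3, "need at least 3 (K, velocity) pairs")
    if np.ptp(k) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, degenerate=True)
    fit = stats.linregress(k, v)
    return RegressionResult(float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2)


def estimate_rate_constant(series: AdsorptionSeries) -> float:
    """Whole-series rate constant from the exponential decay fit.

    Under first-order binding ``Pt = P0 * exp(-K*B*t)``, so the OLS slope of
    ``ln(Pt/P0)`` on t equals ``-K*B``. Zero counts cannot be log-transformed
    and are excluded with a warning.
    """
    mask = series.free_phage > 0
    if not mask.all():
        warnings.warn(
            f"{int((~mask).sum())} zero-count point(s) excluded from decay fit",
            stacklevel=2,
        )
    t = series.times[mask]
    require(len(t) >= 3, "need at least 3 positive counts for the decay fit")
    log_ratio = np.log(series.free_phage[mask] / series.P0)
    slope = stats.linregress(t, log_ratio).slope
    return max(0.0, -float(slope) / series.B)


def analyze_series(series: AdsorptionSeries) -> AdsorptionParams:
    """Compute the complete adsorption report for one assay series."""
    flags: list[str] = []
    rows = []
    progress = normalized_progress(series)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for t, pt, prog in zip(series.times, series.free_phage, progress):
            if t <= 0:
                continue
            K = adsorption_rate_constant(series.P0, pt, series.B, t)
            rows.append(
                {
                    "time_min": t,
                    "free_phage": pt,
                    "capacity": adsorption_capacity(series.P0, pt),
                    "rate_constant": K,
                    "velocity": adsorption_velocity(K, series.B),
                    "progress_pct": prog,
                }
            )
        efficiency = round_half_up(
            adsorption_efficiency(series.P0, float(series.free_phage[-1])), 2
        )
        fitted = estimate_rate_constant(series)
    if caught:
        flags.extend(sorted({str(w.message) for w in caught}))

    table = pd.DataFrame(rows)
    best = table["rate_constant"].idxmax()
    regression = fit_k_v_regression(
        table["rate_constant"].to_numpy(), table["velocity"].to_numpy()
    )
    return AdsorptionParams(
        table=table,
        efficiency_pct=efficiency,
        max_rate_time_min=float(table.loc[best, "time_min"]),
        max_rate_constant=float(table.loc[best, "rate_constant"]),
        fitted_K=fitted,
        regression=regression,
        flags=tuple(flags),
    )


def read_adsorption_tsv(
    path: str | Path, B: float, moi: float | None = None
) -> AdsorptionSeries:
    """Read a two-column TSV (``time_min``, ``count``) plus the assay's B."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    require(
        {"time_min", "count"} <= set(df.columns),
        f"{path}: expected columns 'time_min' and 'count', got {list(df.columns)}",
    )
    return AdsorptionSeries(df["time_min"].to_numpy(), df["count"].to_numpy(), B=B, moi=moi)


def write_adsorption_tsv(series: AdsorptionSeries, path: str | Path) -> None:
    pd.DataFrame({"time_min": series.times, "count": series.free_phage}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
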