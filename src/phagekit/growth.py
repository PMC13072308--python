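"""One-step growth curve summarization.

A one-step growth assay follows the total plaque-forming titer of a
synchronized infection over time. The curve has three phases: a latent
segment at the initial titer (virions replicating intracellularly), a rise
as cells lyse and release progeny, and a plateau once the infected cohort
has burst. Two quantities summarize it:

* the **relative burst size**, ``(final_titer - initial_titer) / initial_titer``,
  the progeny yield per initially infecting phage;
* the **latent period**, the time until titer first rises sustainably above
  the initial level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import require

__all__ = [
    "GrowthCurve",
    "GrowthSummary",
    "relative_burst_size",
    "segment_phases",
    "read_growth_tsv",
    "write_growth_tsv",
]


@dataclass(frozen=True)
class GrowthCurve:
    """Timed total-titer observations from a one-step growth assay.

    Parameters
    ----------
    times : array-like of float
        Sampling times in minutes, strictly increasing from 0.
    titers : array-like of float
        Total titer (PFU/mL) at each time; ``titers[0]`` is the initial titer.
    moi : float, optional
        Multiplicity of infection of the assay (metadata only).
    """

    times: np.ndarray
    titers: np.ndarray
    moi: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "titers", np.asarray(self.titers, dtype=float))
        require(self.times.ndim == 1 and self.titers.ndim == 1, "times and titers must be 1-D")
        require(len(self.times) == len(self.titers), "times and titers must have equal length")
        require(len(self.times) >= 3, "a growth curve needs at least 3 samples")
        require(self.times[0] == 0, "times must start at 0")
        require(bool(np.all(np.diff(self.times) > 0)), "times must be strictly increasing")
        require(bool(np.all(self.titers >= 0)), "titers must be nonnegative")

    @property
    def initial_titer(self) -> float:
        """Titer at t=0 (PFU/mL)."""
        return float(self.titers[0])


@dataclass(frozen=True)
class GrowthSummary:
    """Per-curve report: burst size, phase boundaries, final titer."""

    relative_burst_size: float
    latent_end_min: float
    rise_end_min: float
    final_titer: float
    initial_titer: float
    no_burst: bool = False
    negative_burst: bool = False
    flags: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "relative_burst_size": self.relative_burst_size,
            "latent_end_min": self.latent_end_min,
            "rise_end_min": self.rise_end_min,
            "final_titer": self.final_titer,
            "initial_titer": self.initial_titer,
            "no_burst": self.no_burst,
            "negative_burst": self.negative_burst,
            "flags": list(self.flags),
        }


def relative_burst_size(initial_titer: float, final_titer: float) -> float:
    """Progeny yield per initially infecting phage.

    ``(final_titer - initial_titer) / initial_titer``; dimensionless
    (particles per infected cell under complete adsorption). Negative when
    the final titer is below the initial one; callers flag, never clamp.
    """
    require(initial_titer > 0, "initial_titer must be positive")
    require(final_titer >= 0, "final_titer must be nonnegative")
    return (final_titer - initial_titer) / initial_titer


def segment_phases(
    curve: GrowthCurve,
    rise_threshold: float = 0.10,
    sustain_points: int = 2,
) -> GrowthSummary:
    """Segment a growth curve into latent / rise / plateau and summarize it.

    The latent period ends at the first sample where the titer exceeds
    ``initial * (1 + rise_threshold)`` and stays above it for
    ``sustain_points`` consecutive samples (guards against single-point
    plating noise). The rise ends at the first subsequent sample reaching
    95% of the curve maximum. The final titer is the maximum of the last
    three samples, robust to one noisy endpoint.

    If the curve never crosses the threshold, the latent end is reported as
    the last time point and the summary carries a ``"no burst detected"`` flag.
    """
    require(0 < rise_threshold, "rise_threshold must be positive")
    require(sustain_points >= 1, "sustain_points must be >= 1")
    initial = curve.initial_titer
    require(initial > 0, "initial titer must be positive to segment phases")

    titers = curve.titers
    times = curve.times
    threshold = initial * (1.0 + rise_threshold)
    above = titers > threshold

    latent_idx: int | None = None
    for i in range(len(above) - sustain_points + 1):
        if above[i : i + sustain_points].all():
            latent_idx = i
            break

    flags: list[str] = []
    final_titer = float(np.max(titers[-3:]))
    burst = relative_burst_size(initial, final_titer)

    if latent_idx is None:
        flags.append("no burst detected")
        latent_end = float(times[-1])
        rise_end = float(times[-1])
    else:
        latent_end = float(times[latent_idx])
        peak = float(np.max(titers))
        rise_mask = (times >= latent_end) & (titers >= 0.95 * peak)
        rise_end = float(times[np.argmax(rise_mask)]) if rise_mask.any() else float(times[-1])

    negative = burst < 0
    if negative:
        flags.append("final titer below initial titer")

    return GrowthSummary(
        relative_burst_size=burst,
        latent_end_min=latent_end,
        rise_end_min=rise_end,
        final_titer=final_titer,
        initial_titer=initial,
        no_burst=latent_idx is None,
        negative_burst=negative,
        flags=tuple(flags),
    )


def read_growth_tsv(path: str | Path, moi: float | None = None) -> GrowthCurve:
    """Read a two-column TSV (``time_min``, ``count``) into a :class:`GrowthCurve`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    require(
        {"time_min", "count"} <= set(df.columns),
        f"{path}: expected columns 'time_min' and 'count', got {list(df.columns)}",
    )
    return GrowthCurve(df["time_min"].to_numpy(), df["count"].to_numpy(), moi=moi)


def write_growth_tsv(curve: GrowthCurve, path: str | Path) -> None:
    """Write a curve as the TSV dialect :func:`read_growth_tsv` accepts."""
    pd.DataFrame({"time_min": curve.times, "count": curve.titers}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
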