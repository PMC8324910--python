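"""Estrous-cycle prediction from serum progesterone (P4) time series.

Goat estrous cycles run 21-23 days; serum P4 rises through the luteal phase
and collapses to a nadir at estrous, so "Day 0" of a cycle is defined as the
P4 nadir.  Sampling blood a few times per week gives a sawtooth-like profile
from which nadirs, the cycle length, and stage-specific surgery windows are
derived:

* MF (mature follicle): 2-5 days *before* the next predicted Day 0;
* CH (corpus hemorrhagicum): Day 0-4 of the cycle;
* CL (corpus luteum): Day 4-12 of the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "P4Series",
    "CycleEstimate",
    "detect_nadirs",
    "estimate_cycle_length",
    "schedule_sampling",
    "read_p4_csv",
]

STAGE_WINDOWS_RELATIVE: dict[str, tuple[float, float]] = {
    "MF": (-5.0, -2.0),
    "CH": (0.0, 4.0),
    "CL": (4.0, 12.0),
}


class InsufficientDataError(ValueError):
    """Raised when a series is too short to support cycle detection."""


@dataclass
class P4Series:
    """Time-stamped serum progesterone concentrations for one animal."""

    days: np.ndarray  # sample days, strictly increasing (fractional allowed)
    p4: np.ndarray  # ng/mL, non-negative
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.p4 = np.asarray(self.p4, dtype=float)
        if self.days.shape != self.p4.shape or self.days.ndim != 1:
            raise ValueError("days and p4 must be 1D arrays of equal length")
        if len(self.days) > 1 and not np.all(np.diff(self.days) > 0):
            raise ValueError("sample days must be strictly increasing")
        if np.any(self.p4 < 0):
            raise ValueError("P4 concentrations must be non-negative")

    @property
    def median_interval(self) -> float:
        """Typical spacing between samples in days."""
        return float(np.median(np.diff(self.days)))


@dataclass
class CycleEstimate:
    """Nadir-based cycle-length estimate."""

    nadir_days: list[float]
    per_cycle_lengths: list[float]
    cycle_length_days: float  # median inter-nadir interval
    consistent: bool  # spread of per-cycle lengths <= tolerance
    spread_tolerance_days: float = 2.0
    animal_id: str = ""

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "nadir_days": list(self.nadir_days),
            "per_cycle_lengths": list(self.per_cycle_lengths),
            "cycle_length_days": self.cycle_length_days,
            "consistent": bool(self.consistent),
        }


def _moving_median(days: np.ndarray, values: np.ndarray, window: float) -> np.ndarray:
    """Centred moving median over a day-based window.

    Selecting neighbours by day *differences* keeps the smoother exactly
    equivariant under time shifts.
    """
    if window <= 0:
        return values.astype(float).copy()
    out = np.empty_like(values, dtype=float)
    half = window / 2.0 + 1e-9
    for i, d in enumerate(days):
        out[i] = np.median(values[np.abs(days - d) <= half])
    return out


def detect_nadirs(
    series: P4Series,
    smoothing_window: float = 7.0,
    min_separation: float = 14.0,
) -> list[float]:
    """Locate P4 nadirs as local minima of the median-smoothed series.

    ``smoothing_window`` is in days (a centred moving median over the samples
    that fall inside it); candidate minima closer than ``min_separation``
    days keep only the deepest.  Nadir days are reported at sample
    resolution — the blood-draw cadence does not support interpolation.
    """
    if len(series.days) < 6:
        raise InsufficientDataError("insufficient data: need at least 6 samples")
    if series.days[-1] - series.days[0] < 2 * min_separation:
        raise InsufficientDataError(
            "insufficient data: series must span at least two putative cycles"
        )
    smooth = _moving_median(series.days, series.p4, smoothing_window)

    # strict interior minima: a nadir needs a fall before it and a rise after
    # it, so series endpoints never qualify (a monotone series has none)
    is_min = np.zeros(len(smooth), dtype=bool)
    is_min[1:-1] = (smooth[1:-1] <= smooth[:-2]) & (smooth[1:-1] <= smooth[2:])
    # drop plateau duplicates: keep the first sample of a flat run
    flat = np.concatenate([[False], smooth[1:] == smooth[:-1]])
    rises_somewhere = np.ptp(smooth) > 0
    candidates = np.nonzero(is_min & ~flat)[0] if rises_somewhere else np.array([], int)
    if len(candidates) == 0:
        return []

    # greedy deepest-first selection with the separation constraint
    order = candidates[np.argsort(smooth[candidates], kind="stable")]
    chosen: list[int] = []
    for idx in order:
        if all(abs(series.days[idx] - series.days[j]) >= min_separation for j in chosen):
            chosen.append(idx)
    return sorted(float(series.days[i]) for i in chosen)


def estimate_cycle_length(
    nadirs: list[float],
    spread_tolerance_days: float = 2.0,
    animal_id: str = "",
) -> CycleEstimate:
    """Summarize per-cycle lengths from successive nadirs.

    The headline cycle length is the median inter-nadir interval; the
    estimate is flagged consistent when the per-cycle spread (max - min)
    does not exceed ``spread_tolerance_days``.
    """
    if len(nadirs) < 2:
        raise InsufficientDataError("need at least 2 nadirs to estimate cycle length")
    nadirs = sorted(float(n) for n in nadirs)
    lengths = list(np.diff(nadirs))
    spread = max(lengths) - min(lengths)
    return CycleEstimate(
        nadir_days=nadirs,
        per_cycle_lengths=[float(x) for x in lengths],
        cycle_length_days=float(np.median(lengths)),
        consistent=bool(spread <= spread_tolerance_days),
        spread_tolerance_days=spread_tolerance_days,
        animal_id=animal_id,
    )


def schedule_sampling(estimate: CycleEstimate, stage: str) -> tuple[float, float]:
    """Compute the absolute-day surgery window for a target stage.

    The next Day 0 is predicted as (last nadir + median cycle length); the
    stage windows relative to that Day 0 are MF: [-5, -2], CH: [0, 4],
    CL: [4, 12] days.  Refuses to schedule from an inconsistent estimate.
    """
    if stage not in STAGE_WINDOWS_RELATIVE:
        raise ValueError(f"unknown stage {stage!r}; expected one of MF, CH, CL")
    if not estimate.consistent:
        raise ValueError(
            "refusing to schedule: cycle-length estimate is inconsistent "
            f"(per-cycle spread exceeds {estimate.spread_tolerance_days} days)"
        )
    day0 = estimate.nadir_days[-1] + estimate.cycle_length_days
    lo, hi = STAGE_WINDOWS_RELATIVE[stage]
    return (day0 + lo, day0 + hi)


def read_p4_csv(path) -> list[P4Series]:
    """Read P4 series from CSV with columns animal_id, day, p4_ng_per_ml."""
    df = pd.read_csv(path)
    required = {"day", "p4_ng_per_ml"}
    if not required <= set(df.columns):
        raise ValueError(f"P4 CSV needs columns {sorted(required)}")
    if "animal_id" not in df.columns:
        df["animal_id"] = ""
    out = []
    for animal, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("day")
        out.append(
            P4Series(
                days=grp["day"].to_numpy(float),
                p4=grp["p4_ng_per_ml"].to_numpy(float),
                animal_id=str(animal),
            )
        )
    return out
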