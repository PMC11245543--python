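"""Bench-assay arithmetic: serine consumption, ROS, redox ratios, proliferation.

Units are enforced at the boundary: serine amounts in micrograms, medium
concentrations in mg/L, well volumes in mL, cell counts as raw counts
(converted to millions where the formula demands), fluorescence in
arbitrary units, confluence in percent, time in hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConsumptionRecord",
    "RosRecord",
    "RatioRecord",
    "serine_consumption",
    "medium_amount_ug",
    "ros_level",
    "redox_ratio",
    "proliferation_slope",
    "relative_proliferation",
]


@dataclass(frozen=True)
class ConsumptionRecord:
    """Serine amounts (ug) and viable cell counts at 0 h and at ``timepoint`` h."""

    amount_t0: float
    amount_t: float
    cells_t0: float
    cells_t: float
    timepoint: float

    def __post_init__(self) -> None:
        if self.amount_t0 < 0 or self.amount_t < 0:
            raise ValueError("serine amounts must be >= 0")
        if self.cells_t0 <= 0 or self.cells_t <= 0:
            raise ValueError("cell counts must be > 0")
        if self.timepoint <= 0:
            raise ValueError("timepoint must be > 0")


@dataclass(frozen=True)
class RosRecord:
    """Stained/unstained well fluorescence (a.u.) and cell count in millions."""

    f_stained: float
    f_unstained: float
    cells_millions: float

    def __post_init__(self) -> None:
        if self.cells_millions <= 0:
            raise ValueError("cell count must be > 0")


@dataclass(frozen=True)
class RatioRecord:
    """Pool sizes (same arbitrary units) for a redox couple."""

    numerator_pool: float
    denominator_pool: float
    label: str = "NADPH/NADP+"

    def __post_init__(self) -> None:
        if self.denominator_pool <= 0:
            raise ValueError("denominator pool must be > 0")


def medium_amount_ug(concentration_mg_per_l: float, volume_ml: float) -> float:
    """Mass (ug) of a solute in a well: concentration (mg/L) x volume (mL).

    mg/L equals ug/mL, so e.g. 30 mg/L serine in a 2 mL well is 60 ug.
    """
    if concentration_mg_per_l < 0 or volume_ml < 0:
        raise ValueError("concentration and volume must be >= 0")
    return concentration_mg_per_l * volume_ml


def serine_consumption(rec: ConsumptionRecord) -> float:
    """Serine consumed (ug) per one-million-cell increase.

    (amount at 0 h - amount at t) / ((cells at t - cells at 0 h) / 1e6).
    The formula presumes growth: a well whose cell count did not increase
    is an error, not an infinite or negative rate.
    """
    delta_cells = rec.cells_t - rec.cells_t0
    if delta_cells <= 0:
        raise ValueError("no cell-number increase; consumption per increase is undefined")
    return (rec.amount_t0 - rec.amount_t) / (delta_cells / 1e6)


def ros_level(rec: RosRecord) -> float:
    """Background-subtracted fluorescence per million cells.

    A stained signal below the unstained background is physically odd but
    allowed: the negative value is returned with a warning.
    """
    diff = rec.f_stained - rec.f_unstained
    if diff < 0:
        warnings.warn(
            f"stained fluorescence ({rec.f_stained}) below unstained background "
            f"({rec.f_unstained}); returning a negative ROS level",
            stacklevel=2,
        )
    return diff / rec.cells_millions


def redox_ratio(rec: RatioRecord) -> float:
    """Pool-size ratio, e.g. NADPH/NADP+ or GSH/GSSG."""
    if rec.numerator_pool < 0:
        raise ValueError("numerator pool must be >= 0")
    return rec.numerator_pool / rec.denominator_pool


def proliferation_slope(timepoints: Sequence[float], confluence: Sequence[float]) -> float:
    """OLS slope (percent confluence per hour) of a live-imaging time course."""
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(confluence, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    if t.size != y.size:
        raise ValueError("timepoints and confluence must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def relative_proliferation(
    treated_counts: Sequence[float], control_counts: Sequence[float]
) -> np.ndarray:
    """Each treated cell count divided by the mean untreated count."""
    control = np.asarray(control_counts, dtype=float)
    treated = np.asarray(treated_counts, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    mean_control = float(control.mean())
    if mean_control <= 0:
        raise ValueError("control mean must be > 0")
    return treated / mean_control
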