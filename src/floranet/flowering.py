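"""Flowering-time readout from simulated AP1 trajectories.

AP1 expression marks commitment to flowering.  The wild-type simulation is
anchored at the observed floral transition (day 12.6 after germination, which
equals the mean rosette-leaf count of wild-type Col-0); the AP1 level reached
at that moment defines a threshold assumed identical across genotypes and
conditions.  A mutant's predicted transition is the first time its simulated
AP1 crosses that threshold, converted to rosette leaves (RL) by an affine
day -> RL map anchored at (12.6 d, 12.6 RL).  The slope of that map is not
identified by the anchor alone; the default of 1 RL/day keeps days and leaves
numerically interchangeable at the anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import Trajectory

#: Sentinel transition day for trajectories that never reach the threshold.
NO_FLOWERING = math.inf


@dataclass
class FloweringCalibration:
    wt_transition_day: float
    ap1_threshold: float
    wt_rl: float = 12.6
    rl_per_day_slope: float = 1.0

    def day_to_rl(self, day: float) -> float:
        if math.isinf(day):
            return NO_FLOWERING
        return self.wt_rl + self.rl_per_day_slope * (day - self.wt_transition_day)


@dataclass
class FloweringPrediction:
    mutant: str
    transition_day: float
    rosette_leaves: float

    @property
    def flowers(self) -> bool:
        return math.isfinite(self.transition_day)


def calibrate(
    wt_traj: Trajectory,
    wt_transition_day: float = 12.6,
    wt_rl: float = 12.6,
    slope: float = 1.0,
) -> FloweringCalibration:
    """Anchor the AP1 threshold and the day->RL map on a wild-type simulation.

    The threshold is the simulated AP1 level at ``wt_transition_day``; AP1
    must actually be rising there (a flat or zero AP1 cannot anchor a
    transition).
    """
    t0, t1 = wt_traj.days[0], wt_traj.days[-1]
    if not (t0 <= wt_transition_day <= t1):
        raise ValueError(
            f"wild-type trajectory [{t0}, {t1}] does not cover day {wt_transition_day}"
        )
    threshold = float(wt_traj.at("AP1", wt_transition_day))
    eps = 0.25
    lo = float(wt_traj.at("AP1", max(t0, wt_transition_day - eps)))
    hi = float(wt_traj.at("AP1", min(t1, wt_transition_day + eps)))
    if threshold <= 0 or hi <= lo:
        raise ValueError(
            "AP1 is flat or zero around the anchor day; cannot calibrate a threshold"
        )
    return FloweringCalibration(
        wt_transition_day=float(wt_transition_day),
        ap1_threshold=threshold,
        wt_rl=float(wt_rl),
        rl_per_day_slope=float(slope),
    )


def first_up_crossing(days: np.ndarray, values: np.ndarray, threshold: float) -> float:
    """First time ``values`` reaches ``threshold`` from below (linear sub-grid
    interpolation); the start day if already at/above; NO_FLOWERING if never."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if values[0] >= threshold:
        return float(days[0])
    above = values >= threshold
    if not above.any():
        return NO_FLOWERING
    k = int(np.argmax(above))
    y0, y1 = values[k - 1], values[k]
    t0, t1 = days[k - 1], days[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def predict_flowering(
    mut_traj: Trajectory,
    cal: FloweringCalibration,
    name: str = "",
) -> FloweringPrediction:
    """Transition day and rosette leaves from a simulated AP1 trajectory."""
    day = first_up_crossing(mut_traj.days, mut_traj.column("AP1"), cal.ap1_threshold)
    return FloweringPrediction(
        mutant=name,
        transition_day=day,
        rosette_leaves=cal.day_to_rl(day),
    )


def rescale_literature_rl(
    rl_values,
    wt_rl_in_source: float,
    wt_rl_target: float = 12.6,
) -> np.ndarray:
    """Rescale rosette-leaf counts from another study onto the common scale.

    Multiplies every value by ``wt_rl_target / wt_rl_in_source`` so the source
    study's wild type lands on the common anchor; ratios between mutants are
    preserved exactly.
    """
    rl = np.asarray(rl_values, dtype=float)
    if wt_rl_in_source <= 0:
        raise ValueError("source wild-type RL must be positive")
    if np.any(rl <= 0):
        raise ValueError("rosette-leaf counts must be positive")
    return rl * (wt_rl_target / wt_rl_in_source)
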