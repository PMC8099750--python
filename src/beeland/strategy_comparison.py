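"""Speed comparison of the hybrid strategy against pure reference laws.

Over the span of two consecutive constant-r segments (including their
transition), the observed mean approach speed UH is compared against the
speed the same start/end distances would have been covered at under

* a pure constant-r law at the first segment's set point
  (t = ln(y_start/y_end) / r*), and
* a pure constant-tau-dot law with the dataset-average tau-dot c and the
  initial time to contact matched to the first set point, tau0 = 1/r*
  (t = (tau0/c) ((y_end/y_start)^-c - 1)).

For any c in (-1, 0) the constant-tau-dot reference is strictly faster
than the constant-r reference over the same span (the inequality
(1 - x^a)/a < -ln x for x in (0,1), a in (0,1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .kinematics import KinematicTrack
from .segment_detection import SegmentPair

log = logging.getLogger("beeland")


def time_constant_r(y_start: float, y_end: float, r_set: float) -> float:
    """Traversal time from y_start to y_end under constant r = r_set."""
    if not (y_start >= y_end > 0):
        raise ParameterError("require y_start >= y_end > 0")
    if r_set <= 0:
        raise ParameterError("r_set must be > 0")
    return float(np.log(y_start / y_end) / r_set)


def time_constant_taudot(y_start: float, y_end: float, tau0: float,
                         c: float) -> float:
    """Traversal time from y_start to y_end under constant tau-dot = c.

    tau0 is the time to contact at y_start. The c -> 0 limit recovers the
    constant-r time with r = 1/tau0.
    """
    if not (y_start >= y_end > 0):
        raise ParameterError("require y_start >= y_end > 0")
    if tau0 <= 0:
        raise ParameterError("tau0 must be > 0")
    if not (-1 < c < 0):
        raise ParameterError("c must lie in (-1, 0)")
    return float((tau0 / c) * ((y_end / y_start) ** (-c) - 1.0))


@dataclass
class SpeedRatioResult:
    """Observed vs reference mean speeds over one two-segment span."""

    track_id: str
    UH: float        # observed mean approach speed over the span (m/s)
    Ur: float        # reference: constant r at the first set point
    Utaudot: float   # reference: constant tau-dot at the dataset-average c
    ratio_r: float   # UH / Ur
    ratio_taudot: float  # UH / Utaudot
    c_ref: float
    y_span_start: float
    y_span_end: float


def speed_ratios(pair: SegmentPair, kt: KinematicTrack,
                 c_ref: float) -> SpeedRatioResult | None:
    """Speed-ratio result for one segment pair, or None for degenerate spans."""
    if not (-1 < c_ref < 0):
        raise ParameterError("c_ref must lie in (-1, 0)")
    i0, i1 = pair.first.i_start, pair.second.i_end
    if i1 - i0 <= 2:
        log.warning("degenerate span for track %s; pair skipped",
                    pair.track_id)
        return None
    y_s = float(kt.y_s[i0])
    y_e = float(kt.y_s[i1])
    dy = y_s - y_e
    elapsed = float(kt.t[i1] - kt.t[i0])
    UH = dy / elapsed
    Ur = dy / time_constant_r(y_s, y_e, pair.first.r_star)
    Ut = dy / time_constant_taudot(y_s, y_e, 1.0 / pair.first.r_star, c_ref)
    return SpeedRatioResult(
        track_id=pair.track_id, UH=UH, Ur=Ur, Utaudot=Ut,
        ratio_r=UH / Ur, ratio_taudot=UH / Ut, c_ref=c_ref,
        y_span_start=y_s, y_span_end=y_e)


def speed_ratio_table(pairs: Sequence[SegmentPair],
                      kts, c_ref: float) -> pd.DataFrame:
    """Per-pair ratio table over many tracks (skipping degenerate spans)."""
    if not isinstance(kts, dict):
        kts = {kt.track_id: kt for kt in kts}
    rows = []
    for p in pairs:
        res = speed_ratios(p, kts[p.track_id], c_ref)
        if res is not None:
            rows.append(vars(res))
    return pd.DataFrame(rows)


def summarize_ratios(table: pd.DataFrame) -> dict[str, float]:
    """Mean and sd of both speed ratios over all pairs."""
    return {
        "n": int(len(table)),
        "ratio_r_mean": float(table["ratio_r"].mean()),
        "ratio_r_sd": float(table["ratio_r"].std(ddof=1)),
        "ratio_taudot_mean": float(table["ratio_taudot"].mean()),
        "ratio_taudot_sd": float(table["ratio_taudot"].std(ddof=1)),
    }
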