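"""Per-sample state variables of a landing approach.

From the smoothed perpendicular distance y(t) the stage derives the
approach velocity V = -dy/dt, approach acceleration A = -d2y/dt2 (= dV/dt),
relative rate of expansion r = V/y and time to contact tau = y/V = 1/r,
and isolates the deceleration phases (V decreasing) on which all segment
analysis operates.

Smoothing and differentiation use a centered Savitzky-Golay filter: a local
least-squares polynomial fit whose analytic derivatives give V and A in one
pass. Samples within half a window of either end are masked, as are samples
at or below the touchdown threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .config import PipelineConfig
from .errors import ParameterError, TrackRejectedError
from .tracks_io import RawTrack


def smooth_and_differentiate(series: np.ndarray, window: int, order: int,
                             dt: float, track_id: str = "<series>"
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Savitzky-Golay smoothed value, first and second derivative.

    The filter fits a polynomial of the given order in a centered sliding
    window; derivatives come from the fitted polynomial, so any signal that
    is exactly a polynomial of degree <= order is reproduced exactly at
    interior samples. Endpoint samples (within (window-1)/2 of either end)
    are returned but should be masked by the caller.
    """
    series = np.asarray(series, dtype=float)
    if window % 2 != 1 or order < 2 or window <= order:
        raise ParameterError("window must be odd and > order >= 2")
    if len(series) < window:
        raise TrackRejectedError(track_id,
                                 f"length {len(series)} < window {window}")
    s = savgol_filter(series, window, order, deriv=0, delta=dt)
    d1 = savgol_filter(series, window, order, deriv=1, delta=dt)
    d2 = savgol_filter(series, window, order, deriv=2, delta=dt)
    return s, d1, d2


@dataclass
class KinematicTrack:
    """A RawTrack plus its derived state variables.

    ``tau`` is NaN wherever V <= eps_v. ``mask`` marks samples that are
    interior to the smoothing window and above the touchdown threshold.
    ``U_start`` is the 3D ground speed at maneuver start (the first sample
    of the last contiguous approach interval ending at touchdown).
    """

    raw: RawTrack
    y_s: np.ndarray          # smoothed perpendicular distance (m)
    V: np.ndarray            # approach velocity, positive toward platform
    A: np.ndarray            # dV/dt = -d2y/dt2
    r: np.ndarray            # relative rate of expansion V/y (1/s)
    tau: np.ndarray          # time to contact y/V (s); NaN where V small
    mask: np.ndarray         # bool validity mask
    U_start: float
    i_start: int             # maneuver start sample
    i_touchdown: int         # first sample with y_s <= y_td (or last sample)
    config: PipelineConfig

    @property
    def track_id(self) -> str:
        return self.raw.track_id

    @property
    def t(self) -> np.ndarray:
        return self.raw.t

    def __len__(self) -> int:
        return len(self.raw)


def compute_state_variables(track: RawTrack,
                            config: PipelineConfig) -> KinematicTrack:
    """Derive V, A, r, tau and the validity mask from a RawTrack."""
    w, p, dt = config.smooth_window, config.smooth_order, track.dt
    y_s, dy, d2y = smooth_and_differentiate(track.y, w, p, dt, track.track_id)
    x_s, dx, _ = smooth_and_differentiate(track.x, w, p, dt, track.track_id)
    z_s, dz, _ = smooth_and_differentiate(track.z, w, p, dt, track.track_id)

    V = -dy
    A = -d2y
    n = len(track)
    half = (w - 1) // 2
    interior = np.zeros(n, dtype=bool)
    interior[half:n - half] = True

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(y_s > 0, V / y_s, np.nan)
        tau = np.where(V > config.eps_v, y_s / V, np.nan)

    # touchdown: first sample at or below the distance threshold
    below = np.nonzero(y_s <= config.y_td)[0]
    i_td = int(below[0]) if len(below) else n - 1

    mask = interior & (y_s > config.y_td) & np.isfinite(r)
    mask[i_td:] = False

    # maneuver start: first sample of the last contiguous run of approach
    # motion (V > eps_v) that ends at touchdown
    i_start = i_td
    while i_start > 0 and V[i_start - 1] > config.eps_v:
        i_start -= 1
    ground_speed = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    j = min(max(i_start, half), n - half - 1)
    U_start = float(ground_speed[j])

    return KinematicTrack(raw=track, y_s=y_s, V=V, A=A, r=r, tau=tau,
                          mask=mask, U_start=U_start, i_start=i_start,
                          i_touchdown=i_td, config=config)


def deceleration_phases(kt: KinematicTrack) -> list[tuple[int, int]]:
    """Maximal intervals where the bee approaches and slows down.

    A sample belongs to a deceleration phase when it is valid, V > eps_v
    and dV/dt < 0. Interruptions shorter than ``gap_max`` seconds are
    merged (hysteresis), then maximal intervals are returned as inclusive
    (i_start, i_end) pairs.
    """
    cfg = kt.config
    good = kt.mask & (kt.V > cfg.eps_v) & (kt.A < 0)
    if not good.any():
        return []
    idx = np.nonzero(good)[0]
    gap_samples = int(round(cfg.gap_max / kt.raw.dt))
    phases: list[list[int]] = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i - phases[-1][1] <= gap_samples + 1:
            phases[-1][1] = i
        else:
            phases.append([i, i])
    return [(int(a), int(b)) for a, b in phases if b > a]


def kinematics_frame(kt: KinematicTrack):
    """Per-sample state variables as a DataFrame (for the kinematics CSV)."""
    import pandas as pd

    return pd.DataFrame({
        "track_id": kt.track_id, "t": kt.t, "y": kt.y_s, "V": kt.V,
        "A": kt.A, "r": kt.r, "tau": kt.tau, "mask": kt.mask.astype(int),
    })


def maneuver_displacement(kt: KinematicTrack) -> float:
    """Total displacement normal to the platform over the maneuver (m)."""
    return float(kt.y_s[kt.i_start] - kt.y_s[kt.i_touchdown])
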