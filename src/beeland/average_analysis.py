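"""Average-per-treatment analysis.

The literature method: pool many tracks of one treatment cell, bin the
deceleration-phase samples by distance, and read a single set point of the
relative rate of expansion from a fixed distance window (0.04-0.11 m by
default) where the mean approach velocity falls proportionally with
distance. Contrasts between treatment cells then come from an ordinary
linear model on per-track window means (one value per track, so no random
effect is needed). This stage exists for contrast with the per-track
segment analysis, which resolves the multiple set points the averaging
method blurs together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .config import PipelineConfig
from .errors import ModelSpecError, ParameterError
from .kinematics import KinematicTrack, deceleration_phases

log = logging.getLogger("beeland")


@dataclass
class AverageProfile:
    """Bin-averaged V(y) and r(y) of one treatment cell."""

    cell: tuple
    bin_centers: np.ndarray
    mean_V: np.ndarray
    mean_r: np.ndarray
    n_tracks: np.ndarray       # tracks contributing to each bin
    mask: np.ndarray           # bins meeting the n_min requirement
    per_track: pd.DataFrame    # track_id x bin means (long form)


def _decel_samples(kt: KinematicTrack) -> np.ndarray:
    sel = np.zeros(len(kt), dtype=bool)
    for a, b in deceleration_phases(kt):
        sel[a:b + 1] = True
    return sel


def bin_average_tracks(kts: Sequence[KinematicTrack],
                       bin_width: float | None = None,
                       cell: tuple | None = None,
                       config: PipelineConfig | None = None) -> AverageProfile:
    """Across-track bin averages of V and r within deceleration phases.

    Each track contributes its per-bin mean; bins are then averaged across
    tracks so every track carries equal weight. Bins visited by fewer than
    ``n_min`` tracks are masked.
    """
    if cell is not None:
        kts = [kt for kt in kts if kt.raw.cell == cell]
    cfg = config or (kts[0].config if kts else PipelineConfig())
    bw = bin_width if bin_width is not None else cfg.bin_width
    if not kts:
        log.warning("bin_average_tracks: empty cell %s", cell)
        return AverageProfile(cell, np.array([]), np.array([]), np.array([]),
                              np.array([], dtype=int), np.array([], dtype=bool),
                              pd.DataFrame(columns=["track_id", "bin", "V", "r"]))

    y_max = max(float(np.nanmax(kt.y_s[_decel_samples(kt)]))
                for kt in kts if _decel_samples(kt).any())
    edges = np.arange(cfg.y_td, y_max + bw, bw)
    centers = 0.5 * (edges[:-1] + edges[1:])

    rows = []
    for kt in kts:
        sel = _decel_samples(kt)
        if not sel.any():
            continue
        y = kt.y_s[sel]
        df = pd.DataFrame({
            "bin": np.digitize(y, edges) - 1,
            "V": kt.V[sel], "r": kt.r[sel]})
        df = df[(df["bin"] >= 0) & (df["bin"] < len(centers))]
        g = df.groupby("bin")[["V", "r"]].mean().reset_index()
        g.insert(0, "track_id", kt.track_id)
        rows.append(g)
    per_track = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["track_id", "bin", "V", "r"])

    mean_V = np.full(len(centers), np.nan)
    mean_r = np.full(len(centers), np.nan)
    n_tracks = np.zeros(len(centers), dtype=int)
    if len(per_track):
        g = per_track.groupby("bin")
        agg = g[["V", "r"]].mean()
        cnt = g["track_id"].nunique()
        mean_V[agg.index] = agg["V"]
        mean_r[agg.index] = agg["r"]
        n_tracks[cnt.index] = cnt
    mask = n_tracks >= cfg.n_min
    return AverageProfile(cell, centers, mean_V, mean_r, n_tracks, mask,
                          per_track)


def window_mean_expansion_rate(profile: AverageProfile,
                               y_lo: float = 0.04, y_hi: float = 0.11
                               ) -> tuple[float, float]:
    """Track-weighted mean r over the distance window, with its SE.

    Each track contributes the mean of its per-bin means over the window;
    the standard error is across tracks.
    """
    if len(profile.bin_centers) == 0:
        raise ParameterError("empty profile")
    in_win = (profile.bin_centers >= y_lo) & (profile.bin_centers <= y_hi)
    bins = np.nonzero(in_win)[0]
    sub = profile.per_track[profile.per_track["bin"].isin(bins)]
    if sub.empty:
        raise ParameterError(
            f"no profile data inside window [{y_lo}, {y_hi}] m")
    per_track = sub.groupby("track_id")["r"].mean()
    se = (float(per_track.std(ddof=1) / np.sqrt(len(per_track)))
          if len(per_track) > 1 else np.nan)
    return float(per_track.mean()), se


def window_setpoint_records(kts: Sequence[KinematicTrack],
                            config: PipelineConfig | None = None
                            ) -> pd.DataFrame:
    """Per-track window-mean r* with treatment metadata (model input)."""
    cfg = config or (kts[0].config if kts else PipelineConfig())
    rows = []
    for kt in kts:
        sel = _decel_samples(kt) & (kt.y_s >= cfg.window_lo) & (kt.y_s <= cfg.window_hi)
        if not sel.any():
            continue
        rows.append({
            "track_id": kt.track_id,
            "r_star": float(np.nanmean(kt.r[sel])),
            "light": kt.raw.light.value,
            "pattern": kt.raw.pattern.value,
            "landing_type": kt.raw.landing_type.value,
        })
    return pd.DataFrame(rows)


def treatment_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Ordinary linear model of per-track window r* on the treatment factors.

    One response value per track means a random intercept would be
    unidentifiable, so cell contrasts come from OLS. Returns a coefficient
    table with estimates, 95% CIs and per-contrast p values (uncorrected).
    """
    factors = [f for f in ("light", "pattern", "landing_type")
               if f in records.columns and records[f].nunique() > 1]
    if not factors:
        raise ModelSpecError("treatment comparison needs >= 2 cells")
    formula = "r_star ~ " + " + ".join(f"C({f})" for f in factors)
    res = smf.ols(formula, records).fit()
    ci = res.conf_int()
    return pd.DataFrame({
        "term": res.params.index,
        "estimate": res.params.values,
        "se": res.bse.values,
        "ci_lo": ci[0].values,
        "ci_hi": ci[1].values,
        "p": res.pvalues.values,
    })
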