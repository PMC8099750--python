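"""Constant-r segment detection — the per-track analysis core.

A constant-r segment is a stretch of a deceleration phase in which the
relative rate of expansion r is held (nearly) constant. A candidate window
[i, j] is *admissible* when

* it covers at least ``dy_min`` meters and lasts at least ``t_min`` seconds,
* the normalized spread of r — its standard deviation over the window
  divided by its mean — stays within f * tol_r / sqrt(12) * 2, i.e. within
  the sd of a uniform drift spanning the peak-to-peak band (2 mean r)
  * f * tol_r (the sd statistic, unlike the raw range, does not grow with
  window length under noise, so long genuine bouts are not split), and
* the absolute least-squares slope of r against t, normalized by mean r,
  is <= f * tol_slope (rejects slow monotone drift whose spread happens to
  stay small).

The sensitivity factor f scales both tolerances, so raising f admits more
and wider windows. From the admissible set, detection selects a maximal
non-overlapping subset greedily by window length (ties broken by smaller
spread, then earlier start), then merges adjacent selections whose pooled
window is itself admissible. A brute-force dynamic program over the same
admissible set provides the exact maximum-coverage reference for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ParameterError, TrackTooLongError
from .kinematics import KinematicTrack, deceleration_phases

log = logging.getLogger("beeland")

SEGMENT_COLUMNS = ["track_id", "i_start", "i_end", "t_start", "t_end",
                   "y_start", "y_end", "y_star", "V_star", "A_star",
                   "r_star", "dy1", "f_used", "residual"]


@dataclass
class ConstantRSegment:
    """One detected bout of constant relative rate of expansion."""

    track_id: str
    i_start: int
    i_end: int            # inclusive
    t_start: float
    t_end: float
    y_start: float
    y_end: float
    y_star: float         # mean distance over the segment (m)
    V_star: float         # mean approach speed (m/s)
    A_star: float         # mean dV/dt (m/s^2)
    r_star: float         # set-point estimate (1/s)
    dy1: float            # displacement during the segment (m)
    f_used: float
    residual: float       # normalized r spread achieved (sd(r)/mean r)

    @property
    def n_samples(self) -> int:
        return self.i_end - self.i_start + 1


@dataclass
class SegmentPair:
    """Two consecutive segments of one track and their transition."""

    first: ConstantRSegment
    second: ConstantRSegment
    dy2: float            # y at first start - y at second end (m)
    dr_star: float        # second r* - first r* (1/s)
    near_zero_v: bool     # any V < 0.05 m/s during the transition

    @property
    def track_id(self) -> str:
        return self.first.track_id


# ---------------------------------------------------------------------------
# admissible-window enumeration


def _admissible_windows(t: np.ndarray, y: np.ndarray, r: np.ndarray,
                        f: float, cfg: PipelineConfig
                        ) -> list[tuple[int, int, int, float]]:
    """All admissible windows of one deceleration phase.

    Returns tuples (i, j, length, residual) in local phase indices, j
    inclusive. O(n^2) time, vectorized over the right endpoint.
    """
    n = len(r)
    tol_spread = f * cfg.tol_r / np.sqrt(3.0)   # sd of a full-band drift
    tol_slope = f * cfg.tol_slope
    min_len = max(int(np.ceil(cfg.t_min / (t[1] - t[0]))) + 1, 3) if n > 1 else 3

    # prefix sums for O(1) window means, variances and slopes
    cr = np.concatenate(([0.0], np.cumsum(r)))
    crr = np.concatenate(([0.0], np.cumsum(r * r)))
    ct = np.concatenate(([0.0], np.cumsum(t)))
    ctt = np.concatenate(([0.0], np.cumsum(t * t)))
    ctr = np.concatenate(([0.0], np.cumsum(t * r)))

    out: list[tuple[int, int, int, float]] = []
    for i in range(n - min_len + 1):
        js = np.arange(i + min_len - 1, n)
        if len(js) == 0:
            continue
        m = (js - i + 1).astype(float)
        mean_r = (cr[js + 1] - cr[i]) / m
        var = (crr[js + 1] - crr[i]) / m - mean_r ** 2
        spread = np.sqrt(np.maximum(var, 0.0)) / mean_r
        # least-squares slope of r on t over [i, j]
        st = ct[js + 1] - ct[i]
        stt = ctt[js + 1] - ctt[i]
        str_ = ctr[js + 1] - ctr[i]
        sr = cr[js + 1] - cr[i]
        denom = stt - st * st / m
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.where(denom > 0, (str_ - st * sr / m) / denom, 0.0)
        ok = ((mean_r > 0)
              & (spread <= tol_spread)
              & (np.abs(slope) / mean_r <= tol_slope)
              & (y[i] - y[js] >= cfg.dy_min))
        for j, res in zip(js[ok], spread[ok]):
            out.append((i, int(j), int(j - i + 1), float(res)))
    return out


def _window_admissible(t, y, r, i, j, f, cfg) -> tuple[bool, float]:
    """Admissibility check of a single window (used when merging)."""
    seg = r[i:j + 1]
    mean_r = float(seg.mean())
    if mean_r <= 0:
        return False, np.inf
    spread = float(seg.std() / mean_r)
    ts = t[i:j + 1]
    denom = float(((ts - ts.mean()) ** 2).sum())
    slope = float(((ts - ts.mean()) * (seg - mean_r)).sum() / denom) if denom else 0.0
    ok = (spread <= f * cfg.tol_r / np.sqrt(3.0)
          and abs(slope) / mean_r <= f * cfg.tol_slope
          and y[i] - y[j] >= cfg.dy_min
          and (t[j] - t[i]) >= cfg.t_min - 1e-12)
    return ok, spread


# ---------------------------------------------------------------------------
# selection strategies


def _make_greedy_select(t: np.ndarray, y: np.ndarray, r: np.ndarray,
                        f: float, cfg: PipelineConfig):
    """Longest-first greedy selector with trim-to-fit.

    Windows are taken in order of decreasing length (ties: smaller spread,
    earlier start). A window that collides with already-selected samples is
    not discarded outright: it is trimmed to the free run containing its
    start or end and kept if the trimmed window is still admissible. This
    recovers coverage lost to windows that overhang a previous selection by
    a few samples.
    """

    def select(windows: list[tuple[int, int, int, float]], n: int
               ) -> list[tuple[int, int, float]]:
        order = sorted(windows, key=lambda w: (-w[2], w[3], w[0]))
        occupied = np.zeros(n, dtype=bool)
        chosen: list[tuple[int, int, float]] = []
        for i, j, _, res in order:
            overlap = occupied[i:j + 1]
            if not overlap.any():
                occupied[i:j + 1] = True
                chosen.append((i, j, res))
                continue
            if overlap.all():
                continue
            # trim to the free run touching either end of the window
            trims = [(i, i + int(np.argmax(overlap)) - 1),
                     (j - int(np.argmax(overlap[::-1])) + 1, j)]
            trims = [(a, b) for a, b in trims if b > a]
            trims.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
            for a, b in trims:
                ok, res2 = _window_admissible(t, y, r, a, b, f, cfg)
                if ok:
                    occupied[a:b + 1] = True
                    chosen.append((a, b, res2))
                    break
        chosen.sort()
        return chosen

    return select


def _dp_select(windows: list[tuple[int, int, int, float]], n: int
               ) -> list[tuple[int, int, float]]:
    """Exact maximum-coverage selection via dynamic programming."""
    by_end: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, _, res in windows:
        by_end[j].append((i, res))
    best = np.zeros(n + 1, dtype=np.int64)        # best[k]: coverage in [0, k)
    choice: list[tuple[int, int, float] | None] = [None] * (n + 1)
    prev = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        best[j + 1] = best[j]
        prev[j + 1] = j
        choice[j + 1] = None
        for i, res in by_end[j]:
            val = best[i] + (j - i + 1)
            if val > best[j + 1]:
                best[j + 1] = val
                choice[j + 1] = (i, j, res)
                prev[j + 1] = i
    out: list[tuple[int, int, float]] = []
    k = n
    while k > 0:
        if choice[k] is None:
            k -= 1
        else:
            i, j, res = choice[k]
            out.append((i, j, res))
            k = i
    out.reverse()
    return out


# ---------------------------------------------------------------------------
# public operations


def _summarize(kt: KinematicTrack, i: int, j: int, f: float, residual: float
               ) -> ConstantRSegment:
    """Segment summary over global sample interval [i, j]."""
    cfg = kt.config
    y = kt.y_s[i:j + 1]
    V = kt.V[i:j + 1]
    r = kt.r[i:j + 1]
    if cfg.r_star_estimator == "slope":
        r_star = float((V * y).sum() / (y * y).sum())
    else:
        r_star = float(r.mean())
    return ConstantRSegment(
        track_id=kt.track_id, i_start=i, i_end=j,
        t_start=float(kt.t[i]), t_end=float(kt.t[j]),
        y_start=float(kt.y_s[i]), y_end=float(kt.y_s[j]),
        y_star=float(y.mean()), V_star=float(V.mean()),
        A_star=float(kt.A[i:j + 1].mean()), r_star=r_star,
        dy1=float(kt.y_s[i] - kt.y_s[j]), f_used=f, residual=residual)


def _detect(kt: KinematicTrack, f: float, cfg: PipelineConfig,
            mode: str) -> list[ConstantRSegment]:
    segments: list[ConstantRSegment] = []
    for p0, p1 in deceleration_phases(kt):
        t = kt.t[p0:p1 + 1]
        y = kt.y_s[p0:p1 + 1]
        r = kt.r[p0:p1 + 1]
        windows = _admissible_windows(t, y, r, f, cfg)
        select = (_make_greedy_select(t, y, r, f, cfg) if mode == "greedy"
                  else _dp_select)
        chosen = select(windows, len(r))
        # merge adjacent selections whose pooled window is admissible
        merged = True
        while merged and len(chosen) > 1:
            merged = False
            for k in range(len(chosen) - 1):
                i1, _, _ = chosen[k]
                _, j2, _ = chosen[k + 1]
                ok, res = _window_admissible(t, y, r, i1, j2, f, cfg)
                if ok:
                    chosen[k:k + 2] = [(i1, j2, res)]
                    merged = True
                    break
        for i, j, res in chosen:
            segments.append(_summarize(kt, p0 + i, p0 + j, f, res))
    segments.sort(key=lambda s: s.i_start)
    return segments


def detect_constant_r_segments(kt: KinematicTrack, f: float | None = None,
                               config: PipelineConfig | None = None
                               ) -> list[ConstantRSegment]:
    """Detect constant-r segments in one track at sensitivity f.

    Greedy longest-first selection over the admissible windows of each
    deceleration phase, followed by admissible merging. Deterministic:
    identical inputs give identical segment lists.
    """
    cfg = config or kt.config
    f = cfg.f if f is None else f
    if f <= 0:
        raise ParameterError("f must be > 0")
    return _detect(kt, f, cfg, "greedy")


def brute_force_segments(kt: KinematicTrack, f: float | None = None,
                         config: PipelineConfig | None = None,
                         max_samples: int = 2000) -> list[ConstantRSegment]:
    """Exact maximum-coverage segmentation (testing oracle, O(n^2))."""
    if len(kt) > max_samples:
        raise TrackTooLongError(
            f"track {kt.track_id!r} has {len(kt)} samples > {max_samples}")
    cfg = config or kt.config
    f = cfg.f if f is None else f
    if f <= 0:
        raise ParameterError("f must be > 0")
    return _detect(kt, f, cfg, "dp")


def covered_samples(segments: Iterable[ConstantRSegment]) -> int:
    return sum(s.n_samples for s in segments)


def monotone_selections(kt: KinematicTrack, f_values: Sequence[float],
                        config: PipelineConfig | None = None
                        ) -> dict[float, list[ConstantRSegment]]:
    """Greedy detections over an ascending f grid with monotone coverage.

    Any window admissible at f1 stays admissible at every f2 > f1, so a
    lower-f selection is always a valid (if conservative) segmentation at
    higher f. Greedy selection alone does not guarantee that its coverage
    grows with f; here the selection for each f is whichever of (fresh
    greedy result, previous f's selection) covers more samples, which
    enforces per-track coverage non-decreasing in f.
    """
    cfg = config or kt.config
    out: dict[float, list[ConstantRSegment]] = {}
    prev: list[ConstantRSegment] = []
    for f in sorted(f_values):
        fresh = detect_constant_r_segments(kt, f, cfg)
        if covered_samples(fresh) < covered_samples(prev):
            fresh = [replace_f(s, f) for s in prev]
        out[f] = fresh
        prev = fresh
    return out


def replace_f(seg: ConstantRSegment, f: float) -> ConstantRSegment:
    from dataclasses import replace
    return replace(seg, f_used=f)


def sweep_f(kts: Sequence[KinematicTrack], f_values: Sequence[float],
            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Detection summary over a grid of sensitivity factors.

    Returns one row per distinct f with the segment count, number of tracks
    with at least one segment, the fraction of deceleration-phase samples
    covered, and summary statistics of the detected set points.
    """
    fs = sorted(set(f_values))
    if len(fs) < len(f_values):
        log.warning("sweep_f: duplicate f values collapsed")
    cfg = config or (kts[0].config if kts else PipelineConfig())
    decel_total = sum(b - a + 1 for kt in kts for a, b in deceleration_phases(kt))
    per_track = [monotone_selections(kt, fs, cfg) for kt in kts]
    rows = []
    for f in fs:
        all_segs = [sel[f] for sel in per_track]
        flat = [s for segs in all_segs for s in segs]
        r_stars = np.array([s.r_star for s in flat])
        rows.append({
            "f": f,
            "n_segments": len(flat),
            "n_tracks_with_segments": sum(bool(s) for s in all_segs),
            "coverage_fraction": (covered_samples(flat) / decel_total
                                  if decel_total else 0.0),
            "r_star_mean": float(r_stars.mean()) if len(flat) else np.nan,
            "r_star_median": float(np.median(r_stars)) if len(flat) else np.nan,
            "r_star_sd": float(r_stars.std(ddof=1)) if len(flat) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def pair_consecutive_segments(kt: KinematicTrack,
                              segments: Sequence[ConstantRSegment]
                              ) -> list[SegmentPair]:
    """Pair each adjacent couple of segments of one track.

    K segments yield K-1 pairs. The near-zero-velocity flag is true when
    any sample strictly between the two segments has V < 0.05 m/s.
    """
    segs = sorted(segments, key=lambda s: s.i_start)
    pairs = []
    for a, b in zip(segs[:-1], segs[1:]):
        between = kt.V[a.i_end + 1:b.i_start]
        pairs.append(SegmentPair(
            first=a, second=b,
            dy2=float(a.y_start - b.y_end),
            dr_star=float(b.r_star - a.r_star),
            near_zero_v=bool(len(between) and (between < 0.05).any())))
    return pairs


def segments_to_frame(segments: Sequence[ConstantRSegment]) -> pd.DataFrame:
    """Segment list as a DataFrame with exactly the segment fields."""
    if not segments:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.DataFrame([{c: getattr(s, c if c != "y_star" else "y_star")
                          for c in SEGMENT_COLUMNS} for s in segments])
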