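"""Ground-truth recovery scoring for synthetic datasets.

Matches detected constant-r segments against the generator's bout
annotations. A bout is first clipped to the samples where detection is
defined at all (inside a deceleration phase; smoothing endpoints and
samples at or below the touchdown threshold are masked by construction) and
counts as matched when a single detected segment overlaps at least half of
the clipped bout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import KinematicTrack, deceleration_phases
from .segment_detection import ConstantRSegment


@dataclass
class BoutMatch:
    track_id: str
    bout: int
    r_true: float
    overlap: float          # fraction of the clipped bout covered
    matched: bool
    r_detected: float | None
    r_rel_err: float | None


def match_bouts(kt: KinematicTrack, segments: Sequence[ConstantRSegment],
                truth: pd.DataFrame, min_dy: float = 0.02,
                min_overlap: float = 0.5) -> list[BoutMatch]:
    """Score one track's detections against its annotated bouts.

    Bouts displacing less than ``min_dy`` (m) are ignored, as are bouts
    with fewer than 3 samples inside the detectable region.
    """
    valid = np.zeros(len(kt), dtype=bool)
    for a, b in deceleration_phases(kt):
        valid[a:b + 1] = True
    out: list[BoutMatch] = []
    for _, ann in truth.iterrows():
        if ann.y_start - ann.y_end < min_dy:
            continue
        idx = np.arange(int(ann.i_start), min(int(ann.i_end) + 1, len(kt)))
        idx = idx[valid[idx]]
        if len(idx) < 3:
            continue
        lo, hi = idx[0], idx[-1]
        best, best_ov = None, 0.0
        for s in segments:
            ov = max(0, min(hi, s.i_end) - max(lo, s.i_start) + 1) / len(idx)
            if ov > best_ov:
                best_ov, best = ov, s
        matched = best_ov >= min_overlap
        out.append(BoutMatch(
            track_id=kt.track_id, bout=int(ann.bout), r_true=float(ann.r_set),
            overlap=best_ov, matched=matched,
            r_detected=best.r_star if matched else None,
            r_rel_err=(abs(best.r_star - ann.r_set) / ann.r_set
                       if matched else None)))
    return out


def recovery_summary(matches: Sequence[BoutMatch],
                     r_tol: float = 0.10) -> dict[str, float]:
    """Fraction of bouts matched and, among matches, fraction of set points
    recovered within ``r_tol`` relative error."""
    n = len(matches)
    matched = [m for m in matches if m.matched]
    return {
        "n_bouts": n,
        "frac_matched": len(matched) / n if n else np.nan,
        "frac_r_within_tol": (np.mean([m.r_rel_err <= r_tol for m in matched])
                              if matched else np.nan),
    }
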