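"""Track data model and CSV I/O.

A :class:`RawTrack` is one landing approach: uniformly sampled 3D body
position plus its treatment metadata (light level, platform pattern,
landing type). The y axis is the perpendicular distance in front of the
landing platform, so y decreases toward touchdown. All downstream stages
consume these objects; no stage reads files directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, TrackValidationError

log = logging.getLogger("beeland")

TRACK_COLUMNS = ["track_id", "time_s", "x_m", "y_m", "z_m",
                 "light", "pattern", "landing_type"]


class Light(str, Enum):
    """Ambient light condition. Illuminance is metadata only and never
    enters any computation."""

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    @property
    def illuminance_lx(self) -> float:
        return {"low": 13.7, "medium": 33.3, "high": 144.9}[self.value]


class Pattern(str, Enum):
    """Visual pattern on the landing platform."""

    CHECKERBOARD = "checkerboard"
    SPOKE = "spoke"


class LandingType(str, Enum):
    """Whether the approach followed a takeoff or free flight."""

    TAKEOFF = "takeoff"
    FREE_FLIGHT = "free_flight"


#: all 12 treatment cells in a fixed, reproducible order
CELLS: tuple[tuple[Light, Pattern, LandingType], ...] = tuple(
    (li, pa, la) for li in Light for pa in Pattern for la in LandingType
)


@dataclass
class RawTrack:
    """One landing approach: uniformly sampled positions plus metadata."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    light: Light = Light.MEDIUM
    pattern: Pattern = Pattern.CHECKERBOARD
    landing_type: LandingType = LandingType.FREE_FLIGHT

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if any(len(getattr(self, k)) != n for k in ("x", "y", "z")):
            raise TrackValidationError(
                f"track {self.track_id!r}: position series length mismatch")
        self.light = Light(self.light)
        self.pattern = Pattern(self.pattern)
        self.landing_type = LandingType(self.landing_type)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def cell(self) -> tuple[Light, Pattern, LandingType]:
        return (self.light, self.pattern, self.landing_type)

    def validate_sampling(self, rtol: float = 1e-6) -> None:
        """Raise unless t is strictly increasing and uniformly sampled."""
        dts = np.diff(self.t)
        if len(dts) == 0:
            raise TrackValidationError(f"track {self.track_id!r}: empty")
        if np.any(dts <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: time not strictly increasing")
        med = np.median(dts)
        if np.max(np.abs(dts - med)) / med >= rtol:
            raise TrackValidationError(
                f"track {self.track_id!r}: non-uniform sampling")

    def with_metadata(self, light=None, pattern=None, landing_type=None,
                      track_id=None) -> "RawTrack":
        return replace(
            self,
            track_id=self.track_id if track_id is None else track_id,
            light=self.light if light is None else Light(light),
            pattern=self.pattern if pattern is None else Pattern(pattern),
            landing_type=(self.landing_type if landing_type is None
                          else LandingType(landing_type)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "track_id": self.track_id,
            "time_s": self.t,
            "x_m": self.x,
            "y_m": self.y,
            "z_m": self.z,
            "light": self.light.value,
            "pattern": self.pattern.value,
            "landing_type": self.landing_type.value,
        })


def read_tracks(path: str | Path, fmt: str = "csv",
                dt_rtol: float = 1e-6) -> list[RawTrack]:
    """Read a track CSV into a list of :class:`RawTrack`.

    Rows are sorted by time within each track. A track with non-uniform
    sampling (e.g. a duplicated or missing frame) is skipped with a logged
    warning; inconsistent metadata within a track raises.
    """
    if fmt != "csv":
        raise FormatError(f"unsupported track format: {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"track file {path} missing columns: {missing}")

    tracks: list[RawTrack] = []
    for tid, g in df.groupby("track_id", sort=False):
        g = g.sort_values("time_s")
        for col in ("light", "pattern", "landing_type"):
            if g[col].nunique() != 1:
                raise TrackValidationError(
                    f"track {tid!r}: inconsistent metadata in column {col!r}")
        track = RawTrack(
            track_id=str(tid),
            t=g["time_s"].to_numpy(),
            x=g["x_m"].to_numpy(),
            y=g["y_m"].to_numpy(),
            z=g["z_m"].to_numpy(),
            light=Light(g["light"].iloc[0]),
            pattern=Pattern(g["pattern"].iloc[0]),
            landing_type=LandingType(g["landing_type"].iloc[0]),
        )
        try:
            track.validate_sampling(rtol=dt_rtol)
        except TrackValidationError as exc:
            log.warning("skipping track: %s", exc)
            continue
        tracks.append(track)
    return tracks


def write_tracks(tracks: Iterable[RawTrack], path: str | Path) -> None:
    """Write tracks to CSV (comma-separated, '.' decimal, header row)."""
    path = Path(path)
    frames = [tr.to_frame() for tr in tracks]
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=TRACK_COLUMNS)
    # float_format=%.17g keeps the round trip exact to double precision
    out.to_csv(path, index=False, float_format="%.17g")


def write_segments(segments: Sequence, path: str | Path) -> None:
    """Write detected constant-r segments to CSV, one row per segment."""
    from .segment_detection import ConstantRSegment, segments_to_frame
    segments_to_frame(segments).to_csv(Path(path), index=False,
                                       float_format="%.17g")


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a segment CSV back into a DataFrame."""
    return pd.read_csv(Path(path))
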