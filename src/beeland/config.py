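"""Pipeline configuration.

A single :class:`PipelineConfig` travels through every stage so that
smoothing, touchdown definition, segment-detection tolerances and the
average-analysis window are set in one place and serialize to YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError

#: validation range for the detection sensitivity factor f; values outside
#: are allowed only with ``allow_f_outside_range=True``
F_RANGE = (0.25, 2.5)


@dataclass
class PipelineConfig:
    """All tunable parameters of the landing-deceleration pipeline.

    Parameters
    ----------
    sampling_rate
        Track sampling rate in Hz. Simulated tracks are generated at this
        rate; recorded tracks must match it to within ``dt_rtol``.
    smooth_window
        Length (odd, in samples) of the centered Savitzky-Golay window used
        to smooth positions and obtain derivatives. 15 samples at 200 Hz is
        0.075 s: constant-r bouts typically last ~0.1 s (0.035 m at
        ~0.35 m/s), so the window must stay below the bout duration or it
        smears bout edges into the transitions and erases the shortest
        bouts; 0.075 s still averages ~4x the raw-sample noise down.
        Scales with sampling rate.
    smooth_order
        Polynomial order of the local fit (>= 2 so accelerations exist).
        The cubic default removes the leading-order bias on the first
        derivative of exponential-like approaches, leaving r accurate to
        a few 1e-7 relative on clean tracks; even orders leave ~0.1%.
    f
        Dimensionless sensitivity factor scaling both admissibility
        tolerances of the constant-r segment detector. Larger f admits more
        (and wider) segments.
    tol_r
        Base half-width of the admissible r band around the window mean,
        as a fraction of mean r. Enforced through the window sd:
        sd(r)/mean r <= f * tol_r / sqrt(3), the sd of a drift sweeping
        the full band. The sd form keeps long windows from being rejected
        just because noise extremes accumulate with window length.
    tol_slope
        Base tolerance on |d r/dt| / mean r within a window (1/s); guards
        against slow monotone drift with small range.
    dy_min
        Minimum displacement (m) a candidate segment must cover.
    t_min
        Minimum duration (s) of a candidate segment.
    y_td
        Touchdown distance threshold (m): the maneuver ends at the first
        sample with y <= y_td.
    eps_v
        Velocity floor (m/s) below which tau is undefined and the bee is
        considered not approaching.
    gap_max
        Deceleration-phase hysteresis (s): shorter interruptions are merged.
    window_lo, window_hi
        Distance window (m) of the average-per-treatment analysis.
    bin_width
        Bin width (m) for bin-averaged V(y) profiles.
    n_min
        Minimum tracks per bin for a profile bin to be reported.
    r_star_estimator
        How a segment's set point is summarized: ``"mean"`` (mean of r over
        the segment, default) or ``"slope"`` (through-origin slope of V on y).
    seed
        Default seed for stochastic stages (bootstrap, simulation).
    """

    sampling_rate: float = 200.0
    smooth_window: int = 15
    smooth_order: int = 3
    f: float = 1.0
    tol_r: float = 0.10
    tol_slope: float = 0.20
    dy_min: float = 0.01
    t_min: float = 0.05
    y_td: float = 0.005
    eps_v: float = 1e-3
    gap_max: float = 0.05
    window_lo: float = 0.04
    window_hi: float = 0.11
    bin_width: float = 0.01
    n_min: int = 5
    r_star_estimator: str = "mean"
    seed: int = 0
    dt_rtol: float = 1e-6
    allow_f_outside_range: bool = False

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.smooth_window % 2 != 1 or self.smooth_window <= self.smooth_order:
            raise ParameterError("smooth_window must be odd and > smooth_order")
        if self.smooth_order < 2:
            raise ParameterError("smooth_order must be >= 2")
        for name in ("tol_r", "tol_slope", "dy_min", "t_min", "y_td", "eps_v",
                     "gap_max", "bin_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.f <= 0:
            raise ParameterError("f must be > 0")
        if not self.allow_f_outside_range and not (F_RANGE[0] <= self.f <= F_RANGE[1]):
            raise ParameterError(
                f"f={self.f} outside validated range {F_RANGE}; "
                "set allow_f_outside_range=True to override")
        if self.window_lo >= self.window_hi:
            raise ParameterError("window_lo must be < window_hi")
        if self.r_star_estimator not in ("mean", "slope"):
            raise ParameterError("r_star_estimator must be 'mean' or 'slope'")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        data.update(kwargs)
        return PipelineConfig(**data)
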