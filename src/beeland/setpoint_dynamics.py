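"""Set-point statistics: the log-log mixed model, gamma fit and transitions.

The central inference: if set points r* are regulated along a constant
time-to-contact-rate schedule, then ln r* is linear in ln y* with slope
tau-dot. A linear mixed-effects model of ln r* on ln y* (random intercept
per track, REML) therefore reports its distance slope as the tau-dot
estimate; treatment factors (light, platform pattern, landing type) enter
as fixed effects, and pattern x ln y* / landing-type x ln y* interactions
let tau-dot differ between those levels. The pooled set-point distribution
is summarized by a maximum-likelihood gamma fit with bootstrap confidence
intervals, and transitions between consecutive segments by the fraction of
set-point increases and the displacement budget of segments vs transitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegenerateFitError, ModelSpecError, ParameterError
from .kinematics import KinematicTrack, maneuver_displacement
from .segment_detection import ConstantRSegment, SegmentPair

log = logging.getLogger("beeland")

FACTORS = ("light", "pattern", "landing_type")


def records_from_segments(kts: Mapping[str, KinematicTrack] | Sequence[KinematicTrack],
                          segments: Sequence[ConstantRSegment]) -> pd.DataFrame:
    """Build the set-point record table (one row per detected segment)."""
    if not isinstance(kts, Mapping):
        kts = {kt.track_id: kt for kt in kts}
    ordinal: dict[str, int] = {}
    rows = []
    for s in sorted(segments, key=lambda s: (s.track_id, s.i_start)):
        kt = kts[s.track_id]
        ordinal[s.track_id] = ordinal.get(s.track_id, 0) + 1
        rows.append({
            "track_id": s.track_id, "y_star": s.y_star, "r_star": s.r_star,
            "light": kt.raw.light.value, "pattern": kt.raw.pattern.value,
            "landing_type": kt.raw.landing_type.value,
            "ordinal": ordinal[s.track_id],
        })
    return pd.DataFrame(rows)


@dataclass
class SetPointModelFit:
    """Fitted log-log mixed model of r* on y*."""

    slope: float                 # coefficient on ln y* (reference cell)
    slope_se: float
    slope_ci: tuple[float, float]
    params: pd.Series
    cov: pd.DataFrame
    group_var: float             # random-intercept variance
    formula: str
    method: str                  # "mixedlm", or "ols" for degenerate data
    factors: tuple[str, ...]
    levels: dict                 # factor -> sorted levels (first = reference)
    interactions: tuple[str, ...]
    dropped_interactions: tuple[str, ...]
    n_records: int
    n_tracks: int
    result: object = field(repr=False)

    def slope_for(self, **levels) -> float:
        """tau-dot estimate for a specific factor cell.

        Sums the base ln y* slope and any retained interaction terms for
        the given levels, e.g. ``slope_for(landing_type="takeoff")``.
        """
        total = self.slope
        for name, val in self.params.items():
            if ":" not in name or "log_y" not in name:
                continue
            for fac, lev in levels.items():
                if f"C({fac})[T.{lev}]" in name:
                    total += val
        return total


def _mixedlm(formula: str, df: pd.DataFrame, reml: bool = True):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["track_id"])
        return model.fit(reml=reml, method=["lbfgs", "powell"])


def _fit_fixed_or_mixed(formula: str, df: pd.DataFrame):
    """REML mixed fit; falls back to OLS when the mixed model is singular.

    Singularity arises for perfectly collinear (noise-free) data or when
    every track contributes a single record, leaving the random intercept
    unidentifiable; the fixed-effects point estimates are then the OLS ones
    with zero group variance.
    """
    one_per_group = df.groupby("track_id").size().max() == 1
    if not one_per_group:
        try:
            res = _mixedlm(formula, df)
            if np.isfinite(res.fe_params).all():
                return res, "mixedlm", float(np.asarray(res.cov_re).ravel()[0])
        except (np.linalg.LinAlgError, ValueError):
            pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.ols(formula, df).fit()
    return res, "ols", 0.0


def fit_loglog_model(records: pd.DataFrame,
                     factors: Sequence[str] | None = None,
                     interactions: Sequence[str] | None = ("pattern",
                                                           "landing_type"),
                     select: bool = False,
                     alpha: float = 0.05) -> SetPointModelFit:
    """Fit ln r* ~ ln y* (+ factors + slope interactions), random intercept
    per track, by REML.

    ``factors=None`` auto-includes each treatment factor that varies in the
    data; a requested factor with a single level raises. With
    ``select=True`` the slope interactions are screened by likelihood-ratio
    tests (ML fits) and those with p > alpha are dropped before the final
    REML fit; the dropped set is recorded on the result.
    """
    df = records.copy()
    if df["y_star"].nunique() < 2:
        raise ModelSpecError("need >= 2 distinct y* values")
    if (df["y_star"] <= 0).any() or (df["r_star"] <= 0).any():
        raise ParameterError("y* and r* must be positive")
    df["log_y"] = np.log(df["y_star"])
    df["log_r"] = np.log(df["r_star"])

    if factors is None:
        factors = tuple(f for f in FACTORS
                        if f in df.columns and df[f].nunique() > 1)
    else:
        factors = tuple(factors)
        for f in factors:
            if df[f].nunique() < 2:
                raise ModelSpecError(
                    f"factor {f!r} has a single level; drop it from the model")
    interactions = tuple(f for f in (interactions or ()) if f in factors)

    def build(inters: tuple[str, ...]) -> str:
        terms = ["log_y"] + [f"C({f})" for f in factors]
        terms += [f"log_y:C({f})" for f in inters]
        return "log_r ~ " + " + ".join(terms)

    dropped: tuple[str, ...] = ()
    if select and interactions:
        try:
            keep = []
            full_ml = _mixedlm(build(interactions), df, reml=False)
            for f in interactions:
                reduced = tuple(i for i in interactions if i != f)
                red_ml = _mixedlm(build(reduced), df, reml=False)
                lr = 2.0 * (full_ml.llf - red_ml.llf)
                dfree = full_ml.df_modelwc - red_ml.df_modelwc
                p = scipy.stats.chi2.sf(max(lr, 0.0), max(dfree, 1))
                if p <= alpha:
                    keep.append(f)
            dropped = tuple(f for f in interactions if f not in keep)
            interactions = tuple(keep)
        except (np.linalg.LinAlgError, ValueError):
            log.warning("interaction screening failed; keeping all terms")

    formula = build(interactions)
    res, method, group_var = _fit_fixed_or_mixed(formula, df)
    fe = res.fe_params if hasattr(res, "fe_params") else res.params
    cov = res.cov_params().loc[fe.index, fe.index]
    slope = float(fe["log_y"])
    se = float(np.sqrt(cov.loc["log_y", "log_y"]))
    z = scipy.stats.norm.ppf(0.975)
    return SetPointModelFit(
        slope=slope, slope_se=se, slope_ci=(slope - z * se, slope + z * se),
        params=fe, cov=cov, group_var=group_var,
        formula=formula, method=method,
        factors=factors,
        levels={f: sorted(df[f].unique()) for f in factors},
        interactions=interactions,
        dropped_interactions=dropped,
        n_records=len(df), n_tracks=df["track_id"].nunique(), result=res)


def marginal_means(fit: SetPointModelFit, y_ref: float = 0.15,
                   by: Sequence[str] | None = None) -> pd.DataFrame:
    """Model-predicted set point r*(y_ref) and speed V*(y_ref) per cell.

    For each combination of the ``by`` factors, the linear predictor at
    ln y_ref is averaged (equal weights) over the levels of the remaining
    factors and back-transformed from the log scale; V* = y_ref * r*.
    Standard errors come from the fixed-effects covariance by the delta
    method.
    """
    if y_ref <= 0:
        raise ParameterError("y_ref must be > 0")
    by = tuple(by) if by is not None else fit.factors
    for f in by:
        if f not in fit.factors:
            raise ModelSpecError(f"factor {f!r} not in the fitted model")

    grids = [fit.levels[f] for f in fit.factors]
    combos = pd.MultiIndex.from_product(grids, names=fit.factors).to_frame(index=False) \
        if fit.factors else pd.DataFrame([{}])

    names = list(fit.params.index)
    X = np.zeros((len(combos), len(names)))
    log_y = np.log(y_ref)
    for rix, row in combos.iterrows():
        for cix, name in enumerate(names):
            X[rix, cix] = _design_value(name, row, log_y)

    out_rows = []
    group_cols = list(by)
    groups = combos.groupby(group_cols, sort=True) if group_cols else [((), combos)]
    cov = fit.cov.to_numpy()
    beta = fit.params.to_numpy()
    z = scipy.stats.norm.ppf(0.975)
    for key, sub in groups:
        L = X[sub.index].mean(axis=0)
        pred = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        r_star = float(np.exp(pred))
        rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        rec.update({
            "log_pred": pred, "log_se": se,
            "r_star": r_star, "r_star_se": r_star * se,
            "r_star_lo": float(np.exp(pred - z * se)),
            "r_star_hi": float(np.exp(pred + z * se)),
            "V_star": y_ref * r_star, "V_star_se": y_ref * r_star * se,
            "y_ref": y_ref,
        })
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def _design_value(name: str, row: pd.Series, log_y: float) -> float:
    val = 1.0
    for part in name.split(":"):
        if part == "Intercept":
            continue
        if part == "log_y":
            val *= log_y
            continue
        if part.startswith("C(") and "[T." in part:
            fac = part[2:part.index(")")]
            lev = part[part.index("[T.") + 3:-1]
            val *= 1.0 if row.get(fac, "") == lev else 0.0
            continue
        raise ModelSpecError(f"unrecognized term {part!r}")
    return val


@dataclass
class GammaFit:
    """Maximum-likelihood gamma fit of the pooled set points."""

    shape: float
    scale: float
    shape_ci: tuple[float, float]
    scale_ci: tuple[float, float]
    median: float
    n: int
    n_boot: int

    @property
    def mean(self) -> float:
        return self.shape * self.scale


def fit_gamma_setpoints(values: np.ndarray, n_boot: int = 1000,
                        seed: int = 0) -> GammaFit:
    """Gamma MLE (location fixed at 0) with bootstrap percentile CIs."""
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ParameterError("need at least 10 set points")
    if (x <= 0).any():
        raise ParameterError("set points must be positive")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero-variance set points admit no gamma fit")
    a, _, b = scipy.stats.gamma.fit(x, floc=0)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for k in range(n_boot):
        xb = rng.choice(x, size=len(x), replace=True)
        try:
            ab, _, bb = scipy.stats.gamma.fit(xb, floc=0)
        except Exception:  # pragma: no cover - extremely rare resample failure
            ab, bb = np.nan, np.nan
        boots[k] = (ab, bb)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return GammaFit(
        shape=float(a), scale=float(b),
        shape_ci=(float(lo[0]), float(hi[0])),
        scale_ci=(float(lo[1]), float(hi[1])),
        median=float(scipy.stats.gamma.ppf(0.5, a, scale=b)),
        n=len(x), n_boot=n_boot)


@dataclass
class TransitionStats:
    """Summary of transitions between consecutive constant-r segments."""

    n_pairs: int
    frac_increasing: float
    mean_dr_increasing: float
    sd_dr_increasing: float
    mean_dy1_frac: float       # mean segment displacement / maneuver displacement
    mean_dy2_frac: float       # mean pair displacement / maneuver displacement
    frac_near_zero_v: float


def transition_statistics(pairs: Sequence[SegmentPair],
                          kts: Mapping[str, KinematicTrack] | Sequence[KinematicTrack],
                          segments: Sequence[ConstantRSegment] | None = None
                          ) -> TransitionStats:
    """Transition statistics over all detected segment pairs.

    Displacement fractions are normalized per track by the total maneuver
    displacement (y at maneuver start minus y at touchdown). An empty pair
    list yields n = 0 statistics rather than an error.
    """
    if not isinstance(kts, Mapping):
        kts = {kt.track_id: kt for kt in kts}
    if not pairs:
        return TransitionStats(0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
    dy_tot = {tid: maneuver_displacement(kt) for tid, kt in kts.items()}
    dr = np.array([p.dr_star for p in pairs])
    inc = dr > 0
    dy2_frac = np.array([p.dy2 / dy_tot[p.track_id] for p in pairs
                         if dy_tot[p.track_id] > 0])
    if segments is None:
        segments = [s for p in pairs for s in (p.first, p.second)]
        seen = set()
        segments = [s for s in segments
                    if id(s) not in seen and not seen.add(id(s))]
    dy1_frac = np.array([s.dy1 / dy_tot[s.track_id] for s in segments
                         if dy_tot.get(s.track_id, 0) > 0])
    return TransitionStats(
        n_pairs=len(pairs),
        frac_increasing=float(inc.mean()),
        mean_dr_increasing=float(dr[inc].mean()) if inc.any() else np.nan,
        sd_dr_increasing=(float(dr[inc].std(ddof=1)) if inc.sum() > 1 else np.nan),
        mean_dy1_frac=float(dy1_frac.mean()) if len(dy1_frac) else np.nan,
        mean_dy2_frac=float(dy2_frac.mean()) if len(dy2_frac) else np.nan,
        frac_near_zero_v=float(np.mean([p.near_zero_v for p in pairs])))
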