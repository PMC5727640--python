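"""Parametric survival machinery.

The cohort model is driven by two Weibull survival curves (progression-free
and overall survival of the control arm) and by pooled hazard ratios that
carry the treatment effect.  Under proportional hazards the active-arm curve
is obtained by exponentiation, ``S_active(t) = S_ref(t) ** HR``, which for a
Weibull leaves the shape untouched and multiplies the scale by the hazard
ratio.

Curves are parameterised as ``S(t) = exp(-scale * t**shape)`` with time in
weeks, matching the weekly model cycle.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Z_95 = float(stats.norm.ppf(0.975))


class FitError(ValueError):
    """Raised when a survival-curve fit is underdetermined."""


@dataclass(frozen=True)
class WeibullCurve:
    """Weibull survival curve ``S(t) = exp(-scale * t**shape)``, t in weeks.

    ``shape > 1`` gives a hazard that rises with time (the typical picture in
    refractory metastatic disease); ``shape = 1`` degenerates to an
    exponential.
    """

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError(f"shape must be positive and finite, got {self.shape}")

    def survival(self, t):
        """Survival fraction at time ``t`` (weeks); scalar or array, t >= 0."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("survival time must be non-negative")
        out = np.exp(-self.scale * np.power(t_arr, self.shape))
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def median(self) -> float:
        """Time at which survival reaches one half: (ln2 / scale)^(1/shape)."""
        return (math.log(2.0) / self.scale) ** (1.0 / self.shape)

    def adjusted(self, hr: float) -> "WeibullCurve":
        return adjust_survival(self, hr)


def weibull_survival(curve: WeibullCurve, t) -> float:
    """Evaluate ``S(t) = exp(-scale * t**shape)``; convenience wrapper."""
    return curve.survival(t)


def adjust_survival(reference: WeibullCurve, hr: float) -> WeibullCurve:
    """Apply a hazard ratio to a reference curve: S_active = S_ref ** hr.

    For a Weibull this is exact: the scale multiplies by ``hr`` and the shape
    is preserved, so the proportional-hazards adjustment stays inside the
    Weibull family.
    """
    if not (hr > 0 and math.isfinite(hr)):
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    return WeibullCurve(scale=reference.scale * hr, shape=reference.shape)


@dataclass(frozen=True)
class KMPoints:
    """Ordered Kaplan-Meier points: times (weeks) and survival fractions."""

    times: tuple
    survival: tuple
    at_risk: tuple | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and survival must be 1-d and equal length")
        if len(t) and (np.any(np.diff(t) <= 0) or np.any(t <= 0)):
            raise ValueError("times must be strictly increasing and positive")
        if len(s) and (np.any(np.diff(s) > 1e-12) or np.any(s <= 0) or np.any(s > 1)):
            raise ValueError("survival must be non-increasing and in (0, 1]")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "survival", tuple(float(x) for x in s))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_weeks": self.times, "survival": self.survival}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "KMPoints":
        df = pd.read_csv(path)
        return cls(times=tuple(df["time_weeks"]), survival=tuple(df["survival"]))


@dataclass(frozen=True)
class WeibullFit:
    """Result of the complementary-log-log regression fit of a Weibull."""

    curve: WeibullCurve
    r_squared: float
    scale_se: float  # SE of the intercept ln(scale) on the regression scale
    shape_se: float  # SE of the slope (the shape itself)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scale": self.curve.scale,
                    "shape": self.curve.shape,
                    "r_squared": self.r_squared,
                    "scale_se": self.scale_se,
                    "shape_se": self.shape_se,
                },
                indent=2,
            )
        )


def fit_weibull(points: KMPoints) -> WeibullFit:
    """Fit a Weibull to Kaplan-Meier points by linearised least squares.

    Taking logs twice, ``ln(-ln S(t)) = ln(scale) + shape * ln(t)``, so an
    ordinary least-squares regression of the complementary-log-log of
    survival on log time yields the shape as the slope and log-scale as the
    intercept, with the regression R^2 as the goodness-of-fit diagnostic.
    Points with survival exactly 1 or 0 carry no information on this scale
    and are dropped with a warning.
    """
    t = np.asarray(points.times, dtype=float)
    s = np.asarray(points.survival, dtype=float)
    usable = (s > 0.0) & (s < 1.0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "fit_weibull: dropped %d point(s) with survival at 0 or 1", n_dropped
        )
    t, s = t[usable], s[usable]
    if len(np.unique(t)) < 2:
        raise FitError("need at least 2 usable points with distinct times")
    x = np.log(t)
    y = np.log(-np.log(s))
    res = stats.linregress(x, y)
    curve = WeibullCurve(scale=float(np.exp(res.intercept)), shape=float(res.slope))
    # with exactly 2 points the regression is saturated; SEs are undefined
    se_slope = float(res.stderr) if len(t) > 2 else float("nan")
    se_inter = float(res.intercept_stderr) if len(t) > 2 else float("nan")
    return WeibullFit(
        curve=curve,
        r_squared=float(res.rvalue**2),
        scale_se=se_inter,
        shape_se=se_slope,
    )


@dataclass(frozen=True)
class HazardRatioEstimate:
    """A hazard ratio with its 95% CI and the SE of ln(HR).

    When ``log_hr_se`` is not given it is derived from the CI assuming
    normality of ln(HR): ``se = (ln ci_high - ln ci_low) / (2 * 1.96)``.
    An explicit ``log_hr_se`` overrides the CI-derived value, which matters
    when a published interval is not centred on the point estimate.
    """

    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("hr", "ci_low", "ci_high"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive, got {v}")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")
        if self.log_hr_se is None:
            object.__setattr__(
                self,
                "log_hr_se",
                (math.log(self.ci_high) - math.log(self.ci_low)) / (2.0 * Z_95),
            )
        if self.log_hr_se < 0:
            raise ValueError("log_hr_se must be non-negative")

    @classmethod
    def from_log_hr(cls, log_hr: float, se: float) -> "HazardRatioEstimate":
        return cls(
            hr=math.exp(log_hr),
            ci_low=math.exp(log_hr - Z_95 * se),
            ci_high=math.exp(log_hr + Z_95 * se),
            log_hr_se=se,
        )


def pool_hazard_ratios(
    estimates: Sequence[HazardRatioEstimate],
) -> HazardRatioEstimate:
    """Fixed-effect inverse-variance pooling of hazard ratios on the log scale.

    Each trial contributes weight ``1 / se^2``; the pooled ln(HR) is the
    weighted mean and its SE is ``1 / sqrt(sum of weights)``, so the pooled
    interval is never wider than the narrowest input interval.
    """
    if not estimates:
        raise ValueError("need at least one hazard-ratio estimate to pool")
    log_hrs = np.array([math.log(e.hr) for e in estimates])
    ses = np.array([e.log_hr_se for e in estimates], dtype=float)
    if np.any(~np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("every estimate must carry a finite positive log-HR SE")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * log_hrs) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    return HazardRatioEstimate.from_log_hr(pooled, pooled_se)
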