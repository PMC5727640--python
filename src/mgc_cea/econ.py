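"""Incremental cost-effectiveness and sensitivity analyses.

Implements the decision-analytic layer over the cohort engine: incremental
cost-effectiveness ratios with dominance handling, net monetary benefit,
one-way (tornado) sensitivity analysis over the declared parameter ranges,
probabilistic sensitivity analysis (PSA) with the distribution families
conventional in health economics — triangular for costs, beta for utilities
and proportions, lognormal for hazard ratios — and the cost-effectiveness
acceptability curve (CEAC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import OutcomeSummary, Strategy, run_strategy
from .parameters import ModelInputs, RangedValue

logger = logging.getLogger(__name__)

DominanceTag = Literal["dominant", "dominated", "equivalent"]

#: default willingness-to-pay grid for the CEAC, USD per QALY
DEFAULT_WTP_GRID = tuple(range(0, 60001, 1000))


@dataclass(frozen=True)
class IcerResult:
    """Incremental comparison of an alternative against a reference strategy.

    ``icer`` is the cost per unit of effect gained and is reported only when
    the ratio is meaningful (both deltas non-zero with matching
    interpretation); a cheaper-and-better alternative is tagged
    ``dominant``, a dearer-and-worse one ``dominated``, and identical
    outcomes ``equivalent``.  Negative ratios are never reported.
    """

    delta_cost: float
    delta_effect: float
    icer: float | None = None
    dominance: DominanceTag | None = None
    effect_units: str = "QALY"

    def describe(self) -> str:
        if self.dominance is not None:
            return self.dominance
        return f"{self.icer:,.0f} per {self.effect_units}"


def _icer_from_deltas(dc: float, de: float, units: str, tol: float = 1e-12) -> IcerResult:
    if abs(dc) <= tol and abs(de) <= tol:
        return IcerResult(dc, de, dominance="equivalent", effect_units=units)
    if de > tol and dc <= tol:
        return IcerResult(dc, de, dominance="dominant", effect_units=units)
    if de <= tol and dc > tol:
        return IcerResult(dc, de, dominance="dominated", effect_units=units)
    if abs(de) <= tol:
        # same effect, different cost: sign of cost decides
        tag: DominanceTag = "dominant" if dc < 0 else "dominated"
        return IcerResult(dc, de, dominance=tag, effect_units=units)
    return IcerResult(dc, de, icer=dc / de, effect_units=units)


def compute_icer(
    reference: OutcomeSummary,
    alternative: OutcomeSummary,
    effect: Literal["qalys", "ly"] = "qalys",
) -> IcerResult:
    """ICER of ``alternative`` versus ``reference`` on QALYs (or life-years)."""
    dc = alternative.total_cost - reference.total_cost
    if effect == "qalys":
        de = alternative.qalys - reference.qalys
        units = "QALY"
    elif effect == "ly":
        de = alternative.overall_ly - reference.overall_ly
        units = "LY"
    else:
        raise ValueError(f"unknown effect measure '{effect}'")
    return _icer_from_deltas(dc, de, units)


def net_monetary_benefit(summary: OutcomeSummary, wtp: float) -> float:
    """NMB = wtp x QALYs - total cost; higher is better at the given threshold."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * summary.qalys - summary.total_cost


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _sensitivity_parameters(inputs: ModelInputs) -> dict[str, tuple[float, float, float]]:
    """(base, low, high) per varied parameter; HR ranges come from the CIs."""
    c, u = inputs.costs, inputs.utilities

    def rv(x: RangedValue):
        return (x.value, x.low, x.high)

    return {
        "apatinib_unit_cost": rv(c.apatinib_unit_cost),
        "supportive_care_per_cycle": rv(c.supportive_care_per_cycle),
        "end_of_life_palliative": rv(c.end_of_life_palliative),
        "coverage_fraction": rv(c.coverage_fraction),
        "u_pfs": rv(u.u_pfs),
        "u_pd": rv(u.u_pd),
        "hr_pfs": (inputs.hr_pfs.hr, inputs.hr_pfs.ci_low, inputs.hr_pfs.ci_high),
        "hr_os": (inputs.hr_os.hr, inputs.hr_os.ci_low, inputs.hr_os.ci_high),
    }


def _icer_value(inputs: ModelInputs, comparison: tuple[Strategy, Strategy], overrides: dict) -> float:
    ref = run_strategy(inputs, comparison[0], overrides=overrides, warn_clamp=False)
    alt = run_strategy(inputs, comparison[1], overrides=overrides, warn_clamp=False)
    res = compute_icer(ref, alt)
    if res.icer is None:
        return math.nan
    return res.icer


def one_way_sensitivity(
    inputs: ModelInputs,
    comparison: tuple[Strategy, Strategy] = ("control", "apatinib_pap"),
    parameters: Sequence[str] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: each parameter to its low then high, all else at base.

    Entries are sorted by descending ICER span with an alphabetical
    tie-break.  Parameters with a degenerate range (low = high = base)
    yield zero span; a parameter with no derivable range is skipped with a
    warning.
    """
    space = _sensitivity_parameters(inputs)
    names = list(parameters) if parameters is not None else list(space)
    entries: list[TornadoEntry] = []
    for name in names:
        if name not in space:
            logger.warning("one_way_sensitivity: no range for '%s'; skipped", name)
            continue
        _, low, high = space[name]
        entries.append(
            TornadoEntry(
                parameter=name,
                low=low,
                high=high,
                icer_at_low=_icer_value(inputs, comparison, {name: low}),
                icer_at_high=_icer_value(inputs, comparison, {name: high}),
            )
        )
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "span": e.span,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling recipe for one parameter in the PSA."""

    name: str
    family: Literal["triangular", "beta", "lognormal", "fixed"]
    args: tuple

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "triangular":
            lo, mode, hi = self.args
            if hi <= lo:
                return np.full(n, mode)
            return rng.triangular(lo, mode, hi, size=n)
        if self.family == "beta":
            a, b = self.args
            return rng.beta(a, b, size=n)
        if self.family == "lognormal":
            mu, sigma = self.args
            return np.exp(rng.normal(mu, sigma, size=n))
        return np.full(n, self.args[0])

    def mean(self) -> float:
        if self.family == "triangular":
            lo, mode, hi = self.args
            return (lo + mode + hi) / 3.0
        if self.family == "beta":
            a, b = self.args
            return a / (a + b)
        if self.family == "lognormal":
            mu, sigma = self.args
            return math.exp(mu + sigma**2 / 2.0)
        return float(self.args[0])


def beta_from_moments(mean: float, sd: float) -> tuple[float, float] | None:
    """Method-of-moments (alpha, beta) for a beta on [0,1]; None if infeasible."""
    if sd <= 0 or not 0 < mean < 1:
        return None
    var = sd**2
    common = mean * (1 - mean) / var - 1.0
    if common <= 0:
        return None
    return mean * common, (1 - mean) * common


def _triangular(name: str, rv: RangedValue) -> ParameterDistribution:
    return ParameterDistribution(name, "triangular", (rv.low, rv.value, rv.high))


def _beta(name: str, rv: RangedValue) -> ParameterDistribution:
    ab = beta_from_moments(rv.value, (rv.high - rv.low) / 4.0)
    if ab is None:
        logger.warning("PSA: beta unresolvable for '%s'; held fixed at base", name)
        return ParameterDistribution(name, "fixed", (rv.value,))
    return ParameterDistribution(name, "beta", ab)


def default_psa_distributions(inputs: ModelInputs) -> list[ParameterDistribution]:
    """The conventional PSA recipe for this parameter set.

    Triangular (low, mode=base, high) for the three unit costs; beta via
    method of moments (mean = base, sd = range/4) for the two utilities and
    the coverage proportion; lognormal for the two hazard ratios with the
    SE of ln(HR) taken from the estimate (CI-derived unless overridden).
    """
    c, u = inputs.costs, inputs.utilities
    return [
        _triangular("apatinib_unit_cost", c.apatinib_unit_cost),
        _triangular("supportive_care_per_cycle", c.supportive_care_per_cycle),
        _triangular("end_of_life_palliative", c.end_of_life_palliative),
        _beta("coverage_fraction", c.coverage_fraction),
        _beta("u_pfs", u.u_pfs),
        _beta("u_pd", u.u_pd),
        ParameterDistribution(
            "hr_pfs", "lognormal", (math.log(inputs.hr_pfs.hr), inputs.hr_pfs.log_hr_se)
        ),
        ParameterDistribution(
            "hr_os", "lognormal", (math.log(inputs.hr_os.hr), inputs.hr_os.log_hr_se)
        ),
    ]


@dataclass(frozen=True)
class PsaResult:
    """Joint parameter draws propagated through the cohort model."""

    draws: pd.DataFrame  # columns: draw, strategy, cost, qalys
    parameter_samples: pd.DataFrame  # one column per sampled parameter
    seed: int
    distributions: tuple = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return int(self.draws["draw"].nunique())

    @property
    def strategies(self) -> tuple:
        return tuple(self.draws["strategy"].unique())

    def pivot(self, column: str) -> pd.DataFrame:
        return self.draws.pivot(index="draw", columns="strategy", values=column)


def run_psa(
    inputs: ModelInputs,
    n: int = 1000,
    seed: int = 0,
    strategies: Sequence[Strategy] = ("control", "apatinib_no_pap", "apatinib_pap"),
    distributions: Sequence[ParameterDistribution] | None = None,
) -> PsaResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Draws ``n`` joint, independent parameter samples and reruns the full
    cohort model per draw for each strategy.  Deterministic under a fixed
    seed.
    """
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    dists = list(distributions) if distributions is not None else default_psa_distributions(inputs)
    samples = {d.name: d.sample(rng, n) for d in dists}
    sample_frame = pd.DataFrame(samples)

    records = []
    clamped_draws = 0
    for i in range(n):
        overrides = {k: float(v[i]) for k, v in samples.items()}
        draw_clamped = False
        for strat in strategies:
            s = run_strategy(inputs, strat, overrides=overrides, warn_clamp=False)
            draw_clamped = draw_clamped or s.clamp_magnitude > 0.0
            records.append(
                {"draw": i, "strategy": strat, "cost": s.total_cost, "qalys": s.qalys}
            )
        clamped_draws += draw_clamped
    if clamped_draws:
        logger.warning(
            "run_psa: PFS/OS curves crossed in %d of %d draws; "
            "progressed occupancy clamped at 0 there",
            clamped_draws,
            n,
        )
    return PsaResult(
        draws=pd.DataFrame(records),
        parameter_samples=sample_frame,
        seed=seed,
        distributions=tuple(dists),
    )


@dataclass(frozen=True)
class CeacCurve:
    """Probability of cost-effectiveness across a willingness-to-pay grid."""

    comparison: tuple
    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "p_ce": self.probability})

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp - wtp)))
        return float(self.probability[idx])


def ceac(
    psa: PsaResult,
    wtp_grid: Sequence[float] = DEFAULT_WTP_GRID,
    comparison: tuple[Strategy, Strategy] = ("control", "apatinib_pap"),
) -> CeacCurve:
    """Fraction of PSA draws in which the alternative has the higher NMB.

    For each threshold on the grid the probability is the share of draws
    where ``wtp x dQALY - dCost > 0`` for the alternative versus the
    reference.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("willingness-to-pay grid must be strictly increasing")
    cost = psa.pivot("cost")
    eff = psa.pivot("qalys")
    ref, alt = comparison
    d_cost = (cost[alt] - cost[ref]).to_numpy()
    d_eff = (eff[alt] - eff[ref]).to_numpy()
    prob = np.array([(wtp * d_eff - d_cost > 0).mean() for wtp in grid])
    return CeacCurve(comparison=comparison, wtp=grid, probability=prob)
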