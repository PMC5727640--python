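"""Three-state cohort engine: trace construction and outcome accrual.

State occupancy is read directly off the two survival curves
(partitioned-survival form): at cycle time t the progression-free fraction
is S_pfs(t), the dead fraction is 1 - S_os(t) and the progressed fraction
is the remainder, clamped at zero if the curves cross.  Outcomes
(life-years, QALYs, payer costs) are accrued cycle by cycle with
state membership evaluated at cycle start and discounted at an annual rate
compounded per cycle.  No half-cycle correction is applied; with weekly
cycles its effect is below one percent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .parameters import ModelConfig, ModelInputs, UtilityInputs
from .survival import WeibullCurve, adjust_survival

logger = logging.getLogger(__name__)

Strategy = Literal["control", "apatinib_no_pap", "apatinib_pap"]
STRATEGIES: tuple[Strategy, ...] = ("control", "apatinib_no_pap", "apatinib_pap")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy of {progression-free, progressed, dead}.

    Arrays hold cycle starts k = 0..N (N = number of cycles in the horizon);
    accrual operations integrate over the N cycles using start-of-cycle
    membership.  ``incident_deaths[k]`` is the fraction dying during cycle
    k-1, i.e. newly dead at cycle start k.
    """

    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    incident_deaths: np.ndarray
    #: largest amount by which S_pfs exceeded S_os before clamping (0 = no clamp)
    clamp_magnitude: float = 0.0

    @property
    def n_cycles(self) -> int:
        return len(self.pfs) - 1

    def to_frame(self, config: ModelConfig | None = None) -> pd.DataFrame:
        k = np.arange(len(self.pfs))
        df = pd.DataFrame(
            {
                "cycle": k,
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
                "incident_deaths": self.incident_deaths,
            }
        )
        if config is not None:
            df.insert(1, "week", k * config.cycle_length_weeks())
            df["discount_factor"] = discount_factors(config, len(k))
        return df

    def to_csv(self, path, config: ModelConfig | None = None) -> None:
        self.to_frame(config).to_csv(path, index=False)


def build_trace(
    pfs_curve: WeibullCurve, os_curve: WeibullCurve, config: ModelConfig
) -> CohortTrace:
    """Partitioned-survival occupancy at every cycle start.

    pfs_k = S_pfs(t_k), dead_k = 1 - S_os(t_k),
    pd_k = max(0, S_os(t_k) - S_pfs(t_k)).

    The clamp prevents a negative progressed fraction when extreme
    sensitivity values make the PFS curve cross above the OS curve; a bound
    clamp is logged because it signals inconsistent curve inputs.
    """
    n = config.n_cycles()
    t = np.arange(n + 1) * config.cycle_length_weeks()
    s_pfs = pfs_curve.survival(t)
    s_os = os_curve.survival(t)
    clamp = float(np.max(s_pfs - s_os, initial=0.0))
    if clamp > 1e-12:
        logger.debug(
            "build_trace: PFS curve exceeds OS curve (max excess %.3g); "
            "progressed occupancy clamped at 0",
            clamp,
        )
    else:
        clamp = 0.0
    pfs = np.minimum(s_pfs, s_os)
    dead = 1.0 - s_os
    pd_ = np.maximum(0.0, s_os - s_pfs)
    incident = np.diff(dead, prepend=0.0)
    return CohortTrace(
        pfs=pfs, pd=pd_, dead=dead, incident_deaths=incident, clamp_magnitude=clamp
    )


def discount_factor(cycle_index: int, config: ModelConfig) -> float:
    """Per-cycle discount factor (1 + r)^(-k / cycles_per_year)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    return float(
        (1.0 + config.annual_discount_rate)
        ** (-cycle_index / config.cycles_per_year())
    )


def discount_factors(config: ModelConfig, n: int) -> np.ndarray:
    k = np.arange(n)
    return (1.0 + config.annual_discount_rate) ** (-k / config.cycles_per_year())


def life_years(
    trace: CohortTrace,
    config: ModelConfig,
    state_filter: Literal["pfs", "alive"] = "alive",
    discounted: bool = True,
) -> float:
    """Life-years in the chosen states (alive = pfs + progressed).

    Discounting follows the config rate by default; pass
    ``discounted=False`` for the undiscounted accumulation conventional in
    outcome tables that discount only costs and QALYs.
    """
    if state_filter == "pfs":
        occ = trace.pfs
    elif state_filter == "alive":
        occ = trace.pfs + trace.pd
    else:
        raise ValueError(f"unknown state_filter '{state_filter}'")
    n = trace.n_cycles
    df = discount_factors(config, n) if discounted else np.ones(n)
    return float(np.sum(occ[:n] * df) * config.cycle_length_years())


def qalys(trace: CohortTrace, utilities: UtilityInputs, config: ModelConfig) -> float:
    """Discounted quality-adjusted life-years over the trace."""
    return qalys_at(trace, utilities.u_pfs.value, utilities.u_pd.value, config)


def qalys_at(
    trace: CohortTrace, u_pfs: float, u_pd: float, config: ModelConfig
) -> float:
    n = trace.n_cycles
    df = discount_factors(config, n)
    w = u_pfs * trace.pfs[:n] + u_pd * trace.pd[:n]
    return float(np.sum(w * df) * config.cycle_length_years())


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted payer costs (USD) split by the state that generated them."""

    cost_pfs_state: float
    cost_pd_state: float
    cost_death: float

    @property
    def total(self) -> float:
        return self.cost_pfs_state + self.cost_pd_state + self.cost_death


def _drug_cycle_cost(
    inputs: ModelInputs, strategy: Strategy, n_cycles: int, unit_cost: float | None
) -> np.ndarray:
    """Full (pre-coverage) drug charge per cycle, by cycle index."""
    charge = np.zeros(n_cycles)
    if strategy == "control":
        return charge
    days = 7.0 * config_days_factor(inputs.config)
    charge[:] = inputs.costs.daily_drug_charge(unit_cost) * days
    if strategy == "apatinib_pap" and inputs.pap.enabled:
        paid = inputs.pap.paid_cycles(inputs.config)
        charge[paid:] = 0.0
    return charge


def config_days_factor(config: ModelConfig) -> float:
    """Days per cycle divided by 7 (1.0 for weekly cycles)."""
    return config.cycle_length_weeks()


def accrue_costs(
    trace: CohortTrace,
    inputs: ModelInputs,
    strategy: Strategy,
    *,
    overrides: dict | None = None,
) -> CostBreakdown:
    """Discounted payer costs over the trace for one strategy.

    Per cycle the payer pays ``coverage_fraction`` of the full charges:
    drug (apatinib strategies, zeroed after the PAP paid window) plus, in
    the control arm, supportive care while progression-free; supportive
    care per cycle in the progressed state; and a one-time end-of-life
    palliative charge at the cycle of incident death.  ``overrides`` lets
    sensitivity analyses substitute unit costs without rebuilding inputs
    (keys: apatinib_unit_cost, supportive_care_per_cycle,
    end_of_life_palliative, coverage_fraction).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy '{strategy}'")
    ov = overrides or {}
    supportive = ov.get(
        "supportive_care_per_cycle", inputs.costs.supportive_care_per_cycle.value
    )
    eol = ov.get("end_of_life_palliative", inputs.costs.end_of_life_palliative.value)
    coverage = ov.get("coverage_fraction", inputs.costs.coverage_fraction.value)
    unit_cost = ov.get("apatinib_unit_cost")

    n = trace.n_cycles
    config = inputs.config
    df = discount_factors(config, n + 1)

    drug = _drug_cycle_cost(inputs, strategy, n, unit_cost)
    on_drug = strategy != "control"
    supp_in_pfs = (not on_drug) or inputs.costs.pfs_supportive_with_drug
    pfs_cycle_charge = drug + (supportive if supp_in_pfs else 0.0)

    cost_pfs = coverage * np.sum(trace.pfs[:n] * pfs_cycle_charge * df[:n])
    cost_pd = coverage * np.sum(trace.pd[:n] * supportive * df[:n])
    # deaths incident at cycle start k (k = 1..N) are charged at that cycle
    cost_death = coverage * eol * np.sum(trace.incident_deaths[1:] * df[1:])
    return CostBreakdown(
        cost_pfs_state=float(cost_pfs),
        cost_pd_state=float(cost_pd),
        cost_death=float(cost_death),
    )


@dataclass(frozen=True)
class OutcomeSummary:
    """Discounted outcomes of one strategy: the rows of the base-case table."""

    strategy: Strategy
    disease_free_ly: float
    overall_ly: float
    qalys: float
    costs: CostBreakdown
    clamp_magnitude: float = 0.0

    @property
    def total_cost(self) -> float:
        return self.costs.total

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "disease_free_ly": self.disease_free_ly,
            "overall_ly": self.overall_ly,
            "qalys": self.qalys,
            "cost_pfs_state": self.costs.cost_pfs_state,
            "cost_pd_state": self.costs.cost_pd_state,
            "cost_death": self.costs.cost_death,
            "total_cost": self.total_cost,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def strategy_curves(
    inputs: ModelInputs,
    strategy: Strategy,
    *,
    hr_pfs: float | None = None,
    hr_os: float | None = None,
) -> tuple[WeibullCurve, WeibullCurve]:
    """PFS/OS curves for a strategy: HR-adjusted control curves for apatinib."""
    if strategy == "control":
        return inputs.control_pfs, inputs.control_os
    hp = inputs.hr_pfs.hr if hr_pfs is None else hr_pfs
    ho = inputs.hr_os.hr if hr_os is None else hr_os
    return (
        adjust_survival(inputs.control_pfs, hp),
        adjust_survival(inputs.control_os, ho),
    )


def run_strategy(
    inputs: ModelInputs,
    strategy: Strategy,
    *,
    overrides: dict | None = None,
    warn_clamp: bool = True,
) -> OutcomeSummary:
    """Full pipeline for one strategy: adjust curves, trace, accrue outcomes.

    ``overrides`` may additionally carry ``hr_pfs``, ``hr_os``, ``u_pfs``,
    ``u_pd`` for sensitivity analyses.  ``warn_clamp=False`` defers
    crossing-curve warnings to a caller that aggregates them (the PSA).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy '{strategy}'")
    ov = overrides or {}
    pfs_curve, os_curve = strategy_curves(
        inputs, strategy, hr_pfs=ov.get("hr_pfs"), hr_os=ov.get("hr_os")
    )
    trace = build_trace(pfs_curve, os_curve, inputs.config)
    if warn_clamp and trace.clamp_magnitude > 0.0:
        logger.warning(
            "%s: PFS curve crossed above OS curve (max excess %.3g); "
            "progressed occupancy clamped at 0",
            strategy,
            trace.clamp_magnitude,
        )
    u_pfs = ov.get("u_pfs", inputs.utilities.u_pfs.value)
    u_pd = ov.get("u_pd", inputs.utilities.u_pd.value)
    # life-years are reported undiscounted (only costs and QALYs are
    # discounted, the usual convention in oncology outcome tables)
    return OutcomeSummary(
        strategy=strategy,
        disease_free_ly=life_years(trace, inputs.config, "pfs", discounted=False),
        overall_ly=life_years(trace, inputs.config, "alive", discounted=False),
        qalys=qalys_at(trace, u_pfs, u_pd, inputs.config),
        costs=accrue_costs(trace, inputs, strategy, overrides=overrides),
        clamp_magnitude=trace.clamp_magnitude,
    )


def run_all_strategies(
    inputs: ModelInputs, *, overrides: dict | None = None
) -> dict[Strategy, OutcomeSummary]:
    return {s: run_strategy(inputs, s, overrides=overrides) for s in STRATEGIES}
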