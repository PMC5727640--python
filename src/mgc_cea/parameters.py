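"""Parameter space of the analysis: loading, validation, defaults.

Everything the model consumes — survival parameters, hazard ratios, unit
costs with their sensitivity ranges, utilities, discounting and horizon
settings, the patient-assistance-programme (PAP) rules and the
budget-impact demographics — lives in one :class:`ModelInputs` object,
loadable from a versioned YAML file.  The packaged ``base_case.yaml``
carries the published base-case values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml

from .survival import HazardRatioEstimate, WeibullCurve

SCHEMA_VERSION = 1

WEEKS_PER_YEAR = 52  # fixed convention: a model year is exactly 52 weekly cycles
MONTHS_PER_YEAR = 12


class SchemaError(ValueError):
    """A required field is missing or the file does not match the schema."""


class ValidationError(ValueError):
    """A parameter value violates its declared bounds."""


@dataclass(frozen=True)
class RangedValue:
    """A base-case value with the (low, high) range used in sensitivity analyses."""

    value: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.value <= self.high):
            raise ValidationError(
                f"range must satisfy low <= value <= high, got "
                f"({self.low}, {self.value}, {self.high})"
            )

    @classmethod
    def from_base(cls, value: float, rel: float = 0.25) -> "RangedValue":
        """Symmetric +/-``rel`` range around a base value."""
        return cls(value=value, low=value * (1 - rel), high=value * (1 + rel))


def _require(mapping: dict, key: str, where: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise SchemaError(f"missing required field '{key}' in section '{where}'")
    return mapping[key]


def _ranged(mapping: dict, key: str, where: str) -> RangedValue:
    node = _require(mapping, key, where)
    if not isinstance(node, dict):
        raise SchemaError(f"field '{where}.{key}' must be a mapping with value/low/high")
    return RangedValue(
        value=float(_require(node, "value", f"{where}.{key}")),
        low=float(_require(node, "low", f"{where}.{key}")),
        high=float(_require(node, "high", f"{where}.{key}")),
    )


@dataclass(frozen=True)
class ModelConfig:
    """Global model settings: cycle, horizon, discounting, threshold."""

    cycle_length: float = 1.0
    cycle_unit: Literal["week", "month"] = "week"
    horizon_years: float = 10.0
    annual_discount_rate: float = 0.05
    wtp_threshold: float = 22200.0
    currency_year: int = 2015

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValidationError("cycle_length must be positive")
        if self.cycle_unit not in ("week", "month"):
            raise ValidationError(f"unknown cycle_unit '{self.cycle_unit}'")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError("annual_discount_rate must be in [0, 1)")
        if self.wtp_threshold <= 0:
            raise ValidationError("wtp_threshold must be positive")
        if self.horizon_years * self.cycles_per_year() < 1:
            raise ValidationError("horizon must cover at least one cycle")

    def cycles_per_year(self) -> float:
        """Cycles in one calendar year (52 weeks exactly; 12 months)."""
        per_year = WEEKS_PER_YEAR if self.cycle_unit == "week" else MONTHS_PER_YEAR
        return per_year / self.cycle_length

    def n_cycles(self) -> int:
        """Total number of cycles in the horizon (floor)."""
        return int(math.floor(self.horizon_years * self.cycles_per_year()))

    def cycle_length_weeks(self) -> float:
        if self.cycle_unit == "week":
            return self.cycle_length
        return self.cycle_length * WEEKS_PER_YEAR / MONTHS_PER_YEAR

    def cycle_length_years(self) -> float:
        return 1.0 / self.cycles_per_year()


def cycles_per_year(config: ModelConfig) -> float:
    """Number of model cycles per calendar year under the 52-week convention."""
    return config.cycles_per_year()


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities (time-trade-off scale, anchored 0 = dead, 1 = full health)."""

    u_pfs: RangedValue = RangedValue(0.88, 0.80, 0.97)
    u_pd: RangedValue = RangedValue(0.41, 0.28, 0.63)

    def __post_init__(self) -> None:
        for name in ("u_pfs", "u_pd"):
            rv = getattr(self, name)
            if not (0.0 <= rv.low and rv.high <= 1.0):
                raise ValidationError(f"{name} range must lie within [0, 1]")


@dataclass(frozen=True)
class CostInputs:
    """Unit costs (USD) and the payer's coverage rule.

    ``price_basis`` resolves the ambiguity of the published apatinib charge:
    ``per_day`` reads ``apatinib_unit_cost`` as the charge for the full
    850 mg daily dose (the default; it reproduces the published base-case
    totals), ``per_unit`` reads it per 425 mg unit so the daily charge is
    ``(daily_dose_mg / unit_strength_mg) * apatinib_unit_cost``.
    """

    apatinib_unit_cost: RangedValue = RangedValue(106.5, 53.2, 106.5)
    supportive_care_per_cycle: RangedValue = RangedValue(117.1, 32.3, 322.6)
    end_of_life_palliative: RangedValue = RangedValue(1483.9, 1072.3, 2119.3)
    coverage_fraction: RangedValue = RangedValue(0.60, 0.45, 0.75)
    daily_dose_mg: float = 850.0
    unit_strength_mg: float = 425.0
    price_basis: Literal["per_day", "per_unit"] = "per_day"
    pfs_supportive_with_drug: bool = False

    def __post_init__(self) -> None:
        for name in (
            "apatinib_unit_cost",
            "supportive_care_per_cycle",
            "end_of_life_palliative",
        ):
            if getattr(self, name).low < 0:
                raise ValidationError(f"{name} must be non-negative")
        cov = self.coverage_fraction
        if not (0.0 <= cov.low and cov.high <= 1.0):
            raise ValidationError("coverage_fraction range must lie within [0, 1]")
        if self.daily_dose_mg <= 0 or self.unit_strength_mg <= 0:
            raise ValidationError("doses must be positive")
        ratio = self.daily_dose_mg / self.unit_strength_mg
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                "daily_dose_mg must be a whole multiple of unit_strength_mg"
            )
        if self.price_basis not in ("per_day", "per_unit"):
            raise ValidationError(f"unknown price_basis '{self.price_basis}'")

    def daily_drug_charge(self, unit_cost: float | None = None) -> float:
        """Full (pre-coverage) apatinib charge per day of treatment."""
        c = self.apatinib_unit_cost.value if unit_cost is None else unit_cost
        if self.price_basis == "per_unit":
            return c * self.daily_dose_mg / self.unit_strength_mg
        return c


PapVariant = Literal["none", "1+X", "2+X", "3+X"]

_PAP_PAID_MONTHS = {"none": 0, "1+X": 1, "2+X": 2, "3+X": 3}


@dataclass(frozen=True)
class PapPolicy:
    """Patient assistance programme: drug is paid for ``paid_months`` then free.

    Under "3+X" patients (and hence the payer, for its coverage share) pay
    for the first three months of apatinib and receive it free thereafter
    until progression.
    """

    enabled: bool = True
    variant: PapVariant = "3+X"
    paid_months: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in _PAP_PAID_MONTHS:
            raise ValidationError(f"unknown PAP variant '{self.variant}'")
        if self.paid_months is None:
            object.__setattr__(self, "paid_months", float(_PAP_PAID_MONTHS[self.variant]))
        if self.paid_months < 0:
            raise ValidationError("paid_months must be non-negative")

    def paid_cycles(self, config: ModelConfig) -> int:
        """Paid duration in whole cycles (3 months -> 13 weekly cycles)."""
        cycles = self.paid_months * config.cycles_per_year() / MONTHS_PER_YEAR
        return int(round(cycles))


@dataclass(frozen=True)
class BudgetInputs:
    """Demographic funnel for the budget-impact projection.

    Eligible patients per fiscal year = population x incidence x fraction
    with advanced disease x fraction reaching third-line therapy x uptake.
    """

    population: float = 1_000_000.0
    annual_incident_gc_per_million: float = 215.5
    fraction_advanced: float = 2.0 / 3.0
    fraction_reaching_third_line: float = 0.7
    uptake_by_year: tuple = (0.8, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError("population must be positive")
        if self.annual_incident_gc_per_million < 0:
            raise ValidationError("incidence must be non-negative")
        for name in ("fraction_advanced", "fraction_reaching_third_line"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if len(self.uptake_by_year) != 5:
            raise ValidationError("uptake_by_year must list 5 fiscal years")
        if any(not 0.0 <= u <= 1.0 for u in self.uptake_by_year):
            raise ValidationError("uptake fractions must lie in [0, 1]")
        object.__setattr__(self, "uptake_by_year", tuple(float(u) for u in self.uptake_by_year))


@dataclass(frozen=True)
class ModelInputs:
    """The complete, validated parameter set of the analysis."""

    config: ModelConfig = field(default_factory=ModelConfig)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    costs: CostInputs = field(default_factory=CostInputs)
    pap: PapPolicy = field(default_factory=PapPolicy)
    control_pfs: WeibullCurve = WeibullCurve(scale=0.04191, shape=1.4165)
    control_os: WeibullCurve = WeibullCurve(scale=0.02143, shape=1.18716)
    hr_pfs: HazardRatioEstimate = HazardRatioEstimate(0.34, 0.27, 0.595)
    hr_os: HazardRatioEstimate = HazardRatioEstimate(0.57, 0.537, 0.937)
    budget: BudgetInputs = field(default_factory=BudgetInputs)

    def with_pap_variant(self, variant: PapVariant) -> "ModelInputs":
        return replace(
            self, pap=PapPolicy(enabled=variant != "none", variant=variant)
        )


def default_inputs() -> ModelInputs:
    """The packaged base case (equivalent to loading ``data/base_case.yaml``)."""
    return load_inputs(None)


def _load_hr(node: dict, where: str) -> HazardRatioEstimate:
    return HazardRatioEstimate(
        hr=float(_require(node, "hr", where)),
        ci_low=float(_require(node, "ci_low", where)),
        ci_high=float(_require(node, "ci_high", where)),
        log_hr_se=float(node["log_hr_se"]) if "log_hr_se" in node else None,
    )


def load_inputs(path: str | Path | None = None) -> ModelInputs:
    """Load and validate a full parameter set from a YAML config file.

    With ``path=None`` the packaged base-case configuration is used.
    Raises :class:`SchemaError` for missing fields and
    :class:`ValidationError` for out-of-range values.
    """
    if path is None:
        text = (
            resources.files("mgc_cea").joinpath("data/base_case.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError("config file must contain a YAML mapping")
    if doc.get("schema") != SCHEMA_VERSION:
        raise SchemaError(f"config must declare 'schema: {SCHEMA_VERSION}'")

    cfg_node = _require(doc, "config", "top level")
    config = ModelConfig(
        cycle_length=float(_require(cfg_node, "cycle_length", "config")),
        cycle_unit=str(cfg_node.get("cycle_unit", "week")),
        horizon_years=float(_require(cfg_node, "horizon_years", "config")),
        annual_discount_rate=float(_require(cfg_node, "annual_discount_rate", "config")),
        wtp_threshold=float(_require(cfg_node, "wtp_threshold", "config")),
        currency_year=int(cfg_node.get("currency_year", 2015)),
    )

    surv = _require(doc, "survival", "top level")
    pfs_node = _require(surv, "control_pfs", "survival")
    os_node = _require(surv, "control_os", "survival")
    control_pfs = WeibullCurve(
        scale=float(_require(pfs_node, "scale", "survival.control_pfs")),
        shape=float(_require(pfs_node, "shape", "survival.control_pfs")),
    )
    control_os = WeibullCurve(
        scale=float(_require(os_node, "scale", "survival.control_os")),
        shape=float(_require(os_node, "shape", "survival.control_os")),
    )
    hr_pfs = _load_hr(_require(surv, "hr_pfs", "survival"), "survival.hr_pfs")
    hr_os = _load_hr(_require(surv, "hr_os", "survival"), "survival.hr_os")

    cost_node = _require(doc, "costs", "top level")
    costs = CostInputs(
        apatinib_unit_cost=_ranged(cost_node, "apatinib_unit_cost", "costs"),
        supportive_care_per_cycle=_ranged(cost_node, "supportive_care_per_cycle", "costs"),
        end_of_life_palliative=_ranged(cost_node, "end_of_life_palliative", "costs"),
        coverage_fraction=_ranged(cost_node, "coverage_fraction", "costs"),
        daily_dose_mg=float(cost_node.get("daily_dose_mg", 850.0)),
        unit_strength_mg=float(cost_node.get("unit_strength_mg", 425.0)),
        price_basis=str(cost_node.get("price_basis", "per_day")),
        pfs_supportive_with_drug=bool(cost_node.get("pfs_supportive_with_drug", False)),
    )

    util_node = _require(doc, "utilities", "top level")
    utilities = UtilityInputs(
        u_pfs=_ranged(util_node, "u_pfs", "utilities"),
        u_pd=_ranged(util_node, "u_pd", "utilities"),
    )

    pap_node = doc.get("pap", {})
    pap = PapPolicy(
        enabled=bool(pap_node.get("enabled", True)),
        variant=str(pap_node.get("variant", "3+X")),
        paid_months=float(pap_node["paid_months"]) if "paid_months" in pap_node else None,
    )

    bud_node = doc.get("budget", {})
    budget = BudgetInputs(
        population=float(bud_node.get("population", 1_000_000)),
        annual_incident_gc_per_million=float(
            bud_node.get("annual_incident_gc_per_million", 215.5)
        ),
        fraction_advanced=float(bud_node.get("fraction_advanced", 2.0 / 3.0)),
        fraction_reaching_third_line=float(
            bud_node.get("fraction_reaching_third_line", 0.7)
        ),
        uptake_by_year=tuple(bud_node.get("uptake_by_year", (0.8, 1, 1, 1, 1))),
    )

    return ModelInputs(
        config=config,
        utilities=utilities,
        costs=costs,
        pap=pap,
        control_pfs=control_pfs,
        control_os=control_os,
        hr_pfs=hr_pfs,
        hr_os=hr_os,
        budget=budget,
    )


def dump_inputs(inputs: ModelInputs, path: str | Path) -> None:
    """Write a ModelInputs back to YAML (round-trips through load_inputs)."""

    def rv(x: RangedValue) -> dict:
        return {"value": x.value, "low": x.low, "high": x.high}

    doc = {
        "schema": SCHEMA_VERSION,
        "config": {
            "cycle_length": inputs.config.cycle_length,
            "cycle_unit": inputs.config.cycle_unit,
            "horizon_years": inputs.config.horizon_years,
            "annual_discount_rate": inputs.config.annual_discount_rate,
            "wtp_threshold": inputs.config.wtp_threshold,
            "currency_year": inputs.config.currency_year,
        },
        "survival": {
            "control_pfs": {"scale": inputs.control_pfs.scale, "shape": inputs.control_pfs.shape},
            "control_os": {"scale": inputs.control_os.scale, "shape": inputs.control_os.shape},
            "hr_pfs": {
                "hr": inputs.hr_pfs.hr,
                "ci_low": inputs.hr_pfs.ci_low,
                "ci_high": inputs.hr_pfs.ci_high,
                "log_hr_se": inputs.hr_pfs.log_hr_se,
            },
            "hr_os": {
                "hr": inputs.hr_os.hr,
                "ci_low": inputs.hr_os.ci_low,
                "ci_high": inputs.hr_os.ci_high,
                "log_hr_se": inputs.hr_os.log_hr_se,
            },
        },
        "costs": {
            "apatinib_unit_cost": rv(inputs.costs.apatinib_unit_cost),
            "supportive_care_per_cycle": rv(inputs.costs.supportive_care_per_cycle),
            "end_of_life_palliative": rv(inputs.costs.end_of_life_palliative),
            "coverage_fraction": rv(inputs.costs.coverage_fraction),
            "daily_dose_mg": inputs.costs.daily_dose_mg,
            "unit_strength_mg": inputs.costs.unit_strength_mg,
            "price_basis": inputs.costs.price_basis,
            "pfs_supportive_with_drug": inputs.costs.pfs_supportive_with_drug,
        },
        "utilities": {"u_pfs": rv(inputs.utilities.u_pfs), "u_pd": rv(inputs.utilities.u_pd)},
        "pap": {
            "enabled": inputs.pap.enabled,
            "variant": inputs.pap.variant,
            "paid_months": inputs.pap.paid_months,
        },
        "budget": {
            "population": inputs.budget.population,
            "annual_incident_gc_per_million": inputs.budget.annual_incident_gc_per_million,
            "fraction_advanced": inputs.budget.fraction_advanced,
            "fraction_reaching_third_line": inputs.budget.fraction_reaching_third_line,
            "uptake_by_year": list(inputs.budget.uptake_by_year),
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
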