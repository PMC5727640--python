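"""Budget-impact projection of listing apatinib with patient assistance.

Projects the payer's incremental expenditure over five fiscal years for a
defined population.  Each fiscal year's eligible-patient count is a simple
demographic funnel (population x gastric-cancer incidence x fraction with
advanced disease x fraction reaching third-line therapy x uptake), and each
eligible patient contributes the per-patient incremental payer cost of the
apatinib-with-PAP strategy over supportive care, taken from the cohort
engine.  Budget streams are conventionally undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import run_strategy
from .parameters import BudgetInputs, ModelInputs

__all__ = ["BudgetInputs", "BudgetResult", "project_budget"]


@dataclass(frozen=True)
class BudgetResult:
    """Per-fiscal-year treated patients and incremental expenditure (USD)."""

    fiscal_years: tuple
    patients: tuple
    incremental_expenditure: tuple
    per_patient_incremental_cost: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fiscal_year": self.fiscal_years,
                "patients": self.patients,
                "incremental_expenditure_usd": self.incremental_expenditure,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def eligible_patients(budget: BudgetInputs, uptake: float) -> float:
    """Eligible third-line patients in one fiscal year at the given uptake."""
    return (
        budget.population
        / 1_000_000.0
        * budget.annual_incident_gc_per_million
        * budget.fraction_advanced
        * budget.fraction_reaching_third_line
        * uptake
    )


def project_budget(
    inputs: ModelInputs,
    first_fiscal_year: int = 2016,
    per_patient_cost: float | None = None,
) -> BudgetResult:
    """Five-year incremental expenditure of covering apatinib with PAP.

    ``per_patient_cost`` defaults to the cohort model's incremental
    discounted payer cost of the apatinib-with-PAP strategy versus control
    under the same inputs.
    """
    if per_patient_cost is None:
        control = run_strategy(inputs, "control")
        pap = run_strategy(inputs, "apatinib_pap")
        per_patient_cost = pap.total_cost - control.total_cost
    years, counts, spend = [], [], []
    for offset, uptake in enumerate(inputs.budget.uptake_by_year):
        n = eligible_patients(inputs.budget, uptake)
        years.append(first_fiscal_year + offset)
        counts.append(n)
        spend.append(n * per_patient_cost)
    return BudgetResult(
        fiscal_years=tuple(years),
        patients=tuple(counts),
        incremental_expenditure=tuple(spend),
        per_patient_incremental_cost=float(per_patient_cost),
    )
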