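"""Five-year budget impact of covering apatinib with 3+X assistance.

Projects the incremental payer expenditure for a one-million-person region:
eligible third-line patients per fiscal year times the per-patient
incremental cost from the cohort model.
"""

from mgc_cea import load_inputs, project_budget

result = project_budget(load_inputs())
print(f"per-patient incremental payer cost: ${result.per_patient_incremental_cost:,.0f}")
for year, n, spend in zip(
    result.fiscal_years, result.patients, result.incremental_expenditure
):
    print(f"  {year}: {n:6.1f} patients -> ${spend / 1e6:.2f}M")

print(
    "\nSpending rises with first-year uptake and then stays constant once "
    "uptake plateaus, in the $0.3-0.5M per year range for a million-person "
    "region."
)
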