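# Methods

`mgc_cea` models the cost-effectiveness, from a health-insurance (payer)
perspective, of adding the oral VEGFR-2 inhibitor apatinib as a third-line
treatment for chemotherapy-refractory metastatic gastric cancer (mGC),
against best supportive care. This note records the model, its
assumptions, the numerical conventions, and the choices made where the
published description leaves the design open.

## Model structure

The clinical course is represented by three mutually exclusive health
states — progression-free (PFS), progressed (PD), dead — on a weekly cycle
over a 10-year horizon (520 cycles; a model year is exactly 52 weeks).
Occupancy is *partitioned-survival*: at cycle time `t`,

```
pfs(t)  = S_pfs(t)
dead(t) = 1 − S_os(t)
pd(t)   = max(0, S_os(t) − S_pfs(t))
```

where `S_pfs` and `S_os` are Weibull survival functions
`S(t) = exp(−λ t^γ)` with time in weeks. Although the source analysis
labels itself a Markov model, only the two survival curves are supplied, so
reading state membership directly off the curves (the standard
partitioned-survival construction) is the only reproducible reading; it
needs no transition matrix and cannot leak probability (occupancies sum to
one by construction). The clamp on `pd` prevents a negative progressed
fraction when extreme sensitivity values push the PFS curve above the OS
curve; when it binds the event is logged, per-draw magnitudes are carried
on the trace, and the probabilistic analysis reports one aggregate warning.

The treatment effect enters through proportional hazards:
`S_active(t) = S_ref(t)^HR`, which for a Weibull multiplies the scale by
the hazard ratio and preserves the shape. The base-case curves are the
control arm's (PFS: λ=0.04191, γ=1.4165; OS: λ=0.02143, γ=1.18716) and the
apatinib arm applies pooled hazard ratios HR_PFS=0.34 and HR_OS=0.57.

### Accrual and discounting

State membership is evaluated at cycle start and held for one cycle; no
half-cycle correction is applied. Costs and QALYs are discounted at 5%
per year, compounded per cycle as `(1+r)^(−k/52)`. Life-years are reported
undiscounted, the convention of the outcome table this model reproduces
(its LY rows match the undiscounted cycle-start sums to the third decimal,
while its QALYs match the discounted sums); `life_years()` exposes a
`discounted=` switch for the other convention.

A consequence of cycle-start accrual worth stating plainly: a
left-endpoint sum of a decreasing survival function exceeds its integral by
up to half a cycle of total variation. For the control OS curve that bias
is ≈0.5 weeks on a ≈24-week restricted mean, i.e. ≈2% — visible when
comparing the zero-discount life-years against an independent quadrature of
the Weibull. The bias is kept because the published outcome values are
themselves cycle-start sums (e.g. disease-free LY 0.173 equals the
cycle-start sum 0.1739, not the integral 0.164); the unit tests assert the
honest sandwich bound (integral ≤ accrual ≤ integral + one cycle) rather
than exact agreement.

## Survival-curve fitting and hazard-ratio pooling

`fit_weibull` fits Kaplan–Meier points by unweighted least squares on the
complementary-log-log transform, `ln(−ln S) = ln λ + γ ln t`: the slope is
the shape, the intercept the log-scale, and the regression R² is the
goodness diagnostic (the published fits report r²=0.972/0.989 on this kind
of scale). Points with S exactly 1 or 0 carry no information on this
transform and are dropped with a warning; fewer than two usable distinct
times is an error. Maximum-likelihood fitting of the raw times is
deliberately out of scope — the fitting target is digitised curve points,
not individual patient data.

`pool_hazard_ratios` is fixed-effect inverse-variance pooling on ln(HR)
with weights 1/SE². SEs default to the CI-derived
`(ln hi − ln lo)/(2·1.96)` under normal ln(HR); an explicit SE overrides
this, which matters because the published intervals are not centred on
their point estimates (0.34 in 0.27–0.595; 0.57 in 0.537–0.937, the latter
labelled "96%" — treated as a typo). The base case uses the point
estimates verbatim; the intervals feed only the sensitivity dispersions.

## Costing

All charges are full (gross) amounts; the payer pays
`coverage_fraction = 0.60` of every charge (critical-illness insurance
covering 60% of medical expenditure). Per cycle:

- **PFS state, control arm**: supportive care, $117.1/cycle.
- **PFS state, apatinib arms**: drug charge only (the
  `pfs_supportive_with_drug` flag adds supportive care alongside the drug;
  default off, the reading consistent with the published totals).
- **PD state, all arms**: supportive care $117.1/cycle.
- **Death**: one-time end-of-life palliative charge $1,483.9 at the cycle
  of incident death, booked to the death component.

**Drug price basis.** The price list gives "$106.5 per 425 mg" with an 850
mg/day dose, but the published totals are only reproducible if $106.5 is
the charge for the full daily dose; the literal two-units-per-day reading
doubles the drug cost and overshoots the published incremental cost by
~2×. The default is therefore `price_basis: per_day` (weekly drug charge
7 × 106.5 = $745.5); `per_unit` implements the literal reading
(7 × 2 × 106.5). Under `per_day` the model reproduces the published
totals within 4–10%.

**Patient assistance programme (PAP).** Under "3+X", drug is charged for
the first 3 months (13 weekly cycles) and free thereafter until
progression; "1+X"/"2+X" variants round 52/12 weeks-per-month to whole
cycles (4 and 9). The payer subsidises its coverage share of the paid
window only.

## Sensitivity analyses

**One-way (tornado).** Each parameter is set to its low and high bound
with everything else at base, and the ICER recomputed; entries sort by
descending span (alphabetical tie-break). Cost and utility bounds come
from the declared ranges; hazard ratios use their CIs; the coverage
fraction, which has no published range, uses ±25% of base (0.45–0.75), the
convention stated for unranged parameters. Under these inputs the large
spans belong to HR_OS, the drug price, coverage and HR_PFS (10–15 k$/QALY);
the utilities' printed ranges are too narrow to move the ICER by more than
~3.6 k$/QALY, and the end-of-life cost is negligible because it accrues
almost fully in both arms.

**Probabilistic (PSA).** 1000 joint, independent draws by default:
triangular (low, mode=base, high) for the three unit costs; beta for the
two utilities and the coverage proportion, method-of-moments with mean =
base and SD = range/4 (a parameter whose moment-matched beta is infeasible
is held fixed and logged); lognormal for the hazard ratios with the
CI-derived SE of ln(HR). Every draw reruns the full cohort model per
strategy; results are bit-reproducible under a fixed seed
(`numpy.random.default_rng`). The CEAC reports, per threshold on a
0–60,000 (step 1,000) $/QALY grid, the fraction of draws in which the
alternative's net monetary benefit (`wtp × QALYs − cost`) exceeds the
reference's.

A caution on the PSA's location: the drug-price triangle implied by the
printed range (53.2–106.5 with mode at 106.5) has mean $88.7 — 17% below
the base price — and the supportive-care triangle is skewed the other way;
both skews favour the apatinib-with-PAP strategy. With these prescribed
families the probability of cost-effectiveness at $22,200/QALY computes to
≈0.78–0.80 (and ≈0.06 for full price), where the source analysis reports
≈0.65 (and ≈0). The source's near-zero full-price probability is itself
inconsistent with sampling half-price draws from that triangle, suggesting
its PSA used narrower drug-price dispersion than its one-way range; no
such narrower range is published, so none is substituted here.

## Budget impact

Undiscounted, five fiscal years, for a configurable population (default
one million): eligible patients per year = population × incidence
(215.5 per million per year, reading the printed "21.55 per 1,000,000" as
per-100,000 in line with the companion statement of ~215 per million) ×
fraction advanced (2/3) × fraction reaching third-line therapy × uptake.
The per-patient incremental payer cost is taken from the cohort model
(apatinib 3+X vs control, ≈$4,440). The third-line fraction (0.7) and
uptake schedule (0.8 in year 1, then 1.0) are not published; the defaults
are a plausible oncology-adoption funnel chosen once, and they place the
projection in the $0.36M/$0.45M (year 1 / plateau) range, within the
$0.34–0.45M spread of the published figures. Spending is constant once
uptake plateaus because the eligible pool is incidence-driven.

## Synthetic data

No trial data are deposited, so the generator supplies statistically
equivalent inputs for the fitting and pooling steps: Weibull event times by
inverse transform with independent exponential censoring; the
product-limit estimator (via `lifelines`) read on a 2-week grid truncated
at the 95th percentile of observed times, mimicking digitised points while
avoiding the unstable tail; and per-trial ln(HR) draws around the true
value with SE `sqrt(1/d₁ + 1/d₂)`. What this does *not* emulate: real KM
curves are read with digitisation error and correlated step heights, real
trials differ in follow-up and risk-set structure, and censoring in trials
is rarely exponential. Passing recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions, not
robustness to those real-data features.

## Numerical conventions and degenerate inputs

- Year = 52 weeks exactly; 3 months = 13 weekly cycles; 10 years = 520
  cycles. Monthly cycles use 12 per year.
- Trace conservation holds to 1e-9; cost components are non-negative and
  sum to the total within 1e-6.
- `fit_weibull` with exactly two points returns a saturated fit (r²=1,
  SEs undefined as NaN).
- ICERs are reported only when cost and effect deltas point the same way;
  otherwise a dominance tag (`dominant`/`dominated`/`equivalent`) is set
  and no negative ratio is ever printed.
- Degenerate PSA distributions (point masses) reproduce the base case
  exactly; a zero-width beta range falls back to a fixed parameter with a
  logged warning.
- Currency values carry a `currency_year` label (2015 USD); no inflation
  adjustment is performed anywhere.

## Known limitations

- The cost side inherits the source's ambiguities (drug price basis,
  internally inconsistent per-state cost rows); per-state cost components
  should be read as this model's convention, not as a reproduction.
- Adverse-event costs and disutilities are excluded by design.
- PSA parameters are sampled independently; no correlation structure.
- Extrapolation rests entirely on the Weibull family; alternative
  parametric families and spline extrapolation are out of scope.
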