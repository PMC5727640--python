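"""Recovering Weibull survival parameters from Kaplan-Meier points.

Simulates a 500-patient cohort from the control-arm overall-survival curve
with light censoring, evaluates the product-limit estimator on a 2-week
reading grid (mimicking points read off a published figure), and refits the
Weibull by complementary-log-log regression.
"""

from mgc_cea import WeibullCurve, fit_weibull, km_estimate, simulate_cohort

truth = WeibullCurve(scale=0.02143, shape=1.18716)  # control-arm OS
cohort = simulate_cohort(truth, n=500, censor_hazard=0.01, seed=7)
points = km_estimate(cohort)
fit = fit_weibull(points)

print(f"events: {int(cohort.events.sum())}/{cohort.n}, KM points: {len(points.times)}")
print(f"true curve:   scale={truth.scale:.5f} shape={truth.shape:.5f}")
print(
    f"fitted curve: scale={fit.curve.scale:.5f} shape={fit.curve.shape:.5f} "
    f"(r2={fit.r_squared:.3f})"
)
print(f"median survival: true {truth.median():.1f} wk, fitted {fit.curve.median():.1f} wk")
print(
    "\nThe fitted parameters sit within a few percent of the generating ones; "
    "r2 near 1 reflects the near-linearity of ln(-ln S) in ln t for Weibull data."
)
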