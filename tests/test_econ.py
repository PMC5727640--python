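"""ICERs, net monetary benefit, tornado, PSA and CEAC behaviour."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mgc_cea import (
    ceac,
    compute_icer,
    net_monetary_benefit,
    one_way_sensitivity,
    run_psa,
)
from mgc_cea.econ import (
    ParameterDistribution,
    beta_from_moments,
    default_psa_distributions,
)
from mgc_cea.parameters import RangedValue


class TestIcer:
    def test_base_case_icer_matches_published_value(self, base_summaries):
        res = compute_icer(base_summaries["control"], base_summaries["apatinib_no_pap"])
        assert res.dominance is None
        assert res.icer == pytest.approx(40997, rel=0.15)

    def test_identical_summaries_are_equivalent(self, base_summaries):
        res = compute_icer(base_summaries["control"], base_summaries["control"])
        assert res.dominance == "equivalent"
        assert res.icer is None

    def test_cheaper_and_better_is_dominant(self, base_summaries):
        control = base_summaries["control"]
        alt = base_summaries["apatinib_pap"]
        cheaper = replace(
            alt, costs=replace(alt.costs, cost_pfs_state=0.0, cost_pd_state=0.0, cost_death=0.0)
        )
        assert compute_icer(control, cheaper).dominance == "dominant"
        # and the reverse comparison is dominated
        assert compute_icer(cheaper, control).dominance == "dominated"

    def test_life_year_variant(self, base_summaries):
        res = compute_icer(
            base_summaries["control"], base_summaries["apatinib_no_pap"], effect="ly"
        )
        assert res.effect_units == "LY"
        assert res.icer == pytest.approx(
            res.delta_cost / res.delta_effect, rel=1e-12
        )


class TestNetMonetaryBenefit:
    def test_zero_threshold_is_negative_cost(self, base_summaries):
        s = base_summaries["control"]
        assert net_monetary_benefit(s, 0.0) == -s.total_cost

    def test_qaly_term_scales_linearly(self, base_summaries):
        s = base_summaries["apatinib_pap"]
        n1 = net_monetary_benefit(s, 10000.0)
        n2 = net_monetary_benefit(s, 20000.0)
        assert n2 - n1 == pytest.approx(10000.0 * s.qalys, rel=1e-12)

    @pytest.mark.parametrize("wtp", [5000.0, 22200.0, 40000.0, 60000.0])
    def test_incremental_nmb_sign_agrees_with_icer_threshold(self, base_summaries, wtp):
        """dNMB > 0 exactly when the ICER falls below the threshold (dE > 0)."""
        ref, alt = base_summaries["control"], base_summaries["apatinib_pap"]
        res = compute_icer(ref, alt)
        assert res.delta_effect > 0
        d_nmb = net_monetary_benefit(alt, wtp) - net_monetary_benefit(ref, wtp)
        assert (d_nmb > 0) == (res.icer < wtp)

    def test_constant_cost_shift_preserves_ranking(self, base_summaries):
        ref, alt = base_summaries["control"], base_summaries["apatinib_pap"]
        shift = 12345.0
        shifted = [
            replace(s, costs=replace(s.costs, cost_death=s.costs.cost_death + shift))
            for s in (ref, alt)
        ]
        before = net_monetary_benefit(alt, 22200.0) - net_monetary_benefit(ref, 22200.0)
        after = net_monetary_benefit(shifted[1], 22200.0) - net_monetary_benefit(
            shifted[0], 22200.0
        )
        assert after == pytest.approx(before, abs=1e-6)


@pytest.fixture(scope="module")
def entries(base_inputs):
    return one_way_sensitivity(base_inputs, ("control", "apatinib_pap"))


@pytest.fixture(scope="module")
def psa_small(base_inputs):
    return run_psa(base_inputs, n=200, seed=42)


class TestTornado:
    def test_entries_cover_every_varied_parameter_once(self, entries):
        names = [e.parameter for e in entries]
        assert sorted(names) == sorted(
            [
                "apatinib_unit_cost",
                "supportive_care_per_cycle",
                "end_of_life_palliative",
                "coverage_fraction",
                "u_pfs",
                "u_pd",
                "hr_pfs",
                "hr_os",
            ]
        )

    def test_sorted_by_descending_span(self, entries):
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)

    def test_all_icers_finite_under_base_ranges(self, entries):
        for e in entries:
            assert math.isfinite(e.icer_at_low) and math.isfinite(e.icer_at_high)

    def test_known_influential_parameters_lead(self, entries):
        """Drug price, both hazard ratios and the insurance coverage share are
        the dominant drivers; the one-off end-of-life cost barely moves the
        ICER because it accrues in both arms."""
        names = [e.parameter for e in entries]
        top4 = set(names[:4])
        assert {"apatinib_unit_cost", "hr_os", "hr_pfs", "coverage_fraction"} == top4
        assert names[-1] == "end_of_life_palliative"

    def test_degenerate_range_has_zero_span(self, base_inputs):
        frozen = replace(
            base_inputs,
            utilities=replace(
                base_inputs.utilities, u_pd=RangedValue(0.41, 0.41, 0.41)
            ),
        )
        entries = one_way_sensitivity(frozen, ("control", "apatinib_pap"), ["u_pd"])
        assert len(entries) == 1
        assert entries[0].span == 0.0

    def test_unknown_parameter_skipped_with_warning(self, base_inputs, caplog):
        with caplog.at_level("WARNING"):
            entries = one_way_sensitivity(
                base_inputs, ("control", "apatinib_pap"), ["u_pd", "not_a_parameter"]
            )
        assert [e.parameter for e in entries] == ["u_pd"]
        assert "not_a_parameter" in caplog.text


class TestPsa:
    def test_seeded_reproducibility(self, base_inputs, psa_small):
        again = run_psa(base_inputs, n=200, seed=42)
        pd.testing.assert_frame_equal(psa_small.draws, again.draws)
        pd.testing.assert_frame_equal(
            psa_small.parameter_samples, again.parameter_samples
        )

    def test_draw_count_per_strategy(self, psa_small):
        counts = psa_small.draws.groupby("strategy").size()
        assert set(counts) == {200}
        assert psa_small.n == 200

    def test_point_mass_distributions_reproduce_base_case(
        self, base_inputs, base_summaries
    ):
        dists = [
            ParameterDistribution(d.name, "fixed", (base_val,))
            for d, base_val in zip(
                default_psa_distributions(base_inputs),
                [106.5, 117.1, 1483.9, 0.60, 0.88, 0.41, 0.34, 0.57],
            )
        ]
        psa = run_psa(base_inputs, n=5, seed=0, distributions=dists)
        for strat in ("control", "apatinib_no_pap", "apatinib_pap"):
            sub = psa.draws[psa.draws.strategy == strat]
            assert np.allclose(sub["cost"], base_summaries[strat].total_cost)
            assert np.allclose(sub["qalys"], base_summaries[strat].qalys)

    def test_sample_means_match_distribution_means(self, base_inputs):
        """At n=1000 every parameter's sample mean sits within 3 standard
        errors of its closed-form triangular/beta/lognormal mean."""
        n = 1000
        psa = run_psa(base_inputs, n=n, seed=7, strategies=("control",))
        for dist in default_psa_distributions(base_inputs):
            x = psa.parameter_samples[dist.name]
            se = x.std(ddof=1) / math.sqrt(n)
            assert abs(x.mean() - dist.mean()) < 3 * se, dist.name

    def test_beta_moment_matching(self):
        ab = beta_from_moments(0.88, (0.97 - 0.80) / 4)
        assert ab is not None
        a, b = ab
        assert a / (a + b) == pytest.approx(0.88, rel=1e-12)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(0.0425, rel=1e-6)

    def test_infeasible_beta_falls_back_to_fixed(self, caplog):
        # sd too large for the mean: no valid beta exists
        assert beta_from_moments(0.98, 0.4) is None

    def test_invalid_draw_count_rejected(self, base_inputs):
        with pytest.raises(ValueError):
            run_psa(base_inputs, n=0, seed=1)


class TestCeac:
    def test_degenerate_psa_gives_step_function_at_base_icer(
        self, base_inputs, base_summaries
    ):
        dists = [
            ParameterDistribution(d.name, "fixed", (v,))
            for d, v in zip(
                default_psa_distributions(base_inputs),
                [106.5, 117.1, 1483.9, 0.60, 0.88, 0.41, 0.34, 0.57],
            )
        ]
        psa = run_psa(base_inputs, n=10, seed=0, distributions=dists)
        base_icer = compute_icer(
            base_summaries["control"], base_summaries["apatinib_pap"]
        ).icer
        grid = [base_icer - 2000, base_icer - 1, base_icer + 1, base_icer + 2000]
        curve = ceac(psa, grid, ("control", "apatinib_pap"))
        np.testing.assert_allclose(curve.probability, [0.0, 0.0, 1.0, 1.0], atol=1e-12)

    def test_monotone_when_alternative_always_gains_health(self, base_inputs):
        """Holding the hazard ratios fixed below one makes every draw gain
        QALYs, so the acceptability curve cannot decrease with the threshold."""
        dists = [
            d
            for d in default_psa_distributions(base_inputs)
            if d.name not in ("hr_pfs", "hr_os")
        ]
        psa = run_psa(base_inputs, n=300, seed=5, distributions=dists)
        d_eff = psa.pivot("qalys")
        assert (d_eff["apatinib_pap"] > d_eff["control"]).all()
        curve = ceac(psa, range(0, 60001, 2000), ("control", "apatinib_pap"))
        assert np.all(np.diff(curve.probability) >= -1e-12)
        assert np.all((curve.probability >= 0) & (curve.probability <= 1))

    def test_empty_grid_rejected(self, base_inputs):
        psa = run_psa(base_inputs, n=2, seed=0, strategies=("control", "apatinib_pap"))
        with pytest.raises(ValueError):
            ceac(psa, [], ("control", "apatinib_pap"))
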