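"""Adverse-event model: transition logits, IIV sampling, Markov chain."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import cavtesim as cs
from cavtesim.ae import simulate_grades_from_concentration

QUIET = cs.AEModelParameters(b01=-30.0, b11=-30.0, b21=-30.0, cv_ae=0.0, emax_scale=0.0)


class TestDrugEffect:
    def test_zero_concentration(self, typical_ae_ind):
        assert cs.drug_effect(0.0, 0, typical_ae_ind) == 0.0

    def test_half_maximal_at_ec50(self, typical_ae_ind):
        de = cs.drug_effect(typical_ae_ind.ec50, 0, typical_ae_ind)
        assert de == pytest.approx(4.73 / 2)
        de1 = cs.drug_effect(typical_ae_ind.ec50, 1, typical_ae_ind)
        assert de1 == pytest.approx(1.09 / 2)

    def test_saturates_at_emax(self, typical_ae_ind):
        assert cs.drug_effect(1e9, 0, typical_ae_ind) == pytest.approx(4.73, rel=1e-6)
        assert cs.drug_effect(1e9, 2, typical_ae_ind) == pytest.approx(1.09, rel=1e-6)

    def test_scale_multiplies(self, typical_ae_ind):
        scaled = dataclasses.replace(typical_ae_ind, emax_scale=0.5)
        assert cs.drug_effect(10.0, 0, scaled) == pytest.approx(
            0.5 * cs.drug_effect(10.0, 0, typical_ae_ind)
        )

    def test_invalid_inputs(self, typical_ae_ind):
        with pytest.raises(ValueError):
            cs.drug_effect(-1.0, 0, typical_ae_ind)
        with pytest.raises(ValueError):
            cs.drug_effect(1.0, 3, typical_ae_ind)


class TestTransitionProbabilities:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        prev=st.sampled_from([0, 1, 2]),
        de=st.floats(0.0, 12.0, allow_nan=False),
    )
    def test_valid_distribution_and_ordering(self, prev, de):
        p = cs.AEModelParameters()
        ind = cs.sample_individual_ae(
            dataclasses.replace(p, cv_ae=0.0), 1, seed=0
        )[0]
        p0, p1, p2 = cs.transition_probabilities(prev, de, ind)
        assert p0 + p1 + p2 == pytest.approx(1.0)
        assert all(0.0 <= q <= 1.0 for q in (p0, p1, p2))
        # cumulative ordering: P(>=2) <= P(>=1)
        assert p2 <= p1 + p2

    def test_baseline_grade0_rate(self, typical_ae_ind):
        p0, p1, p2 = cs.transition_probabilities(0, 0.0, typical_ae_ind)
        assert 1.0 - p0 == pytest.approx(float(expit(-6.59)), rel=1e-12)
        assert 1.0 - p0 == pytest.approx(1.372e-3, rel=1e-3)

    def test_monotone_in_drug_effect(self, typical_ae_ind):
        for prev in (0, 1, 2):
            lo = cs.transition_probabilities(prev, 0.5, typical_ae_ind)
            hi = cs.transition_probabilities(prev, 1.5, typical_ae_ind)
            assert hi[1] + hi[2] > lo[1] + lo[2]
            assert hi[2] > lo[2]

    def test_invalid_grade(self, typical_ae_ind):
        with pytest.raises(ValueError):
            cs.transition_probabilities(5, 0.0, typical_ae_ind)


class TestSampleIndividualAE:
    def test_zero_cv_identity(self):
        p = cs.AEModelParameters(cv_ae=0.0)
        for ind in cs.sample_individual_ae(p, 3, seed=1):
            assert ind.b01 == p.b01 and ind.b22 == p.b22
            assert ind.emax0 == p.emax0 and ind.ec50 == p.ec50

    def test_logit_parameter_spread(self):
        cohort = cs.sample_individual_ae(cs.AEModelParameters(), 10_000, seed=3)
        b01 = np.array([i.b01 for i in cohort])
        assert b01.std() == pytest.approx(0.659, rel=0.05)
        assert b01.mean() == pytest.approx(-6.59, abs=0.05)

    def test_positive_parameters_stay_positive(self):
        cohort = cs.sample_individual_ae(cs.AEModelParameters(), 50_000, seed=5)
        assert min(i.ec50 for i in cohort) > 0
        assert min(i.emax0 for i in cohort) > 0

    def test_substreams_stable_under_cohort_growth(self):
        small = cs.sample_individual_ae(cs.AEModelParameters(), 4, seed=9)
        large = cs.sample_individual_ae(cs.AEModelParameters(), 8, seed=9)
        assert large[:4] == small

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            cs.sample_individual_ae(cs.AEModelParameters(), 0, seed=1)


class TestSimulateHistory:
    def test_quiet_model_never_events(self, typical_ind):
        ind_ae = cs.sample_individual_ae(QUIET, 1, seed=2)[0]
        h = cs.simulate_event_history(
            typical_ind, ind_ae, cs.DosingRegimen(), 168.0, seed=4
        )
        assert np.all(h.grades == 0)
        assert cs.first_event(h) is None

    def test_reproducible_and_bounded(self, typical_ind, typical_ae_ind):
        reg = cs.DosingRegimen()
        h1 = cs.simulate_event_history(typical_ind, typical_ae_ind, reg, 168.0, seed=8)
        h2 = cs.simulate_event_history(typical_ind, typical_ae_ind, reg, 168.0, seed=8)
        assert np.array_equal(h1.grades, h2.grades)
        assert h1.assessment_times[-1] <= reg.eot
        assert h1.assessment_times.size == 16

    def test_interval_must_divide_treatment(self, typical_ind, typical_ae_ind):
        with pytest.raises(ValueError):
            cs.simulate_event_history(
                typical_ind, typical_ae_ind, cs.DosingRegimen(), 167.0, seed=1
            )

    def test_cohort_matches_per_subject_streams(self):
        n = 6
        reg = cs.DosingRegimen()
        pk = cs.sample_individual_pk(cs.PKParameters(), n, seed=21)
        ae = cs.sample_individual_ae(cs.AEModelParameters(emax_scale=1.0), n, seed=22)
        master = np.random.SeedSequence(23)
        cohort = cs.simulate_cohort_histories(pk, ae, reg, 168.0, seed=master)
        children = np.random.SeedSequence(23).spawn(n)
        for i in range(n):
            solo = cs.simulate_event_history(pk[i], ae[i], reg, 168.0, seed=children[i])
            assert np.array_equal(solo.grades, cohort[i].grades)


class TestMarkovOracle:
    def test_no_event_fraction_matches_absorption_probability(self):
        """At fixed concentration and no IIV the chain leaves grade 0 with a
        constant per-assessment hazard, so the censored fraction is
        (1 - expit(b01 + DE))^K; check 10^4 subjects within 3 SE."""
        n, k_assess, conc0 = 10_000, 16, 20.0
        params = cs.AEModelParameters(b01=-3.0, cv_ae=0.0, emax_scale=0.5)
        cohort = cs.sample_individual_ae(params, n, seed=31)
        conc = np.full((n, k_assess), conc0)
        grades = simulate_grades_from_concentration(conc, cohort, seed=32)
        frac_no_event = np.mean(grades.max(axis=1) == 0)
        de = cs.drug_effect(conc0, 0, cohort[0])
        p_event = float(expit(params.b01 + de))
        expected = (1.0 - p_event) ** k_assess
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac_no_event - expected) < 3 * se

    def test_event_count_monotone_in_emax_scale(self):
        """Common random numbers couple the chains: until the first event the
        previous grade is 0 for every scale, so the any-event indicator is
        pathwise non-decreasing in the Emax multiplier."""
        n = 300
        reg = cs.DosingRegimen()
        pk = cs.sample_individual_pk(cs.PKParameters(), n, seed=41)
        counts = []
        censored = []
        for s in (0.25, 0.5, 0.75, 1.0, 1.25, 1.5):
            ae = cs.sample_individual_ae(
                cs.AEModelParameters(emax_scale=s), n, seed=42
            )
            hists = cs.simulate_cohort_histories(pk, ae, reg, 168.0, seed=43)
            events = sum(cs.first_event(h) is not None for h in hists)
            counts.append(events)
            censored.append(n - events)
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert all(b <= a for a, b in zip(censored, censored[1:]))


class TestFirstEvent:
    def test_definition_on_weekly_grid(self):
        times = 168.0 * np.arange(1, 6)
        h = cs.EventHistory(0, times, [0, 0, 2, 1, 0])
        assert cs.first_event(h) == (3 * 168.0, 2)

    def test_censored_returns_none(self):
        h = cs.EventHistory(0, 168.0 * np.arange(1, 4), [0, 0, 0])
        assert cs.first_event(h) is None

    def test_history_validation(self):
        with pytest.raises(ValueError):
            cs.EventHistory(0, np.array([2.0, 1.0]), np.array([0, 0]))
        with pytest.raises(ValueError):
            cs.EventHistory(0, np.array([1.0, 2.0]), np.array([0, 5]))
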