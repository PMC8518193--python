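"""Compartment enumeration, probability composition, annual costs, averages."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microcoi import (
    CASE_TYPES,
    GENDERS,
    SPECIALTIES,
    TREATMENTS,
    CaseDistribution,
    Compartment,
    TreatmentChoice,
    annual_cost_per_patient,
    average_treatment_cost,
    compartment_probabilities,
    enumerate_compartments,
    generate_probability_tables,
    table2_summaries,
)
from microcoi import peru


def uniform_tables():
    cases = CaseDistribution(
        {(g, c, s): 1.0 for g in GENDERS for c in CASE_TYPES for s in SPECIALTIES}
    )
    choice = TreatmentChoice(
        table={(s,): {t: 1.0 for t in TREATMENTS} for s in SPECIALTIES},
        conditioning=("specialty",),
    )
    return cases, choice


class TestEnumeration:
    def test_exactly_180_compartments(self):
        comps = enumerate_compartments()
        assert len(comps) == 180
        assert len(set(comps)) == 180

    def test_one_gender_restriction_halves(self):
        comps = [c for c in enumerate_compartments() if c.gender == "male"]
        assert len(comps) == 90

    def test_order_is_stable(self):
        assert enumerate_compartments() == enumerate_compartments()
        assert enumerate_compartments()[0] == Compartment(
            "male", "new", "primary_care", "podophyllin"
        )


class TestProbabilities:
    def test_uniform_times_uniform_is_uniform(self):
        probs = compartment_probabilities(*uniform_tables())
        assert all(p == pytest.approx(1 / 180) for p in probs.values())

    def test_degenerate_choice_restricts_support(self):
        cases, _ = uniform_tables()
        choice = TreatmentChoice(
            table={(s,): {"podophyllin": 1.0} for s in SPECIALTIES},
            conditioning=("specialty",),
        )
        probs = compartment_probabilities(cases, choice)
        nonzero = [c for c, p in probs.items() if p > 0]
        assert len(nonzero) == 30
        assert all(c.treatment == "podophyllin" for c in nonzero)

    def test_normalised_to_one(self):
        cases, choice = generate_probability_tables(2.0, seed=4)
        probs = compartment_probabilities(cases, choice)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_marginal_over_treatments_recovers_case_distribution(self):
        cases, choice = generate_probability_tables(1.5, seed=8)
        probs = compartment_probabilities(cases, choice)
        norm = cases.normalized()
        for g in GENDERS:
            for c in CASE_TYPES:
                for s in SPECIALTIES:
                    marg = sum(
                        p for comp, p in probs.items()
                        if (comp.gender, comp.case_type, comp.specialty) == (g, c, s)
                    )
                    assert marg == pytest.approx(norm.prob(g, c, s), abs=1e-12)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            CaseDistribution({("male", "new", "urology"): -0.1})


class TestAnnualCost:
    def test_tca_new_case(self):
        c = Compartment("male", "new", "primary_care", "tca")
        cost = annual_cost_per_patient(c, {"tca": 10.84}, 6.04, peru.PROTOCOL)
        assert cost == pytest.approx(6.04 + 2.5 * 10.84)  # 33.14

    def test_surgical_excision_single_session(self):
        c = Compartment("female", "new", "urology", "surgical_excision")
        cost = annual_cost_per_patient(c, {"surgical_excision": 24.59}, 6.04, peru.PROTOCOL)
        assert cost == pytest.approx(30.63)

    def test_recurrent_scales_with_episodes(self):
        new = Compartment("male", "new", "urology", "tca")
        rec = Compartment("male", "recurrent", "urology", "tca")
        costs = {"tca": 10.84}
        per_course = annual_cost_per_patient(new, costs, 6.04, peru.PROTOCOL)
        assert annual_cost_per_patient(rec, costs, 6.04, peru.PROTOCOL) == pytest.approx(
            1.7 * per_course
        )

    def test_monotone_in_every_argument(self):
        c = Compartment("male", "new", "urology", "tca")
        base = annual_cost_per_patient(c, {"tca": 10.0}, 6.0, peru.PROTOCOL)
        assert annual_cost_per_patient(c, {"tca": 11.0}, 6.0, peru.PROTOCOL) > base
        assert annual_cost_per_patient(c, {"tca": 10.0}, 7.0, peru.PROTOCOL) > base

    def test_missing_protocol_entry(self):
        c = Compartment("male", "new", "urology", "tca")
        with pytest.raises(KeyError):
            annual_cost_per_patient(c, {"podophyllin": 1.0}, 6.0, peru.PROTOCOL)

    def test_never_below_diagnosis_cost(self, noisy_bundle):
        probs = compartment_probabilities(
            noisy_bundle.case_distribution, noisy_bundle.treatment_choice
        )
        truth = noisy_bundle.truth
        diag = truth.session_costs["diagnosis"]
        for comp in probs:
            cost = annual_cost_per_patient(
                comp,
                {t: truth.session_costs[t] for t in TREATMENTS},
                diag,
                noisy_bundle.protocol,
            )
            assert cost >= diag


class TestAverage:
    def test_midpoint(self):
        comps = enumerate_compartments()[:2]
        probs = {comps[0]: 0.5, comps[1]: 0.5}
        costs = {comps[0]: 40.0, comps[1]: 80.0}
        assert average_treatment_cost(probs, costs) == pytest.approx(60.0)

    def test_degenerate_mass(self):
        comps = enumerate_compartments()[:2]
        probs = {comps[0]: 1.0, comps[1]: 0.0}
        costs = {comps[0]: 42.0, comps[1]: 99.0}
        assert average_treatment_cost(probs, costs) == pytest.approx(42.0)

    def test_zero_mass_rejected(self):
        comps = enumerate_compartments()[:1]
        with pytest.raises(ValueError, match="zero probability mass"):
            average_treatment_cost({comps[0]: 0.0}, {comps[0]: 1.0})

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_by_extremes_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        comps = enumerate_compartments()
        p = rng.dirichlet(np.ones(len(comps)))
        costs_arr = rng.uniform(1, 100, len(comps))
        probs = dict(zip(comps, p))
        costs = dict(zip(comps, costs_arr))
        avg = average_treatment_cost(probs, costs)
        assert costs_arr.min() - 1e-9 <= avg <= costs_arr.max() + 1e-9
        perm = rng.permutation(len(comps))
        probs2 = {comps[i]: p[i] for i in perm}
        costs2 = {comps[i]: costs_arr[i] for i in perm}
        assert average_treatment_cost(probs2, costs2) == pytest.approx(avg)


class TestTable2:
    def test_uniform_usage(self):
        probs = compartment_probabilities(*uniform_tables())
        costs = {c: 10.0 for c in probs}
        t2 = table2_summaries(probs, costs, peru.PROTOCOL)
        assert np.allclose(t2["usage_probability"], 1 / 6)

    def test_fixture_usage_matches_published(self, fixture_bundle):
        probs = compartment_probabilities(
            fixture_bundle.case_distribution, fixture_bundle.treatment_choice
        )
        costs = {c: 10.0 for c in probs}
        t2 = table2_summaries(probs, costs, fixture_bundle.protocol)
        total = sum(peru.USAGE_PROBABILITIES.values())  # printed column: 99.9%
        for t, printed in peru.USAGE_PROBABILITIES.items():
            assert t2.loc[t, "usage_probability"] == pytest.approx(
                printed / total, abs=1e-9
            )

    def test_usage_probabilities_sum_to_one(self, noisy_bundle):
        probs = compartment_probabilities(
            noisy_bundle.case_distribution, noisy_bundle.treatment_choice
        )
        costs = {c: 1.0 for c in probs}
        t2 = table2_summaries(probs, costs, noisy_bundle.protocol)
        assert t2["usage_probability"].sum() == pytest.approx(1.0)
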