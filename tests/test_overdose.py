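"""Overdose hazard, the bystander tree, and its analytic oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thnsim import (BystanderParams, OverdoseEvent, PopulationParams,
                    RiskParams, analytic_death_probability, build_population,
                    daily_overdose_probability, draw_overdoses, relative_risk,
                    resolve_overdose)
from thnsim.overdose import resolve_events
from thnsim.population import Person
from thnsim.rng import GeneratorSource


def _person(use_type="NIOU", sex="male", age="18-24", dsr=None):
    return Person(pid=0, use_type=use_type, sex=sex, age_group=age, cli=False,
                  in_jail=False, release_day=None, days_since_release=dsr,
                  has_kit=False, peer_kit=False, alive=True)


def enumerate_death_probability(availability, bp, rp):
    """Independent brute-force oracle: enumerate all 2^3 bystander branches."""
    p_adm = bp.p_administer if availability else 0.0
    total = 0.0
    for by, adm, ems in itertools.product([0, 1], repeat=3):
        pr = (bp.p_bystander if by else 1 - bp.p_bystander)
        pr *= (p_adm if adm else 1 - p_adm) if by else (0.0 if adm else 1.0)
        pr *= (bp.p_ems if ems else 1 - bp.p_ems) if by else (0.0 if ems else 1.0)
        if adm:
            m = 1 - bp.eff_naloxone
        elif ems:
            m = 1 - bp.eff_ems
        else:
            m = 1.0
        total += pr * rp.f_fatal * m
    return total


class TestRelativeRisk:
    def test_all_reference_categories_give_unity(self):
        assert relative_risk(_person(), RiskParams()) == 1.0

    def test_direct_product(self):
        rp = RiskParams(rr_female=0.8, rr_iou=3.0, rr_release_wk0_2=6.0,
                        rr_age_30plus=2.0)
        p = _person(use_type="IOU", sex="female", age=">=30", dsr=5)
        assert relative_risk(p, rp) == pytest.approx(0.8 * 3 * 6 * 2)  # 28.8

    def test_published_upper_bound_product(self):
        rp = RiskParams(rr_female=1.41, rr_iou=9.0, rr_release_wk0_2=10.0,
                        rr_age_30plus=5.15)
        p = _person(use_type="IOU", sex="female", age=">=30", dsr=0)
        assert relative_risk(p, rp) == pytest.approx(653.535, abs=0.01)

    @pytest.mark.parametrize("dsr,field", [
        (0, "rr_release_wk0_2"), (13, "rr_release_wk0_2"),
        (14, "rr_release_wk3_4"), (27, "rr_release_wk3_4"),
        (28, "rr_release_wk5plus"), (400, "rr_release_wk5plus"),
    ])
    def test_release_window_boundaries(self, dsr, field):
        rp = RiskParams()
        assert relative_risk(_person(dsr=dsr), rp) == getattr(rp, field)

    def test_non_user_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            relative_risk(_person(use_type="NONE"), RiskParams())


class TestDailyProbability:
    def test_reference_person_gets_baseline(self):
        rp = RiskParams(p0_daily_od=3.3e-4)
        assert daily_overdose_probability(_person(), rp) == pytest.approx(3.3e-4)

    def test_multiplication(self):
        rp = RiskParams(p0_daily_od=3.3e-4, rr_female=0.8, rr_iou=3.0,
                        rr_release_wk0_2=6.0, rr_age_30plus=2.0)
        p = _person(use_type="IOU", sex="female", age=">=30", dsr=5)
        assert daily_overdose_probability(p, rp) == pytest.approx(9.504e-3)

    def test_clamped_at_one(self):
        rp = RiskParams(p0_daily_od=0.9, rr_iou=9.0)
        assert daily_overdose_probability(_person(use_type="IOU"), rp) == 1.0


class TestBystanderTree:
    def test_frozen_enumeration_value(self):
        """The worked tree example: f=0.10, p_by=0.6, kit available,
        p_adm=0.7, p_ems=0.5, eff_nx=0.95, eff_ems=0.5 ->
        0.10 x (0.4 + 0.6 x (0.7x0.05 + 0.3x(0.5x0.5 + 0.5))) = 0.05560."""
        bp = BystanderParams(p_bystander=0.6, p_administer=0.7, p_ems=0.5,
                             eff_naloxone=0.95, eff_ems=0.5)
        rp = RiskParams(f_fatal=0.10)
        assert enumerate_death_probability(True, bp, rp) == pytest.approx(0.05560)
        assert analytic_death_probability(True, bp, rp) == pytest.approx(0.05560)

    def test_unwitnessed_event_is_plain_fatality(self):
        bp = BystanderParams(p_bystander=0.0)
        rp = RiskParams(f_fatal=0.11)
        assert analytic_death_probability(True, bp, rp) == pytest.approx(0.11)

    def test_perfect_reversal(self):
        bp = BystanderParams(p_bystander=1.0, p_administer=1.0, eff_naloxone=1.0)
        assert analytic_death_probability(True, bp, RiskParams()) == 0.0

    def test_no_availability_is_independent_of_p_administer(self):
        rp = RiskParams()
        a = analytic_death_probability(False, BystanderParams(p_administer=0.5), rp)
        b = analytic_death_probability(False, BystanderParams(p_administer=0.9), rp)
        assert a == b

    def test_zero_coverage_closed_form(self):
        bp, rp = BystanderParams(), RiskParams()
        expected = rp.f_fatal * (1 - bp.p_bystander * bp.p_ems * bp.eff_ems)
        assert analytic_death_probability(False, bp, rp) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1), st.floats(0, 1), st.booleans())
    def test_analytic_matches_enumeration_everywhere(self, pby, padm, pems,
                                                     effn, effe, f, avail):
        bp = BystanderParams(p_bystander=pby, p_administer=padm, p_ems=pems,
                             eff_naloxone=effn, eff_ems=effe)
        rp = RiskParams(f_fatal=f)
        assert analytic_death_probability(avail, bp, rp) == pytest.approx(
            enumerate_death_probability(avail, bp, rp), abs=1e-12)

    def test_monotonicity_by_finite_differences(self):
        rp = RiskParams(f_fatal=0.1)
        grid = np.linspace(0.05, 0.95, 7)
        for avail in (True, False):
            for a in (0.5, 0.9):
                vals = [analytic_death_probability(
                    avail, BystanderParams(p_bystander=p, p_administer=a), rp)
                    for p in grid]
                assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))
        # non-increasing in p_administer given availability; in eff_naloxone
        vals = [analytic_death_probability(True, BystanderParams(p_administer=a), rp)
                for a in grid]
        assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))
        vals = [analytic_death_probability(True, BystanderParams(eff_naloxone=e), rp)
                for e in grid]
        assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))
        # non-decreasing in f_fatal
        vals = [analytic_death_probability(True, BystanderParams(),
                                           RiskParams(f_fatal=f)) for f in grid]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_scalar_resolver_matches_analytic(self, rng):
        bp = BystanderParams()
        rp = RiskParams(f_fatal=0.10)
        n = 40_000
        deaths = sum(resolve_overdose(_person(), True, bp, rp, rng).fatal
                     for _ in range(n))
        p = analytic_death_probability(True, bp, rp)
        se = np.sqrt(p * (1 - p) / n)
        assert deaths / n == pytest.approx(p, abs=3 * se)

    def test_tree_branch_frequencies_chi2(self, rng):
        """Empirical branch frequencies match the analytic tree (chi-square
        goodness of fit, alpha = 0.001, n = 1e5)."""
        from scipy.stats import chisquare
        bp = BystanderParams(p_bystander=0.6, p_administer=0.7, p_ems=0.5)
        rp = RiskParams(f_fatal=0.10)
        n = 100_000
        avail = np.ones(n, dtype=bool)
        u = rng.random((n, 4))
        by, adm, ems, fatal = resolve_events(avail, bp, rp, u)
        # branch = (bystander, administered, ems); expected probabilities
        obs, exp = [], []
        for b, a, e in itertools.product([0, 1], repeat=3):
            if (a or e) and not b:
                continue  # impossible branches
            pr = bp.p_bystander if b else 1 - bp.p_bystander
            if b:
                pr *= bp.p_administer if a else 1 - bp.p_administer
                pr *= bp.p_ems if e else 1 - bp.p_ems
            obs.append(((by == b) & (adm == a) & (ems == e)).sum())
            exp.append(pr * n)
        stat, pval = chisquare(obs, exp)
        assert pval > 0.001

    def test_event_invariants_enforced(self):
        with pytest.raises(ValueError):
            OverdoseEvent(pid=0, day=0, bystander_present=False,
                          naloxone_available=True, naloxone_administered=True,
                          ems_called=False, fatal=False,
                          victim_released_ever=False)
        with pytest.raises(ValueError):
            OverdoseEvent(pid=0, day=0, bystander_present=False,
                          naloxone_available=False, naloxone_administered=False,
                          ems_called=True, fatal=False,
                          victim_released_ever=False)


class TestDrawOverdoses:
    def _pop(self):
        pp = PopulationParams(n_iou=500, n_niou=1500, n_cli=100,
                              frac_inmates_iou=0.02, frac_inmates_niou=0.02)
        return build_population(pp, seed=9)

    def test_zero_baseline_gives_no_events(self, rng):
        pop = self._pop()
        rp = RiskParams(p0_daily_od=0.0)
        assert draw_overdoses(pop, 0, rp, GeneratorSource(rng)).size == 0

    def test_jailed_users_never_overdose(self, rng):
        pop = self._pop()
        pop.in_jail[pop.user_ids] = True
        rp = RiskParams(p0_daily_od=1.0)
        assert draw_overdoses(pop, 0, rp, GeneratorSource(rng)).size == 0

    def test_event_count_matches_closed_form_expectation(self, rng):
        pop = self._pop()
        rp = RiskParams(p0_daily_od=3.3e-4)
        from thnsim.overdose import static_relative_risk
        p = np.minimum(1.0, rp.p0_daily_od * static_relative_risk(pop, rp))
        expected_daily = p.sum()
        src = GeneratorSource(rng)
        ndays = 365
        total = sum(draw_overdoses(pop, d, rp, src).size for d in range(ndays))
        mean, var = ndays * expected_daily, ndays * (p * (1 - p)).sum()
        assert abs(total - mean) < 3 * np.sqrt(var) + 1
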