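"""Death sampling, CRN streams, lifecourse simulation and its closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import demsim as ds
from demsim.engine import (
    STREAM_DEATH,
    RandomStreams,
    assign_caregiving,
    assign_dementia_onset,
    compute_hyll,
    sample_death_age,
)
from demsim.parameters import constant_rate_parameter_set


class TestSampleDeathAge:
    def test_constant_hazard_closed_form(self):
        # t* = E / h for a constant hazard
        assert sample_death_age([0.0693] * 110, 0.693) == pytest.approx(10.0, rel=1e-12)

    def test_doubling_hazard_halves_death_age(self):
        h = np.full(110, 0.03)
        t1 = sample_death_age(h, 0.8)
        t2 = sample_death_age(2 * h, 0.8)
        assert t2 == pytest.approx(t1 / 2, rel=1e-12)

    def test_threshold_beyond_total_hazard_dies_at_cap(self):
        assert sample_death_age([0.001] * 110, 5.0) == 110.0
        assert sample_death_age(np.zeros(110), 0.5) == 110.0

    def test_piecewise_inversion(self):
        # 2 years at 0.1 then 0.4: E=0.3 crosses 0.25 years into the step-up
        assert sample_death_age([0.1, 0.1, 0.4], 0.3) == pytest.approx(2.25, rel=1e-12)

    @given(st.floats(0.01, 2.0), st.floats(0.01, 5.0))
    def test_inversion_recovers_threshold(self, h, e):
        t = sample_death_age(np.full(110, h), e)
        assert h * t == pytest.approx(min(e, h * 110), rel=1e-9)


class TestRandomStreams:
    def test_reproducible_per_actor(self):
        a = RandomStreams(42).uniform(np.arange(100), 3, 2011)
        b = RandomStreams(42).uniform(np.arange(100), 3, 2011)
        assert np.array_equal(a, b)

    def test_order_independent(self):
        ids = np.array([5, 1, 9])
        s = RandomStreams(7)
        assert np.array_equal(s.uniform(ids, 1, 0), s.uniform(ids[::-1], 1, 0)[::-1])

    def test_streams_and_counters_are_independent_axes(self):
        s = RandomStreams(0)
        ids = np.arange(50)
        assert not np.array_equal(s.uniform(ids, 1, 0), s.uniform(ids, 2, 0))
        assert not np.array_equal(s.uniform(ids, 1, 0), s.uniform(ids, 1, 1))

    def test_open_unit_interval_and_roughly_uniform(self):
        u = RandomStreams(3).uniform(np.arange(100_000), 4, 1999)
        assert u.min() > 0.0 and u.max() < 1.0
        assert abs(u.mean() - 0.5) < 3 * (1 / np.sqrt(12 * 100_000))
        # no gross non-uniformity across deciles
        counts = np.histogram(u, bins=10, range=(0, 1))[0]
        assert np.all(np.abs(counts - 10_000) < 5 * np.sqrt(10_000 * 0.1 * 0.9))


class TestOnset:
    def test_zero_incidence_never_onsets(self):
        p = constant_rate_parameter_set(mortality_rate=0.01, incidence_rate=0.0)
        res = ds.run_population(p, n_actors=2000, seed=0)
        assert res.events["onsets_n"].sum() == 0
        assert np.isnan(res.actors["onset_time"]).all()

    def test_huge_rate_onsets_first_eligible_year(self):
        p = constant_rate_parameter_set(mortality_rate=1e-12, incidence_rate=10.0)
        s = RandomStreams(0)
        hits = sum(
            assign_dementia_onset(50, 0, 2001, p, s, actor_id=i) is not None
            for i in range(5000)
        )
        assert hits / 5000 > 0.999

    def test_below_minimum_age_probability_zero(self):
        p = constant_rate_parameter_set(
            mortality_rate=0.01, incidence_rate=5.0, incidence_min_age=40
        )
        s = RandomStreams(0)
        assert all(
            assign_dementia_onset(30, 0, 2001, p, s, actor_id=i) is None
            for i in range(200)
        )

    def test_onset_age_distribution_is_geometric(self):
        # constant hazard 0.05 from age 65, no mortality: years-to-onset is
        # geometric with p = 1 - exp(-0.05)
        p = constant_rate_parameter_set(
            mortality_rate=1e-15, incidence_rate=0.05, incidence_min_age=65,
            year_start=2000, year_end=2100, cohort_years=1,
            births_per_year_per_sex=1000.0,
        )
        n = 50_000
        res = ds.run_population(p, n_actors=n, seed=9)
        onset_year = res.actors["onset_time"].to_numpy()
        k = np.floor(onset_year).astype(float) - 2066  # first eligible year
        prob = 1.0 - np.exp(-0.05)
        for kk in range(30):
            pk = prob * (1 - prob) ** kk
            obs = np.sum(k == kk)
            se = np.sqrt(n * pk * (1 - pk))
            assert abs(obs - n * pk) < 3 * se, kk


class TestDeathAndYll:
    def test_forced_onset_constant_hazard_exact_inversion(self):
        # m0=0.1, HR=2 from entry: death = entry + E/0.2, twin = entry + E/0.1
        p = constant_rate_parameter_set(
            mortality_rate=0.1, hazard_ratio=2.0, year_start=2000,
            year_end=2001, cohort_years=1,
        )
        res = ds.run_population(p, n_actors=500, seed=4, force_onset_at_entry=True)
        E = RandomStreams(4).exponential(
            np.sort(res.actors["id"].to_numpy()).astype(np.uint64), STREAM_DEATH
        )
        adf = res.actors.sort_values("id")
        uncapped = (E / 0.1) < 108.0  # keep clear of the age-110 cap
        np.testing.assert_allclose(
            adf["death_time"].to_numpy()[uncapped], (2001 + E / 0.2)[uncapped],
            rtol=0, atol=1e-9,
        )
        np.testing.assert_allclose(
            adf["death_time_cf"].to_numpy()[uncapped], (2001 + E / 0.1)[uncapped],
            rtol=0, atol=1e-9,
        )
        np.testing.assert_allclose(
            adf["yll"].to_numpy()[uncapped], (E / 0.1 - E / 0.2)[uncapped],
            rtol=0, atol=1e-9,
        )

    def test_no_onset_implies_zero_yll_exactly(self, small_run):
        a = small_run.actors
        no_onset = a["onset_time"].isna() & a["death_time"].notna()
        assert no_onset.any()
        assert (a.loc[no_onset, "yll"] == 0.0).all()

    def test_counterfactual_never_dies_first_when_hr_geq_1(self, small_run):
        a = small_run.actors
        both = a["death_time"].notna() & a["death_time_cf"].notna()
        assert (a.loc[both, "death_time_cf"] >= a.loc[both, "death_time"]).all()

    def test_deaths_capped_at_110th_birthday(self, small_run):
        a = small_run.actors
        died = a["death_time"].notna()
        age_at_death = a.loc[died, "death_time"] - a.loc[died, "birth_time"]
        assert (age_at_death <= 110.0 + 1e-9).all()


class TestHyll:
    def test_identity_for_identical_paths(self):
        assert compute_hyll([0.7, 0.6], [1, 0.4], [0.7, 0.6], [1, 0.4]) == 0.0

    def test_hand_summed_example(self):
        # factual: 3 years at 0.4; twin: those 3 years at 0.8 plus 2 more
        got = compute_hyll([0.4] * 3, [1, 1, 1], [0.8] * 5, [1, 1, 1, 1, 1])
        assert got == pytest.approx(3 * 0.8 + 2 * 0.8 - 3 * 0.4, rel=1e-12)
        assert got == pytest.approx(2.8, rel=1e-12)

    def test_utility_one_limit_equals_yll(self):
        p = constant_rate_parameter_set(
            mortality_rate=0.1, hazard_ratio=2.0, hui3_nodem=1.0, hui3_dem=1.0,
            year_start=2000, year_end=2001, cohort_years=1,
        )
        res = ds.run_population(p, n_actors=2000, seed=6, force_onset_at_entry=True)
        a = res.actors.dropna(subset=["yll"])
        np.testing.assert_allclose(a["hyll"], a["yll"], rtol=0, atol=1e-9)

    def test_twin_escapes_the_dementia_decrement_by_default(self):
        p = constant_rate_parameter_set(
            mortality_rate=0.1, hazard_ratio=1.0, hui3_nodem=0.9, hui3_dem=0.5,
            year_start=2000, year_end=2001, cohort_years=1,
        )
        res = ds.run_population(p, n_actors=500, seed=2, force_onset_at_entry=True)
        a = res.actors.dropna(subset=["hyll"])
        # HR=1: YLL = 0, but the twin lives the same years at 0.9 vs 0.5
        assert (a["yll"] == 0.0).all()
        assert (a["hyll"] > 0).all()
        res2 = ds.run_population(p, n_actors=500, seed=2, force_onset_at_entry=True,
                                 counterfactual_hui3="factual_status")
        a2 = res2.actors.dropna(subset=["hyll"])
        assert np.allclose(a2["hyll"], 0.0, atol=1e-9)


class TestCaregiving:
    def test_zero_receipt_probability_no_recipients(self):
        p = constant_rate_parameter_set(
            mortality_rate=0.02, receipt_dementia=0.0, receipt_nondementia=0.0,
            year_start=2000, year_end=2020,
        )
        res = ds.run_population(p, n_actors=3000, seed=0, force_onset_at_entry=True)
        assert res.annual["care_recipients_w"].sum() == 0.0

    def test_degenerate_hours_distribution(self):
        p = constant_rate_parameter_set(
            mortality_rate=1e-12, receipt_dementia=1.0,
            hours_probs=(0.0, 0.0, 0.0, 1.0),
            year_start=2000, year_end=2010, cohort_years=1,
        )
        res = ds.run_population(p, n_actors=1000, seed=1, force_onset_at_entry=True)
        ann = res.annual.loc[2002:]  # first possible care year is entry + 1
        assert (ann["care_recipients_w"] == ann["dem_mid"]).all()
        assert (ann["care_ge71_w"] == ann["care_recipients_w"]).all()
        # 80 h/week x 52 weeks per full-year recipient
        np.testing.assert_allclose(
            ann["care_hours_w"], ann["care_recipients_w"] * 80.0 * 52.0)

    def test_receipt_fraction_binomial(self):
        # p = 0.77 for dementia cells; pooled actor-years are Bernoulli(0.77)
        p = constant_rate_parameter_set(
            mortality_rate=1e-12, receipt_dementia=0.77,
            year_start=2000, year_end=2025, cohort_years=1,
        )
        res = ds.run_population(p, n_actors=1000, seed=5, force_onset_at_entry=True)
        ann = res.annual.loc[2002:]
        n_years = (ann["dem_mid"] / res.weight).sum()
        got = (ann["care_recipients_w"] / res.weight).sum()
        se = np.sqrt(n_years * 0.77 * 0.23)
        assert n_years >= 20_000
        assert abs(got - 0.77 * n_years) < 3 * se

    def test_assign_caregiving_record_fields(self, synth_params):
        s = RandomStreams(1)
        recs = [
            assign_caregiving(82, 1, True, 0.3, synth_params, s, actor_id=i, year=2011)
            for i in range(300)
        ]
        got = [r for r in recs if r["received"]]
        assert 0.77 * 300 - 3 * np.sqrt(300 * 0.77 * 0.23) < len(got)
        assert all(r["bin"] in ds.HOUR_BINS for r in got)
        assert all(r["caregiver_oop"] == synth_params.caregiving.caregiver_oop for r in got)


class TestCosts:
    def test_phase_proration_reconstructed_from_lifecourses(self):
        # onset-year cost accrues from the onset date at the incident rate;
        # the following year splits incident/prevalent at the anniversary
        p = constant_rate_parameter_set(
            mortality_rate=1e-12, incidence_rate=0.2, incidence_min_age=0,
            sector_cost=2000.0, incident_cost=10000.0,
            year_start=2000, year_end=2012, cohort_years=1,
        )
        res = ds.run_population(p, n_actors=500, seed=8)
        a = res.actors
        w = res.weight
        for year in (2004, 2008):
            onset = a["onset_time"].to_numpy()
            lived_end = year + 1.0  # nobody dies at this hazard
            dem_start = np.maximum(float(year), onset)
            inc = np.clip(np.minimum(onset + 1.0, lived_end) - dem_start, 0, None)
            dem = np.clip(lived_end - dem_start, 0, None)
            expected = w * np.nansum(inc * 10000.0 + (dem - inc) * 2000.0)
            assert res.annual.loc[year, "cost_hospitalization_w"] == pytest.approx(
                expected, rel=1e-9)

    def test_zero_prevalence_zero_cost(self):
        p = constant_rate_parameter_set(mortality_rate=0.01, sector_cost=5000.0)
        res = ds.run_population(p, n_actors=1000, seed=0)
        for s in ds.SECTORS:
            assert res.annual[f"cost_{s}_w"].sum() == 0.0


class TestSimulateActor:
    def test_matches_population_run(self, synth_params, small_pop):
        res = ds.run_population(synth_params, actors=small_pop, seed=5)
        streams = RandomStreams(5)
        by_id = res.actors.set_index("id")
        for i in (0, 17, 123, 499):
            lc = ds.simulate_actor(small_pop[i], synth_params, streams=streams)
            row = by_id.loc[small_pop[i].id]
            for attr, col in [("death_date", "death_time"),
                              ("counterfactual_death_date", "death_time_cf"),
                              ("onset_date", "onset_time")]:
                got = getattr(lc, attr)
                if got is None:
                    assert np.isnan(row[col])
                else:
                    assert got == row[col]

    def test_lifecourse_annual_records(self, synth_params, small_pop):
        lc = ds.simulate_actor(small_pop[3], synth_params, streams=RandomStreams(5))
        yrs = lc.years
        assert (yrs["hui3"].dropna() >= ds.HUI3_MIN).all()
        assert (yrs["hui3"].dropna() <= ds.HUI3_MAX).all()
        assert (yrs["fraction_lived"] <= 1.0).all()
        assert yrs["age"].is_monotonic_increasing
        if lc.onset_date is not None:
            onset_year = int(lc.onset_date)
            assert yrs.set_index("year").loc[onset_year, "dementia"]


class TestDeterminism:
    def test_same_seed_identical_tables(self, synth_params):
        r1 = ds.run_population(synth_params, n_actors=5000, seed=11)
        r2 = ds.run_population(synth_params, n_actors=5000, seed=11)
        pd.testing.assert_frame_equal(r1.annual, r2.annual)
        pd.testing.assert_frame_equal(r1.events, r2.events)
        assert r1.annual.to_csv() == r2.annual.to_csv()

    def test_actor_order_invariance(self, synth_params, small_pop):
        r1 = ds.run_population(synth_params, actors=small_pop, seed=5)
        perm = np.random.default_rng(1).permutation(len(small_pop))
        r2 = ds.run_population(synth_params, actors=small_pop.permuted(perm), seed=5)
        pd.testing.assert_frame_equal(r1.annual, r2.annual)
        pd.testing.assert_frame_equal(r1.events, r2.events)

    def test_event_log_balance_exact(self, small_run):
        e = small_run.events
        lhs = e["prev_jan_n"].to_numpy()[1:]
        rhs = (e["prev_jan_n"] + e["onsets_n"] - e["dem_deaths_n"]
               - e["dem_emigrants_n"]).to_numpy()[:-1]
        assert np.array_equal(lhs, rhs)

    def test_split_runs_match_union_per_actor(self, synth_params, small_pop):
        # the same actors simulated in two halves give identical lifecourses
        full = ds.run_population(synth_params, actors=small_pop, seed=5)
        half1 = ds.run_population(
            synth_params, actors=small_pop.permuted(np.arange(0, 250)), seed=5)
        half2 = ds.run_population(
            synth_params, actors=small_pop.permuted(np.arange(250, 500)), seed=5)
        merged = pd.concat([half1.actors, half2.actors]).sort_values("id")
        ref = full.actors.sort_values("id")
        for col in ("onset_time", "death_time", "death_time_cf", "yll", "hyll"):
            np.testing.assert_array_equal(merged[col].to_numpy(), ref[col].to_numpy())
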