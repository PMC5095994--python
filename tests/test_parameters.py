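"""Rate tables, hazard conversions, bundle I/O and the synthetic generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import demsim as ds
from demsim.parameters import (
    AgeSexYearTable,
    ConfigError,
    MissingInputError,
    MortalityModel,
    ParameterError,
    SynthConfig,
    rate_lookup,
    rate_to_annual_prob,
)


class TestRateToAnnualProb:
    @pytest.mark.parametrize(
        "rate,expected",
        [
            (0.0, 0.0),
            (0.02, 0.019801326693244747),  # 1 - exp(-0.02)
            (0.05, 0.048770575499285984),
        ],
    )
    def test_values(self, rate, expected):
        assert rate_to_annual_prob(rate) == pytest.approx(expected, rel=1e-12)

    def test_large_rate_saturates(self):
        assert rate_to_annual_prob(50.0) == pytest.approx(1.0, abs=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            rate_to_annual_prob(-0.1)

    @given(st.floats(0, 30), st.floats(0, 30))
    def test_monotone_and_bounded(self, a, b):
        pa, pb = rate_to_annual_prob(a), rate_to_annual_prob(b)
        assert 0.0 <= pa < 1.0  # < 1 up to double-precision saturation
        if a < b:
            assert pa <= pb


class TestAgeSexYearTable:
    def table(self):
        vals = np.zeros((111, 2, 32))
        vals[75, 1, 11] = 0.02  # (75, female, 2011), span 2000-2031
        return AgeSexYearTable(vals, 2000, name="t")

    def test_direct_lookup(self):
        assert rate_lookup(self.table(), 75, "female", 2011) == 0.02

    def test_age_clamps_to_open_ended_last_row(self):
        t = self.table()
        t.values[110, 0, 0] = 0.5
        assert t.lookup(115, "male", 2000) == t.lookup(110, "male", 2000) == 0.5

    def test_year_clamps_to_span(self):
        t = self.table()
        t.values[60, 0, 0] = 0.1
        t.values[60, 0, -1] = 0.4
        assert t.lookup(60, "male", 1990) == 0.1
        assert t.lookup(60, "male", 2050) == 0.4

    def test_negative_age_is_domain_error(self):
        with pytest.raises(ParameterError):
            self.table().lookup(-1, "male", 2000)

    def test_negative_hazard_names_cell(self):
        t = self.table()
        t.values[70, 0, 11] = -0.01
        with pytest.raises(ParameterError, match=r"age=70.*male.*2011"):
            t.validate("hazard")

    def test_probability_above_one_rejected(self):
        t = self.table()
        t.values[10, 1, 0] = 1.5
        with pytest.raises(ParameterError):
            t.validate("probability")


class TestMortalityModel:
    def model(self, rho=0.01):
        return MortalityModel(
            reference_rates=np.full((111, 2), 0.10),
            reference_year=2006,
            improvement=np.full((111, 2), rho),
        )

    def test_no_improvement_returns_reference(self):
        m = self.model(rho=0.0)
        for y in (1990, 2006, 2040):
            assert ds.baseline_mortality(m, 80, "male", y) == 0.10

    def test_exponential_decline_closed_form(self):
        # 0.10 * exp(-0.01 * 20) after 20 years
        m = self.model()
        assert ds.baseline_mortality(m, 80, "female", 2026) == pytest.approx(
            0.10 * np.exp(-0.2), rel=1e-12
        )

    def test_growth_variant_ordering(self):
        base = self.model()
        rates = {
            v: base.with_variant(v).rate(70, 0, 2030) for v in ("low", "mid", "high")
        }
        assert rates["high"] <= rates["mid"] <= rates["low"]

    def test_nonincreasing_in_year(self):
        m = self.model()
        years = np.arange(2006, 2040)
        r = [m.rate(75, 1, y) for y in years]
        assert np.all(np.diff(r) <= 0)


class TestSynthesis:
    def test_deterministic_for_same_seed(self):
        a = ds.synthesize_parameter_set(1)
        b = ds.synthesize_parameter_set(1)
        assert np.array_equal(a.incidence.values, b.incidence.values)
        assert np.array_equal(a.mortality.reference_rates, b.mortality.reference_rates)
        assert np.array_equal(a.hui3.mean, b.hui3.mean)

    def test_seed_changes_world(self):
        a = ds.synthesize_parameter_set(1)
        b = ds.synthesize_parameter_set(2)
        assert not np.array_equal(a.incidence.values, b.incidence.values)

    def test_incidence_doubling_time_closed_form(self):
        cfg = SynthConfig(
            incidence_rate_at_65=0.01,
            incidence_doubling_time=6.0,
            jitter_sd=0.0,
            female_incidence_factor=1.0,
        )
        p = ds.synthesize_parameter_set(0, cfg)
        assert p.incidence.lookup(65, "male", 2011) == pytest.approx(0.01, rel=1e-12)
        assert p.incidence.lookup(71, "male", 2011) == pytest.approx(0.02, rel=1e-12)

    def test_nonpositive_gompertz_beta_rejected(self):
        with pytest.raises(ConfigError):
            ds.synthesize_parameter_set(0, SynthConfig(gompertz_beta=0.0))

    @pytest.mark.parametrize("seed", [0, 1, 5])
    def test_mortality_strictly_increasing_until_cap(self, seed, request):
        p = ds.synthesize_parameter_set(seed)
        for s in (0, 1):
            r = p.mortality.reference_rates[:, s]
            below_cap = r < r.max()
            assert np.all(np.diff(r[below_cap]) > 0)

    @pytest.mark.parametrize("seed", [0, 1, 5])
    def test_incidence_nondecreasing_above_min_age(self, seed):
        p = ds.synthesize_parameter_set(seed)
        a0 = p.metadata.incidence_min_age
        inc = p.incidence.values[a0:, :, 0]
        assert np.all(np.diff(inc, axis=0) >= 0)
        assert np.all(p.incidence.values[:a0] == 0)

    def test_hui3_declines_with_age_and_dementia_decrement(self):
        p = ds.synthesize_parameter_set(1)
        nodem = p.hui3.mean[:, 0, 0]
        dem = p.hui3.mean[:, 0, 1]
        assert np.all(np.diff(nodem[30:]) <= 0)
        assert np.all(dem[40:] < nodem[40:])


class TestBundleIO:
    def test_round_trip_bit_exact(self, synth_params, tmp_path):
        ds.save_parameter_set(synth_params, tmp_path / "b")
        p2 = ds.load_parameter_set(tmp_path / "b")
        pairs = [
            (synth_params.incidence.values, p2.incidence.values),
            (synth_params.hazard_ratio.hr.values, p2.hazard_ratio.hr.values),
            (synth_params.mortality.reference_rates, p2.mortality.reference_rates),
            (synth_params.mortality.improvement, p2.mortality.improvement),
            (synth_params.hui3.mean, p2.hui3.mean),
            (synth_params.hui3.sd, p2.hui3.sd),
            (synth_params.caregiving.receipt_prob, p2.caregiving.receipt_prob),
            (synth_params.caregiving.hours_probs, p2.caregiving.hours_probs),
            (synth_params.costs.annual_cost, p2.costs.annual_cost),
            (synth_params.costs.out_of_pocket, p2.costs.out_of_pocket),
            (synth_params.demography.cohorts.births, p2.demography.cohorts.births),
            (synth_params.demography.migration.immigration, p2.demography.migration.immigration),
            (synth_params.demography.migration.emigration_rate, p2.demography.migration.emigration_rate),
        ]
        for a, b in pairs:
            assert np.array_equal(a, b)
        assert p2.metadata == synth_params.metadata

    def test_missing_table_named(self, synth_params, tmp_path):
        d = ds.save_parameter_set(synth_params, tmp_path / "b")
        (d / "hui3.csv").unlink()
        with pytest.raises(MissingInputError, match="hui3"):
            ds.load_parameter_set(d)

    def test_missing_sector_named(self, synth_params, tmp_path):
        d = ds.save_parameter_set(synth_params, tmp_path / "b")
        costs = pd.read_csv(d / "costs.csv")
        costs[costs["sector"] != "long_term_care"].to_csv(d / "costs.csv", index=False)
        with pytest.raises(MissingInputError, match="missing input: long_term_care"):
            ds.load_parameter_set(d)

    def test_negative_incidence_cell_named(self, synth_params, tmp_path):
        d = ds.save_parameter_set(synth_params, tmp_path / "b")
        inc = pd.read_csv(d / "incidence.csv")
        sel = (inc.age == 70) & (inc.sex == "male") & (inc.year == 2011)
        inc.loc[sel, "value"] = -0.01
        inc.to_csv(d / "incidence.csv", index=False)
        with pytest.raises(ParameterError, match=r"age=70.*male.*2011"):
            ds.load_parameter_set(d)

    def test_incidence_below_min_age_rejected(self, synth_params):
        bad = synth_params.incidence.values.copy()
        bad[10, 0, 0] = 0.01
        p = synth_params.replace(
            incidence=AgeSexYearTable(bad, synth_params.incidence.year_start)
        )
        with pytest.raises(ParameterError, match="below age"):
            p.validate()


class TestDomainTypes:
    def test_hui3_means_must_be_in_range(self):
        mean = np.full((111, 2, 2), 0.8)
        mean[0, 0, 0] = 1.2
        with pytest.raises(ParameterError):
            ds.HUI3Table(mean, np.zeros((111, 2, 2)))

    @given(st.floats(-6, 6))
    def test_hui3_samples_clipped(self, z):
        p = ds.synthesize_parameter_set(1)
        v = p.hui3.sample(np.array([80]), np.array([1]), np.array([1]), np.array([z]))
        assert ds.HUI3_MIN <= v[0] <= ds.HUI3_MAX

    def test_caregiving_hour_probs_must_sum_to_one(self):
        p = ds.synthesize_parameter_set(1)
        cg = p.caregiving
        with pytest.raises(ParameterError, match="sum to 1"):
            dataclasses.replace(cg, hours_probs=cg.hours_probs * 1.01)

    def test_hour_bins_partition_the_line(self):
        # half-open bins [0,7), [7,15), [15,71), [71, inf)
        cg = ds.synthesize_parameter_set(1).caregiving
        lo = np.array(ds.parameters.HOUR_BIN_EDGES)
        assert np.all(cg.hours_values >= lo)
        assert np.all(cg.hours_values[:-1] < lo[1:])

    def test_hazard_ratio_effective_product(self):
        p = ds.synthesize_parameter_set(1)
        hr2 = p.hazard_ratio.scaled(0.9)
        assert np.allclose(hr2.year_matrix(2011), p.hazard_ratio.year_matrix(2011) * 0.9)
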