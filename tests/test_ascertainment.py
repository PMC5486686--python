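"""Case filtering, banded incidence and population-weighted amalgamation."""

import datetime as dt
import random

import numpy as np
import pandas as pd
import pytest

from fraxkit.ascertainment import (
    CaseRecord,
    ExclusionReason,
    amalgamate,
    band_label,
    band_low_for_age,
    filter_cases,
    tabulate_incidence,
)
from fraxkit.synthetic import default_sim_config, generate_registry


def make_record(pid="P1", age=70, date="2012-06-01", code="S72.0", **kw):
    return CaseRecord(
        patient_id=pid,
        region=kw.pop("region", "r1"),
        sex=kw.pop("sex", "female"),
        age_years=age,
        admission_date=dt.date.fromisoformat(date),
        icd10_code=code,
        **kw,
    )


def pop_table(region="r1", count=10_000, bands=(70,), sexes=("female",)):
    rows = [
        {
            "region": region,
            "sex": s,
            "age_low": b,
            "age_high": b + 5,
            "person_count": count,
            "year": 2012,
        }
        for s in sexes
        for b in bands
    ]
    return pd.DataFrame(rows)


class TestFilterCases:
    def test_demo_fixture_retains_five_with_five_distinct_reasons(self, demo_records):
        included, log = filter_cases(demo_records)
        assert len(included) == 5
        assert len(log) == 5
        reasons = {reason for _, reason in log.entries}
        assert reasons == {
            ExclusionReason.DUPLICATE_SAME_FRACTURE,
            ExclusionReason.NEOPLASIA,
            ExclusionReason.S729_NO_SURGERY,
            ExclusionReason.PRIOR_YEAR_SAME_SITE,
            ExclusionReason.NON_HIP_CODE,
        }

    def test_empty_input(self):
        included, log = filter_cases([])
        assert included == [] and len(log) == 0

    def test_all_clean_identity(self):
        records = [
            make_record(pid=f"P{i}", date=f"2012-0{1 + i % 9}-10") for i in range(20)
        ]
        included, log = filter_cases(records)
        assert len(included) == 20 and len(log) == 0

    def test_under_age_excluded_at_default_floor(self):
        included, log = filter_cases([make_record(age=39)])
        assert included == []
        assert log.entries[0][1] is ExclusionReason.UNDER_AGE

    def test_configurable_minimum_age(self):
        rec = make_record(age=45)
        included, _ = filter_cases([rec], min_age=50)
        assert included == []
        included, _ = filter_cases([rec], min_age=40)
        assert included == [rec]

    def test_refused_hospitalization_retained(self):
        rec = make_record(refused_hospitalization=True, source="ambulance")
        included, log = filter_cases([rec])
        assert included == [rec] and len(log) == 0

    def test_s729_with_surgery_retained(self):
        rec = make_record(code="S72.9", hip_surgery=True)
        included, _ = filter_cases([rec])
        assert included == [rec]

    def test_same_site_different_patients_both_retained(self):
        recs = [make_record(pid="A"), make_record(pid="B")]
        included, _ = filter_cases(recs)
        assert len(included) == 2

    def test_different_site_same_patient_both_retained(self):
        recs = [
            make_record(code="S72.0", date="2012-03-01"),
            make_record(code="S72.1", date="2012-04-01"),
        ]
        included, _ = filter_cases(recs)
        assert len(included) == 2

    def test_second_fracture_after_window_is_new_case(self):
        recs = [
            make_record(date="2011-01-10"),
            make_record(date="2012-02-10"),  # 396 days later
        ]
        included, _ = filter_cases(recs)
        assert len(included) == 2

    def test_conservation_on_simulated_registry(self):
        records, _ = generate_registry(default_sim_config(seed=13))
        included, log = filter_cases(records)
        assert len(included) + len(log) == len(records)

    def test_order_independence(self):
        records, _ = generate_registry(default_sim_config(seed=21))
        included, _ = filter_cases(records)
        shuffled = list(records)
        random.Random(99).shuffle(shuffled)
        included_shuffled, _ = filter_cases(shuffled)
        assert included == included_shuffled

    def test_idempotence(self, demo_records):
        included, _ = filter_cases(demo_records)
        again, log = filter_cases(included)
        assert again == included and len(log) == 0

    def test_unknown_sex_rejected_at_record_construction(self):
        with pytest.raises(ValueError, match="unknown sex"):
            make_record(sex="unknown")


class TestBands:
    @pytest.mark.parametrize(
        "age,low", [(40, 40), (44, 40), (45, 45), (72, 70), (95, 95), (104, 95)]
    )
    def test_band_assignment(self, age, low):
        assert band_low_for_age(age) == low

    def test_labels(self):
        assert band_label(70) == "70-74"
        assert band_label(95) == "95+"


class TestTabulateIncidence:
    def test_hand_division(self):
        cases = [make_record(pid=f"P{i}", age=70 + i % 5) for i in range(5)]
        table = tabulate_incidence(cases, pop_table(), "r1", 1.0)
        row = table[(table.sex == "female") & (table.age_low == 70)].iloc[0]
        assert row["rate"] == pytest.approx(5e-4)
        assert row["n_cases"] == 5 and row["person_years"] == 10_000

    def test_zero_cases_zero_rate(self):
        table = tabulate_incidence([], pop_table(), "r1", 1.0)
        assert (table["rate"] == 0).all()

    def test_two_year_window_halves_rate(self):
        cases = [make_record(pid=f"P{i}") for i in range(5)]
        one = tabulate_incidence(cases, pop_table(), "r1", 1.0)
        two = tabulate_incidence(cases, pop_table(), "r1", 2.0)
        assert two["rate"].iloc[0] == pytest.approx(one["rate"].iloc[0] / 2)

    def test_case_in_zero_population_band_errors(self):
        pop = pop_table(count=0)
        with pytest.raises(ValueError, match="zero recorded population"):
            tabulate_incidence([make_record()], pop, "r1", 1.0)

    def test_case_in_uncovered_band_errors(self):
        pop = pop_table(bands=(40,))
        with pytest.raises(ValueError, match="absent from the population"):
            tabulate_incidence([make_record(age=70)], pop, "r1", 1.0)

    def test_unknown_region_errors(self):
        with pytest.raises(ValueError, match="no rows for region"):
            tabulate_incidence([], pop_table(), "nowhere", 1.0)


def incidence_row(region, rate, pop, sex="female", age_low=70, years=1.0):
    return {
        "region": region,
        "sex": sex,
        "age_low": age_low,
        "age_high": age_low + 5,
        "n_cases": int(round(rate * pop * years)),
        "person_years": pop * years,
        "rate": rate,
    }


class TestAmalgamate:
    def test_weighted_mean_by_hand(self):
        t1 = pd.DataFrame([incidence_row("r1", 100e-5, 200_000)])
        t2 = pd.DataFrame([incidence_row("r2", 300e-5, 600_000)])
        pops = pop_table("r1", 200_000, bands=(70,))
        pops = pd.concat([pops, pop_table("r2", 600_000, bands=(70,))])
        pooled = amalgamate([t1, t2], pops)
        assert pooled["rate"].iloc[0] == pytest.approx(250e-5)

    def test_equal_rates_unchanged(self):
        t1 = pd.DataFrame([incidence_row("r1", 2e-3, 100_000)])
        t2 = pd.DataFrame([incidence_row("r2", 2e-3, 500_000)])
        pops = pd.concat(
            [pop_table("r1", 100_000), pop_table("r2", 500_000)]
        )
        pooled = amalgamate([t1, t2], pops)
        assert pooled["rate"].iloc[0] == pytest.approx(2e-3)

    def test_single_region_identity(self):
        t1 = pd.DataFrame([incidence_row("r1", 1.5e-3, 50_000)])
        pooled = amalgamate([t1], pop_table("r1", 50_000))
        assert pooled["rate"].iloc[0] == pytest.approx(1.5e-3)
        assert pooled["n_cases"].iloc[0] == t1["n_cases"].iloc[0]

    def test_mismatched_bands_rejected(self):
        t1 = pd.DataFrame([incidence_row("r1", 1e-3, 1000, age_low=70)])
        t2 = pd.DataFrame([incidence_row("r2", 1e-3, 1000, age_low=75)])
        pops = pd.concat([pop_table("r1"), pop_table("r2")])
        with pytest.raises(ValueError, match="mismatched band"):
            amalgamate([t1, t2], pops)

    def test_weighted_pooling_equals_raw_pooling_for_equal_windows(self):
        """Population-weighted rate pooling is algebraically identical to
        pooling raw numerators/denominators when windows have equal length."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_regions = int(rng.integers(2, 5))
            tables, pop_frames = [], []
            total_cases = 0
            total_py = 0.0
            for i in range(n_regions):
                pop = int(rng.integers(10_000, 500_000))
                cases = int(rng.integers(0, 300))
                rate = cases / pop
                tables.append(
                    pd.DataFrame([incidence_row(f"r{i}", rate, pop)])
                )
                pop_frames.append(pop_table(f"r{i}", pop))
                total_cases += cases
                total_py += pop
            pooled = amalgamate(tables, pd.concat(pop_frames))
            assert pooled["rate"].iloc[0] == pytest.approx(
                total_cases / total_py, abs=1e-15
            )
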