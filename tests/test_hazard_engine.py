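"""Competing-mortality probability engine and risk-factor model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fraxkit.hazards import (
    CountryModel,
    RiskFactorProfile,
    RiskModelConfig,
    adjusted_hazard,
    death_hazard_fn,
    example_risk_config,
    lifetime_probability,
    mof_hazard,
    probability,
    risk_multiplier,
    ten_year_probability,
)


def const(v):
    return lambda age: np.full(np.shape(age), v, dtype=float)


def closed_form(hf, hd, T):
    tot = hf + hd
    if tot == 0:
        return 0.0
    return hf / tot * (1.0 - np.exp(-T * tot))


def neutral_profile(age=70.0, sex="female", **kw):
    return RiskFactorProfile(age=age, sex=sex, bmi=25.0, **kw)


class TestRiskMultiplier:
    def test_neutral_profile_multiplier_one(self):
        cfg = example_risk_config()
        p = neutral_profile(tscore=0.0)
        assert risk_multiplier(p, cfg, "hip") == pytest.approx(1.0)
        assert risk_multiplier(p, cfg, "mof") == pytest.approx(1.0)

    def test_two_factors_multiply(self):
        cfg = RiskModelConfig(
            relative_risks={"prior_fracture": 2.0, "current_smoking": 1.5}
        )
        p = neutral_profile(prior_fracture=True, current_smoking=True)
        assert risk_multiplier(p, cfg, "hip") == pytest.approx(3.0)

    def test_bmd_gradient_power(self):
        cfg = RiskModelConfig(gradient_of_risk=1.8, reference_tscore=0.0)
        p = neutral_profile(tscore=-2.0)
        assert risk_multiplier(p, cfg, "hip") == pytest.approx(1.8**2)

    def test_secondary_osteoporosis_inactive_with_bmd(self):
        cfg = RiskModelConfig(
            relative_risks={"secondary_osteoporosis": 1.6},
            secondary_osteoporosis_inactive_with_bmd=True,
        )
        with_bmd = neutral_profile(tscore=0.0, secondary_osteoporosis=True)
        without_bmd = neutral_profile(secondary_osteoporosis=True)
        assert risk_multiplier(with_bmd, cfg, "hip") == pytest.approx(1.0)
        assert risk_multiplier(without_bmd, cfg, "hip") == pytest.approx(1.6)

    def test_bmi_effect_neutral_at_25_and_configurable(self):
        cfg = RiskModelConfig(rr_per_bmi_unit=1.05)
        assert risk_multiplier(neutral_profile(), cfg, "hip") == pytest.approx(1.0)
        thin = RiskFactorProfile(age=70, sex="female", bmi=20.0)
        assert risk_multiplier(thin, cfg, "hip") == pytest.approx(1.05**5)

    def test_adjusted_hazard_scales_pointwise(self):
        cfg = RiskModelConfig(relative_risks={"prior_fracture": 2.0})
        h = adjusted_hazard(const(1e-3), neutral_profile(prior_fracture=True), cfg)
        assert h(70.0) == pytest.approx(2e-3)


class TestMofHazard:
    def test_unit_ratio_identity(self, base_model):
        ratio = pd.DataFrame(
            {"sex": ["female"] * 2, "age": [50, 80], "ratio": [1.0, 1.0]}
        )
        cfg = RiskModelConfig(hip_to_mof_ratio=ratio)
        model = CountryModel(hip=base_model.hip, death=base_model.death, risk=cfg)
        assert mof_hazard(model, "female", 70.0) == pytest.approx(
            base_model.hip["female"].rate(70.0)
        )

    def test_ratio_multiplies(self):
        from fraxkit.incidence import PiecewiseLogLinearModel

        hip = PiecewiseLogLinearModel(
            sex="female", intercept=float(np.log(2e-3)), slope_pre=0, slope_post=0
        )
        ratio = pd.DataFrame({"sex": ["female"], "age": [70], "ratio": [4.0]})
        model = CountryModel(
            hip={"female": hip},
            death=pd.DataFrame({"sex": [], "age": [], "hazard": []}),
            risk=RiskModelConfig(hip_to_mof_ratio=ratio),
        )
        assert mof_hazard(model, "female", 70.0) == pytest.approx(8e-3)

    def test_nearest_tabulated_age_used(self):
        ratio = pd.DataFrame(
            {"sex": ["male", "male"], "age": [50, 70], "ratio": [5.0, 2.0]}
        )
        cfg = RiskModelConfig(hip_to_mof_ratio=ratio)
        assert cfg.ratio("male", 55.0) == 5.0
        assert cfg.ratio("male", 65.0) == 2.0

    def test_missing_ratio_table_errors(self, base_model):
        cfg = RiskModelConfig()
        model = CountryModel(hip=base_model.hip, death=base_model.death, risk=cfg)
        with pytest.raises(ValueError, match="ratio table"):
            mof_hazard(model, "female", 70.0)


class TestIntegrator:
    def test_zero_fracture_hazard(self):
        assert ten_year_probability(const(0.0), const(0.02), 60.0) == 0.0
        assert lifetime_probability(const(0.0), const(0.02), 50.0) == 0.0

    def test_constant_hazard_no_mortality(self):
        p = ten_year_probability(const(0.05), const(0.0), 60.0)
        assert p == pytest.approx(1 - np.exp(-0.5), abs=1e-8)

    def test_constant_competing_hazards(self):
        p = ten_year_probability(const(0.01), const(0.02), 60.0)
        assert p == pytest.approx(closed_form(0.01, 0.02, 10.0), abs=1e-8)

    def test_lifetime_closed_form(self):
        p = lifetime_probability(const(0.01), const(0.02), 50.0, max_age=110.0)
        assert p == pytest.approx(closed_form(0.01, 0.02, 60.0), abs=1e-8)

    def test_lifetime_at_least_ten_year(self, base_model):
        h = base_model.hip_hazard("female")
        hd = base_model.death_hazard("female")
        assert lifetime_probability(h, hd, 60.0) >= ten_year_probability(h, hd, 60.0)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError, match="max_age"):
            lifetime_probability(const(0.01), const(0.01), 80.0, max_age=80.0)

    def test_quadrature_halving_below_1e8(self, base_model):
        h = base_model.hip_hazard("female")
        hd = base_model.death_hazard("female")
        p1 = ten_year_probability(h, hd, 80.0, step=0.005)
        p2 = ten_year_probability(h, hd, 80.0, step=0.0025)
        assert abs(p1 - p2) < 1e-8

    def test_competing_mortality_lowers_probability(self):
        lo = ten_year_probability(const(0.02), const(0.01), 60.0)
        hi = ten_year_probability(const(0.02), const(0.05), 60.0)
        assert hi < lo

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        hf=st.floats(min_value=0.0, max_value=0.5),
        hd=st.floats(min_value=0.0, max_value=0.5),
        horizon=st.floats(min_value=1.0, max_value=60.0),
    )
    def test_bounds_and_horizon_monotonicity(self, hf, hd, horizon):
        p_short = lifetime_probability(const(hf), const(hd), 50.0, 50.0 + horizon)
        p_long = lifetime_probability(const(hf), const(hd), 50.0, 50.0 + 60.0)
        assert 0.0 <= p_short <= 1.0
        assert p_long >= p_short - 1e-12


class TestDeathHazardInterpolation:
    def test_log_linear_between_years(self):
        table = pd.DataFrame(
            {"sex": ["female"] * 71, "age": range(40, 111), "hazard": 1e-4}
        )
        table.loc[table["age"] == 70, "hazard"] = 1e-4
        table.loc[table["age"] == 71, "hazard"] = 4e-4
        h = death_hazard_fn(table, "female")
        assert float(h(70.5)) == pytest.approx(np.sqrt(1e-4 * 4e-4), rel=1e-10)

    def test_outside_table_rejected(self, death_table):
        h = death_hazard_fn(death_table, "male")
        with pytest.raises(ValueError, match="undefined"):
            h(120.0)


class TestProbabilityComposition:
    def test_neutral_profile_equals_baseline_integral(self, base_model):
        p_engine = probability(
            base_model, neutral_profile(age=70.0), outcome="hip", horizon="ten_year"
        )
        p_direct = ten_year_probability(
            base_model.hip_hazard("female"), base_model.death_hazard("female"), 70.0
        )
        assert p_engine == pytest.approx(p_direct, rel=1e-12)

    def test_each_risk_factor_increases_probability(self, base_model):
        base = probability(base_model, neutral_profile(age=65.0))
        from fraxkit.hazards import CLINICAL_RISK_FACTORS

        for factor in CLINICAL_RISK_FACTORS:
            p = probability(
                base_model, neutral_profile(age=65.0).with_factors(**{factor: True})
            )
            assert p > base, factor

    def test_lower_tscore_increases_probability(self, base_model):
        p0 = probability(base_model, neutral_profile(age=65.0, tscore=-1.0))
        p1 = probability(base_model, neutral_profile(age=65.0, tscore=-2.5))
        assert p1 > p0

    def test_scaled_model_lower_everywhere(self, base_model, scaled_model):
        rng = np.random.default_rng(3)
        for _ in range(10):
            prof = neutral_profile(
                age=float(rng.integers(50, 85)),
                sex=("female", "male")[int(rng.integers(2))],
                tscore=float(rng.uniform(-3.5, 0)),
                prior_fracture=bool(rng.integers(2)),
                current_smoking=bool(rng.integers(2)),
            )
            for outcome in ("hip", "mof"):
                assert probability(scaled_model, prof, outcome) < probability(
                    base_model, prof, outcome
                )

    def test_ten_year_age_range_enforced(self, base_model):
        with pytest.raises(ValueError, match="40-90"):
            probability(base_model, neutral_profile(age=95.0), horizon="ten_year")
        # but lifetime outputs are available there
        assert probability(base_model, neutral_profile(age=95.0), horizon="lifetime") > 0

    def test_model_json_round_trip(self, base_model, tmp_path):
        path = tmp_path / "model.json"
        base_model.to_json(path)
        back = CountryModel.from_json(path)
        prof = neutral_profile(age=70.0, tscore=-2.0, prior_fracture=True)
        for outcome in ("hip", "mof"):
            assert probability(back, prof, outcome) == pytest.approx(
                probability(base_model, prof, outcome), rel=1e-12
            )
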