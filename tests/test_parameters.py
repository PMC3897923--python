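"""Parameter loading, validation, time conversions, life tables."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tkawait import (
    LifeTable,
    ParameterSet,
    annual_to_monthly_prob,
    bundled_config_path,
    load_parameters,
    monthly_discount_factor,
    monthly_mortality,
    read_life_table,
    write_life_table,
)
from tkawait.errors import ConfigurationError, FormatError, ValidationError
from tkawait.parameters import save_parameters


class TestAnnualToMonthly:
    @pytest.mark.parametrize(
        "annual,monthly",
        [
            (0.0, 0.0),
            (1.0, 1.0),
            (0.005, 1 - 0.995 ** (1 / 12)),  # = 0.00041762 to 1e-8
        ],
    )
    def test_closed_form(self, annual, monthly):
        assert annual_to_monthly_prob(annual) == pytest.approx(monthly, abs=1e-12)
        assert annual_to_monthly_prob(0.005) == pytest.approx(0.00041762, abs=1e-8)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            annual_to_monthly_prob(bad)

    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
    def test_twelve_cycle_inverse(self, p):
        m = annual_to_monthly_prob(p)
        assert 1 - (1 - m) ** 12 == pytest.approx(p, abs=1e-10)

    @given(st.floats(0.0, 0.999), st.floats(1e-6, 1e-3))
    def test_strictly_increasing(self, p, eps):
        assert annual_to_monthly_prob(min(p + eps, 1.0)) > annual_to_monthly_prob(p)


class TestDiscountFactor:
    def test_closed_forms(self):
        assert monthly_discount_factor(0.0) == 1.0
        # 1.03**(-1/12); twelve cycles compound to one annual step
        assert monthly_discount_factor(0.03) == pytest.approx(0.9975398, abs=1e-7)
        assert monthly_discount_factor(1.0) == pytest.approx(2 ** (-1 / 12), abs=1e-12)
        assert monthly_discount_factor(1.0) == pytest.approx(0.9438743, abs=1e-7)

    @given(st.floats(0.0, 2.0))
    def test_annual_compounding(self, r):
        assert monthly_discount_factor(r) ** 12 == pytest.approx(1 / (1 + r), rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            monthly_discount_factor(-0.01)


class TestParameterSet:
    def test_bundled_config_is_base_case(self):
        params, ranges = load_parameters(bundled_config_path())
        assert params.u_oa == 0.6
        assert params.c_tka == 26_865
        assert params.wait_months == 24
        assert params == ParameterSet()
        assert ranges["u_oa"].low == 0.4 and ranges["u_oa"].high == 0.8

    def test_ranges_straddle_base(self):
        params, ranges = load_parameters(bundled_config_path())
        base = params.to_dict()
        tiers = {
            "p_rev_primary_0_9": params.p_rev_primary_by_tier[0],
            "p_rev_primary_10_19": params.p_rev_primary_by_tier[1],
            "p_rev_primary_20plus": params.p_rev_primary_by_tier[2],
            "p_rev_revision_0_9": params.p_rev_revision_by_tier[0],
            "p_rev_revision_10_19": params.p_rev_revision_by_tier[1],
            "p_rev_revision_20plus": params.p_rev_revision_by_tier[2],
        }
        for name, r in ranges.items():
            value = tiers.get(name, base.get(name))
            assert r.low <= value <= r.high, name

    @pytest.mark.parametrize(
        "field,value",
        [
            ("u_oa", 1.2),
            ("dis_rev", 0.1),
            ("p_mort30_primary", -0.01),
            ("wait_months", -1),
            ("c_tka", -5.0),
            ("scenario", "C"),
        ],
    )
    def test_out_of_range_rejected(self, field, value):
        with pytest.raises(ValidationError):
            ParameterSet(**{field: value})

    def test_decreasing_tiers_warn_but_construct(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="tkawait.parameters"):
            p = ParameterSet(p_rev_primary_by_tier=(0.02, 0.01, 0.005))
        assert p.p_rev_primary_by_tier == (0.02, 0.01, 0.005)
        assert "non-decreasing" in caplog.text

    def test_empty_file_lists_all_missing_keys(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        with pytest.raises(ConfigurationError) as err:
            load_parameters(path)
        for key in ("u_oa", "c_tka", "wait_months", "p_mort30_revision"):
            assert key in str(err.value)

    def test_missing_key_named(self, tmp_path):
        params, ranges = load_parameters(bundled_config_path())
        doc = params.to_dict()
        del doc["c_rev"]
        import yaml

        path = tmp_path / "partial.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ConfigurationError, match="c_rev"):
            load_parameters(path)

    def test_roundtrip_exact(self, tmp_path):
        params, ranges = load_parameters(bundled_config_path())
        out = tmp_path / "copy.yaml"
        save_parameters(params, out, ranges)
        params2, ranges2 = load_parameters(out)
        assert params2 == params
        assert ranges2 == ranges

    def test_bridge_utility_fallback(self):
        p = ParameterSet(u_oa_bridge=None)
        assert p.bridge_wait_utility == pytest.approx(0.6 + 0.33 * 0.3)
        assert ParameterSet().bridge_wait_utility == 0.7


class TestLifeTable:
    def test_bundled_fixture_roundtrip(self, life_table, tmp_path):
        assert life_table.min_age == 0
        assert life_table.max_age == 110
        assert life_table.q_annual(110) == 1.0
        out = tmp_path / "lt.csv"
        write_life_table(life_table, out)
        lt2 = read_life_table(out)
        np.testing.assert_array_equal(lt2.ages, life_table.ages)
        np.testing.assert_allclose(lt2.qx, life_table.qx, rtol=0, atol=0)

    def test_two_row_table_valid(self):
        lt = LifeTable(np.array([60, 61]), np.array([0.01, 1.0]))
        assert lt.q_annual(60) == 0.01

    def test_age_gap_rejected(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("age,qx\n60,0.01\n62,0.02\n")
        with pytest.raises(FormatError):
            read_life_table(path)

    def test_q_out_of_bounds_rejected(self):
        with pytest.raises(ValidationError):
            LifeTable(np.array([60, 61]), np.array([0.01, 1.5]))

    def test_monthly_mortality_closed_form(self):
        lt = LifeTable(np.array([60, 61]), np.array([0.012, 1.0]))
        expected = 1 - 0.988 ** (1 / 12)
        assert monthly_mortality(lt, 60.5) == pytest.approx(expected, abs=1e-12)
        assert monthly_mortality(lt, 60.5) == pytest.approx(0.0010055, abs=1e-7)

    def test_piecewise_constant_within_year(self):
        lt = LifeTable(np.array([60, 61]), np.array([0.012, 0.5]))
        vals = {monthly_mortality(lt, 60 + k / 12) for k in range(12)}
        assert len(vals) == 1

    def test_above_max_age_forces_absorption(self):
        lt = LifeTable(np.array([60, 61]), np.array([0.01, 0.02]))
        assert monthly_mortality(lt, 75.0) == 1.0

    def test_below_min_age_rejected(self):
        lt = LifeTable(np.array([60, 61]), np.array([0.01, 0.02]))
        with pytest.raises(ValueError):
            monthly_mortality(lt, 59.0)

    def test_zero_q_gives_zero(self):
        lt = LifeTable(np.array([60, 61]), np.array([0.0, 1.0]))
        assert monthly_mortality(lt, 60.9) == 0.0
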