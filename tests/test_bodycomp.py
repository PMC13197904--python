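"""FFAT adjustment arithmetic, paired statistics, and sensitivity analyses
checked against closed-form and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leansift import bodycomp
from leansift.bodycomp import (diet_sensitivity, ffat_adjust,
                               loss_proportions, paired_change_summary,
                               regional_totals, tee_sensitivity)


class TestFFATAdjust:
    def test_cohort_mean_example(self):
        # 49.0 − 0.176·35.4 by hand
        adj = ffat_adjust(49.0, 35.4)
        assert adj.aLST == pytest.approx(42.7696, abs=1e-10)
        assert adj.adipose_tissue == pytest.approx(35.4 / 0.85)
        assert adj.FFAT == pytest.approx(35.4 / 0.85 - 35.4)

    def test_zero_fm(self):
        adj = ffat_adjust(50.0, 0.0)
        assert adj.aLST == 50.0 and adj.FFAT == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            ffat_adjust(-1.0, 5.0)
        with pytest.raises(ValueError):
            ffat_adjust(1.0, -5.0)

    @pytest.mark.parametrize("d_lst, d_fm, expected", [
        (-1.61, -4.28, -0.86),   # total body, female
        (-2.26, -4.92, -1.39),   # total body, male
        (-0.80, -2.09, -0.43),   # appendicular, female
        (-1.02, -1.87, -0.69),   # appendicular, male
    ])
    def test_adjustment_applied_to_mean_changes(self, d_lst, d_fm, expected):
        """Linearity: the correction applied to mean changes reproduces the
        adjusted mean changes (2 dp)."""
        assert round(bodycomp.adjust_change(d_lst, d_fm), 2) == expected

    @given(lst=st.floats(0, 100), fm=st.floats(0, 100),
           dl=st.floats(0.01, 10), df=st.floats(0.01, 10))
    @settings(derandomize=True, max_examples=50)
    def test_monotone(self, lst, fm, dl, df):
        base = ffat_adjust(lst, fm).aLST
        assert ffat_adjust(lst + dl, fm).aLST > base
        assert ffat_adjust(lst, fm + df).aLST < base

    def test_linearity_of_means(self, rng):
        lst = rng.normal(50, 5, 40)
        fm = rng.uniform(20, 40, 40)
        per_subject = ffat_adjust(lst, fm).aLST.mean()
        of_means = ffat_adjust(lst.mean(), fm.mean()).aLST
        assert per_subject == pytest.approx(of_means, rel=1e-12)


class TestRegionalTotals:
    def test_zero_scan(self):
        scan = pd.DataFrame({"region": list(bodycomp.APPENDICULAR_REGIONS)
                             + ["trunk", "head"],
                             "lst_kg": 0.0, "fm_kg": 0.0, "bmc_kg": 0.0})
        out = regional_totals(scan)
        assert (out.to_numpy() == 0).all()

    def test_trunk_only(self):
        scan = pd.DataFrame({"region": ["trunk"], "lst_kg": [30.0],
                             "fm_kg": [20.0], "bmc_kg": [2.0]})
        out = regional_totals(scan)
        assert out["mass_app"].item() == 0.0
        assert out["mass_total"].item() == pytest.approx(52.0)

    def test_sums_match_bruteforce(self, rng):
        regions = list(bodycomp.APPENDICULAR_REGIONS) + ["trunk", "head"]
        scan = pd.DataFrame({"region": regions,
                             "lst_kg": rng.uniform(1, 10, 6),
                             "fm_kg": rng.uniform(1, 10, 6),
                             "bmc_kg": rng.uniform(0.1, 1, 6)})
        out = regional_totals(scan)
        app = scan[scan.region.isin(bodycomp.APPENDICULAR_REGIONS)]
        assert out["lst_kg_total"].item() == pytest.approx(scan.lst_kg.sum())
        assert out["lst_kg_app"].item() == pytest.approx(app.lst_kg.sum())
        assert out["mass_total"].item() == pytest.approx(
            scan[["lst_kg", "fm_kg", "bmc_kg"]].to_numpy().sum())


class TestPairedChange:
    def test_closed_form_example(self):
        # diffs [−1, −2, −3]: mean −2, SE 1/√3, t crit 4.3027
        s = paired_change_summary([0, 0, 0], [-1, -2, -3])
        assert s.mean_diff == pytest.approx(-2.0)
        assert s.ci_lo == pytest.approx(-4.484, abs=5e-4)
        assert s.ci_hi == pytest.approx(0.484, abs=5e-4)

    def test_degenerate_zero_variance(self):
        s = paired_change_summary([1.0, 2.0], [1.0, 2.0])
        assert s.degenerate and np.isnan(s.p) and s.mean_diff == 0.0

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            paired_change_summary([1, 2], [1, 2, 3])

    def test_constant_shift_ci_shrinks(self, rng):
        x = rng.normal(0, 1, 400)
        noise = rng.normal(0, 1, 400)
        wide = paired_change_summary(x[:100], x[:100] + 2 + noise[:100])
        narrow = paired_change_summary(x, x + 2 + noise)
        assert abs(narrow.mean_diff - 2) < 0.5
        assert (narrow.ci_hi - narrow.ci_lo) < (wide.ci_hi - wide.ci_lo)


class TestLossProportions:
    def test_constant_fraction(self):
        d_mass = np.array([-4.0, -8.0, -2.0])
        med, (q1, q3), nex = loss_proportions(0.25 * d_mass, d_mass)
        assert med == 25.0 and q1 == q3 == 25.0 and nex == 0

    def test_interpolated_quartiles(self):
        # proportions 10, 20, 30, 40 under type-7 quantiles
        d_mass = np.full(4, -10.0)
        d_comp = np.array([-1.0, -2.0, -3.0, -4.0])
        med, (q1, q3), _ = loss_proportions(d_comp, d_mass)
        assert med == pytest.approx(25.0)
        assert (q1, q3) == (pytest.approx(17.5), pytest.approx(32.5))

    def test_zero_mass_change_excluded(self):
        med, _, nex = loss_proportions([1.0, 1.0], [-2.0, 0.0])
        assert nex == 1 and med == pytest.approx(-50.0)

    @given(k=st.floats(0.01, 100))
    @settings(derandomize=True, max_examples=30)
    def test_scale_invariance(self, k):
        d_comp = np.array([-1.0, -2.0, 0.5])
        d_mass = np.array([-4.0, -5.0, -3.0])
        a = loss_proportions(d_comp, d_mass)
        b = loss_proportions(k * d_comp, k * d_mass)
        assert a[0] == pytest.approx(b[0], rel=1e-9)


class TestDietSensitivity:
    def test_identical_groups(self):
        df = pd.DataFrame({"diet": ["HLC"] * 3 + ["HLF"] * 3,
                           "d_lst": [1.0, 2.0, 3.0] * 2})
        out = diet_sensitivity(df)
        assert out["stat"].item() == pytest.approx(0.0)
        assert out["p"].item() == pytest.approx(1.0)

    def test_ranksum_exact_p_by_enumeration(self):
        """{1,2,3} vs {4,5,6}: enumerate all C(6,3)=20 group assignments."""
        df = pd.DataFrame({"diet": ["A"] * 3 + ["B"] * 3,
                           "prop": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        out = diet_sensitivity(df, value_cols=(), prop_cols=("prop",))
        values = df["prop"].to_numpy()
        observed = values[:3].sum()
        null = [sum(c) for c in itertools.combinations(values, 3)]
        mean_null = np.mean(null)
        p_exact = np.mean([abs(s - mean_null) >= abs(observed - mean_null)
                           for s in null])
        assert out["p"].item() == pytest.approx(p_exact)  # = 0.1

    def test_single_group_error(self):
        df = pd.DataFrame({"diet": ["HLC"] * 4, "d_lst": range(4)})
        with pytest.raises(ValueError):
            diet_sensitivity(df)


class TestTEESensitivity:
    def test_constant_outcome(self):
        out = tee_sensitivity([1.0] * 6, np.arange(6.0), np.arange(6.0),
                              ["HLC", "HLF"] * 3)
        slopes = out[out.term != "const"]["coef"]
        assert np.allclose(slopes, 0.0, atol=1e-10)

    def test_exact_linear_case(self):
        tee = np.array([30.0, 32, 34, 36, 38, 40])
        out = tee_sensitivity(2 * tee, tee, tee, ["HLC"] * 3 + ["HLF"] * 3)
        coef = out.set_index("term")["coef"]
        assert coef["tee_mean"] == pytest.approx(2.0)

    def test_matches_normal_equations(self, rng):
        tee3 = rng.uniform(25, 45, 6)
        tee6 = tee3 + rng.normal(0, 2, 6)
        diet = ["HLC", "HLF", "HLC", "HLF", "HLC", "HLF"]
        y = rng.normal(-2, 1, 6)
        out = tee_sensitivity(y, tee3, tee6, diet)
        X = np.column_stack([np.ones(6), (tee3 + tee6) / 2,
                             np.array([d == "HLF" for d in diet], float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(out["coef"].to_numpy(), beta, atol=1e-9)


def test_sex_summary_table_shape(small_cohort):
    subjects, scans, _ = small_cohort
    tab = bodycomp.sex_summary_table(subjects, scans, "total")
    assert set(tab["measure"]) == {"mass", "fm", "lst", "alst"}
    assert set(tab["sex"]) == {"female", "male"}
    # aLST change equals LST − 0.176·FM row-wise in the means
    for sex in ("female", "male"):
        sub = tab[tab.sex == sex].set_index("measure")
        assert sub.loc["alst", "mean_diff"] == pytest.approx(
            sub.loc["lst", "mean_diff"] - 0.176 * sub.loc["fm", "mean_diff"])
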