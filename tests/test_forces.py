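"""Neutrality regression, ENC-GC3s curve, PR2 coordinates, index correlations."""

import numpy as np
import pandas as pd
import pytest

from cubkit.forces import (
    enc_curve_points,
    enc_expected,
    enc_ratio,
    index_correlations,
    neutrality_fit,
    pr2_points,
)


def ols_oracle(x, y):
    """Closed-form simple OLS: slope = cov(x,y)/var(x)."""
    x, y = np.asarray(x), np.asarray(y)
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    intercept = y.mean() - slope * x.mean()
    r = np.corrcoef(x, y)[0, 1]
    return slope, intercept, r


class TestNeutralityFit:
    def test_identity_gives_slope_one(self):
        gc3 = np.linspace(0.2, 0.8, 20)
        t = pd.DataFrame({"gc3": gc3, "gc12": gc3})
        fit = neutrality_fit(t)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_gc12_gives_slope_zero(self):
        t = pd.DataFrame({"gc3": np.linspace(0.2, 0.8, 20), "gc12": 0.5})
        fit = neutrality_fit(t)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0.2, 0.8, 200)
        y = 0.4 * x + rng.normal(0, 0.02, 200)
        t = pd.DataFrame({"gc3": x, "gc12": y})
        fit = neutrality_fit(t)
        slope, intercept, r = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_constant_gc3_errors(self):
        t = pd.DataFrame({"gc3": [0.5] * 10, "gc12": np.linspace(0, 1, 10)})
        with pytest.raises(ValueError, match="GC3"):
            neutrality_fit(t)

    def test_too_few_genes_errors(self):
        t = pd.DataFrame({"gc3": [0.1, 0.9], "gc12": [0.2, 0.8]})
        with pytest.raises(ValueError):
            neutrality_fit(t)


class TestEncCurve:
    @pytest.mark.parametrize(
        "s,expected", [(0.5, 60.5), (1.0, 32.0), (0.0, 31.0)]
    )
    def test_expected_curve_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            enc_expected(1.2)

    def test_curve_shape_unimodal_peak_near_half(self):
        # the +s term shifts the peak a hair above s = 0.5 (argmax ~0.502)
        grid = np.linspace(0, 1, 1001)
        vals = enc_expected(grid)
        assert vals.max() == pytest.approx(60.5, abs=0.01)
        assert grid[vals.argmax()] == pytest.approx(0.5, abs=0.01)
        signs = np.sign(np.diff(vals))
        assert (np.diff(signs) != 0).sum() == 1  # single rise-then-fall
        assert vals[0] == pytest.approx(31.0) and vals[-1] == pytest.approx(32.0)

    def test_ratio_zero_when_observed_equals_expected(self):
        assert enc_ratio(enc_expected(0.3), 0.3) == pytest.approx(0.0)

    def test_ratio_arithmetic(self):
        assert enc_ratio(48.0, 0.5) == pytest.approx((60.5 - 48) / 60.5)

    def test_ratio_positive_when_observed_below_curve(self):
        assert enc_ratio(40.0, 0.5) > 0

    def test_curve_points_frame(self):
        t = pd.DataFrame({"gc3s": [0.5, 0.3], "enc": [50.0, 45.0]})
        pts = enc_curve_points(t)
        assert pts.loc[0, "enc_exp"] == pytest.approx(60.5)
        assert pts.loc[0, "enc_ratio"] == pytest.approx((60.5 - 50) / 60.5)


class TestPr2:
    def test_balanced_third_bases_at_center(self):
        t = pd.DataFrame({"a3": [5], "t3": [5], "g3": [5], "c3": [5]})
        pts, occ = pr2_points(t)
        assert pts.loc[0, "x"] == 0.5 and pts.loc[0, "y"] == 0.5

    def test_zero_denominator_flagged_and_excluded(self):
        t = pd.DataFrame({"a3": [0, 2], "t3": [0, 2], "g3": [0, 5], "c3": [9, 1]})
        pts, occ = pr2_points(t)
        assert not pts.loc[0, "valid"]
        assert pts.loc[0, "quadrant"] == "undefined"
        assert occ.sum() == pytest.approx(1.0)

    def test_quadrant_labels(self):
        t = pd.DataFrame({"a3": [8, 1], "t3": [2, 9], "g3": [8, 1], "c3": [2, 9]})
        pts, occ = pr2_points(t)
        assert list(pts["quadrant"]) == ["GA", "CT"]

    def test_synthetic_third_base_ratios_match_sampler_law(self, mutation_table):
        """Mean PR2 coordinates track the generator's analytic third-base
        probabilities.  Note y = A3/(A3+T3) sits below 0.5 even under
        strand-symmetric bias: dropping the stop codons (third bases A, G, A)
        depletes third-position A among sense codons."""
        from cubkit.genetic_code import ALL_CODONS, bacterial_code
        from cubkit.synthetic import _mutation_codon_probs

        code = bacterial_code()
        _, table, truth = mutation_table
        pts, _ = pr2_points(table)
        valid = pts[pts["valid"]]
        xs, ys = [], []
        for theta in truth.loc[valid.index, "theta"]:
            p = _mutation_codon_probs(theta, code)
            third = {b: sum(p[i] for i, c in enumerate(ALL_CODONS) if c[2] == b)
                     for b in "ACGT"}
            xs.append(third["G"] / (third["G"] + third["C"]))
            ys.append(third["A"] / (third["A"] + third["T"]))
        assert abs(valid["x"].mean() - np.mean(xs)) < 0.02
        assert abs(valid["y"].mean() - np.mean(ys)) < 0.02


class TestIndexCorrelations:
    def test_independent_columns_mostly_insignificant(self, rng):
        t = pd.DataFrame({
            "cai": rng.normal(size=1000), "enc": rng.normal(size=1000),
            "gc3": rng.normal(size=1000),
        })
        df = index_correlations(t, ["cai", "enc", "gc3"])
        assert (df["r"].abs() < 0.1).all()
        assert (df["p"] > 0.01).all()

    def test_matches_direct_formula_oracle(self, rng):
        x = rng.normal(size=300)
        y = 0.5 * x + rng.normal(size=300)
        t = pd.DataFrame({"cai": x, "enc": y, "gc": rng.normal(size=300)})
        df = index_correlations(t, ["cai", "enc", "gc"]).set_index(["index_a", "index_b"])
        r_direct = np.corrcoef(x, y)[0, 1]
        assert df.loc[("cai", "enc"), "r"] == pytest.approx(r_direct, abs=1e-12)

    def test_constant_column_yields_nan_not_error(self):
        t = pd.DataFrame({"aromo": [0.08] * 10,
                          "cai": np.linspace(0, 1, 10),
                          "enc": np.linspace(30, 60, 10)})
        df = index_correlations(t, ["aromo", "cai", "enc"])
        sub = df[(df["index_a"] == "aromo")]
        assert sub["r"].isna().all()

    def test_significance_flags_consistent(self, mutation_table):
        _, table, _ = mutation_table
        df = index_correlations(table)
        ok = df["p"].notna()
        assert (df.loc[ok, "sig_01"] <= df.loc[ok, "sig_05"]).all()
        assert ((df.loc[ok, "p"] < 0.05) == df.loc[ok, "sig_05"]).all()
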