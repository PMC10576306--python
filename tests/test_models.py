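"""Per-wavelength ANOVA/OLS/LMM, Tukey contrasts, BY adjustment, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from specvar.errors import DesignError, ParameterError
from specvar.models import (
    ModelSpec,
    adjust_bh,
    adjust_by,
    design_matrix,
    fit_anova_spectrum,
    fit_lmm_spectrum,
    fit_ols_spectrum,
    select_model_aic,
    significant_regions,
    tukey_posthoc,
)

from conftest import make_reflectance_set


def _meta(**cols):
    n = len(next(iter(cols.values())))
    df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(n)], **cols})
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli
# ---------------------------------------------------------------------------

class TestAdjustBY:
    def test_single_test_unchanged(self):
        np.testing.assert_allclose(adjust_by([0.03]), [0.03])

    def test_hand_computed_triple(self):
        # m=3, c(3)=11/6: scaled = [0.055, 0.055, 0.0733...], step-up keeps order
        out = adjust_by([0.01, 0.02, 0.04])
        np.testing.assert_allclose(out, [0.055, 0.055, 0.0733333333], atol=1e-9)

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_by(np.ones(10)), np.ones(10))

    def test_matches_reference_implementation(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=200) ** 2
        ours = adjust_by(p)
        theirs = multipletests(p, method="fdr_by")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_dominates_bh_and_is_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        by = adjust_by(p)
        bh = adjust_bh(p)
        assert (by >= bh - 1e-15).all()
        assert (by >= p - 1e-15).all()
        # monotone: shrinking one raw p never increases any adjusted p
        q = p.copy()
        q[13] *= 0.5
        assert (adjust_by(q) <= by + 1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ParameterError):
            adjust_by([0.1, 1.4])
        with pytest.raises(ParameterError):
            adjust_by([0.1, np.nan])


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

class TestANOVA:
    def test_identical_groups(self):
        cr = np.tile([[0.5]], (6, 1))
        rs = make_reflectance_set(cr, _meta(experiment=["A", "A", "A", "B", "B", "B"]))
        res = fit_anova_spectrum(rs, "experiment", eta_ci=False)
        assert res.stats["F"].iloc[0] == 0.0
        assert res.stats["eta2"].iloc[0] == 0.0

    def test_hand_computed_two_groups(self):
        cr = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        rs = make_reflectance_set(cr, _meta(experiment=["A", "A", "A", "B", "B", "B"]))
        res = fit_anova_spectrum(rs, "experiment")
        row = res.stats.iloc[0]
        assert row["F"] == pytest.approx(13.5)
        assert (row["df1"], row["df2"]) == (1, 4)
        assert row["eta2"] == pytest.approx(27 / 35)
        assert 0 < row["eta2_ci_low"] < row["eta2"]
        assert row["eta2_ci_high"] == 1.0

    def test_null_rejection_rate(self):
        """Three groups from one normal: ~5% of raw p-values fall below 0.05."""
        rng = np.random.default_rng(7)
        cr = rng.normal(0.3, 0.01, size=(30, 2101))
        rs = make_reflectance_set(cr, _meta(experiment=np.repeat(["A", "B", "C"], 10)))
        res = fit_anova_spectrum(rs, "experiment", eta_ci=False)
        frac = (res.stats["p_raw"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.03

    def test_eta_ci_zero_when_not_significant(self):
        cr = np.array([[0.1], [0.11], [0.09], [0.1], [0.12], [0.08]])
        rs = make_reflectance_set(cr, _meta(experiment=["A", "A", "A", "B", "B", "B"]))
        res = fit_anova_spectrum(rs, "experiment")
        assert res.stats["eta2_ci_low"].iloc[0] == 0.0

    def test_small_level_rejected(self):
        cr = np.zeros((3, 2))
        rs = make_reflectance_set(cr, _meta(experiment=["A", "A", "B"]))
        with pytest.raises(DesignError):
            fit_anova_spectrum(rs, "experiment")


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

class TestOLS:
    def test_constant_response(self):
        cr = np.full((8, 2), 0.4)
        rs = make_reflectance_set(cr, _meta(genotype_group=list("AABBCCDD")))
        res = fit_ols_spectrum(rs, ModelSpec(fixed=("genotype_group",)))
        assert (res.stats["r2"] == 0).all()
        slopes = res.coefficients[res.coefficients["term"] != "Intercept"]
        np.testing.assert_allclose(slopes["estimate"], 0.0, atol=1e-12)

    def test_exact_group_effect(self):
        y = np.array([0.0, 0.0, 0.0, 2.0, 2.0, 2.0])[:, None]
        rs = make_reflectance_set(y, _meta(genotype_group=list("AAABBB")))
        res = fit_ols_spectrum(rs, ModelSpec(fixed=("genotype_group",)))
        b = res.coefficients.set_index("term")["estimate"]
        assert b["genotype_group[B]"] == pytest.approx(2.0, abs=1e-12)
        assert res.stats["r2"].iloc[0] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        meta = _meta(
            genotype_group=rng.choice(list("ABC"), 24),
            time_window=rng.choice(["am", "noon"], 24),
        )
        cr = rng.normal(0.3, 0.05, size=(24, 3))
        rs = make_reflectance_set(cr, meta)
        spec = ModelSpec(fixed=("genotype_group", "time_window"))
        res = fit_ols_spectrum(rs, spec)
        X, names, _ = design_matrix(meta, spec)
        for j in range(3):
            beta = np.linalg.solve(X.T @ X, X.T @ cr[:, j])
            got = (
                res.coefficients[res.coefficients["wavelength"] == rs.wavelengths[j]]
                .set_index("term")
                .loc[names, "estimate"]
                .to_numpy()
            )
            np.testing.assert_allclose(got, beta, atol=1e-10)

    def test_wald_ci_coverage(self):
        """95% Wald CIs cover the true coefficient 90-99% of the time."""
        rng = np.random.default_rng(4)
        n, reps = 200, 500
        groups = rng.choice(list("AB"), n)
        meta = _meta(genotype_group=groups)
        true_beta = 0.03
        y = 0.2 + true_beta * (groups == "B")[:, None] + rng.normal(0, 0.05, (n, reps))
        rs = make_reflectance_set(y, meta, wavelengths=np.arange(400, 400 + reps))
        res = fit_ols_spectrum(rs, ModelSpec(fixed=("genotype_group",)), adjust=False)
        cf = res.coefficients[res.coefficients["term"] == "genotype_group[B]"]
        covered = ((cf["ci_low"] <= true_beta) & (true_beta <= cf["ci_high"])).mean()
        assert 0.90 <= covered <= 0.99

    def test_aic_matches_gaussian_formula(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.3, 0.02, size=(12, 1))
        rs = make_reflectance_set(y, _meta(genotype_group=list("AAABBBCCCDDD")))
        res = fit_ols_spectrum(rs, ModelSpec(fixed=("genotype_group",)))
        import statsmodels.api as sm

        X, _, _ = design_matrix(rs.meta_aligned(), ModelSpec(fixed=("genotype_group",)))
        ref = sm.OLS(y[:, 0], X).fit()
        # statsmodels does not count sigma^2 as an estimated parameter;
        # the R lm convention used here does, adding exactly 2 to AIC
        assert res.stats["aic"].iloc[0] == pytest.approx(ref.aic + 2.0, abs=1e-8)

    def test_rank_deficiency_names_aliased_terms(self):
        meta = _meta(genotype_group=list("AABB"), time_window=["am", "am", "pm", "pm"])
        cr = np.zeros((4, 1)) + 0.3
        rs = make_reflectance_set(cr, meta)
        with pytest.raises(DesignError, match="aliased"):
            fit_ols_spectrum(rs, ModelSpec(fixed=("genotype_group", "time_window")))


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

def _lmm_data(seed, n_plants=20, n_times=3, var_plant=0.04, var_resid=0.01, effect=0.05):
    rng = np.random.default_rng(seed)
    plant = np.repeat([f"P{i}" for i in range(n_plants)], n_times)
    time = np.tile(["am", "noon", "pm"][:n_times], n_plants)
    b = rng.normal(0, np.sqrt(var_plant), n_plants)
    y = (
        0.3
        + effect * (time == "noon")
        + np.repeat(b, n_times)
        + rng.normal(0, np.sqrt(var_resid), n_plants * n_times)
    )
    meta = _meta(plant_id=plant, time_window=time)
    rs = make_reflectance_set(y[:, None], meta, wavelengths=[500])
    return rs


def _reml_profile_oracle(y, X, groups):
    """Brute-force profiled REML for a random-intercept model.

    Maximizes the REML criterion over the variance ratio theta = var_b/var_e
    by direct numerical optimization of the closed-form profile.
    """
    y = np.asarray(y, float)
    n, p = X.shape
    labels, inv = np.unique(groups, return_inverse=True)
    Z = np.zeros((n, len(labels)))
    Z[np.arange(n), inv] = 1.0

    def neg_reml(log_theta):
        theta = np.exp(log_theta)
        W = np.eye(n) + theta * Z @ Z.T
        Wi = np.linalg.inv(W)
        XtWiX = X.T @ Wi @ X
        beta = np.linalg.solve(XtWiX, X.T @ Wi @ y)
        r = y - X @ beta
        s2 = (r @ Wi @ r) / (n - p)
        _, ld_w = np.linalg.slogdet(W)
        _, ld_x = np.linalg.slogdet(XtWiX)
        return (n - p) * np.log(s2) + ld_w + ld_x

    res = optimize.minimize_scalar(neg_reml, bounds=(-15, 10), method="bounded")
    theta = np.exp(res.x)
    W = np.eye(n) + theta * Z @ Z.T
    Wi = np.linalg.inv(W)
    beta = np.linalg.solve(X.T @ Wi @ X, X.T @ Wi @ y)
    r = y - X @ beta
    s2 = (r @ Wi @ r) / (n - p)
    return theta * s2, s2, beta


class TestLMM:
    def test_matches_profiled_reml_oracle(self):
        rs = _lmm_data(seed=0)
        spec = ModelSpec(fixed=("time_window",), random="plant_id")
        res = fit_lmm_spectrum(rs, spec)
        X, names, _ = design_matrix(rs.meta_aligned(), spec)
        vb, ve, beta = _reml_profile_oracle(rs.cr[:, 0], X, rs.meta_aligned()["plant_id"])
        row = res.stats.iloc[0]
        assert row["var_random"] == pytest.approx(vb, rel=1e-3)
        assert row["var_resid"] == pytest.approx(ve, rel=1e-3)
        got = res.coefficients.set_index("term").loc[names, "estimate"].to_numpy()
        np.testing.assert_allclose(got, beta, atol=1e-6)

    def test_zero_group_variance_matches_ols(self):
        # responses independent of plant: REML pushes var_random to zero
        rng = np.random.default_rng(12)
        n_plants, n_times = 12, 3
        plant = np.repeat([f"P{i}" for i in range(n_plants)], n_times)
        time = np.tile(["am", "noon", "pm"], n_plants)
        y = 0.3 + 0.02 * (time == "noon") + rng.normal(0, 0.01, n_plants * n_times)
        meta = _meta(plant_id=plant, time_window=time)
        rs = make_reflectance_set(y[:, None], meta, wavelengths=[500])
        spec = ModelSpec(fixed=("time_window",), random="plant_id")
        lmm = fit_lmm_spectrum(rs, spec)
        ols = fit_ols_spectrum(rs, ModelSpec(fixed=("time_window",)))
        row = lmm.stats.iloc[0]
        if row["boundary"]:
            a = lmm.coefficients.set_index("term")["estimate"]
            b = ols.coefficients.set_index("term")["estimate"]
            np.testing.assert_allclose(a[b.index], b, atol=1e-6)
            assert row["conditional_r2"] == pytest.approx(row["marginal_r2"], abs=1e-9)
        else:  # tiny but nonzero variance: still near-identical fits
            assert row["var_random"] < 1e-4

    def test_marginal_not_above_conditional(self):
        for seed in range(3):
            rs = _lmm_data(seed=seed)
            res = fit_lmm_spectrum(rs, ModelSpec(fixed=("time_window",), random="plant_id"))
            row = res.stats.iloc[0]
            assert row["marginal_r2"] <= row["conditional_r2"] + 1e-12
            assert 0 <= row["marginal_r2"] <= 1 and 0 <= row["conditional_r2"] <= 1

    def test_variance_component_recovery(self):
        """Median recovered variance components near truth over replicates."""
        vb_err, ve_err = [], []
        spec = ModelSpec(fixed=("time_window",), random="plant_id")
        for seed in range(30):
            rs = _lmm_data(seed=100 + seed, n_plants=50)
            row = fit_lmm_spectrum(rs, spec).stats.iloc[0]
            vb_err.append(abs(row["var_random"] - 0.04) / 0.04)
            ve_err.append(abs(row["var_resid"] - 0.01) / 0.01)
        assert np.median(vb_err) < 0.25
        assert np.median(ve_err) < 0.25


# ---------------------------------------------------------------------------
# Tukey post-hoc
# ---------------------------------------------------------------------------

class TestTukey:
    def test_two_levels_equals_t_test(self):
        rng = np.random.default_rng(8)
        y = np.concatenate([rng.normal(0.3, 0.02, 6), rng.normal(0.35, 0.02, 6)])
        meta = _meta(genotype_group=list("AAAAAABBBBBB"))
        rs = make_reflectance_set(y[:, None], meta, wavelengths=[500])
        tk = tukey_posthoc(rs, ModelSpec(fixed=("genotype_group",)), "genotype_group")
        t, p = stats.ttest_ind(y[:6], y[6:])
        assert tk["p_raw"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_three_groups_separated_mean(self):
        rng = np.random.default_rng(9)
        y = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(5, 1, 10)]
        )
        meta = _meta(genotype_group=["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        rs = make_reflectance_set(y[:, None], meta, wavelengths=[500])
        tk = tukey_posthoc(
            rs, ModelSpec(fixed=("genotype_group",)), "genotype_group", adjust=False
        ).set_index("contrast")
        assert tk.loc["A - C", "p_raw"] < 1e-6
        assert tk.loc["B - C", "p_raw"] < 1e-6
        assert tk.loc["A - B", "p_raw"] > 0.05  # null contrast stays non-significant

    def test_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(10)
        y = rng.normal(0.3, 0.05, 18)
        labels = np.array(list("ABC") * 6)
        meta = _meta(genotype_group=labels)
        rs = make_reflectance_set(y[:, None], meta, wavelengths=[500])
        ours = tukey_posthoc(
            rs, ModelSpec(fixed=("genotype_group",)), "genotype_group", adjust=False
        )
        ref = pairwise_tukeyhsd(y, labels)
        np.testing.assert_allclose(
            np.sort(ours["p_raw"].to_numpy()), np.sort(ref.pvalues), atol=1e-6
        )


# ---------------------------------------------------------------------------
# AIC forward selection
# ---------------------------------------------------------------------------

def _selection_data(seed, interaction=0.0, n_per_cell=4):
    rng = np.random.default_rng(seed)
    cells = [(a, b, c) for a in "ABC" for b in ("am", "noon") for c in (1, 2)]
    rows = [cell for cell in cells for _ in range(n_per_cell)]
    A = np.array([r[0] for r in rows])
    B = np.array([r[1] for r in rows])
    C = np.array([r[2] for r in rows])
    n = len(rows)
    y = (
        0.3
        + 0.05 * (A == "B")
        + 0.08 * (A == "C")
        + 0.04 * (B == "noon")
        + 0.03 * (C == 2)
        + interaction * ((A == "C") & (B == "noon"))
    )
    cr = y[:, None] + rng.normal(0, 0.02, (n, 4))
    meta = _meta(genotype_group=A, time_window=B, leaf_number=C)
    return make_reflectance_set(cr, meta, wavelengths=[450, 550, 650, 750])


BASE = ModelSpec(fixed=("genotype_group", "time_window", "leaf_number"))
FULL = ModelSpec(
    fixed=BASE.fixed,
    interactions=(
        ("genotype_group", "time_window"),
        ("genotype_group", "leaf_number"),
        ("time_window", "leaf_number"),
    ),
)


class TestModelSelection:
    def test_base_equals_full_returned_unchanged(self):
        rs = _selection_data(0)
        out = select_model_aic(rs, BASE, BASE, [450, 550, 650, 750])
        assert out == BASE

    def test_no_interaction_data_selects_base(self):
        hits = 0
        reps = 40
        for seed in range(reps):
            rs = _selection_data(seed)
            out = select_model_aic(rs, BASE, FULL, [450, 550, 650, 750])
            hits += out.interactions == ()
        assert hits / reps >= 0.9

    def test_strong_interaction_detected(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            rs = _selection_data(1000 + seed, interaction=0.2)
            out = select_model_aic(rs, BASE, FULL, [450, 550, 650, 750])
            hits += ("genotype_group", "time_window") in out.interactions
        assert hits / reps >= 0.9

    def test_two_main_effects_direct_comparison(self):
        rs = _selection_data(5, interaction=0.2)
        base2 = ModelSpec(fixed=("genotype_group", "time_window"))
        full2 = ModelSpec(
            fixed=base2.fixed, interactions=(("genotype_group", "time_window"),)
        )
        out = select_model_aic(rs, base2, full2, [450, 550, 650, 750])
        assert out == full2


# ---------------------------------------------------------------------------
# significant regions
# ---------------------------------------------------------------------------

class TestRegions:
    def test_single_run(self):
        wl = np.arange(400, 500)
        p = np.ones(100)
        p[0:21] = 0.01  # 400-420 nm
        regions = significant_regions(p, wl, alpha=0.05)
        assert [(r.start_nm, r.end_nm) for r in regions] == [(400, 420)]

    def test_empty(self):
        assert significant_regions(np.ones(50), np.arange(400, 450)) == []

    def test_two_runs_split_by_one_wavelength(self):
        wl = np.arange(400, 410)
        p = np.full(10, 0.01)
        p[5] = 0.2
        regions = significant_regions(p, wl)
        assert [(r.start_nm, r.end_nm) for r in regions] == [(400, 404), (406, 409)]
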