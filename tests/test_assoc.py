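"""Logistic IRLS, trend and genotype models, case-only age test."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2, norm, spearmanr

from malebc import SnpSimSpec, ValidationError, fit_logistic, raf, trend_test
from malebc.assoc import (
    Z975,
    age_at_onset_test,
    age_stratified_trend,
    analyze_panel,
    analyze_snp,
    genotype_model_test_from_counts,
    trend_test_from_counts,
)
from malebc.cohort_sim import genotype_probabilities, simulate_genotype_counts


# ---------------------------------------------------------------------------
# independent grid-search oracle for the trend model on a 2x3 count table
# ---------------------------------------------------------------------------

def _count_loglik(alpha, beta, case, ctrl):
    g = np.array([0.0, 1.0, 2.0])
    eta = alpha + beta * g
    return float(np.sum(case * (eta - np.logaddexp(0, eta)) - ctrl * np.logaddexp(0, eta)))


def _profile_alpha(beta, case, ctrl):
    g = np.array([0.0, 1.0, 2.0])

    def score(alpha):
        mu = expit(alpha + beta * g)
        return float(np.sum(case - (case + ctrl) * mu))

    return brentq(score, -30, 30, xtol=1e-12)


def grid_search_trend_oracle(case, ctrl):
    """Profile-likelihood grid search: coarse pass over [-3, 3], then a
    1e-4-step fine pass around the coarse optimum."""
    case, ctrl = np.asarray(case, float), np.asarray(ctrl, float)

    def profiled(beta):
        return _count_loglik(_profile_alpha(beta, case, ctrl), beta, case, ctrl)

    coarse = np.arange(-3.0, 3.0 + 1e-9, 0.01)
    ll = [profiled(b) for b in coarse]
    b0 = coarse[int(np.argmax(ll))]
    fine = np.arange(b0 - 0.02, b0 + 0.02 + 1e-12, 1e-4)
    llf = [profiled(b) for b in fine]
    j = int(np.argmax(llf))
    beta_hat = fine[j]
    # intercept-only maximum has the closed form ln(cases/controls)
    a0 = np.log(case.sum() / ctrl.sum())
    ll0 = _count_loglik(a0, 0.0, case, ctrl)
    return beta_hat, llf[j], ll0


CASE_COUNTS = np.array([30.0, 50.0, 20.0])
CTRL_COUNTS = np.array([45.0, 40.0, 15.0])


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        X = np.ones((2, 1))
        y = np.array([1.0, 0.0])
        fit = fit_logistic(X, y, sample_weight=np.array([40.0, 60.0]))
        assert fit.beta[0] == pytest.approx(np.log(40 / 60), abs=1e-10)

    def test_two_by_two_saturated_closed_form(self):
        # (a,b;c,d) = (10,20;20,10): slope = ln(ad/bc) = ln(0.25)
        X = np.array([[1, 1], [1, 1], [1, 0], [1, 0]], float)
        y = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([10.0, 20.0, 20.0, 10.0])
        fit = fit_logistic(X, y, w)
        assert fit.beta[1] == pytest.approx(np.log(0.25), abs=1e-8)

    def test_loglikelihood_nondecreasing_over_iterations(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X = np.column_stack([np.ones(80), rng.normal(size=(80, 2))])
            y = (rng.random(80) < expit(X @ np.array([0.3, 1.0, -2.0]))).astype(float)
            fit = fit_logistic(X, y)
            diffs = np.diff(fit.ll_path)
            assert (diffs >= -1e-9).all()

    def test_separation_is_flagged_not_raised(self):
        X = np.array([[1, 0], [1, 1]], float)
        y = np.array([0.0, 1.0])
        w = np.array([30.0, 30.0])
        fit = fit_logistic(X, y, w)
        assert not fit.converged

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones((3, 1)), np.ones(3))


class TestTrendTest:
    def test_matches_grid_search_oracle(self):
        beta_o, ll1_o, ll0_o = grid_search_trend_oracle(CASE_COUNTS, CTRL_COUNTS)
        or_hat, _, p, fit = trend_test_from_counts(CASE_COUNTS, CTRL_COUNTS)
        assert np.log(or_hat) == pytest.approx(beta_o, abs=1e-3)
        p_oracle = chi2.sf(2 * (ll1_o - ll0_o), df=1)
        assert p == pytest.approx(p_oracle, abs=1e-6)

    def test_null_identity(self):
        or_hat, _, p = trend_test(
            pd.array([0, 1, 2, 0, 1, 2] * 10, dtype="Int8"),
            np.array([1, 1, 1, 0, 0, 0] * 10),
        )
        assert or_hat == pytest.approx(1.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_large_cohort_recovers_generating_or(self):
        rng = np.random.default_rng(8)
        snp = SnpSimSpec("rs", 0.27, 1.48)
        case, ctrl = simulate_genotype_counts(snp, 100_000, 100_000, rng)
        or_hat, _, _, _ = trend_test_from_counts(case, ctrl)
        assert 1.46 <= or_hat <= 1.50

    def test_monomorphic_flagged_with_p_one(self):
        or_hat, _, p, fit = trend_test_from_counts([10, 0, 0], [20, 0, 0])
        assert np.isnan(or_hat) and p == 1.0 and fit is None
        r = analyze_snp("rs", pd.array([0] * 30, dtype="Int8"), np.array([1] * 10 + [0] * 20))
        assert "monomorphic" in r.flags

    def test_missing_genotypes_dropped_complete_case(self):
        g = pd.array([0, 1, 2, None, 0, 1, 2, None], dtype="Int8")
        s = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        or_hat, _, p = trend_test(g, s)
        assert or_hat == pytest.approx(1.0, abs=1e-8)

    def test_single_arm_rejected(self):
        with pytest.raises(ValidationError):
            trend_test_from_counts([10, 5, 1], [0, 0, 0])

    def test_ci_brackets_estimate_and_wald_matches_lrt_ordering(self):
        # CI invariant plus rank agreement of Wald and LRT p-values across a panel
        rng = np.random.default_rng(10)
        p_lrt, p_wald = [], []
        for psi in np.linspace(0.8, 1.6, 12):
            snp = SnpSimSpec("rs", float(rng.uniform(0.1, 0.6)), float(psi))
            case, ctrl = simulate_genotype_counts(snp, 433, 1569, rng)
            or_hat, (lo, hi), p, fit = trend_test_from_counts(case, ctrl)
            assert lo <= or_hat <= hi
            se = fit.se[1]
            z = abs(np.log(or_hat)) / se
            p_lrt.append(p)
            p_wald.append(2 * norm.sf(z))
        rho = spearmanr(p_lrt, p_wald).statistic
        assert rho >= 0.99


class TestGenotypeModel:
    def test_saturated_table_equals_cross_product_ratios(self):
        # cases (10,20,10) / controls (20,20,10)
        or_het, or_hom, ci_h, ci_hh, p, flags = genotype_model_test_from_counts(
            [10, 20, 10], [20, 20, 10]
        )
        assert or_het == pytest.approx((20 * 20) / (10 * 20), abs=1e-8)
        assert or_hom == pytest.approx((10 * 20) / (10 * 10), abs=1e-8)
        assert not flags

    def test_equal_rows_give_unit_ors(self):
        or_het, or_hom, *_ , p, flags = genotype_model_test_from_counts(
            [30, 40, 30], [30, 40, 30]
        )
        assert or_het == pytest.approx(1.0, abs=1e-8)
        assert or_hom == pytest.approx(1.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_multiplicative_large_n_or_hom_is_or_het_squared(self):
        # expected counts under the multiplicative model at large n
        snp = SnpSimSpec("rs", 0.3, 1.4)
        case = genotype_probabilities(snp, "case") * 1e6
        ctrl = genotype_probabilities(snp, "control") * 1e6
        or_het, or_hom, *_ = genotype_model_test_from_counts(case, ctrl)
        or_t, _, _, _ = trend_test_from_counts(case, ctrl)
        assert or_hom == pytest.approx(or_het**2, rel=1e-6)
        assert or_hom == pytest.approx(or_t**2, rel=1e-6)

    def test_empty_genotype_class_flagged_other_or_estimated(self):
        or_het, or_hom, *_ , p, flags = genotype_model_test_from_counts(
            [10, 20, 0], [20, 20, 0]
        )
        assert "class_2_empty" in flags
        assert np.isnan(or_hom)
        assert or_het == pytest.approx(2.0, abs=1e-8)


class TestRaf:
    def test_all_risk_homozygous(self):
        assert raf(pd.array([2, 2, 2], dtype="Int8")) == 1.0

    def test_count_arithmetic(self):
        # genotype counts (5,3,1): (3 + 2) / 18
        g = pd.array([0] * 5 + [1] * 3 + [2], dtype="Int8")
        assert raf(g) == pytest.approx(5 / 18)

    def test_sampling_bound_on_simulated_controls(self):
        rng = np.random.default_rng(3)
        snp = SnpSimSpec("rs", 0.42, 1.0)
        g = rng.choice(3, size=10_000, p=genotype_probabilities(snp, "control"))
        assert raf(g) == pytest.approx(0.42, abs=0.01)

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            raf(pd.array([None, None], dtype="Int8"))


class TestAgeAtOnset:
    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(6)
        n = 5000
        ages = np.clip(np.round(rng.normal(65, 10, n)), 30, 85)
        p_allele = expit(0.3 + 0.02 * (ages - 65))
        g = rng.binomial(2, p_allele)
        gamma, p = age_at_onset_test(g, ages)
        assert gamma == pytest.approx(0.02, abs=0.005)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            ages = rng.uniform(40, 80, 400)
            g = rng.binomial(2, 0.3, 400)
            _, p = age_at_onset_test(g, ages)
            rejections += p <= 0.05
        rate = rejections / n_reps
        assert abs(rate - 0.05) < 0.03

    def test_constant_age_rejected(self):
        with pytest.raises(ValidationError):
            age_at_onset_test(np.array([0, 1, 2]), np.array([60.0, 60.0, 60.0]))

    def test_age_strata_sizes_reproduce_crafted_manifest(self):
        # cases aged <60 (119), 60-69 (153), >=70 (161) versus all controls
        rng = np.random.default_rng(2)
        ages = np.concatenate([
            rng.integers(30, 60, 119),
            rng.integers(60, 70, 153),
            rng.integers(70, 80, 161),
        ])
        n_cases, n_ctrl = ages.size, 300
        manifest = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n_cases + n_ctrl)],
                "group": ["case"] * n_cases + ["control"] * n_ctrl,
                "age_at_diagnosis": pd.array(
                    list(ages) + [None] * n_ctrl, dtype="Int64"
                ),
            }
        )
        geno = pd.DataFrame(
            {"rs1": pd.array(rng.integers(0, 3, n_cases + n_ctrl), dtype="Int8")},
            index=pd.Index(manifest["sample_id"], name="sample_id"),
        )
        table = age_stratified_trend(manifest, geno)
        sizes = table.set_index("stratum")["n_cases"].to_dict()
        assert sizes == {"<60": 119, "60-69": 153, ">=70": 161}


def test_panel_table_shape_and_trend_significance(qc_cohort):
    manifest, genotypes, _ = qc_cohort
    table = analyze_panel(manifest, genotypes)
    assert len(table) == 12
    assert set(table["snp_id"]) == set(genotypes.columns)
    assert (table["n_used"] <= 2002).all()
    assert ((table["p_trend"] > 0) & (table["p_trend"] <= 1)).all()
    # CIs bracket the point estimates
    ok = table.dropna(subset=["or_trend"])
    assert ((ok["or_trend_low"] <= ok["or_trend"]) & (ok["or_trend"] <= ok["or_trend_high"])).all()


def test_null_trend_rejection_rate_calibrated():
    """Under psi = 1 at the study design size, the trend test rejects at the
    nominal 5% rate (within Monte-Carlo tolerance)."""
    snp = SnpSimSpec("rs", 0.3, 1.0)
    streams = np.random.SeedSequence(99).spawn(2000)
    rej = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        case, ctrl = simulate_genotype_counts(snp, 433, 1569, rng)
        _, _, p, _ = trend_test_from_counts(case, ctrl)
        rej += p <= 0.05
    assert abs(rej / 2000 - 0.05) <= 0.01


def test_cross_check_against_statsmodels_glm():
    """Independent route: statsmodels GLM binomial reproduces the IRLS
    coefficients and standard errors."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones(6), [0, 1, 2, 0, 1, 2]])
    y = np.array([1.0, 1, 1, 0, 0, 0])
    w = np.concatenate([CASE_COUNTS, CTRL_COUNTS])
    ours = fit_logistic(X, y, w)
    theirs = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
    assert ours.beta == pytest.approx(theirs.params, abs=1e-6)
    assert ours.se == pytest.approx(theirs.bse, abs=1e-6)
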