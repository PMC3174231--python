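"""Per-SNP case-control association via unconditional logistic regression.

The fitter is an iteratively reweighted least squares (IRLS / Newton-Raphson)
maximiser of the Bernoulli log-likelihood, with frequency weights so that
genotype-count tables fit in microseconds.  Two genetic models are fitted per
locus:

* multiplicative (trend): ``logit P(case) = a + b*g`` with dosage
  ``g in {0,1,2}``; per-allele OR ``exp(b)``, 1-df likelihood-ratio test;
* unconstrained genotype model: indicator coding of the heterozygote and
  risk-homozygote classes against the zero-copy baseline; 2-df LRT.

Headline p-values come from the likelihood-ratio statistic; the Wald
construction supplies the 95% confidence intervals that accompany each OR.
A case-only model tests whether the risk-allele count (binomial with two
trials per subject) trends with age at diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .cohort_sim import ValidationError

#: 97.5th percentile of the standard normal, pinned for reproducibility.
Z975 = 1.959964

#: |beta| beyond which a fit is flagged as (quasi-)separated.
SEPARATION_BOUND = 15.0


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit: coefficients on the log-odds scale,
    their covariance (inverse observed information), and convergence info."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    ll_path: list = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class AssocResult:
    """Per-SNP association summary (one row of the results table)."""

    snp_id: str
    raf_all: float
    or_het: float
    or_het_ci: tuple
    or_hom: float
    or_hom_ci: tuple
    or_trend: float
    or_trend_ci: tuple
    p_trend: float
    p_genotype: float
    n_used: int
    flags: list = field(default_factory=list)


def _loglik(eta: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    max_iter: int = 50,
    tol_ll: float = 1e-10,
    tol_grad: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood logistic regression by IRLS.

    Newton steps with step-halving, so the log-likelihood is non-decreasing
    across iterations (the trace is kept in ``ll_path``).  Convergence when
    the log-likelihood change falls below ``tol_ll`` or the gradient norm
    below ``tol_grad``.  Quasi-complete separation (any ``|beta| > 15``) is
    flagged as a non-converged result rather than raised.

    Parameters
    ----------
    X : (n, p) design matrix, full rank.
    y : binary outcome vector.
    sample_weight : optional non-negative frequency weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    used = w > 0
    if y[used].min() == y[used].max():
        raise ValidationError("outcome has a single class; logistic model undefined")

    p = X.shape[1]
    beta = np.zeros(p)
    ll = _loglik(X @ beta, y, w)
    path = [ll]
    converged = False
    it = 0
    H = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        wt = w * mu * (1.0 - mu)
        H = X.T @ (wt[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton: halve until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            ll_new = _loglik(X @ (beta + scale * step), y, w)
            if ll_new >= ll - 1e-13:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll_new = _loglik(X @ beta, y, w)
        path.append(ll_new)
        if abs(ll_new - ll) < tol_ll or np.linalg.norm(grad) < tol_grad:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    eta = X @ beta
    mu = expit(eta)
    wt = w * mu * (1.0 - mu)
    H = X.T @ (wt[:, None] * X)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if np.any(np.abs(beta) > SEPARATION_BOUND):
        converged = False
    return FitResult(beta=beta, cov=cov, loglik=ll, converged=converged, n_iter=it, ll_path=path)


def _counts_design(case_counts: np.ndarray, control_counts: np.ndarray, coding: str):
    """Weighted design for a 2x3 genotype count table.

    ``coding='trend'`` uses the dosage column; ``coding='genotype'`` uses
    indicator columns for dosages 1 and 2 (classes with zero total are
    dropped from the design and reported as inestimable).
    """
    g = np.array([0.0, 1.0, 2.0])
    y = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    w = np.concatenate([case_counts, control_counts]).astype(float)
    gg = np.concatenate([g, g])
    if coding == "trend":
        X = np.column_stack([np.ones(6), gg])
        return X, y, w, None
    present = (case_counts + control_counts) > 0
    cols = [np.ones(6)]
    kept = []
    for dose in (1, 2):
        if present[dose]:
            cols.append((gg == dose).astype(float))
            kept.append(dose)
    return np.column_stack(cols), y, w, kept


def raf(genotypes: pd.Series | np.ndarray) -> float:
    """Risk-allele frequency from dosages: (het + 2*hom) / (2*non-missing)."""
    arr = pd.Series(genotypes).dropna().astype(float).to_numpy()
    if arr.size == 0:
        raise ValidationError("all genotypes missing; RAF undefined")
    return float(arr.sum() / (2.0 * arr.size))


def _complete_case(genotypes, status) -> tuple[np.ndarray, np.ndarray]:
    g = pd.Series(genotypes).to_numpy(dtype=float, na_value=np.nan)
    s = np.asarray(status, dtype=float)
    ok = np.isfinite(g)
    return g[ok], s[ok]


def _tabulate(g: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    case = np.bincount(g[s == 1].astype(int), minlength=3)[:3]
    ctrl = np.bincount(g[s == 0].astype(int), minlength=3)[:3]
    return case.astype(float), ctrl.astype(float)


def trend_test_from_counts(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> tuple[float, tuple, float, FitResult | None]:
    """Per-allele trend test on a 2x3 genotype count table.

    Returns (OR, 95% CI, LRT p, fit).  A monomorphic table gives an
    undefined OR with p = 1 and no fit.
    """
    case_counts = np.asarray(case_counts, dtype=float)
    control_counts = np.asarray(control_counts, dtype=float)
    total = case_counts + control_counts
    if (total > 0).sum() <= 1:
        return float("nan"), (float("nan"), float("nan")), 1.0, None
    if case_counts.sum() == 0 or control_counts.sum() == 0:
        raise ValidationError("need at least one case and one control with genotypes")
    X, y, w, _ = _counts_design(case_counts, control_counts, "trend")
    fit1 = fit_logistic(X, y, w)
    fit0 = fit_logistic(X[:, :1], y, w)
    lrt = max(2.0 * (fit1.loglik - fit0.loglik), 0.0)
    p = float(chi2.sf(lrt, df=1))
    beta, se = fit1.beta[1], fit1.se[1]
    ci = (float(np.exp(beta - Z975 * se)), float(np.exp(beta + Z975 * se)))
    return float(np.exp(beta)), ci, max(min(p, 1.0), np.nextafter(0, 1)), fit1


def trend_test(genotypes, status) -> tuple[float, tuple, float]:
    """Per-allele (multiplicative) trend test from per-sample dosages.

    ``status`` is 1 for cases, 0 for controls; missing genotypes are dropped
    per locus (complete-case).
    """
    g, s = _complete_case(genotypes, status)
    if g.size == 0:
        raise ValidationError("no complete cases for trend test")
    case, ctrl = _tabulate(g, s)
    or_, ci, p, _ = trend_test_from_counts(case, ctrl)
    return or_, ci, p


def genotype_model_test_from_counts(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> tuple[float, float, tuple, tuple, float, list]:
    """Unconstrained genotype model on a 2x3 count table.

    Returns (or_het, or_hom, ci_het, ci_hom, 2-df LRT p, flags).  A genotype
    class absent from both arms leaves that OR undefined (flagged) while the
    other is still estimated; the LRT df equals the number of estimable
    contrasts.
    """
    case_counts = np.asarray(case_counts, dtype=float)
    control_counts = np.asarray(control_counts, dtype=float)
    if case_counts.sum() == 0 or control_counts.sum() == 0:
        raise ValidationError("need at least one case and one control with genotypes")
    X, y, w, kept = _counts_design(case_counts, control_counts, "genotype")
    flags = []
    nan_ci = (float("nan"), float("nan"))
    out = {1: (float("nan"), nan_ci), 2: (float("nan"), nan_ci)}
    if (case_counts + control_counts)[0] == 0:
        # no zero-copy baseline: contrasts against it are undefined
        return float("nan"), float("nan"), nan_ci, nan_ci, 1.0, ["baseline_class_empty"]
    if X.shape[1] == 1:
        return float("nan"), float("nan"), nan_ci, nan_ci, 1.0, ["monomorphic"]
    fit1 = fit_logistic(X, y, w)
    fit0 = fit_logistic(X[:, :1], y, w)
    lrt = max(2.0 * (fit1.loglik - fit0.loglik), 0.0)
    p = float(chi2.sf(lrt, df=len(kept)))
    if not fit1.converged:
        flags.append("separation")
    for j, dose in enumerate(kept, start=1):
        b, se = fit1.beta[j], fit1.se[j]
        out[dose] = (float(np.exp(b)), (float(np.exp(b - Z975 * se)), float(np.exp(b + Z975 * se))))
    for dose in (1, 2):
        if dose not in kept:
            flags.append(f"class_{dose}_empty")
    return out[1][0], out[2][0], out[1][1], out[2][1], max(min(p, 1.0), np.nextafter(0, 1)), flags


def genotype_model_test(genotypes, status):
    """Unconstrained genotype model from per-sample dosages; see
    :func:`genotype_model_test_from_counts`."""
    g, s = _complete_case(genotypes, status)
    if g.size == 0:
        raise ValidationError("no complete cases for genotype model")
    case, ctrl = _tabulate(g, s)
    return genotype_model_test_from_counts(case, ctrl)


def analyze_snp(snp_id: str, genotypes, status) -> AssocResult:
    """Fit both genetic models for one locus and assemble the summary row."""
    g, s = _complete_case(genotypes, status)
    if g.size == 0:
        raise ValidationError(f"{snp_id}: all genotypes missing")
    case, ctrl = _tabulate(g, s)
    or_t, ci_t, p_t, fit_t = trend_test_from_counts(case, ctrl)
    flags = []
    if fit_t is None:
        flags.append("monomorphic")
        or_h = or_hh = float("nan")
        ci_h = ci_hh = (float("nan"), float("nan"))
        p_g = 1.0
    else:
        or_h, or_hh, ci_h, ci_hh, p_g, gflags = genotype_model_test_from_counts(case, ctrl)
        flags.extend(gflags)
        if not fit_t.converged:
            flags.append("trend_separation")
    return AssocResult(
        snp_id=snp_id,
        raf_all=raf(genotypes),
        or_het=or_h,
        or_het_ci=ci_h,
        or_hom=or_hh,
        or_hom_ci=ci_hh,
        or_trend=or_t,
        or_trend_ci=ci_t,
        p_trend=p_t,
        p_genotype=p_g,
        n_used=int(g.size),
        flags=flags,
    )


def analyze_panel(manifest: pd.DataFrame, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP association table (results-table shape) for a QC'd cohort."""
    status = (manifest["group"] == "case").astype(int).to_numpy()
    rows = []
    for snp_id in genotypes.columns:
        r = analyze_snp(snp_id, genotypes[snp_id], status)
        rows.append(
            {
                "snp_id": r.snp_id,
                "raf": r.raf_all,
                "n_used": r.n_used,
                "or_het": r.or_het,
                "or_het_low": r.or_het_ci[0],
                "or_het_high": r.or_het_ci[1],
                "or_hom": r.or_hom,
                "or_hom_low": r.or_hom_ci[0],
                "or_hom_high": r.or_hom_ci[1],
                "or_trend": r.or_trend,
                "or_trend_low": r.or_trend_ci[0],
                "or_trend_high": r.or_trend_ci[1],
                "p_trend": r.p_trend,
                "p_genotype": r.p_genotype,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def age_at_onset_test(case_genotypes, case_ages) -> tuple[float, float]:
    """Case-only test for a genotype trend with age at diagnosis.

    The risk-allele count is treated as a binomial outcome with two trials
    per subject, with the logit of the per-allele probability linear in age
    (years).  Returns (slope per year on the logit scale, 1-df LRT p).
    """
    g = pd.Series(case_genotypes).to_numpy(dtype=float, na_value=np.nan)
    a = np.asarray(case_ages, dtype=float)
    ok = np.isfinite(g) & np.isfinite(a)
    g, a = g[ok], a[ok]
    if g.size == 0:
        raise ValidationError("no complete cases for age-at-onset test")
    if np.ptp(a) == 0:
        raise ValidationError("age is constant; trend with age undefined")
    # binomial(2, p) likelihood == weighted Bernoulli rows (g successes, 2-g failures)
    a_c = a - a.mean()  # centred for conditioning; slope is unchanged
    X = np.column_stack([np.ones(2 * g.size), np.concatenate([a_c, a_c])])
    y = np.concatenate([np.ones(g.size), np.zeros(g.size)])
    w = np.concatenate([g, 2.0 - g])
    fit1 = fit_logistic(X, y, w)
    fit0 = fit_logistic(X[:, :1], y, w)
    lrt = max(2.0 * (fit1.loglik - fit0.loglik), 0.0)
    return float(fit1.beta[1]), float(chi2.sf(lrt, df=1))


AGE_STRATA = ((None, 60), (60, 70), (70, None))


def age_stratified_trend(
    manifest: pd.DataFrame, genotypes: pd.DataFrame, boundaries: tuple = (60, 70)
) -> pd.DataFrame:
    """Trend ORs per case age stratum (<60, 60-69, >=70 by default) against
    all controls — the stratified complement to the case-only age test."""
    lo, hi = boundaries
    ages = manifest["age_at_diagnosis"].to_numpy(dtype=float, na_value=np.nan)
    is_case = (manifest["group"] == "case").to_numpy()
    strata = {
        f"<{lo}": is_case & (ages < lo),
        f"{lo}-{hi - 1}": is_case & (ages >= lo) & (ages < hi),
        f">={hi}": is_case & (ages >= hi),
    }
    rows = []
    ctrl = ~is_case
    for label, in_stratum in strata.items():
        sel = in_stratum | ctrl
        status = is_case[sel].astype(int)
        for snp_id in genotypes.columns:
            or_, ci, p = trend_test(genotypes[snp_id][sel], status)
            rows.append(
                {
                    "stratum": label,
                    "n_cases": int(in_stratum.sum()),
                    "snp_id": snp_id,
                    "or_trend": or_,
                    "or_low": ci[0],
                    "or_high": ci[1],
                    "p_trend": p,
                }
            )
    return pd.DataFrame(rows)
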