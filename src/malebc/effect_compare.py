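"""Male-vs-female odds-ratio heterogeneity test.

Both sets of per-allele ORs are taken as log-normally distributed.  Under
the null hypothesis that the male and female ORs are equal, the difference
of the estimated log ORs is normal with mean zero and variance equal to the
sum of the squared standard errors, giving a 1-df chi-square per SNP:

    d = ln(OR_m) - ln(OR_f),   v = se_m^2 + se_f^2,   X^2 = d^2 / v

with ratio exp(d) and 95% CI exp(d ± z*sqrt(v)).  Summing the per-SNP
statistics yields a global k-df test across the panel.  Standard errors are
reconstructed from published confidence intervals:
se = (ln(hi) - ln(lo)) / (2z).

Female reference estimates carry their own sampling variance into the
denominator; male and female estimates are treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import chi2

from .cohort_sim import ValidationError

#: Pinned z quantile at 95% (matching the CI construction in the association stage).
Z975 = 1.959964


def _z(level: float) -> float:
    if abs(level - 0.95) < 1e-12:
        return Z975
    return float(ndtri(1.0 - (1.0 - level) / 2.0))


@dataclass
class OrEstimate:
    """An odds ratio with either a confidence interval or a log-scale SE.

    Exactly one of (CI, ``se_log``) is required; when both are given they
    must agree within 1e-6 on the log scale (the CI-derived value wins).
    """

    label: str
    or_point: float
    ci_low: float | None = None
    ci_high: float | None = None
    level: float = 0.95
    se_log: float | None = None

    def __post_init__(self) -> None:
        if not self.or_point > 0:
            raise ValidationError(f"{self.label}: OR must be positive")
        has_ci = self.ci_low is not None or self.ci_high is not None
        if has_ci and (self.ci_low is None or self.ci_high is None):
            raise ValidationError(f"{self.label}: both CI bounds are required")
        if not has_ci and self.se_log is None:
            raise ValidationError(f"{self.label}: supply a CI or se_log")
        if has_ci:
            if not (self.ci_low > 0 and self.ci_high > 0):
                raise ValidationError(f"{self.label}: CI bounds must be positive")
            if self.ci_low > self.ci_high:
                raise ValidationError(f"{self.label}: ci_low exceeds ci_high")
            if not (self.ci_low <= self.or_point <= self.ci_high):
                raise ValidationError(f"{self.label}: CI does not bracket the OR")
            se_ci = se_from_ci(self)
            if self.se_log is not None and abs(se_ci - self.se_log) > 1e-6:
                raise ValidationError(
                    f"{self.label}: CI-derived SE {se_ci:.8f} conflicts with se_log {self.se_log:.8f}"
                )
            object.__setattr__(self, "se_log", se_ci)
        elif self.se_log is not None and self.se_log < 0:
            raise ValidationError(f"{self.label}: se_log must be non-negative")

    @property
    def log_or(self) -> float:
        return float(np.log(self.or_point))


def se_from_ci(est: OrEstimate) -> float:
    """SE of ln(OR) reconstructed from the confidence interval:
    (ln hi - ln lo) / (2z); zero for a degenerate interval."""
    if est.ci_low is None or est.ci_high is None:
        raise ValidationError(f"{est.label}: no CI to reconstruct an SE from")
    z = _z(est.level)
    return float((np.log(est.ci_high) - np.log(est.ci_low)) / (2.0 * z))


@dataclass
class ComparisonResult:
    """Per-SNP male:female comparison: ratio of ORs with CI, 1-df chi-square
    and p-value."""

    snp_id: str
    ratio: float
    ratio_ci: tuple
    chi_sq: float
    p: float


@dataclass
class GlobalComparison:
    """Sum of the per-SNP chi-squares referred to a chi-square with df equal
    to the number of comparisons."""

    chi_sq_total: float
    df: int
    p: float


def compare_ors(male: OrEstimate, female: OrEstimate, snp_id: str | None = None) -> ComparisonResult:
    """Test equality of two log ORs assuming independent normal errors."""
    d = male.log_or - female.log_or
    v = male.se_log**2 + female.se_log**2
    if v == 0.0:
        if d == 0.0:
            return ComparisonResult(
                snp_id=snp_id or male.label, ratio=1.0, ratio_ci=(1.0, 1.0), chi_sq=0.0, p=1.0
            )
        raise ValidationError("zero variance with unequal estimates: statistic is infinite")
    chi_sq = d * d / v
    half = Z975 * np.sqrt(v)
    return ComparisonResult(
        snp_id=snp_id or male.label,
        ratio=float(np.exp(d)),
        ratio_ci=(float(np.exp(d - half)), float(np.exp(d + half))),
        chi_sq=float(chi_sq),
        p=float(max(chi2.sf(chi_sq, df=1), np.nextafter(0, 1))),
    )


def global_test(results: list[ComparisonResult]) -> GlobalComparison:
    """Combine per-SNP comparisons: chi-square total, df = count, upper-tail p."""
    if not results:
        raise ValidationError("no comparison results to combine")
    total = float(sum(r.chi_sq for r in results))
    df = len(results)
    return GlobalComparison(
        chi_sq_total=total, df=df, p=float(max(chi2.sf(total, df=df), np.nextafter(0, 1)))
    )


def or_estimate_from_row(row, label_col: str = "snp_id") -> OrEstimate:
    """Build an :class:`OrEstimate` from a reference-panel table row
    (columns ``snp_id, or, ci_low, ci_high``)."""
    return OrEstimate(
        label=str(row[label_col]),
        or_point=float(row["or"]),
        ci_low=float(row["ci_low"]),
        ci_high=float(row["ci_high"]),
    )


def compare_panel(
    male_results: pd.DataFrame,
    female_refs: pd.DataFrame,
    stratum_label: str = "all",
) -> tuple[pd.DataFrame, GlobalComparison, list[str]]:
    """Compare a male association table against a female reference panel.

    ``male_results`` is the association-stage output (``snp_id, or_trend,
    or_trend_low, or_trend_high``); ``female_refs`` a reference TSV table
    (``snp_id, or, ci_low, ci_high``).  SNPs are matched on identifier
    (canonically sorted); unmatched male SNPs are listed and excluded.
    Returns the per-SNP table, the global test over matched SNPs, and the
    unmatched identifiers.
    """
    male_ids = set(male_results["snp_id"])
    female_ids = set(female_refs["snp_id"])
    matched = sorted(male_ids & female_ids)
    if not matched:
        raise ValidationError("no SNPs shared between male results and reference panel")
    unmatched = sorted(male_ids - female_ids)

    m_idx = male_results.set_index("snp_id")
    f_idx = female_refs.set_index("snp_id")
    results = []
    for snp in matched:
        male = OrEstimate(
            label=snp,
            or_point=float(m_idx.at[snp, "or_trend"]),
            ci_low=float(m_idx.at[snp, "or_trend_low"]),
            ci_high=float(m_idx.at[snp, "or_trend_high"]),
        )
        female = OrEstimate(
            label=snp,
            or_point=float(f_idx.at[snp, "or"]),
            ci_low=float(f_idx.at[snp, "ci_low"]),
            ci_high=float(f_idx.at[snp, "ci_high"]),
        )
        results.append(compare_ors(male, female, snp_id=snp))
    glob = global_test(results)
    table = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "stratum": stratum_label,
            "ratio": [r.ratio for r in results],
            "ratio_low": [r.ratio_ci[0] for r in results],
            "ratio_high": [r.ratio_ci[1] for r in results],
            "chi_sq": [r.chi_sq for r in results],
            "p": [r.p for r in results],
        }
    )
    return table, glob, unmatched
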