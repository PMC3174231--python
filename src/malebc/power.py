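"""Power of the per-allele trend test: analytic approximation and simulation.

The analytic route uses the allele-count normal approximation: with control
risk-allele frequency p0 and the case frequency pc implied by the
multiplicative model, the variance of the estimated log OR is approximately

    var = 1 / (2 * n_case * pc * (1 - pc)) + 1 / (2 * n_ctrl * p0 * (1 - p0))

and two-sided power at level alpha is Phi(lambda - z) + Phi(-lambda - z)
with lambda = |ln OR| / sqrt(var), z the upper alpha/2 normal quantile.

The simulation route is the gold standard: repeated synthetic cohorts drawn
from the generating model, the trend model fitted to each, and power
estimated as the rejection fraction with a binomial Monte-Carlo interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from . import cohort_sim
from .assoc import trend_test_from_counts
from .cohort_sim import SnpSimSpec, ValidationError


@dataclass(frozen=True)
class PowerSpec:
    """Design for a power calculation.

    ``maf`` is the minor-allele frequency in controls (<= 0.5 by
    convention), used directly as the control risk-allele frequency of the
    alternative model.
    """

    n_cases: int
    n_controls: int
    maf: float
    or_alt: float
    alpha: float = 0.05
    n_reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValidationError("sample sizes must be positive")
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError("minor-allele frequency must lie in (0, 0.5]")
        if not self.or_alt > 0:
            raise ValidationError("alternative OR must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0,1)")

    @property
    def snp(self) -> SnpSimSpec:
        return SnpSimSpec(snp_id="power_locus", raf=self.maf, psi=self.or_alt)


def power_analytic(spec: PowerSpec) -> float:
    """Two-sided power of the per-allele log-OR test, normal approximation."""
    p0 = spec.maf
    pc = cohort_sim.expected_case_raf(spec.snp)
    var = 1.0 / (2.0 * spec.n_cases * pc * (1.0 - pc)) + 1.0 / (
        2.0 * spec.n_controls * p0 * (1.0 - p0)
    )
    lam = abs(np.log(spec.or_alt)) / np.sqrt(var)
    z = ndtri(1.0 - spec.alpha / 2.0)
    return float(ndtr(lam - z) + ndtr(-lam - z))


def power_simulated(spec: PowerSpec) -> tuple[float, tuple[float, float]]:
    """Empirical power over ``n_reps`` simulated cohorts.

    Each replicate draws genotype counts from the generating model (seeded
    per replicate from the master seed), fits the trend model, and tests at
    level ``alpha``.  Returns the rejection fraction and its 95% binomial
    Monte-Carlo interval (normal approximation).
    """
    if spec.n_reps < 100:
        raise ValidationError("at least 100 replicates are required")
    snp = spec.snp
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_reps)
    rejections = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        case, ctrl = cohort_sim.simulate_genotype_counts(
            snp, spec.n_cases, spec.n_controls, rng
        )
        _, _, p, _ = trend_test_from_counts(case, ctrl)
        if p <= spec.alpha:
            rejections += 1
    frac = rejections / spec.n_reps
    half = 1.959964 * np.sqrt(max(frac * (1.0 - frac), 1e-12) / spec.n_reps)
    return float(frac), (float(max(frac - half, 0.0)), float(min(frac + half, 1.0)))
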