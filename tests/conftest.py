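"""Shared fixtures: a study-sized synthetic cohort and its QC'd form."""

from fractions import Fraction
from math import factorial

import pytest
from hypothesis import settings

from malebc import CohortSpec, apply_exclusions, default_snp_panel, simulate_cohort

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

COHORT_SEED = 20260930


@pytest.fixture(scope="session")
def study_cohort():
    """Full-design cohort: 457 cases + 1608 controls + 54 duplicates, with
    the designated QC artifacts."""
    spec = CohortSpec(seed=COHORT_SEED)
    manifest, genotypes = simulate_cohort(default_snp_panel(), spec)
    return manifest, genotypes, spec


@pytest.fixture(scope="session")
def qc_cohort(study_cohort):
    manifest, genotypes, _ = study_cohort
    return apply_exclusions(manifest, genotypes)


def hwe_enumeration_oracle(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """Brute-force exact HWE p-value: enumerate every heterozygote count
    consistent with the allele counts and sum conditional probabilities
    computed with exact integer arithmetic."""
    n = n_hom_risk + n_het + n_hom_other
    n_risk = 2 * n_hom_risk + n_het
    n_rare = min(n_risk, 2 * n - n_risk)
    weights = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        a = (n_rare - h) // 2
        b = n - a - h
        weights[h] = Fraction(2**h * factorial(n), factorial(a) * factorial(h) * factorial(b))
    w_obs = weights[n_het]
    total = sum(weights.values())
    return float(sum(w for w in weights.values() if w <= w_obs) / total)
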