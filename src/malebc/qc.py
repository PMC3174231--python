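"""Sample-exclusion cascade, duplicate concordance, and exact HWE testing.

The exclusion cascade mirrors standard candidate-SNP genotyping QC:

1. drop samples with no-calls at two or more panel loci;
2. collapse each surviving plate-duplicate pair to a single analysis sample,
   recording pairwise concordance first;
3. drop samples of self-reported non-European ancestry.

Hardy-Weinberg equilibrium is assessed in post-exclusion controls with the
exact conditional test: given the total sample size and the number of
rare-allele copies, the heterozygote count follows a known conditional
distribution, and the two-sided p-value sums the probabilities of all
configurations no more probable than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort_sim import ValidationError

# probability ties are compared with this relative slack so that
# exactly-equiprobable configurations are always included together
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class HweCounts:
    """Control genotype counts for one locus: risk-homozygote, heterozygote,
    other-homozygote."""

    n_hom_risk: int
    n_het: int
    n_hom_other: int

    def __post_init__(self) -> None:
        if min(self.n_hom_risk, self.n_het, self.n_hom_other) < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_other


@dataclass
class QcReport:
    """Counts and summary statistics produced by the exclusion cascade."""

    n_attempted: int
    n_excluded_no_call: int
    no_call_breakdown: dict
    n_excluded_ancestry: int
    ancestry_breakdown: dict
    n_duplicate_members_removed: int
    n_cases_final: int
    n_controls_final: int
    locus_completion: dict
    mean_duplicate_concordance: float | None
    hwe_p_controls: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_attempted": self.n_attempted,
            "n_excluded_no_call": self.n_excluded_no_call,
            "no_call_breakdown": dict(self.no_call_breakdown),
            "n_excluded_ancestry": self.n_excluded_ancestry,
            "ancestry_breakdown": dict(self.ancestry_breakdown),
            "n_duplicate_members_removed": self.n_duplicate_members_removed,
            "n_cases_final": self.n_cases_final,
            "n_controls_final": self.n_controls_final,
            "locus_completion": {k: float(v) for k, v in self.locus_completion.items()},
            "mean_duplicate_concordance": (
                None
                if self.mean_duplicate_concordance is None
                else float(self.mean_duplicate_concordance)
            ),
            "hwe_p_controls": {k: float(v) for k, v in self.hwe_p_controls.items()},
        }


def hwe_exact(counts: HweCounts) -> float:
    """Exact two-sided Hardy-Weinberg p-value for one locus.

    Conditions on the observed allele counts: with ``n`` diploid samples and
    ``n_rare`` copies of the rarer allele, the heterozygote count ``h`` (same
    parity as ``n_rare``) has conditional probability proportional to
    ``2**h / ((n_rare - h)/2)! h! ((2n - n_rare - h)/2)!``.  The p-value is
    the summed probability of every configuration whose probability does not
    exceed the observed one.  Computed in log space via ``gammaln`` so large
    counts do not overflow; returns 1.0 when only one configuration exists.
    """
    n = counts.total
    if n < 1:
        raise ValidationError("total genotype count must be at least 1")
    n_risk = 2 * counts.n_hom_risk + counts.n_het
    n_rare = min(n_risk, 2 * n - n_risk)
    probs = _het_distribution(n, n_rare)
    if probs.size <= 1:
        return 1.0
    # heterozygote counts run n_rare % 2, +2, ... ; index of the observed one
    obs_prob = probs[(counts.n_het - n_rare % 2) // 2]
    p = float(probs[probs <= obs_prob * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


@lru_cache(maxsize=None)
def _het_distribution(n: int, n_rare: int) -> np.ndarray:
    """Conditional distribution of the heterozygote count given ``n`` samples
    and ``n_rare`` rare-allele copies, over counts of matching parity.

    Weights are computed in log space (cumulative log-factorials) and
    normalised after shifting by the maximum, so large ``n`` neither
    overflows nor loses the configurations that matter.
    """
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hom_rare - hets
    logw = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    w.setflags(write=False)
    return w


def hwe_counts_from_genotypes(dosages: pd.Series | np.ndarray) -> HweCounts:
    """Tally non-missing dosages 0/1/2 into :class:`HweCounts`
    (dosage 2 = risk-allele homozygote)."""
    arr = pd.Series(dosages).dropna().astype(int).to_numpy()
    if arr.size == 0:
        raise ValidationError("no non-missing genotypes to tally")
    counts = np.bincount(arr, minlength=3)
    return HweCounts(n_hom_risk=int(counts[2]), n_het=int(counts[1]), n_hom_other=int(counts[0]))


def duplicate_concordance(
    genotypes: pd.DataFrame, pairs: list[tuple[str, str]]
) -> float:
    """Mean per-pair genotype concordance.

    Each pair contributes (matching calls) / (loci where both calls are
    non-missing); pairs with no comparable locus are dropped with a warning.
    """
    if not pairs:
        raise ValidationError("no duplicate pairs supplied")
    per_pair = []
    for a, b in pairs:
        if a not in genotypes.index or b not in genotypes.index:
            raise ValidationError(f"duplicate pair ({a}, {b}) references a missing sample")
        ga = genotypes.loc[a].to_numpy(dtype=float, na_value=np.nan)
        gb = genotypes.loc[b].to_numpy(dtype=float, na_value=np.nan)
        both = np.isfinite(ga) & np.isfinite(gb)
        if not both.any():
            warnings.warn(f"pair ({a}, {b}) has no comparable loci; excluded from mean")
            continue
        per_pair.append(float(np.mean(ga[both] == gb[both])))
    if not per_pair:
        raise ValidationError("no duplicate pair has comparable loci")
    return float(np.mean(per_pair))


def _call_rate(row: np.ndarray) -> float:
    return float(np.mean(np.isfinite(row)))


def apply_exclusions(
    manifest: pd.DataFrame,
    genotypes: pd.DataFrame,
    max_no_calls: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, QcReport]:
    """Run the exclusion cascade and return the analysis-ready cohort.

    Order of application: ≥2-no-call exclusion (threshold ``max_no_calls + 1``
    missing panel loci, evaluated from the genotype table itself), duplicate
    collapse (the member with the higher call rate is retained; the
    first-listed member on ties), then ancestry exclusion.  The report
    conserves samples: attempted = final + excluded + removed duplicates.
    """
    manifest = manifest.reset_index(drop=True)
    vals = genotypes.to_numpy(dtype=float, na_value=np.nan)
    if len(manifest) != len(genotypes):
        raise ValidationError("manifest and genotype table disagree on sample count")
    if not (manifest["sample_id"].to_numpy() == genotypes.index.to_numpy()).all():
        raise ValidationError("manifest and genotype table sample order differ")

    n_attempted = len(manifest)
    missing_per_sample = np.isnan(vals).sum(axis=1)
    is_dup_member = manifest["duplicate_of"].notna().to_numpy()

    # 1. no-call exclusions
    fail = missing_per_sample > max_no_calls
    grp = manifest["group"].to_numpy()
    no_call_breakdown = {
        "cases": int((fail & (grp == "case") & ~is_dup_member).sum()),
        "controls": int((fail & (grp == "control") & ~is_dup_member).sum()),
        "duplicate_members": int((fail & is_dup_member).sum()),
    }
    keep = ~fail
    surviving = manifest[keep].copy()
    surv_vals = vals[keep]

    # 2. duplicate concordance + collapse
    id_pos = {s: i for i, s in enumerate(surviving["sample_id"])}
    pairs = []
    for i, dup_of in enumerate(surviving["duplicate_of"]):
        if pd.notna(dup_of) and dup_of in id_pos:
            pairs.append((dup_of, surviving["sample_id"].iloc[i]))
    mean_conc = None
    if pairs:
        surv_geno = pd.DataFrame(
            surv_vals, index=surviving["sample_id"].to_list(), columns=genotypes.columns
        )
        mean_conc = duplicate_concordance(surv_geno, pairs)

    drop_pos = set()
    for a, b in pairs:
        ia, ib = id_pos[a], id_pos[b]
        ra, rb = _call_rate(surv_vals[ia]), _call_rate(surv_vals[ib])
        drop_pos.add(ib if ra >= rb else ia)  # keep higher call rate; first on tie
    n_dup_removed = len(drop_pos)
    keep2 = np.ones(len(surviving), dtype=bool)
    for i in drop_pos:
        keep2[i] = False
    surviving = surviving[keep2].copy()
    surv_vals = surv_vals[keep2]
    # orphaned duplicate rows become the subject's analysis sample
    surviving.loc[surviving["duplicate_of"].notna(), "duplicate_of"] = pd.NA

    # 3. ancestry exclusion
    non_eur = (surviving["ancestry"] == "non_european").to_numpy()
    grp2 = surviving["group"].to_numpy()
    ancestry_breakdown = {
        "cases": int((non_eur & (grp2 == "case")).sum()),
        "controls": int((non_eur & (grp2 == "control")).sum()),
    }
    surviving = surviving[~non_eur].copy()
    surv_vals = surv_vals[~non_eur]

    final_geno = pd.DataFrame(
        {
            c: pd.array(surv_vals[:, j], dtype="Int8")
            for j, c in enumerate(genotypes.columns)
        },
        index=pd.Index(surviving["sample_id"].to_list(), name="sample_id"),
    )
    grp3 = surviving["group"].to_numpy()
    n_cases_final = int((grp3 == "case").sum())
    n_controls_final = int((grp3 == "control").sum())

    completion = {
        c: float(np.mean(np.isfinite(surv_vals[:, j]))) if len(surv_vals) else float("nan")
        for j, c in enumerate(genotypes.columns)
    }
    is_ctrl = grp3 == "control"
    hwe_p = {}
    for j, c in enumerate(genotypes.columns):
        col = surv_vals[is_ctrl, j]
        col = col[np.isfinite(col)]
        if col.size:
            hwe_p[c] = hwe_exact(hwe_counts_from_genotypes(col))

    report = QcReport(
        n_attempted=n_attempted,
        n_excluded_no_call=int(fail.sum()),
        no_call_breakdown=no_call_breakdown,
        n_excluded_ancestry=int(non_eur.sum()),
        ancestry_breakdown=ancestry_breakdown,
        n_duplicate_members_removed=n_dup_removed,
        n_cases_final=n_cases_final,
        n_controls_final=n_controls_final,
        locus_completion=completion,
        mean_duplicate_concordance=mean_conc,
        hwe_p_controls=hwe_p,
    )
    assert (
        report.n_cases_final
        + report.n_controls_final
        + report.n_excluded_no_call
        + report.n_excluded_ancestry
        + report.n_duplicate_members_removed
        == n_attempted
    ), "sample conservation violated"
    return surviving.reset_index(drop=True), final_geno, report
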