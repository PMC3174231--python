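"""Synthetic case-control cohort generator.

Emulates the statistical structure the association pipeline assumes: control
genotypes in Hardy-Weinberg proportions at a specified risk-allele frequency,
case genotypes enriched under a per-allele multiplicative odds model (or an
unconstrained two-parameter model), and the genotyping artifacts the QC stage
must handle — plate duplicates with a small discordance rate, sporadic
no-calls, designated ≥2-no-call sample failures, and self-reported
non-European ancestry flags.

Sampling model
--------------
For a locus with control risk-allele frequency ``p`` the control genotype
(risk-allele dosage ``g`` in {0,1,2}) is drawn from the HWE distribution
``((1-p)^2, 2p(1-p), p^2)``.  Case genotypes are drawn from those weights
multiplied by ``psi**g`` (per-allele odds ratio ``psi``), or by
``(1, psi_het, psi_hom)`` when unconstrained generating ORs are supplied,
renormalised to sum to one.  Loci are independent (no linkage
disequilibrium); samples are independent.

All randomness flows from ``CohortSpec.seed``; a fixed seed yields
byte-identical manifests and genotype tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = pd.NA

MANIFEST_COLUMNS = [
    "sample_id",
    "group",
    "age_at_diagnosis",
    "er_status",
    "duplicate_of",
    "n_no_calls_flag",
    "ancestry",
    "histology",
]


class ValidationError(ValueError):
    """Raised when a simulation or pipeline specification is invalid."""


@dataclass(frozen=True)
class SnpSimSpec:
    """Generating parameters for one locus.

    Parameters
    ----------
    snp_id : locus identifier.
    raf : risk-allele frequency in controls, in (0, 1).
    psi : generating per-allele odds ratio (> 0); ignored when both
        unconstrained overrides are given.
    psi_het, psi_hom : optional unconstrained generating odds ratios for the
        heterozygote and risk-homozygote classes relative to the zero-copy
        baseline; both must be given together and be > 0.
    """

    snp_id: str
    raf: float
    psi: float = 1.0
    psi_het: float | None = None
    psi_hom: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.raf < 1.0):
            raise ValidationError(
                f"{self.snp_id}: risk-allele frequency must lie in (0,1), got {self.raf}"
            )
        if not self.psi > 0:
            raise ValidationError(f"{self.snp_id}: psi must be positive, got {self.psi}")
        if (self.psi_het is None) != (self.psi_hom is None):
            raise ValidationError(
                f"{self.snp_id}: psi_het and psi_hom must be supplied together"
            )
        if self.psi_het is not None and not (self.psi_het > 0 and self.psi_hom > 0):
            raise ValidationError(
                f"{self.snp_id}: unconstrained generating ORs must be positive"
            )

    @property
    def genotype_or(self) -> np.ndarray:
        """Genotype-level odds multipliers (1, w1, w2)."""
        if self.psi_het is not None:
            return np.array([1.0, self.psi_het, self.psi_hom])
        return np.array([1.0, self.psi, self.psi * self.psi])


@dataclass(frozen=True)
class CohortSpec:
    """Cohort dimensions and artifact rates.

    Defaults reproduce the design of a UK population-based male breast
    cancer case-control study: 457 cases and 1608 unmatched controls
    attempted, 54 plate-duplicate samples, 49 samples failing the
    ≥2-no-call rule (11 cases, 34 controls, 4 duplicate-pair members) and
    18 self-reported non-European subjects (13 cases, 5 controls).  Artifact
    counts are applied exactly, not sampled, so downstream QC counts are
    deterministic.
    """

    n_cases: int = 457
    n_controls: int = 1608
    n_duplicate_pairs: int = 54
    no_call_rate: float = 0.0005
    discordance_rate: float = 0.002
    n_no_call_failures_cases: int = 11
    n_no_call_failures_controls: int = 34
    n_no_call_failures_duplicates: int = 4
    n_non_european_cases: int = 13
    n_non_european_controls: int = 5
    age_loc: float = 66.6
    age_scale: float = 10.2
    age_min: int = 18
    age_max: int = 79
    er_known_fraction: float = 0.58
    er_positive_fraction: float = 0.98
    invasive_fraction: float = 0.921
    dcis_fraction: float = 0.072
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cases,
            self.n_controls,
            self.n_duplicate_pairs,
            self.n_no_call_failures_cases,
            self.n_no_call_failures_controls,
            self.n_no_call_failures_duplicates,
            self.n_non_european_cases,
            self.n_non_european_controls,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("all cohort counts must be non-negative")
        for name in ("no_call_rate", "discordance_rate", "er_known_fraction",
                     "er_positive_fraction", "invasive_fraction", "dcis_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if self.n_duplicate_pairs > self.n_cases + self.n_controls:
            raise ValidationError("more duplicate pairs than samples")
        if self.n_no_call_failures_cases + self.n_non_european_cases > self.n_cases:
            raise ValidationError("case artifact counts exceed number of cases")
        if self.n_no_call_failures_controls + self.n_non_european_controls > self.n_controls:
            raise ValidationError("control artifact counts exceed number of controls")
        if self.n_no_call_failures_duplicates > self.n_duplicate_pairs:
            raise ValidationError("duplicate failure count exceeds duplicate pairs")


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent stream per pipeline stage, all derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def genotype_probabilities(snp: SnpSimSpec, arm: str) -> np.ndarray:
    """Genotype (dosage 0/1/2) probabilities in controls (HWE) or cases.

    Case probabilities are the HWE weights multiplied by the genotype odds
    and renormalised — the inverse of the fitted disease model.
    """
    p = snp.raf
    hwe = np.array([(1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p])
    if arm == "control":
        return hwe
    if arm == "case":
        w = hwe * snp.genotype_or
        return w / w.sum()
    raise ValidationError(f"unknown arm {arm!r}")


def expected_case_raf(snp: SnpSimSpec) -> float:
    """Closed-form risk-allele frequency among cases under the generating model."""
    probs = genotype_probabilities(snp, "case")
    return float((probs[1] + 2.0 * probs[2]) / 2.0)


def simulate_genotype_counts(
    snp: SnpSimSpec, n_cases: int, n_controls: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sufficient-statistic fast path: genotype count 3-vectors for each arm.

    Equivalent in distribution to drawing per-sample genotypes; used by the
    power simulator where only the counts matter.
    """
    case = rng.multinomial(n_cases, genotype_probabilities(snp, "case"))
    ctrl = rng.multinomial(n_controls, genotype_probabilities(snp, "control"))
    return case, ctrl


def simulate_genotypes(
    snps: Sequence[SnpSimSpec], spec: CohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a clean cohort: sample manifest plus genotype dosage table.

    Returns
    -------
    manifest : DataFrame with one row per sample (cases first), columns
        ``MANIFEST_COLUMNS``.
    genotypes : DataFrame indexed by ``sample_id`` with one nullable-integer
        dosage column per SNP (missing calls, introduced later by
        :func:`inject_artifacts`, are ``pd.NA``).
    """
    if len(snps) == 0:
        raise ValidationError("at least one SNP is required")
    ids = [s.snp_id for s in snps]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate SNP identifiers in panel")

    rng = _stage_rng(spec.seed, 0)
    n_case, n_ctrl = spec.n_cases, spec.n_controls
    n = n_case + n_ctrl

    sample_id = [f"case_{i + 1:04d}" for i in range(n_case)] + [
        f"ctrl_{i + 1:04d}" for i in range(n_ctrl)
    ]
    group = ["case"] * n_case + ["control"] * n_ctrl

    # ages: discretised truncated normal for cases; controls unknown
    ages = np.full(n, np.nan)
    need = np.arange(n_case)
    draws = rng.normal(spec.age_loc, spec.age_scale, size=4 * max(n_case, 1))
    draws = draws[(draws >= spec.age_min) & (draws <= spec.age_max)]
    while draws.size < n_case:  # pragma: no cover - 4x oversampling almost always enough
        extra = rng.normal(spec.age_loc, spec.age_scale, size=4 * n_case)
        draws = np.concatenate([draws, extra[(extra >= spec.age_min) & (extra <= spec.age_max)]])
    ages[need] = np.round(draws[:n_case])

    # ER status among cases: a fraction have known status; of those, most positive
    er = np.array(["unknown"] * n, dtype=object)
    known = rng.random(n_case) < spec.er_known_fraction
    pos = rng.random(n_case) < spec.er_positive_fraction
    er[:n_case][known & pos] = "pos"
    er[:n_case][known & ~pos] = "neg"

    hist = np.array(["unknown"] * n, dtype=object)
    u = rng.random(n_case)
    hist[:n_case][u < spec.invasive_fraction] = "invasive"
    hist[:n_case][(u >= spec.invasive_fraction) & (u < spec.invasive_fraction + spec.dcis_fraction)] = "dcis"

    manifest = pd.DataFrame(
        {
            "sample_id": sample_id,
            "group": group,
            "age_at_diagnosis": pd.array(
                [int(a) if np.isfinite(a) else None for a in ages], dtype="Int64"
            ),
            "er_status": er,
            "duplicate_of": pd.array([None] * n, dtype="string"),
            "n_no_calls_flag": pd.array([0] * n, dtype="Int64"),
            "ancestry": ["european"] * n,
            "histology": hist,
        }
    )

    geno = {}
    is_case = np.array(group) == "case"
    for snp in snps:
        g = np.empty(n, dtype=np.int64)
        g[is_case] = rng.choice(3, size=n_case, p=genotype_probabilities(snp, "case"))
        g[~is_case] = rng.choice(3, size=n_ctrl, p=genotype_probabilities(snp, "control"))
        geno[snp.snp_id] = pd.array(g, dtype="Int8")
    genotypes = pd.DataFrame(geno, index=pd.Index(sample_id, name="sample_id"))
    return manifest, genotypes


def inject_artifacts(
    manifest: pd.DataFrame, genotypes: pd.DataFrame, spec: CohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add genotyping artifacts to a clean cohort.

    Appends one duplicate row per designated pair (genotypes copied, then
    each call flipped to a different dosage with probability
    ``discordance_rate``); masks sporadic calls to missing at
    ``no_call_rate`` (capped at one per non-designated sample so failure
    counts stay exact); forces exactly two no-calls on the designated
    failure samples; and flags the designated subjects as self-reported
    non-European.  Artifact counts equal the spec counts exactly.
    """
    n_loci = genotypes.shape[1]
    if n_loci < 2 and (
        spec.n_no_call_failures_cases
        or spec.n_no_call_failures_controls
        or spec.n_no_call_failures_duplicates
    ):
        raise ValidationError("≥2-no-call failures require at least two loci")

    manifest = manifest.copy()
    rng = _stage_rng(spec.seed, 1)
    case_idx = np.flatnonzero((manifest["group"] == "case").to_numpy())
    ctrl_idx = np.flatnonzero((manifest["group"] == "control").to_numpy())

    # --- duplicates -------------------------------------------------------
    src_idx = rng.choice(len(manifest), size=spec.n_duplicate_pairs, replace=False)
    dup_rows = manifest.iloc[src_idx].copy()
    dup_rows["duplicate_of"] = manifest["sample_id"].iloc[src_idx].to_numpy()
    dup_rows["sample_id"] = [f"{s}_dup" for s in dup_rows["duplicate_of"]]

    dup_geno = genotypes.iloc[src_idx].copy()
    dup_vals = dup_geno.to_numpy(dtype=float, na_value=np.nan)
    flip = rng.random(dup_vals.shape) < spec.discordance_rate
    # flip to one of the two other dosages, uniformly
    shift = rng.integers(1, 3, size=dup_vals.shape)
    dup_vals = np.where(flip & np.isfinite(dup_vals), (dup_vals + shift) % 3, dup_vals)
    dup_geno = pd.DataFrame(
        {c: pd.array(dup_vals[:, j], dtype="Int8") for j, c in enumerate(genotypes.columns)},
        index=pd.Index(dup_rows["sample_id"].to_list(), name="sample_id"),
    )

    manifest = pd.concat([manifest, dup_rows], ignore_index=True)
    manifest["duplicate_of"] = pd.array(manifest["duplicate_of"], dtype="string")
    genotypes = pd.concat([genotypes, dup_geno])

    n_total = len(manifest)
    dup_pos = np.arange(n_total - spec.n_duplicate_pairs, n_total)

    # --- designated >=2-no-call failures ---------------------------------
    dup_sources = set(src_idx.tolist())
    free_cases = np.array([i for i in case_idx if i not in dup_sources])
    free_ctrls = np.array([i for i in ctrl_idx if i not in dup_sources])
    if len(free_cases) < spec.n_no_call_failures_cases + spec.n_non_european_cases:
        raise ValidationError("not enough non-duplicated cases for designated artifacts")
    if len(free_ctrls) < spec.n_no_call_failures_controls + spec.n_non_european_controls:
        raise ValidationError("not enough non-duplicated controls for designated artifacts")

    pick_cases = rng.choice(free_cases, size=spec.n_no_call_failures_cases, replace=False)
    pick_ctrls = rng.choice(free_ctrls, size=spec.n_no_call_failures_controls, replace=False)
    pick_dups = rng.choice(dup_pos, size=spec.n_no_call_failures_duplicates, replace=False)
    failures = np.concatenate([pick_cases, pick_ctrls, pick_dups]).astype(int)

    vals = genotypes.to_numpy(dtype=float, na_value=np.nan)

    # sporadic no-calls, at most one per non-designated sample
    mask = rng.random(vals.shape) < spec.no_call_rate
    fail_set = set(failures.tolist())
    for i in range(n_total):
        hits = np.flatnonzero(mask[i])
        if i in fail_set:
            mask[i] = False
        elif hits.size > 1:
            keep = rng.choice(hits)
            mask[i] = False
            mask[i, keep] = True
    # forced failures: exactly two missing loci each
    for i in failures:
        loci = rng.choice(n_loci, size=2, replace=False)
        mask[i, loci] = True
    vals[mask] = np.nan

    genotypes = pd.DataFrame(
        {c: pd.array(vals[:, j], dtype="Int8") for j, c in enumerate(genotypes.columns)},
        index=genotypes.index,
    )
    manifest["n_no_calls_flag"] = pd.array(mask.sum(axis=1), dtype="Int64")

    # --- ancestry flags (subject-level; duplicate rows inherit) -----------
    anc_cases = rng.choice(
        np.array([i for i in free_cases if i not in fail_set]),
        size=spec.n_non_european_cases, replace=False,
    )
    anc_ctrls = rng.choice(
        np.array([i for i in free_ctrls if i not in fail_set]),
        size=spec.n_non_european_controls, replace=False,
    )
    anc = manifest["ancestry"].to_numpy(dtype=object)
    for i in np.concatenate([anc_cases, anc_ctrls]).astype(int):
        anc[i] = "non_european"
    # propagate to duplicate rows of flagged subjects
    flagged = set(manifest.loc[np.concatenate([anc_cases, anc_ctrls]).astype(int), "sample_id"])
    for pos in dup_pos:
        if manifest.at[pos, "duplicate_of"] in flagged:
            anc[pos] = "non_european"
    manifest["ancestry"] = anc
    return manifest, genotypes


def simulate_cohort(
    snps: Sequence[SnpSimSpec], spec: CohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean simulation followed by artifact injection, in one call."""
    manifest, genotypes = simulate_genotypes(snps, spec)
    return inject_artifacts(manifest, genotypes, spec)
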