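"""End-to-end orchestration: simulate (or load) → QC → association →
OR comparison → power, with deterministic outputs.

All randomness derives from one master seed; identical config and seed give
byte-identical output files.  Stages write: ``qc_report.json``,
``table1.tsv`` (per-SNP association), ``table2_<stratum>.tsv`` (OR
comparison per reference panel, with a trailing global row),
``descriptives.json`` (histology / ER summary), ``power.json`` and
``run_manifest.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io, reference
from .assoc import analyze_panel
from .cohort_sim import CohortSpec, SnpSimSpec, ValidationError, simulate_cohort
from .effect_compare import compare_panel
from .power import PowerSpec, power_analytic, power_simulated
from .qc import apply_exclusions

log = logging.getLogger("malebc")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of (``manifest_path`` + ``genotypes_path``) or
    ``simulate`` must be provided.  ``references`` maps stratum labels to
    reference-panel TSV paths; the bundled female panel is used when the
    mapping is empty.
    """

    out_dir: str
    seed: int = 0
    manifest_path: str | None = None
    genotypes_path: str | None = None
    simulate: CohortSpec | None = None
    snps: list = field(default_factory=list)
    references: dict = field(default_factory=dict)
    alpha: float = 0.05
    bonferroni_m: int = 12
    power: PowerSpec | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_files = self.manifest_path is not None and self.genotypes_path is not None
        if have_files == (self.simulate is not None):
            raise ValidationError(
                "config must supply either input paths or a simulation spec, not both"
            )
        if self.bonferroni_m < 1:
            raise ValidationError("bonferroni_m must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = None
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"])
            sim_raw.setdefault("seed", raw.get("seed", 0))
            sim = CohortSpec(**sim_raw)
        snps = [SnpSimSpec(**s) for s in raw.get("snps", [])]
        power = None
        if "power" in raw:
            p = dict(raw["power"])
            p.setdefault("seed", raw.get("seed", 0))
            p.setdefault("alpha", raw.get("alpha", 0.05))
            power = PowerSpec(**p)
        return cls(
            out_dir=raw["out_dir"],
            seed=raw.get("seed", 0),
            manifest_path=raw.get("manifest"),
            genotypes_path=raw.get("genotypes"),
            simulate=sim,
            snps=snps,
            references=dict(raw.get("references", {})),
            alpha=raw.get("alpha", 0.05),
            bonferroni_m=raw.get("bonferroni_m", 12),
            power=power,
            log_level=raw.get("log_level", "INFO"),
        )


def summarize_histology_er(manifest: pd.DataFrame) -> dict:
    """Descriptive counts/percentages: histology among cases, ER status among
    known-ER cases.  Percentages are rounded to the nearest integer (raw
    fractions retained alongside)."""
    cases = manifest[manifest["group"] == "case"]
    out: dict = {"n_cases": int(len(cases)), "histology": {}, "er_status": {}}
    n = len(cases)
    for label, cnt in cases["histology"].value_counts().items():
        out["histology"][label] = {
            "n": int(cnt),
            "pct": int(round(100.0 * cnt / n)) if n else 0,
            "fraction": float(cnt / n) if n else 0.0,
        }
    known = cases[cases["er_status"].isin(["pos", "neg"])]
    if len(known) == 0:
        out["er_status"]["unknown"] = {"n": int(n), "pct": 100, "fraction": 1.0}
        out["n_er_known"] = 0
    else:
        out["n_er_known"] = int(len(known))
        for label, cnt in known["er_status"].value_counts().items():
            out["er_status"][label] = {
                "n": int(cnt),
                "pct": int(round(100.0 * cnt / len(known))),
                "fraction": float(cnt / len(known)),
            }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the run report (also written to
    ``run_manifest.json``).  A stage failure propagates after a log line
    naming the stage."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__, "stages": []}

    stage = "input"
    try:
        if config.simulate is not None:
            snps = config.snps or reference.default_snp_panel()
            manifest, genotypes = simulate_cohort(snps, config.simulate)
            io.write_manifest(manifest, out / "manifest.tsv")
            io.write_genotypes(genotypes, out / "genotypes.tsv")
            report["inputs"] = {
                "simulated": True,
                "manifest_sha256": io.sha256_of(out / "manifest.tsv"),
                "genotypes_sha256": io.sha256_of(out / "genotypes.tsv"),
            }
        else:
            manifest = io.read_manifest(config.manifest_path)
            genotypes = io.read_genotypes(config.genotypes_path)
            report["inputs"] = {
                "simulated": False,
                "manifest_sha256": io.sha256_of(config.manifest_path),
                "genotypes_sha256": io.sha256_of(config.genotypes_path),
            }
        report["stages"].append(stage)

        stage = "qc"
        manifest_qc, genotypes_qc, qc_report = apply_exclusions(manifest, genotypes)
        (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=2, sort_keys=True))
        log.info(
            "qc: %d attempted, %d no-call excluded, %d duplicate members removed, "
            "%d ancestry excluded -> %d cases / %d controls",
            qc_report.n_attempted,
            qc_report.n_excluded_no_call,
            qc_report.n_duplicate_members_removed,
            qc_report.n_excluded_ancestry,
            qc_report.n_cases_final,
            qc_report.n_controls_final,
        )
        report["qc"] = {
            "n_cases_final": qc_report.n_cases_final,
            "n_controls_final": qc_report.n_controls_final,
        }
        report["stages"].append(stage)

        stage = "assoc"
        table1 = analyze_panel(manifest_qc, genotypes_qc)
        table1.to_csv(out / "table1.tsv", sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")
        report["assoc"] = {
            "n_snps": int(len(table1)),
            "bonferroni_threshold": config.alpha / config.bonferroni_m,
            "n_significant_trend": int((table1["p_trend"] < config.alpha).sum()),
            "n_significant_bonferroni": int(
                (table1["p_trend"] < config.alpha / config.bonferroni_m).sum()
            ),
        }
        report["stages"].append(stage)

        stage = "descriptives"
        desc = summarize_histology_er(manifest_qc)
        (out / "descriptives.json").write_text(json.dumps(desc, indent=2, sort_keys=True))
        report["stages"].append(stage)

        stage = "compare"
        refs = dict(config.references)
        if not refs:
            bundled = out / "female_reference_all.tsv"
            reference.female_reference_panel().to_csv(bundled, sep="\t", index=False)
            refs = {"all": str(bundled)}
        report["compare"] = {}
        for stratum, path in sorted(refs.items()):
            panel = io.read_reference_panel(path)
            table2, glob, unmatched = compare_panel(table1, panel, stratum_label=stratum)
            global_row = pd.DataFrame(
                {
                    "snp_id": ["ALL_COMBINED"],
                    "stratum": [stratum],
                    "ratio": [float("nan")],
                    "ratio_low": [float("nan")],
                    "ratio_high": [float("nan")],
                    "chi_sq": [glob.chi_sq_total],
                    "p": [glob.p],
                }
            )
            pd.concat([table2, global_row], ignore_index=True).to_csv(
                out / f"table2_{stratum}.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT, na_rep="NA",
            )
            report["compare"][stratum] = {
                "df": glob.df,
                "chi_sq_total": glob.chi_sq_total,
                "p": glob.p,
                "unmatched": unmatched,
            }
        report["stages"].append(stage)

        stage = "power"
        if config.power is not None:
            analytic = power_analytic(config.power)
            simulated, mc = power_simulated(config.power)
            power_out = {
                "analytic": analytic,
                "simulated": simulated,
                "mc_interval": list(mc),
                "n_reps": config.power.n_reps,
            }
            (out / "power.json").write_text(json.dumps(power_out, indent=2, sort_keys=True))
            report["power"] = power_out
            report["stages"].append(stage)
    except Exception:
        log.error("pipeline stage %r failed", stage)
        raise

    (out / "run_manifest.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
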