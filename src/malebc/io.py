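"""Reading and writing the pipeline's file formats.

Tables travel as plain TSV: the sample manifest, the genotype dosage table
(one nullable-integer column per SNP, ``NA`` for no-calls) and reference
panels of published OR estimates.  A minimal VCF round-trip is provided for
interoperability: diploid GT with the risk allele as ALT; multi-allelic
sites are rejected on import.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_sim import MANIFEST_COLUMNS, ValidationError

_NA = "NA"


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_manifest(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(m.columns)
    if missing:
        raise ValidationError(f"manifest is missing columns: {sorted(missing)}")
    m["age_at_diagnosis"] = pd.array(m["age_at_diagnosis"], dtype="Int64")
    m["n_no_calls_flag"] = pd.array(m["n_no_calls_flag"], dtype="Int64")
    m["duplicate_of"] = pd.array(m["duplicate_of"], dtype="string")
    return m


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index=True, na_rep=_NA)


def read_genotypes(path) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False, index_col="sample_id")
    return pd.DataFrame({c: pd.array(g[c], dtype="Int8") for c in g.columns}, index=g.index)


def read_reference_panel(path) -> pd.DataFrame:
    """Reference panel TSV: ``snp_id, or, ci_low, ci_high[, stratum]``."""
    t = pd.read_csv(path, sep="\t")
    required = {"snp_id", "or", "ci_low", "ci_high"}
    missing = required - set(t.columns)
    if missing:
        raise ValidationError(f"reference panel is missing columns: {sorted(missing)}")
    if "stratum" not in t.columns:
        t["stratum"] = "all"
    return t


def write_vcf(
    genotypes: pd.DataFrame,
    path,
    risk_alleles: dict[str, str] | None = None,
    other_alleles: dict[str, str] | None = None,
) -> None:
    """Export dosages as a minimal VCF (risk allele as ALT, diploid GT).

    Placeholder alleles (REF ``A``, ALT ``G``) and positions are used when
    the true alleles/coordinates are unknown: the dosage is the payload.
    """
    risk_alleles = risk_alleles or {}
    other_alleles = other_alleles or {}
    samples = list(genotypes.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for pos, snp_id in enumerate(genotypes.columns, start=1):
            ref = other_alleles.get(snp_id, "A")
            alt = risk_alleles.get(snp_id, "G")
            col = genotypes[snp_id]
            calls = [
                "./." if pd.isna(v) else gt_map[int(v)] for v in col
            ]
            fh.write(f"1\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Import a minimal diploid VCF as a dosage table (ALT-allele count).

    Requires :mod:`cyvcf2`; multi-allelic records are rejected.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is an optional extra
        raise ImportError("VCF import requires the optional dependency cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for record in vcf:
        if len(record.ALT) != 1:
            raise ValidationError(f"multi-allelic site {record.ID or record.POS} not supported")
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(cyvcf2 uses 3), 2/3 unknown
        dosages = []
        for gt in record.genotypes:
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                dosages.append(np.nan)
            else:
                dosages.append(float((a > 0) + (b > 0)))
        data[record.ID or f"pos{record.POS}"] = np.array(dosages)
    out = pd.DataFrame(
        {k: pd.array(v, dtype="Int8") for k, v in data.items()},
        index=pd.Index(samples, name="sample_id"),
    )
    return out


def sha256_of(path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
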