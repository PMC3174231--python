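"""Bundled published summary statistics for the 12 candidate loci.

Twelve SNPs with replicated associations in genome-wide studies of female
breast cancer form the candidate panel.  For each locus the table below
carries the risk allele (defined by the female studies), its frequency in
European-ancestry controls, the published female per-allele odds ratio with
95% CI, and the male per-allele odds ratio with 95% CI estimated in a
case-control study of 433 male breast cancer cases and 1569 controls.

These printed estimates are pipeline *inputs*: the female panel is the
reference against which male effects are compared, and the male estimates
double as defaults for the cohort simulator (the generating per-allele odds
ratios) and as worked-example data.
"""

from __future__ import annotations

import io

import pandas as pd

# snp_id, locus, risk_allele, raf, male trend OR (95% CI), female trend OR (95% CI)
_PANEL_TSV = """\
snp_id	locus	risk_allele	raf	or_male	male_ci_low	male_ci_high	or_female	female_ci_low	female_ci_high
rs11249433	1p11.2	C	0.42	1.12	0.97	1.31	1.20	1.14	1.25
rs13387042	2q35	A	0.50	1.30	1.11	1.51	1.12	1.09	1.15
rs4973768	3p24.1	T	0.47	1.13	0.97	1.32	1.11	1.08	1.13
rs10941679	5p12	G	0.27	1.26	1.07	1.48	1.19	1.13	1.26
rs16886165	5q11.2	G	0.16	0.97	0.79	1.19	1.23	1.12	1.35
rs9383938	6q25.1	T	0.09	1.39	1.09	1.78	1.18	1.11	1.26
rs13281615	8q24.21	G	0.41	1.07	0.92	1.25	1.08	1.05	1.11
rs865686	9q31.2	T	0.62	1.04	0.89	1.22	1.11	1.04	1.19
rs2981579	10q26.13	T	0.42	1.18	1.02	1.38	1.26	1.23	1.30
rs3817198	11p15.5	C	0.32	0.93	0.79	1.09	1.07	1.04	1.11
rs3803662	16q12.1	T	0.27	1.48	1.26	1.75	1.20	1.16	1.24
rs6504950	17q22	G	0.72	0.90	0.76	1.06	1.05	1.03	1.07
"""


def panel_table() -> pd.DataFrame:
    """Full bundled panel as a DataFrame (one row per SNP)."""
    return pd.read_csv(io.StringIO(_PANEL_TSV), sep="\t")


def female_reference_panel() -> pd.DataFrame:
    """Published female per-allele OR reference panel.

    Columns ``snp_id, or, ci_low, ci_high, stratum`` — the TSV layout the
    comparison stage reads (stratum ``all``: overall female disease).
    """
    t = panel_table()
    return pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "or": t["or_female"],
            "ci_low": t["female_ci_low"],
            "ci_high": t["female_ci_high"],
            "stratum": "all",
        }
    )


def male_reference_panel() -> pd.DataFrame:
    """Published male per-allele OR estimates, same layout as the female panel."""
    t = panel_table()
    return pd.DataFrame(
        {
            "snp_id": t["snp_id"],
            "or": t["or_male"],
            "ci_low": t["male_ci_low"],
            "ci_high": t["male_ci_high"],
            "stratum": "male",
        }
    )


def default_snp_panel() -> list:
    """The 12-SNP simulation panel: control RAF from the published table and
    the published male trend OR as the generating per-allele odds ratio."""
    from .cohort_sim import SnpSimSpec

    t = panel_table()
    return [
        SnpSimSpec(snp_id=r.snp_id, raf=float(r.raf), psi=float(r.or_male))
        for r in t.itertuples()
    ]
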