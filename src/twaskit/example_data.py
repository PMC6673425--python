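"""Worked-example tables from a published stroke TWAS.

Small result tables from a transcriptome-wide association analysis of the
MEGASTROKE European-ancestry GWAS against three expression panels (METSIM
adipose, NTR and YFS blood), intersected with a peripheral-blood
case/control expression profile. They serve as compact real-world inputs
for documentation, tests and the acceptance script: the top-ten table
carries z-scores whose two-sided p-values and Bonferroni bookkeeping can be
recomputed, the overlap table exercises the feature-level intersection
arithmetic, and the term table exercises category counting.

The analysis behind these tables examined 11,826 gene-tissue features.
"""

from __future__ import annotations

import pandas as pd

#: Number of gene-tissue features tested in the source analysis (the m of
#: its Bonferroni correction).
N_FEATURES_TESTED = 11_826

#: Top ten gene-tissue features: gene, chromosome, z_TWAS, panel. Only the
#: two leading rows' printed p-values (5.46E-10 and 1.54E-06) are
#: self-consistent with their z-scores, so those are the reference pairs.
TOP_FEATURES = pd.DataFrame(
    [
        ("SLC25A44", 1, 6.2053, "METSIM"),
        ("LRCH1", 13, -4.8058, "METSIM"),
        ("FLJ44606", 5, 4.3540, "NTR"),
        ("PLEKHA1", 10, -4.3171, "METSIM"),
        ("ZNF318", 6, 4.2252, "NTR"),
        ("CD40", 20, 3.9748, "METSIM"),
        ("FES", 15, -3.9545, "METSIM"),
        ("RERE", 1, -3.9425, "NTR"),
        ("SLC25A29", 14, 3.8962, "METSIM"),
        ("LARS", 5, 3.8558, "METSIM"),
    ],
    columns=["GENE", "CHR", "ZTWAS", "PANEL"],
)

#: Candidate genes supported by both the TWAS and the expression profile:
#: per-panel TWAS p-values (NaN where the gene was not significant in that
#: panel) and the expression-profile p-value.
OVERLAP_TABLE = pd.DataFrame(
    [
        ("CISD1", 10, 0.00357, None, None, 0.0055),
        ("RHOU", 1, None, None, 0.00375, 0.0276),
        ("TM6SF1", 15, 0.0136, None, 0.00586, 0.0452),
        ("TP53RK", 20, None, None, 0.00803, 0.0205),
        ("CLDN5", 22, None, None, 0.00804, 0.0008),
        ("NFKBIA", 14, None, 0.00957, None, 0.0114),
        ("MRVI1", 11, 0.00997, None, None, 0.0359),
        ("ZNF667-AS1", 19, 0.01025, None, None, 0.0019),
        ("WDSUB1", 2, None, 0.01414, None, 0.0153),
        ("WSB1", 17, 0.04353, None, 0.01501, 0.0348),
        ("TPM1", 15, None, 0.01590, None, 0.0302),
        ("GOLGA8A", 15, None, None, 0.01704, 0.0062),
        ("TIPARP", 3, 0.02357, None, None, 0.0095),
        ("VRK2", 2, None, None, 0.02953, 0.0211),
        ("TOR1AIP1", 1, None, 0.0339, None, 0.0051),
        ("BARD1", 2, 0.03580, None, 0.04980, 0.0019),
        ("BAG5", 14, None, 0.03791, None, 0.0410),
        ("VASH1", 14, 0.04918, None, 0.03802, 0.0239),
        ("PDIA6", 2, None, None, 0.04136, 0.0031),
    ],
    columns=["GENE", "CHR", "P_METSIM", "P_NTR", "P_YFS", "P_MRNA"],
)

#: Enriched ontology terms reported for the candidate list (category, GO
#: id, name, enrichment p). The annotation database behind these p-values
#: is proprietary, so they document structure, not reproduction targets.
ENRICHED_TERMS = pd.DataFrame(
    [
        ("GOTERM_BP_DIRECT", "GO:0008360", "Regulation of cell shape", 0.0059),
        ("GOTERM_BP_DIRECT", "GO:0060325", "Face morphogenesis", 0.0247),
        ("GOTERM_BP_DIRECT", "GO:0032781", "Positive regulation of ATPase activity", 0.0256),
        ("GOTERM_MF_DIRECT", "GO:0004842", "Ubiquitin-protein transferase activity", 0.0336),
        ("GOTERM_BP_DIRECT", "GO:0016567", "Protein ubiquitination", 0.0350),
        ("GOTERM_MF_DIRECT", "GO:0008092", "Cytoskeletal protein binding", 0.0418),
        ("GOTERM_BP_DIRECT", "GO:0071407", "Cellular response to organic cyclic compound", 0.0481),
        ("GOTERM_BP_DIRECT", "GO:0045732", "Positive regulation of protein catabolic process", 0.0489),
    ],
    columns=["CATEGORY", "ID", "NAME", "P"],
)


def overlap_feature_results() -> list:
    """The overlap table flattened to per-feature TWAS results.

    One :class:`~twaskit.engine.TwasResult` per non-missing (gene, panel)
    p-value; z is back-computed from the two-sided p with the sign left
    positive (the intersection arithmetic only uses p). Permutation p is
    set below threshold because every listed feature passed the filter.
    """
    from scipy import stats

    from .engine import TwasResult

    results = []
    for row in OVERLAP_TABLE.itertuples(index=False):
        for panel in ("METSIM", "NTR", "YFS"):
            p = getattr(row, f"P_{panel}")
            if p is None or pd.isna(p):
                continue
            z = float(stats.norm.isf(p / 2.0))
            results.append(
                TwasResult(gene=row.GENE, panel=panel, z_twas=z, p_twas=float(p),
                           n_overlap=1, p_perm=0.001)
            )
    return results
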