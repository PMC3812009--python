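"""Published summary tables from the equine large-intestine core survey.

These are the printed, desk-checkable numbers of the original 10-animal x
8-region 16S study this pipeline models: the core-size matrix at four OTU
clustering identities (counts, totals and printed percentages), the
family-level classification of each region's 97%-identity core (OTU id
lists, four-rank lineages, relative abundance in percent and its standard
deviation), and the per-region core sizes quoted alongside the core
abundance profile.  They serve as inputs for worked examples — counting
distinct core OTU ids, summing family shares per region, re-deriving the
printed percentages — not as outputs of this package.

Raw sequence data of that survey is deposited at the EBI SRA under study
accession ERP002202 and is not required by anything here.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "core_size_table",
    "core_family_table",
    "PROFILE_CORE_COUNTS",
    "distinct_core_otus",
    "region_core_family_totals",
]

# (identity, region) -> (n_core, n_total, printed percentage text)
_CORE_SIZES: dict[tuple[int, str], tuple[int, int, str]] = {
    (90, "ileum"): (10, 571, "1.8"),
    (90, "caecum"): (75, 599, "12.5"),
    (90, "RVC"): (85, 681, "12.5"),
    (90, "LVC"): (72, 666, "10.8"),
    (90, "LDC"): (57, 795, "7.2"),
    (90, "RDC"): (70, 760, "9.2"),
    (90, "SC"): (55, 746, "7.4"),
    (90, "faeces"): (62, 728, "8.5"),
    (95, "ileum"): (8, 1154, "0.7"),
    (95, "caecum"): (62, 1517, "4.1"),
    (95, "RVC"): (64, 1741, "3.7"),
    (95, "LVC"): (52, 1730, "3"),
    (95, "LDC"): (29, 2013, "1.4"),
    (95, "RDC"): (36, 1895, "1.9"),
    (95, "SC"): (36, 1843, "2"),
    (95, "faeces"): (38, 1844, "2.1"),
    (97, "ileum"): (7, 1478, "0.5"),
    (97, "caecum"): (31, 2263, "1.4"),
    (97, "RVC"): (33, 2526, "1.3"),
    (97, "LVC"): (28, 2480, "1.1"),
    (97, "LDC"): (12, 2802, "0.4"),
    (97, "RDC"): (19, 2683, "0.7"),
    (97, "SC"): (16, 2520, "0.6"),
    (97, "faeces"): (25, 2566, "1"),
    (99, "ileum"): (8, 1980, "0.4"),
    (99, "caecum"): (62, 3747, "1.7"),
    (99, "RVC"): (64, 4050, "1.6"),
    (99, "LVC"): (52, 3860, "1.3"),
    (99, "LDC"): (30, 4145, "0.7"),
    (99, "RDC"): (36, 3823, "0.9"),
    (99, "SC"): (36, 3731, "1"),
    (99, "faeces"): (38, 3722, "1"),
}

#: Core sizes quoted with the 97%-identity core abundance profile.  Note the
#: profile quotes RDC as 18 while the core-size matrix prints 19 — a
#: discrepancy in the source, preserved as printed.
PROFILE_CORE_COUNTS: dict[str, int] = {
    "ileum": 7,
    "caecum": 31,
    "RVC": 33,
    "LVC": 28,
    "LDC": 12,
    "RDC": 18,
    "SC": 16,
    "faeces": 25,
}

# region -> rows of (otu id list ";"-joined, phylum, class, order, family,
#                    relative abundance %, standard deviation)
_CORE_FAMILIES: dict[str, list[tuple[str, str, str, str, str, float, float]]] = {
    "ileum": [
        ("19", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae 1", 3.32, 0.637),
        ("18;314", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", 3.77, 1.555),
        ("9;23", "Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", 8.47, 0.813),
        ("1;3", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", 16.35, 0.462),
    ],
    "caecum": [
        ("1", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", 0.16, 0.015),
        ("40", "unclassified", "unclassified", "unclassified", "unclassified", 0.33, 0.022),
        ("66", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", 0.35, 0.031),
        ("535", "Firmicutes", "Negativicutes", "Selenomonadales", "Acidaminococcaceae", 0.41, 0.022),
        ("105", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", 0.64, 0.052),
        ("52;484;500", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", 1.17, 0.049),
        ("16", "Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", 1.47, 0.127),
        ("32;55;139;485;524;960", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", 2.57, 0.127),
        ("78;118;125;237;390;670;687;2050", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 3.09, 0.087),
        ("82;115;146;158;216;278;495;655", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified", 3.74, 0.194),
    ],
    "RVC": [
        ("860", "Firmicutes", "Clostridia", "Clostridiales", "unclassified", 0.11, 0.009),
        ("1", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", 0.13, 0.009),
        ("147", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiales_Incertae Sedis XIII", 0.20, 0.017),
        ("535", "Firmicutes", "Negativicutes", "Selenomonadales", "Acidaminococcaceae", 0.20, 0.017),
        ("40", "unclassified", "unclassified", "unclassified", "unclassified", 0.65, 0.043),
        ("16", "Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", 1.24, 0.081),
        ("39;66", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", 1.36, 0.089),
        ("32;55", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", 1.77, 0.095),
        ("52;93;207;484;500", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", 2.12, 0.114),
        ("82;155;216;490;497;529", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified", 2.36, 0.118),
        ("6;78;118;125;143;149;193;262;265;288;390;999", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 4.45, 0.127),
    ],
    "LVC": [
        ("302", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiales_Incertae Sedis XII", 0.25, 0.019),
        ("50", "Spirochaetes", "Spirochaetes", "Spirochaetales", "Spirochaetaceae", 0.49, 0.081),
        ("40", "unclassified", "unclassified", "unclassified", "unclassified", 0.77, 0.041),
        ("39;66", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", 1.07, 0.102),
        ("16", "Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", 1.26, 0.088),
        ("52;73;93;236;484;1529", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", 2.02, 0.081),
        ("32;55", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", 2.09, 0.161),
        ("82;140;155;158;476;495", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified", 2.93, 0.120),
        ("61;118;149;193;237;288;390;431", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 3.38, 0.120),
    ],
    "LDC": [
        ("201", "Actinobacteria", "Actinobacteria", "Coriobacteriales", "Coriobacteriaceae", 0.17, 0.009),
        ("207", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", 0.18, 0.015),
        ("46", "Bacteroidetes", "unclassified", "unclassified", "unclassified", 0.63, 0.140),
        ("16", "Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", 0.79, 0.061),
        ("82", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified", 0.80, 0.101),
        ("72", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae 1", 1.21, 0.160),
        ("38;61;78;149;288;340", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 1.59, 0.079),
    ],
    "RDC": [
        ("7", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", 0.13, 0.009),
        ("69", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", 0.34, 0.019),
        ("95", "Spirochaetes", "Spirochaetes", "Spirochaetales", "Spirochaetaceae", 0.48, 0.046),
        ("35", "unclassified", "unclassified", "unclassified", "unclassified", 0.59, 0.051),
        ("17", "Firmicutes", "unclassified", "unclassified", "unclassified", 0.72, 0.154),
        ("82;158;495", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified", 0.98, 0.066),
        ("19;72", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae 1", 0.98, 0.115),
        ("46", "Bacteroidetes", "unclassified", "unclassified", "unclassified", 1.04, 0.196),
        ("38;118;149", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 1.24, 0.046),
        ("11", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", 1.56, 0.112),
        ("8;14;32", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", 3.55, 0.250),
    ],
    "SC": [
        ("82", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified", 0.44, 0.050),
        ("35", "unclassified", "unclassified", "unclassified", "unclassified", 0.45, 0.034),
        ("69;191;263;273;371", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", 1.22, 0.059),
        ("22;38;118;288;365", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 2.21, 0.077),
        ("11", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", 2.23, 0.195),
        ("14;32;55", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", 2.54, 0.199),
    ],
    "faeces": [
        ("127", "Bacteroidetes", "Sphingobacteria", "Sphingobacteriales", "unclassified", 0.27, 0.021),
        ("132;201", "Actinobacteria", "Actinobacteria", "Coriobacteriales", "Coriobacteriaceae", 0.29, 0.018),
        ("82", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified", 0.33, 0.029),
        ("16", "Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae", 0.66, 0.055),
        ("35;111", "unclassified", "unclassified", "unclassified", "unclassified", 0.72, 0.038),
        ("38;143;149", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", 1.39, 0.068),
        ("11", "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae", 1.65, 0.200),
        ("63;69;97;122;191;207;236;240;273;415", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", 2.64, 0.088),
        ("8;14;21;32", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", 5.74, 0.417),
    ],
}


def core_size_table() -> pd.DataFrame:
    """Published core-size matrix as a tidy frame.

    Columns: identity (percent), region, n_core, n_total, printed_pct
    (the percentage text as printed, trailing ``.0`` trimmed where the
    source trimmed it).
    """
    rows = [
        {
            "identity": ident,
            "region": region,
            "n_core": n_core,
            "n_total": n_total,
            "printed_pct": pct,
        }
        for (ident, region), (n_core, n_total, pct) in _CORE_SIZES.items()
    ]
    return pd.DataFrame(rows)


def core_family_table(region: str | None = None) -> pd.DataFrame:
    """Published family-level core classification (97% identity).

    Columns: region, otu_ids, phylum, class, order, family,
    relative_abundance_pct, sd_pct — rows in the printed (ascending
    abundance) order.
    """
    regions = [region] if region is not None else list(_CORE_FAMILIES)
    rows = []
    for reg in regions:
        for otus, ph, kl, od, fam, ab, sd in _CORE_FAMILIES[reg]:
            rows.append(
                {
                    "region": reg,
                    "otu_ids": otus,
                    "phylum": ph,
                    "class": kl,
                    "order": od,
                    "family": fam,
                    "relative_abundance_pct": ab,
                    "sd_pct": sd,
                }
            )
    return pd.DataFrame(rows)


def distinct_core_otus(region: str) -> list[str]:
    """Distinct OTU identifiers in the region's published core id lists."""
    seen: list[str] = []
    for otus, *_ in _CORE_FAMILIES[region]:
        for otu in otus.split(";"):
            if otu not in seen:
                seen.append(otu)
    return seen


def region_core_family_totals() -> pd.Series:
    """Per-region sum of the published family-level core abundances (%)."""
    tab = core_family_table()
    return tab.groupby("region", sort=False)["relative_abundance_pct"].sum()
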