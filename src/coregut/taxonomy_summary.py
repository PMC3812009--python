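"""Taxonomic roll-ups: phylum composition and family-level core summaries.

``phylum_composition`` pools a region's reads by phylum and reports
fractions, bucketing minor phyla (each below a configurable share) into an
``"others"`` category so that per-region proportions still sum to one.

``aggregate_core_families`` groups a region's core OTUs by their full
four-rank lineage.  Lineages that are unclassified at some rank are kept
separate whenever their coarser ranks differ (an unclassified family
within Bacteroidales is not the same row as an OTU only classified to
Bacteroidetes).  The family's relative abundance is the pooled core-OTU
share of the region's sequences (in percent); the dispersion column is the
standard deviation across animals of the per-animal family share.

``family_trajectories`` projects those summaries onto the fixed
gut-passage order of the large-intestine regions so a family's abundance
profile can be followed from caecum to faeces, with zeros where a family
is absent from a region's core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core_analysis import CoreResult
from .data_model import (
    GutRegion,
    LARGE_INTESTINE_ORDER,
    OtuTable,
    RANKS,
    TaxonomyTable,
    UNCLASSIFIED,
    ValidationError,
)

__all__ = [
    "FamilyCoreSummary",
    "phylum_composition",
    "aggregate_core_families",
    "family_trajectories",
    "lineage_label",
]


def phylum_composition(
    table: OtuTable,
    taxonomy: TaxonomyTable,
    others_below: float = 0.01,
) -> pd.DataFrame:
    """Per-region phylum proportions with an "others" bucket.

    Returns a frame indexed by region (gut-passage order) whose columns are
    the phyla reaching ``others_below`` in at least one region, plus
    ``"others"``.  Within each region, any phylum below the threshold has
    its mass moved to ``others``; rows sum to 1 exactly on the underlying
    integer counts.
    """
    phyla = pd.Series(
        {otu: taxonomy.lineage(otu)[0] for otu in table.otu_ids}, dtype=object
    )
    pooled = table.counts.groupby(table.regions, sort=False).sum()
    by_phylum = pooled.T.groupby(phyla.loc[pooled.columns]).sum().T
    fracs = by_phylum.div(by_phylum.sum(axis=1), axis=0)

    keep = fracs.columns[(fracs >= others_below).any(axis=0)]
    out = pd.DataFrame(0.0, index=fracs.index, columns=list(keep))
    out["others"] = 0.0
    for region, row in fracs.iterrows():
        for phylum, share in row.items():
            if phylum in keep and share >= others_below:
                out.loc[region, phylum] = share
            else:
                out.loc[region, "others"] += share
    order = [r.value for r in GutRegion if r.value in out.index]
    out = out.loc[order]
    out.index.name = "region"
    return out


def lineage_label(lineage: tuple[str, str, str, str]) -> str:
    """Display label distinguishing unclassified groups by their deepest
    classified rank (e.g. ``"unclassified Bacteroidales"`` vs
    ``"unclassified Bacteroidetes"``)."""
    phylum, klass, order, family = lineage
    if family != UNCLASSIFIED:
        return family
    for name in (order, klass, phylum):
        if name != UNCLASSIFIED:
            return f"{UNCLASSIFIED} {name}"
    return UNCLASSIFIED


@dataclass
class FamilyCoreSummary:
    """Family-level (full-lineage) breakdown of one region's core."""

    region: GutRegion
    table: pd.DataFrame  # otu_ids, phylum, class, order, family,
    #                      relative_abundance_pct, sd_pct — ascending abundance

    @property
    def total_core_abundance_pct(self) -> float:
        return float(self.table["relative_abundance_pct"].sum())


def aggregate_core_families(
    result: CoreResult,
    taxonomy: TaxonomyTable,
    per_animal_table: OtuTable | None = None,
) -> FamilyCoreSummary:
    """Group a region's core OTUs by full lineage and summarise abundance.

    ``per_animal_table`` defaults to the per-animal counts carried by the
    CoreResult; it must contain every core OTU.  Relative abundance is
    100 x (pooled core-OTU reads of the lineage) / (region pooled total);
    the ``sd_pct`` column is the across-animal standard deviation of the
    per-animal lineage share (ddof=1).
    """
    counts = (
        per_animal_table.counts
        if per_animal_table is not None
        else result.per_animal_counts
    )
    if counts is None:
        raise ValidationError("per-animal counts are required")
    missing = [o for o in result.core_otus if o not in counts.columns]
    if missing:
        raise ValidationError(f"core OTUs missing from table: {missing}")

    groups: dict[tuple[str, str, str, str], list[str]] = {}
    for otu in result.core_otus:
        if otu not in taxonomy:
            warnings.warn(
                f"core OTU {otu!r} missing from taxonomy; treated as fully "
                f"'{UNCLASSIFIED}'",
                stacklevel=2,
            )
        groups.setdefault(taxonomy.lineage(otu), []).append(otu)

    depths = counts.sum(axis=1)
    total = result.region_total_reads
    rows = []
    for lineage, otus in groups.items():
        lineage_counts = counts[otus].sum(axis=1)
        pooled_pct = 100.0 * lineage_counts.sum() / total
        per_animal_pct = 100.0 * lineage_counts / depths
        sd = float(per_animal_pct.std(ddof=1)) if len(per_animal_pct) > 1 else 0.0
        rows.append(
            {
                "otu_ids": ";".join(sorted(otus, key=_otu_sort_key)),
                **dict(zip(RANKS, lineage)),
                "relative_abundance_pct": float(pooled_pct),
                "sd_pct": sd,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["otu_ids", *RANKS, "relative_abundance_pct", "sd_pct"],
    ).sort_values("relative_abundance_pct", kind="stable", ignore_index=True)
    return FamilyCoreSummary(region=result.region, table=table)


def _otu_sort_key(otu: str):
    return (0, int(otu)) if otu.isdigit() else (1, otu)


def family_trajectories(
    summaries: Mapping[GutRegion, FamilyCoreSummary] | list[FamilyCoreSummary],
) -> pd.DataFrame:
    """Long-format family series across the large-intestine passage order.

    One row per (family label, region) for every family appearing in any
    region's core, in the fixed order caecum -> RVC -> LVC -> LDC -> RDC ->
    SC -> faeces (regions absent from the input are skipped); families
    absent from a region's core get mean and sd of 0 there.
    """
    if not isinstance(summaries, Mapping):
        summaries = {s.region: s for s in summaries}
    summaries = {GutRegion.parse(r): s for r, s in summaries.items()}
    regions = [r for r in LARGE_INTESTINE_ORDER if r in summaries]

    per_region: dict[GutRegion, dict[str, tuple[float, float]]] = {}
    labels: list[str] = []
    for region in regions:
        entry = {}
        for _, row in summaries[region].table.iterrows():
            label = lineage_label(tuple(row[r] for r in RANKS))
            entry[label] = (
                entry.get(label, (0.0, 0.0))[0] + row["relative_abundance_pct"],
                row["sd_pct"],
            )
            if label not in labels:
                labels.append(label)
        per_region[region] = entry

    rows = []
    for label in labels:
        for region in regions:
            mean, sd = per_region[region].get(label, (0.0, 0.0))
            rows.append(
                {
                    "family": label,
                    "region": region.value,
                    "mean_pct": mean,
                    "sd_pct": sd,
                }
            )
    return pd.DataFrame(rows)
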