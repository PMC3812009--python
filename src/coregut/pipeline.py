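"""End-to-end run: filter -> normalise -> diversity / core / taxa / heatmap.

``run_pipeline`` chains the stages in the canonical order on a single OTU
table, writes table-shaped TSV outputs plus Newick dendrograms into the
output directory, and emits a manifest (file list with SHA-256 checksums,
the resolved configuration and the seed) so a rerun with identical inputs
and seed reproduces identical checksums.  Any stage failure aborts with a
stage-named error; the log (stderr) records parameters and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community_structure import heatmap_analysis, plot_heatmap
from .core_analysis import (
    CoreParams,
    core_abundance_profile,
    core_size_matrix,
    identify_core,
)
from .data_model import (
    GutRegion,
    OtuTable,
    TaxonomyTable,
    pool_replicates,
    read_otu_table,
    read_taxonomy,
    write_otu_table,
)
from .diversity import alpha_diversity, two_way_anova_lsd
from .preprocess import filter_low_count, min_depth, rarefy
from .taxonomy_summary import (
    aggregate_core_families,
    family_trajectories,
    phylum_composition,
)

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger("coregut")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    otu_table: str
    metadata: str
    taxonomy: str
    out_dir: str
    seed: int = 0
    pool_replicates: bool = True
    min_reads: int = 4
    filter_mode: str = "zero_per_sample"
    depth: int | str = "auto"  # "auto" = minimum sample depth
    theta: float = 0.001
    prevalence: float = 1.0
    others_below: float = 0.01
    heatmap_threshold: float = 0.001
    distance: str = "bray_curtis"
    linkage: str = "average"
    render_heatmap: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s ...", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("read")
def _load(config: RunConfig) -> tuple[OtuTable, TaxonomyTable]:
    table = read_otu_table(config.otu_table, config.metadata)
    taxonomy = read_taxonomy(config.taxonomy)
    if config.pool_replicates:
        table = pool_replicates(table)
    return table, taxonomy


@_stage("filter")
def _filter(config: RunConfig, table: OtuTable) -> OtuTable:
    out, report = filter_low_count(
        table, min_reads=config.min_reads, mode=config.filter_mode
    )
    log.info(
        "filter: zeroed %d cells, dropped %d OTUs",
        report.n_cells_zeroed,
        report.n_otus_dropped,
    )
    return out

@_stage("rarefy")
def _normalise(config: RunConfig, table: OtuTable) -> OtuTable:
    depth = min_depth(table) if config.depth == "auto" else int(config.depth)
    log.info("rarefy: depth=%d seed=%d", depth, config.seed)
    return rarefy(table, depth, seed=config.seed)


@_stage("diversity")
def _diversity(config: RunConfig, table: OtuTable, out: Path) -> Path:
    per_sample = alpha_diversity(table, by="sample")
    regions = [r.value for r in GutRegion if r.value in set(table.regions)]
    summary = per_sample.groupby("region")[
        ["richness", "shannon", "simpson", "goods_coverage"]
    ].mean().loc[regions].T
    n_animals = per_sample["animal_id"].nunique()
    complete = (
        per_sample.groupby("region")["animal_id"].nunique().eq(n_animals).all()
        and len(regions) >= 2
        and n_animals >= 2
    )
    if complete:
        lsd_col, p_col, letters = [], [], {}
        for metric in summary.index:
            res = two_way_anova_lsd(per_sample[metric], table.samples)
            lsd_col.append(res.lsd)
            p_col.append(res.p_region)
            letters[metric] = res.letters
        rendered = summary.copy().astype(object)
        for metric in summary.index:
            for region in regions:
                rendered.loc[metric, region] = (
                    f"{summary.loc[metric, region]:.4g}"
                    f" ({letters[metric][region]})"
                )
        rendered["LSD"] = [f"{v:.4g}" for v in lsd_col]
        rendered["P value"] = [f"{v:.3g}" for v in p_col]
    else:
        log.warning("incomplete animal x region layout; skipping ANOVA columns")
        rendered = summary.round(4)
    path = out / "diversity.tsv"
    rendered.to_csv(path, sep="\t")
    return path


@_stage("core")
def _core(
    config: RunConfig, table: OtuTable, taxonomy: TaxonomyTable, out: Path
) -> list[Path]:
    params = CoreParams(
        prevalence_fraction=config.prevalence, abundance_threshold=config.theta
    )
    ident = table.clustering_identity or 0.97
    sizes = core_size_matrix({ident: table}, params)
    paths = [out / "core_sizes.tsv"]
    sizes.to_csv(paths[0], sep="\t", index=False)

    families, profiles, summaries = [], [], {}
    for region in [r for r in GutRegion if r.value in set(table.regions)]:
        res = identify_core(table.restrict_region(region), params)
        summary = aggregate_core_families(res, taxonomy)
        tab = summary.table.copy()
        tab.insert(0, "region", region.value)
        families.append(tab)
        if region is not GutRegion.ILEUM:
            summaries[region] = summary
        prof = core_abundance_profile(res)
        prof.insert(0, "region", region.value)
        profiles.append(prof)
    paths.append(out / "core_families.tsv")
    pd.concat(families, ignore_index=True).to_csv(paths[1], sep="\t", index=False)
    paths.append(out / "core_profile.tsv")
    pd.concat(profiles, ignore_index=True).to_csv(paths[2], sep="\t", index=False)
    if summaries:
        paths.append(out / "family_trajectories.tsv")
        family_trajectories(summaries).to_csv(paths[3], sep="\t", index=False)
    return paths


@_stage("taxa")
def _taxa(
    config: RunConfig, table: OtuTable, taxonomy: TaxonomyTable, out: Path
) -> Path:
    comp = phylum_composition(table, taxonomy, others_below=config.others_below)
    path = out / "phylum_composition.tsv"
    comp.to_csv(path, sep="\t")
    return path


@_stage("heatmap")
def _heatmap(config: RunConfig, table: OtuTable, out: Path) -> list[Path]:
    result = heatmap_analysis(
        table,
        threshold=config.heatmap_threshold,
        distance=config.distance,
        linkage=config.linkage,
    )
    paths = [
        out / "dendrogram_samples.nwk",
        out / "dendrogram_otus.nwk",
        out / "heatmap_matrix.tsv",
    ]
    result.sample_tree.to_newick(paths[0])
    result.otu_tree.to_newick(paths[1])
    result.ordered_matrix().to_csv(paths[2], sep="\t")
    if config.render_heatmap:
        paths.append(out / "heatmap.png")
        plot_heatmap(result, paths[3])
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return the output manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    log.setLevel(config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run: seed=%d out=%s", config.seed, out)

    table, taxonomy = _load(config)
    table = _filter(config, table)
    table = _normalise(config, table)
    norm_path = out / "normalized_table.tsv"
    write_otu_table(table, norm_path)

    outputs: list[Path] = [norm_path]
    outputs.append(_diversity(config, table, out))
    outputs.extend(_core(config, table, taxonomy, out))
    outputs.append(_taxa(config, table, taxonomy, out))
    try:
        outputs.extend(_heatmap(config, table, out))
    except StageError as exc:
        # a tiny table may not have 2+ OTUs above the heatmap threshold
        log.warning("%s (heatmap skipped)", exc)

    config.to_yaml(out / "config.yaml")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "outputs": {
            p.name: _sha256(p) for p in sorted(outputs, key=lambda p: p.name)
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("done: %d outputs", len(outputs))
    return manifest
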