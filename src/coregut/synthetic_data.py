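"""Synthetic multi-animal, multi-region OTU tables with known ground truth.

The generator emulates the design of a 10-animal x 8-gut-region 16S survey:
per-sample read depths near 3225-3800, a few thousand OTUs overall, a
planted core community per region (present in every animal, pooled share
above the 0.1% threshold with a safety margin) and sparse non-core OTUs
that miss core status through one of two mechanisms — low abundance
(pooled share below half the threshold) or partial occupancy (structurally
absent from at least one animal).

Regional composition follows the anatomy: the ileum has its own signature;
the proximal large intestine (caecum, RVC, LVC) and the distal large
intestine (RDC, SC, faeces) mix two contrasting signatures, with the LDC
halfway between.  Phylum totals per region are tilted to fixed targets
(large intestine dominated by Firmicutes ~46% and Bacteroidetes ~43%; the
ileum by Firmicutes ~70%, Proteobacteria ~14%, Bacteroidetes ~10%) and the
core slots carry field-realistic family lineages (Lactobacillaceae
dominating the ileum core, Lachnospiraceae the proximal and Prevotellaceae
the distal large intestine).

Counts are multinomial draws conditional on a per-sample proportion vector
(region truth x per-animal lognormal jitter x occupancy mask); an optional
Dirichlet concentration adds overdispersion for stress tests.  Everything
is a pure function of the seed: the same seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    GutRegion,
    OtuTable,
    REGION_ORDER,
    TaxonomyTable,
    UNCLASSIFIED,
    ValidationError,
    write_otu_table,
    write_sample_metadata,
    write_taxonomy,
)

__all__ = [
    "RegionCoreSpec",
    "SimParams",
    "SyntheticTruth",
    "simulate_study",
    "make_fixture",
    "score_core_recovery",
    "FIXTURE_NAMES",
]


# -- taxonomy presets -------------------------------------------------------

_LINEAGES: dict[str, tuple[str, str, str, str]] = {
    "Lachnospiraceae": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    "Ruminococcaceae": ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    "Clostridiaceae 1": ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae 1"),
    "Lactobacillaceae": ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae"),
    "Streptococcaceae": ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae"),
    "Erysipelotrichaceae": (
        "Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae",
    ),
    "Acidaminococcaceae": (
        "Firmicutes", "Negativicutes", "Selenomonadales", "Acidaminococcaceae",
    ),
    "Pasteurellaceae": (
        "Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae",
    ),
    "Prevotellaceae": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    "Porphyromonadaceae": (
        "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae",
    ),
    "unclassified Bacteroidales": (
        "Bacteroidetes", "Bacteroidia", "Bacteroidales", UNCLASSIFIED,
    ),
    "unclassified Bacteroidetes": (
        "Bacteroidetes", UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED,
    ),
    "Fibrobacteraceae": (
        "Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae",
    ),
    "Spirochaetaceae": ("Spirochaetes", "Spirochaetes", "Spirochaetales", "Spirochaetaceae"),
    "Coriobacteriaceae": (
        "Actinobacteria", "Actinobacteria", "Coriobacteriales", "Coriobacteriaceae",
    ),
}

# descending-abundance family slots for the planted core, per anatomical group
_CORE_FAMILY_SLOTS: dict[str, list[str]] = {
    "foregut_terminal": [
        "Lactobacillaceae", "Pasteurellaceae", "Lactobacillaceae",
        "Streptococcaceae", "Pasteurellaceae", "Streptococcaceae",
        "Clostridiaceae 1",
    ],
    "proximal_LI": [
        "unclassified Bacteroidales", "Lachnospiraceae", "Prevotellaceae",
        "Erysipelotrichaceae", "Ruminococcaceae", "Fibrobacteraceae",
        "Acidaminococcaceae", "Porphyromonadaceae", "Lactobacillaceae",
        "unclassified Bacteroidales", "Lachnospiraceae", "Ruminococcaceae",
    ],
    "intermediate": [
        "Lachnospiraceae", "Clostridiaceae 1", "unclassified Bacteroidales",
        "Erysipelotrichaceae", "unclassified Bacteroidetes",
        "Ruminococcaceae", "Coriobacteriaceae", "Lachnospiraceae",
    ],
    "distal_LI": [
        "Prevotellaceae", "Ruminococcaceae", "Fibrobacteraceae",
        "Lachnospiraceae", "unclassified Bacteroidetes", "Clostridiaceae 1",
        "Erysipelotrichaceae", "Spirochaetaceae", "Coriobacteriaceae",
        "Prevotellaceae", "Ruminococcaceae", "Lachnospiraceae",
    ],
}

# per-region-group phylum targets (fractions of pooled reads, sum to 1)
_PHYLUM_TARGETS: dict[str, dict[str, float]] = {
    "foregut_terminal": {
        "Firmicutes": 0.70, "Proteobacteria": 0.14, "Bacteroidetes": 0.10,
        "Actinobacteria": 0.02, "TM7": 0.01, "Tenericutes": 0.01,
        "Synergistetes": 0.01, "Cyanobacteria/Chloroplast": 0.01,
    },
    "large_intestine": {
        "Firmicutes": 0.46, "Bacteroidetes": 0.43, "Fibrobacteres": 0.035,
        "Spirochaetes": 0.0225, "Proteobacteria": 0.02, "Actinobacteria": 0.02,
        "TM7": 0.005, "Tenericutes": 0.0025, "Synergistetes": 0.0025,
        "Cyanobacteria/Chloroplast": 0.0025,
    },
}

# phylum weights used when assigning lineages to non-core OTUs
_NONCORE_PHYLUM_WEIGHTS: dict[str, float] = {
    "Firmicutes": 0.50, "Bacteroidetes": 0.30, "Proteobacteria": 0.07,
    "Fibrobacteres": 0.04, "Spirochaetes": 0.03, "Actinobacteria": 0.02,
    "TM7": 0.01, "Tenericutes": 0.01, "Synergistetes": 0.01,
    "Cyanobacteria/Chloroplast": 0.01,
}

_FAMILIES_BY_PHYLUM: dict[str, list[str]] = {}
for fam, (_ph, *_rest) in _LINEAGES.items():
    _FAMILIES_BY_PHYLUM.setdefault(_ph, []).append(fam)


@dataclass(frozen=True)
class RegionCoreSpec:
    """Planted core for one region: size, pooled share and per-OTU floor."""

    n_otus: int
    total_abundance: float
    floor: float

    def __post_init__(self) -> None:
        if self.n_otus < 0:
            raise ValidationError("n_otus must be >= 0")
        if not (0.0 <= self.total_abundance < 1.0):
            raise ValidationError("core total abundance must be in [0, 1)")
        if self.n_otus and self.floor * self.n_otus > self.total_abundance + 1e-12:
            raise ValidationError(
                "infeasible core spec: n_otus * floor exceeds total abundance"
            )


def _default_core_specs() -> dict[str, RegionCoreSpec]:
    # Core totals follow the study pattern (large ileal core concentrated in
    # few OTUs; large-intestine cores 5-15% of reads spread over more OTUs);
    # sizes are scaled so each member's share clears the 0.1% detection
    # threshold with a margin at depth 3225.
    return {
        "ileum": RegionCoreSpec(7, 0.32, 0.010),
        "caecum": RegionCoreSpec(15, 0.140, 0.006),
        "RVC": RegionCoreSpec(16, 0.145, 0.006),
        "LVC": RegionCoreSpec(14, 0.130, 0.006),
        "LDC": RegionCoreSpec(8, 0.055, 0.006),
        "RDC": RegionCoreSpec(10, 0.100, 0.006),
        "SC": RegionCoreSpec(9, 0.090, 0.006),
        "faeces": RegionCoreSpec(12, 0.130, 0.006),
    }


def _default_region_mix() -> dict[str, tuple[float, float]]:
    return {
        "caecum": (0.9, 0.1),
        "RVC": (0.9, 0.1),
        "LVC": (0.9, 0.1),
        "LDC": (0.5, 0.5),
        "RDC": (0.1, 0.9),
        "SC": (0.1, 0.9),
        "faeces": (0.1, 0.9),
    }


@dataclass
class SimParams:
    """Study-design parameters of the generator.

    Defaults reproduce the surveyed design: 10 animals, all 8 regions,
    4818 OTUs, depths uniform on [3225, 3800] (mean ~3500, minimum equal
    to the normalisation depth so rarefaction never fails on fixtures).
    """

    n_animals: int = 10
    regions: tuple[GutRegion, ...] = REGION_ORDER
    n_otus: int = 4818
    depth_min: int = 3225
    depth_max: int = 3800
    core: dict[str, RegionCoreSpec] = field(default_factory=_default_core_specs)
    core_threshold: float = 0.001  # the theta the planted margins protect
    core_decay: float = 0.80  # geometric profile of core shares (ileum: 0.45)
    noncore_sigma: float = 1.5  # lognormal sdlog of signature abundances
    signature_occupancy: float = 0.85  # P(OTU active in one LI signature)
    li_fraction: float = 0.75  # P(non-core OTU belongs to the LI pool)
    ileum_fraction: float = 0.30  # P(non-core OTU belongs to the ileum pool)
    region_mix: dict[str, tuple[float, float]] = field(
        default_factory=_default_region_mix
    )
    patchy_fraction: float = 0.30  # P(low-abundance OTU also made patchy)
    patchy_occupancy: tuple[int, int] = (5, 9)
    animal_sigma: float = 0.25  # per-animal lognormal jitter (sdlog)
    overdispersion: float | None = None  # Dirichlet concentration, optional
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        if not self.regions:
            raise ValidationError("at least one region is required")
        self.regions = tuple(GutRegion.parse(r) for r in self.regions)
        if self.depth_min < 1 or self.depth_max < self.depth_min:
            raise ValidationError("need 1 <= depth_min <= depth_max")
        for region in self.regions:
            spec = self.core.get(region.value)
            if spec is None:
                raise ValidationError(f"no core spec for region {region.value!r}")
            if spec.total_abundance >= 1.0:
                raise ValidationError("core total abundance must be < 1")
        lo, hi = self.patchy_occupancy
        if not (1 <= lo <= hi):
            raise ValidationError("patchy_occupancy bounds must satisfy 1 <= lo <= hi")


@dataclass
class SyntheticTruth:
    """Planted parameters emitted alongside the counts, for recovery tests."""

    core: dict[str, list[str]]  # region -> planted core OTU ids
    proportions: dict[str, pd.Series]  # region -> true share vector (pooled)
    region_groups: dict[str, str]
    mechanisms: dict[str, pd.Series]  # region -> 'core'/'rare'/'patchy' per active OTU
    occupancy: dict[str, pd.DataFrame]  # region -> animals x patchy-OTU presence
    taxonomy: TaxonomyTable = None
    params: SimParams = None


def _geometric_profile(
    n: int, total: float, floor: float, decay: float, rng: np.random.Generator
) -> np.ndarray:
    """Descending shares summing to ``total`` with every entry >= ``floor``."""
    base = decay ** np.arange(n)
    base *= rng.uniform(0.85, 1.18, size=n)
    base = np.sort(base)[::-1]
    base /= base.sum()
    return floor + (total - n * floor) * base


def _assign_noncore_lineages(
    n: int, rng: np.random.Generator
) -> list[tuple[str, str, str, str]]:
    phyla = list(_NONCORE_PHYLUM_WEIGHTS)
    weights = np.array([_NONCORE_PHYLUM_WEIGHTS[p] for p in phyla])
    weights /= weights.sum()
    picks = rng.choice(len(phyla), size=n, p=weights)
    out = []
    for k in picks:
        phylum = phyla[k]
        fams = _FAMILIES_BY_PHYLUM.get(phylum)
        if fams and rng.random() < 0.8:
            out.append(_LINEAGES[fams[rng.integers(len(fams))]])
        else:
            out.append((phylum, UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED))
    return out


def _phylum_tilt(
    shares: np.ndarray,
    phyla: np.ndarray,
    targets: Mapping[str, float],
    core_mass: Mapping[str, float],
    noncore_total: float,
) -> np.ndarray:
    """Rescale non-core shares so each phylum's grand total hits its target."""
    out = np.zeros_like(shares)
    # targets renormalised over phyla actually represented among non-core OTUs
    active = {ph for ph in np.unique(phyla) if shares[phyla == ph].sum() > 0}
    want = {}
    for ph, t in targets.items():
        if ph in active:
            # clamp: a phylum may overshoot its target through core
            # membership alone (large planted cores); its non-core mass then
            # drops to zero and the remaining phyla absorb the difference
            # proportionally
            want[ph] = max(t - core_mass.get(ph, 0.0), 0.0)
    total_want = sum(want.values())
    if total_want <= 0:
        raise ValidationError(
            "no non-core phylum mass left to distribute; core specs leave "
            "no room for a background community"
        )
    scale = noncore_total / total_want
    for ph, w in want.items():
        mask = phyla == ph
        out[mask] = shares[mask] * (w * scale / shares[mask].sum())
    return out


def simulate_study(
    params: SimParams | None = None, seed: int | None = None
) -> tuple[OtuTable, TaxonomyTable, SyntheticTruth]:
    """Draw a full synthetic study: counts, taxonomy and planted truth.

    ``seed`` overrides ``params.seed`` when given.  Counts are multinomial
    per sample conditional on region truth x animal jitter x occupancy.
    """
    if params is None:
        params = SimParams()
    if seed is not None:
        params = dataclasses.replace(params, seed=seed)
    rng = np.random.default_rng(params.seed)

    n_pool = params.n_otus
    otu_ids = np.array([f"OTU{i + 1:04d}" for i in range(n_pool)])
    regions = list(params.regions)
    li_regions = [r for r in regions if r is not GutRegion.ILEUM]

    # --- carve core candidate pools out of the front of the OTU pool
    def spec_of(r: GutRegion) -> RegionCoreSpec:
        return params.core[r.value]

    n_ileum_core = spec_of(GutRegion.ILEUM).n_otus if GutRegion.ILEUM in regions else 0
    prox_need = [
        spec_of(r).n_otus
        for r in li_regions
        if r.group in ("proximal_LI", "intermediate")
    ]
    dist_need = [
        spec_of(r).n_otus
        for r in li_regions
        if r.group in ("distal_LI", "intermediate")
    ]
    prox_pool_n = math.ceil(1.25 * max(prox_need, default=0))
    dist_pool_n = math.ceil(1.25 * max(dist_need, default=0))
    n_core_pool = n_ileum_core + prox_pool_n + dist_pool_n
    if n_core_pool >= n_pool:
        raise ValidationError("n_otus too small for the requested core specs")
    idx = np.arange(n_pool)
    ileum_core_pool = idx[:n_ileum_core]
    prox_core_pool = idx[n_ileum_core : n_ileum_core + prox_pool_n]
    dist_core_pool = idx[n_ileum_core + prox_pool_n : n_core_pool]
    noncore = idx[n_core_pool:]

    # --- taxonomy: non-core OTUs drawn by phylum weight; core-candidate
    #     pools get their group's family slots by pool position, so the
    #     minor-phylum families always sit at the low-share end of a pool
    lineage_of: dict[int, tuple[str, str, str, str]] = dict(
        zip(noncore.tolist(), _assign_noncore_lineages(len(noncore), rng))
    )
    for pool, group in (
        (ileum_core_pool, "foregut_terminal"),
        (prox_core_pool, "proximal_LI"),
        (dist_core_pool, "distal_LI"),
    ):
        slots = _CORE_FAMILY_SLOTS[group]
        for pos, otu_idx in enumerate(pool):
            lineage_of[int(otu_idx)] = _LINEAGES[slots[pos % len(slots)]]

    # --- per-region core membership and shares; members sorted by pool
    #     position and shares assigned in descending order, keeping each
    #     family at a consistent abundance rank across regions
    core_members: dict[str, np.ndarray] = {}
    core_shares: dict[str, np.ndarray] = {}
    for region in regions:
        spec = spec_of(region)
        if region is GutRegion.ILEUM:
            members = ileum_core_pool[: spec.n_otus]
        elif region.group == "intermediate":
            half = spec.n_otus // 2
            members = np.concatenate(
                [
                    rng.choice(prox_core_pool, size=spec.n_otus - half, replace=False),
                    rng.choice(dist_core_pool, size=half, replace=False),
                ]
            )
        elif region.group == "proximal_LI":
            members = rng.choice(prox_core_pool, size=spec.n_otus, replace=False)
        else:
            members = rng.choice(dist_core_pool, size=spec.n_otus, replace=False)
        members = np.sort(members)
        decay = 0.45 if region is GutRegion.ILEUM else params.core_decay
        shares = _geometric_profile(
            spec.n_otus, spec.total_abundance, spec.floor, decay, rng
        )
        core_members[region.value] = members
        core_shares[region.value] = shares

    taxonomy = TaxonomyTable(
        pd.DataFrame(
            [lineage_of[i] for i in range(n_pool)],
            index=pd.Index(otu_ids, name="otu_id"),
            columns=["phylum", "class", "order", "family"],
        )
    )
    phyla_arr = np.array([lineage_of[i][0] for i in range(n_pool)])

    # --- latent signatures for non-core OTUs
    in_li = rng.random(len(noncore)) < params.li_fraction
    in_ileum = rng.random(len(noncore)) < params.ileum_fraction
    orphan = ~(in_li | in_ileum)
    in_li[orphan] = True  # every OTU lives somewhere

    def signature(mask_extra: np.ndarray) -> np.ndarray:
        vals = np.zeros(n_pool)
        active = noncore[mask_extra]
        on = rng.random(len(active)) < params.signature_occupancy
        vals[active[on]] = rng.lognormal(0.0, params.noncore_sigma, size=on.sum())
        return vals

    sig_prox = signature(in_li)
    sig_dist = signature(in_li)
    sig_ileum = signature(in_ileum)

    # --- assemble per-region truth vectors
    proportions: dict[str, pd.Series] = {}
    mechanisms: dict[str, pd.Series] = {}
    occupancy: dict[str, pd.DataFrame] = {}
    cap = 0.45 * params.core_threshold
    group_targets = {
        "foregut_terminal": _PHYLUM_TARGETS["foregut_terminal"],
        "proximal_LI": _PHYLUM_TARGETS["large_intestine"],
        "intermediate": _PHYLUM_TARGETS["large_intestine"],
        "distal_LI": _PHYLUM_TARGETS["large_intestine"],
    }

    for region in regions:
        spec = spec_of(region)
        members = core_members[region.value]
        q = np.zeros(n_pool)
        q[members] = core_shares[region.value]
        core_mass: dict[str, float] = {}
        for otu_idx, share in zip(members, core_shares[region.value]):
            core_mass[phyla_arr[otu_idx]] = (
                core_mass.get(phyla_arr[otu_idx], 0.0) + share
            )

        if region is GutRegion.ILEUM:
            raw = sig_ileum.copy()
        else:
            wp, wd = params.region_mix[region.value]
            raw = wp * sig_prox + wd * sig_dist
        raw[members] = 0.0
        raw[:n_core_pool] = np.where(
            np.isin(np.arange(n_core_pool), members), 0.0, raw[:n_core_pool]
        )
        noncore_total = 1.0 - spec.total_abundance
        tilted = _phylum_tilt(
            raw, phyla_arr, group_targets[region.group], core_mass, noncore_total
        )
        q += tilted
        q /= q.sum()

        active = np.flatnonzero(q)
        mech = pd.Series("rare", index=otu_ids[active], dtype=object)
        mech[otu_ids[members]] = "core"
        nc_active = active[~np.isin(active, members)]
        forced = q[nc_active] >= cap
        random_patchy = rng.random(len(nc_active)) < params.patchy_fraction
        patchy = nc_active[forced | random_patchy]
        mech[otu_ids[patchy]] = "patchy"
        # scale forced-low OTUs that stayed 'rare' is unnecessary: everything
        # at/above the cap is patchy, so rare OTUs all sit below theta/2.

        occ = pd.DataFrame(
            True,
            index=[f"A{k + 1:02d}" for k in range(params.n_animals)],
            columns=otu_ids[patchy],
        )
        if len(patchy):
            lo, hi = params.patchy_occupancy
            hi = min(hi, params.n_animals - 1) if params.n_animals > 1 else lo
            lo = min(lo, hi)
            ks = rng.integers(lo, hi + 1, size=len(patchy))
            ranks = rng.random((params.n_animals, len(patchy))).argsort(axis=0)
            occ.iloc[:, :] = ranks < ks[None, :]

        proportions[region.value] = pd.Series(q, index=otu_ids)
        mechanisms[region.value] = mech
        occupancy[region.value] = occ

    # --- draw counts
    animals = [f"A{k + 1:02d}" for k in range(params.n_animals)]
    otu_pos = {o: i for i, o in enumerate(otu_ids)}
    sample_ids, meta_rows, count_rows = [], [], []
    for region in regions:
        q = proportions[region.value].to_numpy()
        occ = occupancy[region.value]
        patchy_idx = np.array([otu_pos[c] for c in occ.columns], dtype=int)
        for a_i, animal in enumerate(animals):
            p = q.copy()
            if len(patchy_idx):
                present = occ.iloc[a_i].to_numpy()
                p[patchy_idx[~present]] = 0.0
            support = np.flatnonzero(p)
            if params.animal_sigma > 0:
                p[support] *= rng.lognormal(0.0, params.animal_sigma, size=len(support))
            pv = p[support] / p[support].sum()
            if params.overdispersion is not None:
                pv = rng.dirichlet(pv * params.overdispersion)
            depth = int(rng.integers(params.depth_min, params.depth_max + 1))
            row = np.zeros(n_pool, dtype=np.int64)
            row[support] = rng.multinomial(depth, pv)
            sid = f"{animal}.{region.value}"
            sample_ids.append(sid)
            meta_rows.append((animal, region.value, 1))
            count_rows.append(row)

    counts = pd.DataFrame(
        np.vstack(count_rows), index=pd.Index(sample_ids, name="sample_id"),
        columns=otu_ids,
    )
    samples = pd.DataFrame(
        meta_rows,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["animal_id", "region", "replicate"],
    )
    table = OtuTable(counts, samples, clustering_identity=0.97)
    truth = SyntheticTruth(
        core={
            r.value: [str(otu_ids[i]) for i in core_members[r.value]]
            for r in regions
        },
        proportions=proportions,
        region_groups={r.value: r.group for r in regions},
        mechanisms=mechanisms,
        occupancy=occupancy,
        taxonomy=taxonomy,
        params=params,
    )
    return table, taxonomy, truth


def score_core_recovery(
    truth: SyntheticTruth, results: Mapping[str, "object"]
) -> tuple[float, float]:
    """Sensitivity and specificity of core calls against the planted truth.

    ``results`` maps region name to a CoreResult.  Sensitivity pools true
    positives over all planted core OTUs; specificity pools true negatives
    over all observed non-planted OTUs.
    """
    tp = fn = fp = tn = 0
    for region, result in results.items():
        planted = set(truth.core[region])
        called = set(result.core_otus)
        observed = set(
            result.per_animal_counts.columns[result.per_animal_counts.sum(axis=0) > 0]
        )
        tp += len(planted & called)
        fn += len(planted - called)
        fp += len(called - planted)
        tn += len((observed - planted) - called)
    sensitivity = tp / (tp + fn) if (tp + fn) else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    return sensitivity, specificity


FIXTURE_NAMES = ("tiny", "ileum_like", "full_study")


def _fixture_params(name: str, seed: int) -> SimParams:
    if name == "tiny":
        return SimParams(
            n_animals=3,
            regions=(GutRegion.ILEUM, GutRegion.CAECUM),
            n_otus=18,
            depth_min=150,
            depth_max=200,
            core={
                "ileum": RegionCoreSpec(2, 0.40, 0.08),
                "caecum": RegionCoreSpec(3, 0.30, 0.06),
            },
            seed=seed,
        )
    if name == "ileum_like":
        return SimParams(
            regions=(GutRegion.ILEUM,),
            n_otus=300,
            core={"ileum": RegionCoreSpec(7, 0.32, 0.010)},
            seed=seed,
        )
    if name == "full_study":
        return SimParams(seed=seed)
    raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture(name: str, out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a named fixture (counts, metadata, taxonomy, truth) to disk."""
    params = _fixture_params(name, seed)
    table, taxonomy, truth = simulate_study(params)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": out / "otu_table.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.json",
    }
    write_otu_table(table, paths["otu_table"])
    write_sample_metadata(table, paths["metadata"])
    write_taxonomy(taxonomy, paths["taxonomy"])
    truth_doc = {
        "name": name,
        "seed": seed,
        "core": truth.core,
        "region_groups": truth.region_groups,
        "proportions": {
            r: {k: round(float(v), 10) for k, v in s.items() if v > 0}
            for r, s in truth.proportions.items()
        },
        "mechanisms": {r: m.to_dict() for r, m in truth.mechanisms.items()},
        "params": {
            **dataclasses.asdict(truth.params),
            "regions": [r.value for r in truth.params.regions],
            "core": {
                k: dataclasses.asdict(v) for k, v in truth.params.core.items()
            },
        },
    }
    paths["truth"].write_text(
        json.dumps(truth_doc, indent=1, sort_keys=True), encoding="utf-8"
    )
    return paths
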