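"""Core-community identification per gut region.

An OTU belongs to a region's core community when it satisfies two
predicates over the region's even-depth table (one sample per animal):

* **prevalence** — detected (>= 1 read) in at least
  ``ceil(prevalence_fraction * A)`` of the ``A`` animals
  (default: all of them);
* **abundance** — its pooled count across animals is at least a fraction
  ``theta`` (default 0.1%) of the region's pooled sequences.  The
  denominator is the region's pooled normalised total (32 250 reads when
  ten samples are rarefied to 3225), not per-animal totals.  This predicate
  can be switched off to obtain the prevalence-only core.

Both predicates are monotone: raising ``theta`` or the prevalence fraction
can only shrink the core.

:class:`CoreIdentifier` is a scikit-learn style estimator
(``fit`` on a single-region table, fitted attributes with trailing
underscores); :func:`identify_core` is its functional wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_model import GutRegion, OtuTable, ValidationError

__all__ = [
    "CoreParams",
    "CoreResult",
    "CoreIdentifier",
    "identify_core",
    "core_size_matrix",
    "core_abundance_profile",
    "format_core_cell",
    "round_half_up",
]


@dataclass(frozen=True)
class CoreParams:
    """Thresholds of the two core predicates."""

    prevalence_fraction: float = 1.0
    abundance_threshold: float = 0.001
    apply_abundance: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_fraction <= 1.0):
            raise ValidationError("prevalence_fraction must be in (0, 1]")
        if not (0.0 <= self.abundance_threshold < 1.0):
            raise ValidationError("abundance_threshold must be in [0, 1)")


@dataclass
class CoreResult:
    """Core membership and abundances for one region."""

    region: GutRegion
    core_otus: list[str]
    abundances: pd.Series  # per core OTU, fraction of the region's pooled reads
    core_total_abundance: float
    n_total_otus: int  # OTUs observed (nonzero) in the region
    n_animals: int
    region_total_reads: int
    per_animal_counts: pd.DataFrame = field(repr=False, default=None)
    clustering_identity: float | None = None

    @property
    def n_core(self) -> int:
        return len(self.core_otus)


class CoreIdentifier(BaseEstimator):
    """Identify the core community of a single-region OTU table.

    Parameters mirror :class:`CoreParams`.  ``fit`` expects a table
    restricted to one gut region with exactly one sample per animal and
    positive depth everywhere (i.e. post-normalisation).

    Attributes
    ----------
    core_otus_ : list of str
        Core members, ordered by descending pooled abundance.
    abundances_ : pandas.Series
        Pooled relative abundance of each core OTU.
    core_total_abundance_ : float
    n_total_otus_ : int
    region_ : GutRegion
    n_animals_ : int
    """

    def __init__(
        self,
        prevalence_fraction: float = 1.0,
        abundance_threshold: float = 0.001,
        apply_abundance: bool = True,
    ):
        self.prevalence_fraction = prevalence_fraction
        self.abundance_threshold = abundance_threshold
        self.apply_abundance = apply_abundance

    def fit(self, X: OtuTable, y=None) -> "CoreIdentifier":
        params = CoreParams(
            self.prevalence_fraction, self.abundance_threshold, self.apply_abundance
        )
        regions = set(X.regions)
        if len(regions) != 1:
            raise ValidationError(
                f"core identification needs a single-region table; got {sorted(regions)}"
            )
        if X.animals.duplicated().any():
            raise ValidationError("expected one sample per animal")
        depths = X.depths
        if (depths == 0).any():
            zero = depths.index[depths == 0].tolist()
            raise ValidationError(f"zero-depth sample(s): {zero}")

        counts = X.counts
        n_animals = X.n_samples
        pooled = counts.sum(axis=0)
        total = int(pooled.sum())
        prevalence = (counts > 0).sum(axis=0)
        need = math.ceil(params.prevalence_fraction * n_animals)
        is_core = prevalence >= need
        if params.apply_abundance:
            share = pooled / total
            is_core &= share >= params.abundance_threshold

        core = pooled[is_core].sort_values(ascending=False, kind="stable")
        self.core_otus_ = list(core.index)
        self.abundances_ = core / total
        self.core_total_abundance_ = float(self.abundances_.sum())
        self.n_total_otus_ = int((pooled > 0).sum())
        self.region_ = GutRegion.parse(next(iter(regions)))
        self.n_animals_ = n_animals
        self.region_total_reads_ = total
        self._per_animal_counts = counts
        self._clustering_identity = X.clustering_identity
        return self

    def result(self) -> CoreResult:
        return CoreResult(
            region=self.region_,
            core_otus=list(self.core_otus_),
            abundances=self.abundances_.copy(),
            core_total_abundance=self.core_total_abundance_,
            n_total_otus=self.n_total_otus_,
            n_animals=self.n_animals_,
            region_total_reads=self.region_total_reads_,
            per_animal_counts=self._per_animal_counts,
            clustering_identity=self._clustering_identity,
        )


def identify_core(
    table: OtuTable, params: CoreParams | None = None, **kwargs
) -> CoreResult:
    """Core community of a single-region table (functional wrapper)."""
    if params is None:
        params = CoreParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword thresholds, not both")
    est = CoreIdentifier(
        prevalence_fraction=params.prevalence_fraction,
        abundance_threshold=params.abundance_threshold,
        apply_abundance=params.apply_abundance,
    )
    return est.fit(table).result()


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_core_cell(
    n_core: int, n_total: int, trim_trailing_zero: bool = False
) -> str:
    """Render a core-size cell as ``"n_core/n_total (p%)"``.

    The percentage is ``100 * n_core / n_total`` rounded half-up to one
    decimal.  With ``trim_trailing_zero`` a ``.0`` decimal is dropped
    (``"(1%)"`` instead of ``"(1.0%)"``), matching printed tables that
    trim exact integers.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    pct = round_half_up(100.0 * n_core / n_total, 1)
    text = f"{pct:.1f}"
    if trim_trailing_zero and text.endswith(".0"):
        text = text[:-2]
    return f"{n_core}/{n_total} ({text}%)"


def core_size_matrix(
    tables: Mapping[float, OtuTable],
    params: CoreParams | None = None,
) -> pd.DataFrame:
    """Core size per (clustering identity, region).

    ``tables`` maps identity level (e.g. 0.97) to an even-depth OtuTable
    covering the same animals and regions.  Returns a tidy frame with one
    row per (identity, region): core count, total observed OTUs, the
    one-decimal percentage and the rendered ``"n/total (p%)"`` cell.
    """
    if params is None:
        params = CoreParams()
    animal_sets = {
        ident: frozenset(t.animals) for ident, t in tables.items()
    }
    if len(set(animal_sets.values())) > 1:
        raise ValidationError(
            "all identity-level tables must cover the same animals"
        )
    region_sets = {
        ident: frozenset(t.regions) for ident, t in tables.items()
    }
    if len(set(region_sets.values())) > 1:
        raise ValidationError(
            "all identity-level tables must cover the same regions"
        )
    rows = []
    for ident in sorted(tables):
        table = tables[ident]
        present = [
            r for r in GutRegion if r.value in set(table.regions)
        ]
        for region in present:
            res = identify_core(table.restrict_region(region), params)
            pct = round_half_up(100.0 * res.n_core / res.n_total_otus, 1)
            rows.append(
                {
                    "identity": ident,
                    "region": region.value,
                    "n_core": res.n_core,
                    "n_total": res.n_total_otus,
                    "percentage": pct,
                    "rendered": format_core_cell(res.n_core, res.n_total_otus),
                }
            )
    return pd.DataFrame(rows)


def core_abundance_profile(result: CoreResult) -> pd.DataFrame:
    """Per-OTU core abundances plus the non-core remainder.

    Returns one row per core OTU (descending abundance) and a final
    ``"non_core"`` row whose read count is defined by subtraction, so the
    ``reads`` column sums exactly to the region total and the fractions
    to 1 (up to float rounding of exact rationals).
    """
    total = result.region_total_reads
    core_reads = (
        (result.abundances * total).round().astype(np.int64)
        if len(result.abundances)
        else pd.Series(dtype=np.int64)
    )
    if result.per_animal_counts is not None and len(result.core_otus):
        core_reads = result.per_animal_counts[result.core_otus].sum(axis=0)
    remainder = int(total - core_reads.sum())
    rows = [
        {
            "segment": otu,
            "reads": int(core_reads[otu]),
            "fraction": core_reads[otu] / total,
            "is_core": True,
        }
        for otu in result.core_otus
    ]
    rows.append(
        {
            "segment": "non_core",
            "reads": remainder,
            "fraction": remainder / total,
            "is_core": False,
        }
    )
    return pd.DataFrame(rows)
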