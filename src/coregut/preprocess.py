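"""Low-count OTU exclusion and seeded even-depth normalisation.

Two bespoke preprocessing steps precede every comparison across samples:

1. **Low-count exclusion** — counts below a small threshold (default 4
   reads per animal x region sample) are treated as likely sequencing
   artefacts.  The rule's wording admits two readings, both implemented:
   ``zero_per_sample`` zeroes any cell with ``1 <= count < min_reads``
   (preserving OTUs genuinely present elsewhere), while ``drop_global``
   removes an OTU column outright if any sample holds a nonzero count
   below the threshold.  Columns left all-zero are dropped in both modes.

2. **Rarefaction** — every sample is subsampled *without replacement* to a
   common depth (the study depth is 3225 reads, the minimum observed), i.e.
   a multivariate-hypergeometric draw per row.  Row sums after rarefaction
   equal the depth exactly, rarefied counts never exceed the originals, and
   a fixed seed reproduces the output bit-for-bit.

The transformer classes follow the scikit-learn estimator protocol
(``get_params``/``set_params``, ``fit``/``transform``); the module-level
functions are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import OtuTable, ValidationError

__all__ = [
    "FilterReport",
    "LowCountFilter",
    "Rarefier",
    "filter_low_count",
    "rarefy",
    "min_depth",
]

_FILTER_MODES = ("zero_per_sample", "drop_global")


@dataclass
class FilterReport:
    """What the low-count filter removed."""

    min_reads: int
    mode: str
    n_cells_zeroed: int = 0
    dropped_otus: list[str] = field(default_factory=list)

    @property
    def n_otus_dropped(self) -> int:
        return len(self.dropped_otus)


class LowCountFilter(TransformerMixin, BaseEstimator):
    """Exclude OTU counts below ``min_reads`` per animal x region sample.

    Parameters
    ----------
    min_reads : int, default 4
        Minimum reads for a nonzero cell to be kept.
    mode : {"zero_per_sample", "drop_global"}, default "zero_per_sample"
        ``zero_per_sample`` zeroes offending cells only; ``drop_global``
        discards the whole OTU column if any sample offends.

    Attributes
    ----------
    report_ : FilterReport
        Set by :meth:`transform`; cells zeroed and OTU columns dropped.
    """

    def __init__(self, min_reads: int = 4, mode: str = "zero_per_sample"):
        self.min_reads = min_reads
        self.mode = mode

    def _check_params(self) -> None:
        if int(self.min_reads) < 1:
            raise ValidationError("min_reads must be >= 1")
        if self.mode not in _FILTER_MODES:
            raise ValidationError(f"mode must be one of {_FILTER_MODES}")

    def fit(self, X: OtuTable, y=None) -> "LowCountFilter":
        self._check_params()
        return self

    def transform(self, X: OtuTable) -> OtuTable:
        self._check_params()
        min_reads = int(self.min_reads)
        counts = X.counts.copy()
        arr = counts.to_numpy()
        low = (arr >= 1) & (arr < min_reads)
        report = FilterReport(min_reads=min_reads, mode=self.mode)
        if self.mode == "zero_per_sample":
            report.n_cells_zeroed = int(low.sum())
            arr = arr.copy()
            arr[low] = 0
            counts = pd.DataFrame(arr, index=counts.index, columns=counts.columns)
            keep = arr.sum(axis=0) > 0
        else:  # drop_global
            offending = low.any(axis=0)
            keep = ~offending & (arr.sum(axis=0) > 0)
        report.dropped_otus = list(counts.columns[~keep])
        out = X.replace_counts(counts.loc[:, keep])
        self.report_ = report
        return out


def filter_low_count(
    table: OtuTable, min_reads: int = 4, mode: str = "zero_per_sample"
) -> tuple[OtuTable, FilterReport]:
    """Apply the low-count exclusion rule; return (table, report)."""
    est = LowCountFilter(min_reads=min_reads, mode=mode)
    out = est.fit(table).transform(table)
    return out, est.report_


def min_depth(table: OtuTable) -> int:
    """Minimum per-sample read total — the default rarefaction depth."""
    if table.n_samples == 0:
        raise ValidationError("cannot take min depth of an empty table")
    return int(table.depths.min())


def _rarefy_matrix(arr: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Multivariate-hypergeometric subsample of each row to ``depth``."""
    out = np.empty_like(arr)
    for i, row in enumerate(arr):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return out


class Rarefier(TransformerMixin, BaseEstimator):
    """Subsample every sample to an even depth, without replacement.

    Parameters
    ----------
    depth : int or None, default None
        Target depth.  ``None`` uses the table's minimum sample depth
        at :meth:`fit` time (the "lowest number seen" convention).
    seed : int, default 0
        Seed for the subsampling RNG; identical seeds give identical output.
    drop_empty_otus : bool, default False
        Drop OTU columns whose total becomes zero after rarefaction.

    Attributes
    ----------
    depth_ : int
        The resolved target depth.
    """

    def __init__(
        self,
        depth: int | None = None,
        seed: int = 0,
        drop_empty_otus: bool = False,
    ):
        self.depth = depth
        self.seed = seed
        self.drop_empty_otus = drop_empty_otus

    def fit(self, X: OtuTable, y=None) -> "Rarefier":
        self.depth_ = min_depth(X) if self.depth is None else int(self.depth)
        if self.depth_ < 1:
            raise ValidationError("rarefaction depth must be >= 1")
        return self

    def transform(self, X: OtuTable) -> OtuTable:
        if not hasattr(self, "depth_"):
            self.fit(X)
        depth = self.depth_
        depths = X.depths
        shallow = depths[depths < depth]
        if len(shallow):
            names = ", ".join(
                f"{s} ({int(d)} reads)" for s, d in shallow.items()
            )
            raise ValidationError(
                f"cannot rarefy to depth {depth}: sample(s) shallower than "
                f"target: {names}"
            )
        rng = np.random.default_rng(self.seed)
        arr = _rarefy_matrix(X.counts.to_numpy(), depth, rng)
        counts = pd.DataFrame(arr, index=X.counts.index, columns=X.counts.columns)
        out = X.replace_counts(counts)
        if self.drop_empty_otus:
            out = out.drop_empty_otus()
        return out


def rarefy(
    table: OtuTable,
    depth: int | None = None,
    *,
    seed: int = 0,
    drop_empty_otus: bool = False,
) -> OtuTable:
    """Rarefy every sample to ``depth`` (default: minimum sample depth)."""
    est = Rarefier(depth=depth, seed=seed, drop_empty_otus=drop_empty_otus)
    return est.fit(table).transform(table)
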