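"""Alpha diversity, coverage, rarefaction curves and the two-way ANOVA.

Definitions, on a vector of OTU counts ``N_i`` with total ``N`` and
proportions ``p_i = N_i / N``:

* richness ``S`` — number of OTUs with at least one read;
* Shannon–Wiener ``H' = -sum p_i ln p_i`` (natural log, i.e. nats);
* Gini–Simpson ``D = 1 - sum p_i^2`` (the probability that two random
  reads belong to different OTUs); an unbiased small-sample form
  ``1 - sum N_i (N_i - 1) / (N (N - 1))`` is available;
* Good's coverage ``C = 1 - F1 / N`` with ``F1`` the number of singleton
  OTUs — the estimated probability that the next read belongs to an
  already-observed OTU;
* expected rarefaction richness ``E[S_n] = sum_i [1 - C(N - N_i, n)/C(N, n)]``
  (hypergeometric; computed with log-gamma for stability), with a seeded
  Monte-Carlo alternative.

Per-sample scalars (one value per animal x region) are compared by an
additive two-way ANOVA ``y = mu + region + animal + e`` — with one
observation per cell the interaction is inestimable — followed by Fisher's
least significant difference ``LSD = t(1-a/2, df_resid) sqrt(2 MSE / n)``
and a compact letter display over the region means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import OtuTable, REGION_ORDER, ValidationError

__all__ = [
    "richness",
    "shannon",
    "simpson",
    "goods_coverage",
    "rarefaction_curve",
    "alpha_diversity",
    "AnovaResult",
    "two_way_anova_lsd",
]


def _as_counts(counts, require_positive_total: bool = True) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValidationError("counts must be a 1-D vector")
    if arr.size and np.any(arr < 0):
        raise ValidationError("counts must be non-negative")
    if require_positive_total and arr.sum() <= 0:
        raise ValidationError("counts must contain at least one read")
    return arr


def richness(counts) -> int:
    """Number of OTUs with a nonzero count."""
    arr = _as_counts(counts, require_positive_total=False)
    return int(np.count_nonzero(arr))


def shannon(counts) -> float:
    """Shannon–Wiener index H' in nats."""
    arr = _as_counts(counts).astype(float)
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts, unbiased: bool = False) -> float:
    """Gini–Simpson index 1 - sum p_i^2 (or the unbiased estimator)."""
    arr = _as_counts(counts).astype(float)
    n = arr.sum()
    if unbiased:
        if n < 2:
            raise ValidationError("unbiased Simpson requires >= 2 reads")
        return float(1.0 - (arr * (arr - 1.0)).sum() / (n * (n - 1.0)))
    p = arr / n
    return float(1.0 - (p * p).sum())


def goods_coverage(counts) -> float:
    """Good's coverage C = 1 - F1/N (F1 = number of singleton OTUs)."""
    arr = _as_counts(counts)
    f1 = int(np.count_nonzero(arr == 1))
    return float(1.0 - f1 / arr.sum())


def rarefaction_curve(
    counts,
    depths,
    method: str = "analytic",
    reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expected OTU richness at each subsampling depth.

    ``analytic`` evaluates the exact hypergeometric expectation
    ``E[S_n] = sum_i [1 - C(N-N_i, n) / C(N, n)]``; ``monte_carlo``
    averages observed richness over ``reps`` seeded subsamples without
    replacement.  Depths above the sample total are rejected.
    """
    arr = _as_counts(counts).astype(np.int64)
    pos = arr[arr > 0]
    total = int(arr.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if np.any(depths < 1) or np.any(depths > total):
        raise ValidationError(f"depths must lie in [1, {total}]")
    if method == "analytic":
        out = np.empty(len(depths), dtype=float)
        lng = special.gammaln
        for k, n in enumerate(depths):
            # log C(N - N_i, n) - log C(N, n); term is 0 when N - N_i < n
            rem = total - pos
            ok = rem >= n
            log_terms = np.full(len(pos), -np.inf)
            log_terms[ok] = (
                lng(rem[ok] + 1) - lng(n + 1) - lng(rem[ok] - n + 1)
                - (lng(total + 1) - lng(n + 1) - lng(total - n + 1))
            )
            out[k] = float(np.sum(1.0 - np.exp(log_terms)))
        return out
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        out = np.empty(len(depths), dtype=float)
        for k, n in enumerate(depths):
            draws = rng.multivariate_hypergeometric(pos, int(n), size=reps)
            out[k] = float((draws > 0).sum(axis=1).mean())
        return out
    raise ValidationError("method must be 'analytic' or 'monte_carlo'")


_METRIC_FUNCS = {
    "richness": richness,
    "shannon": shannon,
    "simpson": simpson,
    "goods_coverage": goods_coverage,
}


def alpha_diversity(
    table: OtuTable,
    by: str = "sample",
    metrics: tuple[str, ...] = ("richness", "shannon", "simpson", "goods_coverage"),
) -> pd.DataFrame:
    """Diversity metrics per sample or per pooled region.

    ``by="region"`` pools counts across all samples of a region before
    computing each metric (coverage and richness of the pooled community);
    ``by="sample"`` reports one row per sample with its animal and region.
    """
    unknown = [m for m in metrics if m not in _METRIC_FUNCS]
    if unknown:
        raise ValidationError(f"unknown metrics: {unknown}")
    if by == "sample":
        rows = {
            m: [_METRIC_FUNCS[m](row) for _, row in table.counts.iterrows()]
            for m in metrics
        }
        out = pd.DataFrame(rows, index=table.counts.index)
        out.insert(0, "animal_id", table.animals)
        out.insert(1, "region", table.regions)
        return out
    if by == "region":
        pooled = table.counts.groupby(table.regions, sort=False).sum()
        order = [r.value for r in REGION_ORDER if r.value in pooled.index]
        pooled = pooled.loc[order]
        rows = {
            m: [_METRIC_FUNCS[m](row) for _, row in pooled.iterrows()]
            for m in metrics
        }
        out = pd.DataFrame(rows, index=pooled.index)
        out.index.name = "region"
        return out
    raise ValidationError("by must be 'sample' or 'region'")


@dataclass
class AnovaResult:
    """Two-way ANOVA with Fisher's LSD over the region means."""

    anova_table: pd.DataFrame
    ms_resid: float
    df_resid: int
    lsd: float
    alpha: float
    level_means: pd.Series
    letters: dict[str, str]
    p_region: float
    p_animal: float
    f_region: float
    f_animal: float

    def summary(self) -> pd.DataFrame:
        """Region means with their significance letters, in level order."""
        return pd.DataFrame(
            {
                "mean": self.level_means,
                "letters": [self.letters[l] for l in self.level_means.index],
            }
        )


def _compact_letters(means: pd.Series, lsd: float) -> dict[str, str]:
    """Letter display by the sorted-means sweep.

    Levels are sorted ascending; each maximal run of levels whose extreme
    means differ by less than the LSD (or are exactly tied) shares one
    letter.  Ties in the sort are broken by the canonical region order of
    the index, which `means` is expected to follow.
    """
    order = means.sort_values(kind="stable").index.tolist()
    vals = means[order].to_numpy(dtype=float)
    k = len(order)
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and (
            vals[j + 1] - vals[i] < lsd or np.isclose(vals[j + 1], vals[i])
        ):
            j += 1
        runs.append((i, j))
    # keep maximal runs only
    maximal = [
        (a, b)
        for (a, b) in runs
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in runs)
    ]
    maximal.sort()
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {lv: [] for lv in order}
    for idx, (a, b) in enumerate(maximal):
        for pos in range(a, b + 1):
            letters[order[pos]].append(alphabet[idx % len(alphabet)])
    return {lv: "".join(ls) for lv, ls in letters.items()}


def two_way_anova_lsd(
    values: pd.Series,
    samples: pd.DataFrame,
    alpha: float = 0.05,
) -> AnovaResult:
    """Additive two-way ANOVA (region + animal) with LSD letters.

    Parameters
    ----------
    values
        Per-sample scalar (e.g. a diversity index), indexed by sample id.
    samples
        Metadata frame with ``animal_id`` and ``region`` columns indexed
        by sample id (an ``OtuTable.samples`` frame).
    alpha
        Two-sided significance level for the LSD (default 0.05).

    The layout must be complete with exactly one observation per
    animal x region cell; missing or duplicated cells are an error
    (no imputation).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "y": pd.to_numeric(values),
            "region": samples.loc[values.index, "region"],
            "animal": samples.loc[values.index, "animal_id"],
        }
    )
    pivot = df.pivot_table(
        index="animal", columns="region", values="y", aggfunc="count"
    )
    if pivot.isna().any().any() or (pivot != 1).any().any():
        raise ValidationError(
            "two-way ANOVA requires a complete layout with exactly one "
            "observation per animal x region cell"
        )
    n_regions = df["region"].nunique()
    n_animals = df["animal"].nunique()
    if n_regions < 2 or n_animals < 2:
        raise ValidationError("each factor needs >= 2 levels")

    model = ols("y ~ C(region) + C(animal)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ms_resid = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    df_resid = int(aov.loc["Residual", "df"])
    t_crit = float(stats.t.ppf(1 - alpha / 2, df_resid))
    lsd = t_crit * float(np.sqrt(2.0 * ms_resid / n_animals))

    region_order = [r.value for r in REGION_ORDER if r.value in set(df["region"])]
    extra = [r for r in df["region"].unique() if r not in region_order]
    region_order += sorted(extra)
    means = df.groupby("region")["y"].mean().loc[region_order]
    letters = _compact_letters(means, lsd)

    return AnovaResult(
        anova_table=aov,
        ms_resid=ms_resid,
        df_resid=df_resid,
        lsd=lsd,
        alpha=alpha,
        level_means=means,
        letters=letters,
        p_region=float(aov.loc["C(region)", "PR(>F)"]),
        p_animal=float(aov.loc["C(animal)", "PR(>F)"]),
        f_region=float(aov.loc["C(region)", "F"]),
        f_animal=float(aov.loc["C(animal)", "F"]),
    )
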