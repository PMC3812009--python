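import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coregut import OtuTable, SimParams, rarefy, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_table(counts, animals=None, regions=None, sample_ids=None, **kwargs):
    """Assemble an OtuTable from a plain count matrix and parallel labels."""
    counts = np.asarray(counts)
    n = counts.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if animals is None:
        animals = [f"A{i + 1}" for i in range(n)]
    if regions is None:
        regions = ["caecum"] * n
    frame = pd.DataFrame(
        counts,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"OTU{j + 1}" for j in range(counts.shape[1])],
    )
    meta = pd.DataFrame(
        {"animal_id": animals, "region": regions, "replicate": 1},
        index=frame.index,
    )
    return OtuTable(frame, meta, **kwargs)


def expected_observed_share(truth, region: str) -> pd.Series:
    """Expected pooled OTU shares given the planted truth.

    The generator masks 'patchy' OTUs out of some animals and renormalises
    each animal's proportion vector, so the expectation of an observed
    pooled share (at equal depths, no animal jitter) is the mean over
    animals of the masked, renormalised truth vector.
    """
    q = truth.proportions[region]
    occ = truth.occupancy[region]
    n_animals = truth.params.n_animals
    acc = np.zeros(len(q))
    for a in range(n_animals):
        p = q.to_numpy().copy()
        if len(occ.columns):
            absent = occ.columns[~occ.iloc[a].to_numpy()]
            p[q.index.get_indexer(absent)] = 0.0
        acc += p / p.sum()
    return pd.Series(acc / n_animals, index=q.index)


@pytest.fixture(scope="session")
def sim_study():
    """One full-study simulation shared across tests (seed fixed)."""
    table, taxonomy, truth = simulate_study(SimParams(seed=7))
    return table, taxonomy, truth


@pytest.fixture(scope="session")
def sim_rarefied(sim_study):
    table, taxonomy, truth = sim_study
    return rarefy(table, 3225, seed=11), taxonomy, truth
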