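import numpy as np
import pandas as pd
import pytest

from ictonet.discretize import DiscreteTable
from ictonet.preprocess import Group, Recording, SliceSchema, StageAnnotation


def make_discrete(columns: dict[str, list[int]], animal_id: str = "t",
                  arity: dict[str, int] | None = None) -> DiscreteTable:
    """Small integer table for scoring tests; arity defaults to max+1."""
    frame = pd.DataFrame({k: np.asarray(v, dtype=np.int64)
                          for k, v in columns.items()})
    if arity is None:
        arity = {c: (int(frame[c].max()) + 1 if len(frame) else 1)
                 for c in frame.columns}
    return DiscreteTable(animal_id=animal_id, frame=frame, arity=arity,
                         binnings={})


def random_discrete(rng: np.random.Generator, names: list[str], n: int,
                    max_arity: int = 3) -> DiscreteTable:
    """Random categorical table with mild dependence between columns."""
    cols: dict[str, np.ndarray] = {}
    base = rng.integers(0, max_arity, size=n)
    for name in names:
        r = int(rng.integers(2, max_arity + 1))
        noise = rng.integers(0, r, size=n)
        mix = rng.random(n) < 0.5
        cols[name] = np.where(mix, base % r, noise).astype(np.int64)
    frame = pd.DataFrame(cols)
    return DiscreteTable(animal_id="rand", frame=frame,
                         arity={c: int(frame[c].max()) + 1 for c in names},
                         binnings={})


def dm_log_marginal(data: DiscreteTable, parents_of: dict[str, tuple[str, ...]],
                    ess: float) -> float:
    """Independent oracle: log marginal likelihood of a discrete dataset
    under a DAG with BDeu-style Dirichlet priors, computed as the product
    of sequential predictive probabilities (no gamma functions)."""
    from collections import defaultdict

    counts: dict = defaultdict(lambda: defaultdict(int))
    totals: dict = defaultdict(int)
    arities = data.arity
    loglik = 0.0
    rows = data.frame.to_numpy()
    col_index = {c: i for i, c in enumerate(data.columns)}
    for row in rows:
        for child, parents in parents_of.items():
            r = arities[child]
            q = 1
            for p in parents:
                q *= arities[p]
            key = (child, tuple(int(row[col_index[p]]) for p in parents))
            k = int(row[col_index[child]])
            num = counts[key][k] + ess / (r * q)
            den = totals[key] + ess / q
            loglik += np.log(num / den)
            counts[key][k] += 1
            totals[key] += 1
    return loglik


def all_dags(nodes: tuple[str, ...]) -> list[set[tuple[str, str]]]:
    """Exhaustive enumeration of DAGs over the given nodes (25 for 3)."""
    import itertools

    import networkx as nx

    pairs = [(u, v) for u in nodes for v in nodes if u < v]
    dags = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        arcs = set()
        for (u, v), s in zip(pairs, states):
            if s == 1:
                arcs.add((u, v))
            elif s == 2:
                arcs.add((v, u))
        g = nx.DiGraph(arcs)
        g.add_nodes_from(nodes)
        if nx.is_directed_acyclic_graph(g):
            dags.append(arcs)
    return dags


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def basal_schema() -> SliceSchema:
    return SliceSchema()


def make_recording(n_seconds: float = 5.0, rate: float = 1000.0,
                   group: Group = Group.GTCS_GROUP,
                   channels=("TH", "HP", "CX"), seed: int = 0) -> Recording:
    g = np.random.default_rng(seed)
    n = int(round(n_seconds * rate))
    return Recording(animal_id="a0", group=group, sample_rate=rate,
                     channels=channels,
                     samples=g.normal(size=(len(channels), n)))


def make_annotation(group: Group = Group.GTCS_GROUP,
                    starts: dict[str, float] | None = None,
                    end: float = 5.0) -> StageAnnotation:
    if starts is None:
        starts = {"basal": 0.0, "infusion": 1.0, "myo": 2.5}
        if group is Group.GTCS_GROUP:
            starts["gtcs"] = 3.5
    return StageAnnotation(animal_id="a0", group=group, starts=starts,
                           recording_end=end)
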