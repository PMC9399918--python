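"""Model averaging of K replicate DAGs and the analytical arc threshold.

For every unordered node pair the three possible states — forward arc,
reverse arc, absent — are tallied over the replicate DAGs that contain both
nodes.  A directed arc is accepted into the consensus when its frequency
reaches the analytical threshold

    f = 1/3 + 2/K

which exceeds the 1/3 rate a direction would attain if the three states
were equally likely by chance, with a finite-sample margin shrinking in K.
Slices not recorded in every animal (GTCS is observed only in the GTCS
group) are handled through the *effective K* of each pair: the number of
replicates in which both endpoints exist.  Both directions of a pair are
thresholded independently, so an exact tie can legitimately be reported as
bidirectional.  Sub-threshold ("gray") arcs are retained with their counts
for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import StructuralError
from .preprocess import Group, SliceSchema
from .structure import DAGStructure

Arc = tuple[str, str]


@dataclass
class PairCounts:
    """Arc-state tallies for one unordered node pair (a, b), a < b."""

    a: str
    b: str
    forward: int = 0  # a -> b
    reverse: int = 0  # b -> a
    absent: int = 0
    effective_k: int = 0
    by_group: dict[Group, dict[str, int]] = field(default_factory=dict)

    def count(self, u: str, v: str) -> int:
        if (u, v) == (self.a, self.b):
            return self.forward
        if (u, v) == (self.b, self.a):
            return self.reverse
        raise KeyError((u, v))

    def group_count(self, u: str, v: str, group: Group) -> int:
        key = "forward" if (u, v) == (self.a, self.b) else "reverse"
        return self.by_group.get(group, {}).get(key, 0)


@dataclass
class ArcStateCounts:
    K: int
    k_by_group: dict[Group, int]
    pairs: dict[tuple[str, str], PairCounts]

    def directed_count(self, u: str, v: str) -> int:
        pair = self.pairs[tuple(sorted((u, v)))]
        return pair.count(u, v)


@dataclass
class ConsensusGraph:
    """Accepted arcs (with counts) plus retained sub-threshold arcs."""

    accepted: dict[Arc, int]
    rejected: dict[Arc, int]  # observed at least once but below threshold
    effective_k: dict[Arc, int]
    threshold: dict[Arc, float]
    K: int

    @property
    def accepted_arcs(self) -> set[Arc]:
        return set(self.accepted)

    def all_learned_arcs(self) -> set[Arc]:
        return set(self.accepted) | set(self.rejected)


def count_arc_states(dags: Sequence[DAGStructure],
                     groups: Sequence[Group],
                     animal_ids: Sequence[str] | None = None) -> ArcStateCounts:
    """Tally forward / reverse / absent per unordered pair over the DAGs in
    which both nodes exist.  Conservation (forward + reverse + absent =
    effective K) is asserted for every pair."""
    if len(dags) != len(groups):
        raise StructuralError("one group label per DAG is required")
    if animal_ids is not None:
        if len(set(animal_ids)) != len(animal_ids):
            raise StructuralError("duplicate animal ids")
    groups = [Group(g) for g in groups]

    universe: set[str] = set()
    for g in dags:
        universe |= set(g.nodes)
    nodes = sorted(universe)

    pairs: dict[tuple[str, str], PairCounts] = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            pairs[(a, b)] = PairCounts(a=a, b=b)

    for dag, grp in zip(dags, groups):
        node_set = set(dag.nodes)
        arcs = dag.arcs
        for (a, b), pc in pairs.items():
            if a not in node_set or b not in node_set:
                continue
            pc.effective_k += 1
            gc = pc.by_group.setdefault(grp, {"forward": 0, "reverse": 0})
            if (a, b) in arcs:
                pc.forward += 1
                gc["forward"] += 1
            elif (b, a) in arcs:
                pc.reverse += 1
                gc["reverse"] += 1
            else:
                pc.absent += 1

    for pc in pairs.values():
        assert pc.forward + pc.reverse + pc.absent == pc.effective_k, \
            f"conservation violated for pair ({pc.a}, {pc.b})"

    k_by_group = {g: sum(1 for gg in groups if gg is g) for g in Group}
    return ArcStateCounts(K=len(dags), k_by_group=k_by_group, pairs=pairs)


def analytical_threshold(k: int) -> float:
    """Minimum acceptance frequency f = 1/3 + 2/K."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return 1.0 / 3.0 + 2.0 / k


def select_arcs(counts: ArcStateCounts) -> ConsensusGraph:
    """Accept arc u->v iff count / effective_K >= f(effective_K); both
    directions are evaluated independently.  Comparison is >=, so a
    frequency exactly at the threshold passes."""
    accepted: dict[Arc, int] = {}
    rejected: dict[Arc, int] = {}
    eff: dict[Arc, int] = {}
    thr: dict[Arc, float] = {}
    for (a, b), pc in counts.pairs.items():
        if pc.effective_k == 0:
            continue
        f = analytical_threshold(pc.effective_k)
        for (u, v, n) in ((a, b, pc.forward), (b, a, pc.reverse)):
            if n == 0:
                continue
            eff[(u, v)] = pc.effective_k
            thr[(u, v)] = f
            if n / pc.effective_k >= f:
                accepted[(u, v)] = n
            else:
                rejected[(u, v)] = n
    return ConsensusGraph(accepted=accepted, rejected=rejected,
                          effective_k=eff, threshold=thr, K=counts.K)


def arc_frequency_table(counts: ArcStateCounts,
                        consensus: ConsensusGraph | None = None) -> pd.DataFrame:
    """Accepted arcs with per-group and global frequencies (the layout of
    the study's strongest-arcs table)."""
    if consensus is None:
        consensus = select_arcs(counts)
    rows = []
    for (u, v), n in sorted(consensus.accepted.items()):
        pc = counts.pairs[tuple(sorted((u, v)))]
        rows.append({
            "from": u,
            "to": v,
            "myo_group": pc.group_count(u, v, Group.MYO_GROUP),
            "gtcs_group": pc.group_count(u, v, Group.GTCS_GROUP),
            "global": n,
            "effective_k": consensus.effective_k[(u, v)],
            "threshold": consensus.threshold[(u, v)],
        })
    return pd.DataFrame(rows, columns=["from", "to", "myo_group", "gtcs_group",
                                       "global", "effective_k", "threshold"])


def frequency_histograms(counts: ArcStateCounts,
                         schema: SliceSchema = SliceSchema()) -> pd.DataFrame:
    """Per ordered pair: frequency and threshold line, grouped by the slice
    (or slice pair) the arc lives in — the data behind the per-slice
    histogram figures.  Both directions of every pair are listed."""
    rows = []
    for (a, b), pc in counts.pairs.items():
        if pc.effective_k == 0:
            continue
        f = analytical_threshold(pc.effective_k)
        sa, sb = schema.slice_of(a), schema.slice_of(b)
        for (u, v, n) in ((a, b, pc.forward), (b, a, pc.reverse)):
            su, sv = schema.slice_of(u), schema.slice_of(v)
            rows.append({
                "slice": su if sa == sb else f"{su}->{sv}",
                "from": u,
                "to": v,
                "count": n,
                "effective_k": pc.effective_k,
                "frequency": n / pc.effective_k,
                "threshold": f,
            })
    frame = pd.DataFrame(rows, columns=["slice", "from", "to", "count",
                                        "effective_k", "frequency", "threshold"])
    return frame.sort_values(["slice", "from", "to"], ignore_index=True)


def project_slice_graph(consensus: ConsensusGraph,
                        schema: SliceSchema = SliceSchema(),
                        arc_set: str = "all_learned") -> tuple[nx.DiGraph, dict]:
    """Slice-level digraph: edge slice_i -> slice_j (i < j) iff the chosen
    arc set contains an arc between nodes of those slices.  Intra-slice arcs
    produce no slice edge.  Returns the digraph and a reachability report
    focused on whether the first slice reaches the last one, and through
    which intermediate slices."""
    if arc_set not in ("accepted", "all_learned"):
        raise ValueError("arc_set must be 'accepted' or 'all_learned'")
    arcs = (consensus.accepted_arcs if arc_set == "accepted"
            else consensus.all_learned_arcs())
    g = nx.DiGraph()
    g.add_nodes_from(schema.ordered_slices)
    for u, v in arcs:
        su, sv = schema.slice_of(u), schema.slice_of(v)
        if su != sv:
            g.add_edge(su, sv)

    first, last = schema.ordered_slices[0], schema.ordered_slices[-1]
    reachable = nx.has_path(g, first, last)
    report = {
        "arc_set": arc_set,
        "edges": sorted(g.edges()),
        "direct_edge_first_to_last": g.has_edge(first, last),
        "first_reaches_last": reachable,
        "intermediate_slices_on_paths": sorted(
            {s for path in nx.all_simple_paths(g, first, last) for s in path[1:-1]}
        ) if reachable else [],
    }
    return g, report


def recovery_metrics(found: Iterable[Arc], truth: Iterable[Arc],
                     schema: SliceSchema | None = None,
                     restrict: str | None = None) -> dict:
    """Directed-arc precision/recall of a found arc set against a planted
    one; ``restrict='intra'``/``'inter'`` limits both sets to intra- or
    inter-slice arcs."""
    def keep(arc: Arc) -> bool:
        if restrict is None or schema is None:
            return True
        same = schema.slice_of(arc[0]) == schema.slice_of(arc[1])
        return same if restrict == "intra" else not same

    found_set = {a for a in found if keep(a)}
    truth_set = {a for a in truth if keep(a)}
    tp = len(found_set & truth_set)
    # undefined ratios (empty denominator) are reported as None, not NaN
    precision = tp / len(found_set) if found_set else None
    recall = tp / len(truth_set) if truth_set else None
    return {"precision": precision, "recall": recall,
            "n_found": len(found_set), "n_true": len(truth_set),
            "n_correct": tp}


def consensus_dot(consensus: ConsensusGraph, name: str = "consensus") -> str:
    """DOT export: accepted arcs solid black, sub-threshold arcs gray."""
    nodes = sorted({n for arc in (*consensus.accepted, *consensus.rejected)
                    for n in arc})
    lines = [f"digraph {name} {{"]
    for v in nodes:
        lines.append(f'  "{v}";')
    for (u, v), n in sorted(consensus.accepted.items()):
        lines.append(f'  "{u}" -> "{v}" [color=black, label="{n}"];')
    for (u, v), n in sorted(consensus.rejected.items()):
        lines.append(f'  "{u}" -> "{v}" [color=gray, style=dashed, label="{n}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def consensus_networkx(consensus: ConsensusGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for (u, v), n in consensus.accepted.items():
        g.add_edge(u, v, count=n, accepted=True,
                   effective_k=consensus.effective_k[(u, v)],
                   threshold=consensus.threshold[(u, v)])
    for (u, v), n in consensus.rejected.items():
        g.add_edge(u, v, count=n, accepted=False,
                   effective_k=consensus.effective_k[(u, v)],
                   threshold=consensus.threshold[(u, v)])
    return g
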