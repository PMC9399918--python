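"""BDeu-scored hill-climbing structure learning over (channel, slice) nodes.

One DAG is learned per animal from its discretized variable table.  The
score is the Bayesian Dirichlet equivalent uniform (BDeu) marginal
likelihood with a single equivalent-sample-size parameter alpha: for child
X with arity r and a parent set of joint cardinality q,

    score(X | Pa) = sum_j [ lnG(a/q) - lnG(N_j + a/q) ]
                  + sum_jk [ lnG(N_jk + a/(r q)) - lnG(a/(r q)) ]

with N_jk the count of child state k under parent configuration j and
N_j = sum_k N_jk.  Unrealized parent configurations contribute exactly 0,
so counting is sparse over realized configurations only and stays tractable
for 128-ary variables.  BDeu is decomposable (the total is the sum of local
scores) and score-equivalent (Markov-equivalent DAGs tie exactly).

The search is greedy hill climbing over single-arc additions, deletions and
reversals, restricted by acyclicity and temporal precedence (no arc from a
later slice to an earlier one).  Because of score equivalence the two
orientations of a new intra-slice arc are usually an exact tie; ties are
broken uniformly at random with the run's seeded RNG, so replicate runs
spread over the Markov-equivalence class instead of all collapsing onto one
arbitrary orientation — the spread is what the downstream model-averaging
threshold operates on.  On a local optimum the search restarts from a fresh
random DAG until the budget of candidate-move evaluations is exhausted, and
the best-scoring DAG seen is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .discretize import DiscreteTable
from .errors import StructuralError
from .preprocess import SliceSchema

Move = tuple[str, str, str]  # ("add" | "delete" | "reverse", source, target)

_MIN_GAIN = 1e-6  # strict-improvement margin; exact score-equivalent ties sit below
_TIE_TOL = 1e-9

_COMPACT_LIMIT = 1 << 62  # re-encode parent configurations before int64 overflow


class DAGStructure:
    """Directed acyclic graph over variable names with parent/child maps."""

    __slots__ = ("nodes", "_parents", "_children")

    def __init__(self, nodes, arcs=()):
        self.nodes: tuple[str, ...] = tuple(nodes)
        self._parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._children: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in arcs:
            self.add_arc(u, v)

    # -- basic accessors ----------------------------------------------------
    def parents(self, v: str) -> frozenset:
        return frozenset(self._parents[v])

    @property
    def arcs(self) -> set[tuple[str, str]]:
        return {(u, v) for v, ps in self._parents.items() for u in ps}

    def has_arc(self, u: str, v: str) -> bool:
        return u in self._parents[v]

    def add_arc(self, u: str, v: str) -> None:
        if u == v:
            raise StructuralError("self-arcs are not allowed")
        if u not in self._parents or v not in self._parents:
            raise StructuralError(f"unknown node in arc ({u}, {v})")
        self._parents[v].add(u)
        self._children[u].add(v)

    def remove_arc(self, u: str, v: str) -> None:
        self._parents[v].discard(u)
        self._children[u].discard(v)

    def has_path(self, u: str, v: str) -> bool:
        """Directed path u ~> v (including the trivial path u == v)."""
        if u == v:
            return True
        stack, seen = [u], {u}
        while stack:
            for w in self._children[stack.pop()]:
                if w == v:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def copy(self) -> "DAGStructure":
        return DAGStructure(self.nodes, self.arcs)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.arcs))
        return g

    def validate(self, schema: SliceSchema | None = None) -> None:
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise StructuralError("graph contains a directed cycle")
        if schema is not None:
            for u, v in self.arcs:
                if not schema.allows_arc(u, v):
                    raise StructuralError(f"arc {u}->{v} violates temporal precedence")

    def __eq__(self, other) -> bool:
        return (isinstance(other, DAGStructure)
                and self.nodes == other.nodes and self.arcs == other.arcs)

    def __repr__(self) -> str:
        return f"DAGStructure({len(self.nodes)} nodes, {len(self.arcs)} arcs)"


@dataclass
class SearchConfig:
    """Hill-climbing settings.

    ``max_iterations`` is the total budget of candidate-move score
    evaluations accumulated across random restarts (the study's stop
    criterion of one million iterations per run).  ``ess`` is the BDeu
    equivalent sample size; the study does not report its value, so a common
    default of 10 is used and exposed here.
    """

    ess: float = 10.0
    max_iterations: int = 1_000_000
    max_parents: int | None = None
    seed: int = 0
    init_arc_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.ess <= 0:
            raise ValueError("ess must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class HillClimbResult:
    dag: DAGStructure
    score: float
    trace: list[list[float]]  # accepted-score sequence per ascent
    n_evaluations: int
    n_restarts: int


# ---------------------------------------------------------------------------
# BDeu scoring


def _parent_codes(data: DiscreteTable, parents: tuple[str, ...]) -> np.ndarray:
    """Integer code of the joint parent configuration per row, compacted to
    realized configurations whenever the running radix would overflow."""
    n = data.n_rows
    code = np.zeros(n, dtype=np.int64)
    width = 1
    for p in parents:
        r = data.arity[p]
        if width * r >= _COMPACT_LIMIT:
            code = np.unique(code, return_inverse=True)[1].astype(np.int64)
            width = int(code.max()) + 1 if n else 1
            if width * r >= _COMPACT_LIMIT:
                raise StructuralError("parent configuration space too large")
        code = code * r + data.column(p)
        width *= r
    return code


def local_bdeu(child: str, parents, data: DiscreteTable, ess: float) -> float:
    """BDeu local score of ``child`` given ``parents`` (sparse counting)."""
    if ess <= 0:
        raise ValueError("ess must be positive")
    parents = tuple(sorted(parents))
    if child in parents:
        raise StructuralError("child cannot be its own parent")
    for col in (child, *parents):
        if col not in data.arity:
            raise StructuralError(f"column {col!r} missing from data")
    n = data.n_rows
    if n == 0:
        return 0.0
    r = data.arity[child]
    q = float(np.prod([data.arity[p] for p in parents])) if parents else 1.0
    y = data.column(child)
    if parents:
        codes = _parent_codes(data, parents)
        _, inv, n_j = np.unique(codes, return_inverse=True, return_counts=True)
    else:
        inv = np.zeros(n, dtype=np.int64)
        n_j = np.array([n])
    n_jk = np.bincount(inv * r + y, minlength=len(n_j) * r)
    a_j = ess / q
    a_jk = ess / (q * r)
    nz = n_jk > 0
    return float(
        (gammaln(a_j) - gammaln(n_j + a_j)).sum()
        + (gammaln(n_jk[nz] + a_jk) - gammaln(a_jk)).sum()
    )


def total_bdeu(g: DAGStructure, data: DiscreteTable, ess: float) -> float:
    """Decomposable total: sum of local scores over all nodes."""
    return sum(local_bdeu(v, g.parents(v), data, ess) for v in g.nodes)


class ScoreCache:
    """Memoized local BDeu scores keyed by (child, parent set)."""

    def __init__(self, data: DiscreteTable, ess: float):
        self.data = data
        self.ess = ess
        self._cache: dict[tuple[str, frozenset], float] = {}

    def local(self, child: str, parents) -> float:
        key = (child, frozenset(parents))
        try:
            return self._cache[key]
        except KeyError:
            val = local_bdeu(child, parents, self.data, self.ess)
            self._cache[key] = val
            return val


# ---------------------------------------------------------------------------
# neighborhood


def neighbor_moves(g: DAGStructure, schema: SliceSchema,
                   max_parents: int | None = None) -> list[Move]:
    """All single-arc additions, deletions and reversals preserving
    acyclicity, temporal precedence and the parent limit, in a
    deterministic (sorted) order."""
    moves: list[Move] = []
    nodes = sorted(g.nodes)
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            if g.has_arc(u, v):
                moves.append(("delete", u, v))
                # reversal keeps the pair adjacent; the flipped arc must
                # itself respect precedence and not close a cycle
                if schema.allows_arc(v, u) and (
                        max_parents is None or len(g._parents[u]) < max_parents):
                    g.remove_arc(u, v)
                    ok = not g.has_path(u, v)
                    g.add_arc(u, v)
                    if ok:
                        moves.append(("reverse", u, v))
            else:
                if schema.allows_arc(u, v) and not g.has_path(v, u) and (
                        max_parents is None or len(g._parents[v]) < max_parents):
                    moves.append(("add", u, v))
    return moves


def random_dag(nodes, schema: SliceSchema, rng: np.random.Generator,
               arc_prob: float = 0.1,
               max_parents: int | None = None) -> DAGStructure:
    """Random initial DAG: a uniformly random topological order consistent
    with slice precedence, then each order-respecting allowed arc included
    independently with probability ``arc_prob``."""
    nodes = list(nodes)
    perm = [nodes[i] for i in rng.permutation(len(nodes))]
    order = sorted(perm, key=schema.slice_index)  # stable: random within slice
    g = DAGStructure(nodes)
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if schema.allows_arc(u, v) and rng.random() < arc_prob:
                if max_parents is None or len(g._parents[v]) < max_parents:
                    g.add_arc(u, v)
    return g


# ---------------------------------------------------------------------------
# search


def _move_gain(mv: Move, g: DAGStructure, local: dict[str, float],
               cache: ScoreCache) -> float:
    kind, u, v = mv
    if kind == "add":
        return cache.local(v, g._parents[v] | {u}) - local[v]
    if kind == "delete":
        return cache.local(v, g._parents[v] - {u}) - local[v]
    # reverse u->v  =>  v->u
    return (cache.local(v, g._parents[v] - {u}) - local[v]
            + cache.local(u, g._parents[u] | {v}) - local[u])


def _apply_move(mv: Move, g: DAGStructure, local: dict[str, float],
                cache: ScoreCache) -> None:
    kind, u, v = mv
    if kind == "add":
        g.add_arc(u, v)
    elif kind == "delete":
        g.remove_arc(u, v)
    else:
        g.remove_arc(u, v)
        g.add_arc(v, u)
        local[u] = cache.local(u, g._parents[u])
    local[v] = cache.local(v, g._parents[v])


def hill_climb(data: DiscreteTable, schema: SliceSchema,
               cfg: SearchConfig) -> HillClimbResult:
    """Random-restart greedy ascent on the BDeu score.

    Within one ascent the accepted score sequence is strictly increasing;
    restarts continue until the evaluation budget is spent and the best DAG
    seen (first found on exact ties) is returned.
    """
    if data.n_rows == 0:
        raise StructuralError("cannot learn from an empty dataset")
    nodes = tuple(data.columns)
    rng = np.random.default_rng(cfg.seed)
    cache = ScoreCache(data, cfg.ess)

    best_g: DAGStructure | None = None
    best_s = -np.inf
    trace: list[list[float]] = []
    evals = 0
    restarts = 0
    warned = False

    while True:
        g = random_dag(nodes, schema, rng, cfg.init_arc_prob, cfg.max_parents)
        restarts += 1
        local = {v: cache.local(v, g._parents[v]) for v in nodes}
        score = sum(local.values())
        ascent = [score]
        while True:
            moves = neighbor_moves(g, schema, cfg.max_parents)
            if not warned and cfg.max_iterations < len(moves):
                warnings.warn("iteration budget smaller than one neighborhood "
                              "scan; returning best DAG found so far",
                              stacklevel=2)
                warned = True
            if not moves:
                break
            gains = np.array([_move_gain(mv, g, local, cache) for mv in moves])
            evals += len(moves)
            gmax = gains.max()
            if gmax <= _MIN_GAIN:
                break
            tied = np.flatnonzero(gains >= gmax - _TIE_TOL)
            mv = moves[tied[rng.integers(len(tied))]]
            _apply_move(mv, g, local, cache)
            score = sum(local.values())
            ascent.append(score)
            if evals >= cfg.max_iterations:
                break
        trace.append(ascent)
        if score > best_s:
            best_s, best_g = score, g.copy()
        if evals >= cfg.max_iterations:
            break
    assert best_g is not None
    return HillClimbResult(dag=best_g, score=float(best_s), trace=trace,
                           n_evaluations=evals, n_restarts=restarts)


# ---------------------------------------------------------------------------
# parameters and inference


@dataclass
class NodeCPT:
    """Posterior-mean conditional probability table of one node.

    Rows are indexed by the parent-state tuple (in sorted-parent order);
    configurations never observed fall back to the prior mean, which is the
    uniform distribution over the child's states."""

    child: str
    parents: tuple[str, ...]
    arity: int
    table: dict[tuple[int, ...], np.ndarray] = field(default_factory=dict)

    def prob(self, state: int, parent_states: tuple[int, ...] = ()) -> float:
        row = self.table.get(tuple(parent_states))
        if row is None:
            return 1.0 / self.arity
        return float(row[state])


CPTSet = dict[str, NodeCPT]


def fit_cpts(g: DAGStructure, data: DiscreteTable, ess: float) -> CPTSet:
    """Posterior-mean CPT estimates (N_jk + a/(r q)) / (N_j + a/q)."""
    cpts: CPTSet = {}
    for v in g.nodes:
        parents = tuple(sorted(g.parents(v)))
        r = data.arity[v]
        q = float(np.prod([data.arity[p] for p in parents])) if parents else 1.0
        cpt = NodeCPT(child=v, parents=parents, arity=r)
        y = data.column(v)
        if data.n_rows:
            if parents:
                cols = np.stack([data.column(p) for p in parents], axis=1)
                configs, inv = np.unique(cols, axis=0, return_inverse=True)
            else:
                configs = np.zeros((1, 0), dtype=int)
                inv = np.zeros(data.n_rows, dtype=int)
            for j, cfg_states in enumerate(configs):
                mask = inv == j
                n_jk = np.bincount(y[mask], minlength=r).astype(float)
                row = (n_jk + ess / (q * r)) / (mask.sum() + ess / q)
                cpt.table[tuple(int(s) for s in cfg_states)] = row
        cpts[v] = cpt
    return cpts


def joint_probability(cpts: CPTSet, assignment: dict[str, int]) -> float:
    """Chain-rule joint: product over nodes of p(X_i = x_i | Pa_i = pa_i)."""
    missing = set(cpts) - set(assignment)
    if missing:
        raise ValueError(f"assignment lacks nodes {sorted(missing)}")
    p = 1.0
    for v, cpt in cpts.items():
        pa = tuple(assignment[u] for u in cpt.parents)
        p *= cpt.prob(assignment[v], pa)
    return p


# ---------------------------------------------------------------------------
# export


def arcs_frame(g: DAGStructure):
    import pandas as pd

    return pd.DataFrame(sorted(g.arcs), columns=["source", "target"])


def to_dot(g: DAGStructure, name: str = "dag") -> str:
    lines = [f"digraph {name} {{"]
    for v in g.nodes:
        lines.append(f'  "{v}";')
    for u, v in sorted(g.arcs):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
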