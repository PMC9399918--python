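"""Adaptive quantization of real-valued variables into at most 128 levels.

Each column is binned independently with Knuth's Bayesian optimal equal-width
histogram: the number of bins M maximizes the marginal posterior of a
piecewise-constant density model with a Jeffreys prior on bin probabilities,

    log p(M | x) = N ln M + lnG(M/2) - M lnG(1/2) - lnG(N + M/2)
                   + sum_k lnG(n_k + 1/2)          (additive constant dropped)

where n_k are the counts of x in M equal-width bins over [min(x), max(x)]
and lnG is the log-gamma function.  The score is exactly 0 at M = 1 for any
data, so values are comparable across M.  The search is capped at 128 bins
(7 bits).  A constant column has zero data range, for which M > 1 equal-width
binning is undefined; its objective is -inf for M > 1 and the column
quantizes to a single level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .preprocess import VariableTable

MAX_BINS_DEFAULT = 128


@dataclass(frozen=True)
class BinningResult:
    n_bins: int
    edges: np.ndarray  # n_bins + 1 strictly increasing cut points
    log_posterior: float


@dataclass
class DiscreteTable:
    """Integer-coded table; symbols of column c lie in [0, arity[c] - 1]."""

    animal_id: str
    frame: pd.DataFrame
    arity: dict[str, int]
    binnings: dict[str, BinningResult]

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def binning_objective(x: np.ndarray, m: int) -> float:
    """Knuth log posterior of M equal-width bins over the range of x."""
    if m < 1:
        raise ValueError("number of bins must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 1:
        raise ValueError("x must be non-empty")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        # zero data range: only the single-bin model is defined
        return 0.0 if m == 1 else -np.inf
    counts, _ = np.histogram(x, bins=m, range=(lo, hi))
    return float(
        n * np.log(m)
        + gammaln(m / 2.0)
        - m * gammaln(0.5)
        - gammaln(n + m / 2.0)
        + gammaln(counts + 0.5).sum()
    )


def optimal_bins(x: np.ndarray, max_bins: int = MAX_BINS_DEFAULT) -> BinningResult:
    """Maximize the binning objective over M in {1..max_bins}.

    Ties break toward fewer bins.  Edges are equal-width over
    [min(x), max(x)]; a constant column gets the unit-width interval
    centred on its value.
    """
    if max_bins < 1:
        raise ValueError("max_bins must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("x must be non-empty")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return BinningResult(1, np.array([lo - 0.5, lo + 0.5]), 0.0)
    scores = np.array([binning_objective(x, m) for m in range(1, max_bins + 1)])
    m_star = int(np.argmax(scores)) + 1  # argmax takes the first (smallest) M
    return BinningResult(m_star, np.linspace(lo, hi, m_star + 1),
                         float(scores[m_star - 1]))


def quantize(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Map values to bins: edges[k] <= v < edges[k+1], top edge inclusive;
    symbols are relabeled to consecutive integers over realized levels only."""
    x = np.asarray(x, dtype=float).ravel()
    edges = np.asarray(edges, dtype=float).ravel()
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 points")
    if x.size and (x.min() < edges[0] or x.max() > edges[-1]):
        raise ValueError("value outside the binning range")
    idx = np.searchsorted(edges, x, side="right") - 1
    np.clip(idx, 0, edges.size - 2, out=idx)  # top edge joins the last bin
    _, symbols = np.unique(idx, return_inverse=True)
    return symbols.astype(np.int64)


def discretize_column(x: np.ndarray,
                      max_bins: int = MAX_BINS_DEFAULT) -> tuple[np.ndarray, BinningResult]:
    binning = optimal_bins(x, max_bins)
    return quantize(np.asarray(x, dtype=float), binning.edges), binning


def discretize_table(table: VariableTable,
                     max_bins: int = MAX_BINS_DEFAULT) -> DiscreteTable:
    """Independently bin and quantize every column of a variable table."""
    symbols: dict[str, np.ndarray] = {}
    arity: dict[str, int] = {}
    binnings: dict[str, BinningResult] = {}
    for col in table.frame.columns:
        sym, binning = discretize_column(table.frame[col].to_numpy(), max_bins)
        symbols[col] = sym
        arity[col] = int(sym.max()) + 1 if sym.size else 0
        binnings[col] = binning
    return DiscreteTable(animal_id=table.animal_id,
                         frame=pd.DataFrame(symbols),
                         arity=arity, binnings=binnings)


def binning_sidecar(dt: DiscreteTable) -> dict:
    """JSON-serializable record of per-column edges and arity."""
    return {
        col: {"n_bins": dt.binnings[col].n_bins,
              "arity": dt.arity[col],
              "edges": [float(e) for e in dt.binnings[col].edges]}
        for col in dt.columns
    }
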