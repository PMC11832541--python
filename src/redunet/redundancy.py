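"""Redundancy labeling of dynamic FC windows and the BFR score.

A window's correlation matrix is proportionally thresholded at a grid of
connection densities (5-95% in 5% steps by default) and binarized.  Scanning
up from the sparsest density, the first density at which the graph is
one-connected (every region pair joined by at least one pathway) and the
first at which it is two-connected (at least two independent pathways
between every pair) are recorded.  A window whose network becomes
two-connected at the very density at which it first becomes one-connected
is labeled *redundant* (1), otherwise 0.  Brain functional redundancy (BFR)
is the proportion of redundant windows across all sessions: the fraction of
time the network carries built-in back-up routes between every pair of
regions.

"Independent pathways" are internally vertex-disjoint paths (Menger's
theorem), so two-connectedness coincides with biconnectivity and admits a
linear-time check; an edge-disjoint variant is available for sensitivity
analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .dynfc import DynFCStack

logger = logging.getLogger(__name__)

#: Sentinel for "no grid density achieved k-connectedness".
ABSENT = None

PathMode = Literal["vertex", "edge"]
RankMode = Literal["signed", "absolute"]


@dataclass(frozen=True)
class DensityGrid:
    """Ordered connection densities at which windows are thresholded.

    Defaults to 0.05 .. 0.95 in steps of 0.05 (19 values).
    """

    densities: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.densities:
            object.__setattr__(self, "densities", self.default_densities())
        d = self.densities
        if any(not (0.0 < x <= 1.0) for x in d):
            raise ValueError("densities must lie in (0, 1]")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("densities must be strictly increasing")

    @staticmethod
    def default_densities(
        start: float = 0.05, stop: float = 0.95, step: float = 0.05
    ) -> tuple[float, ...]:
        n = int(round((stop - start) / step)) + 1
        return tuple(round(start + i * step, 10) for i in range(n))

    def __iter__(self):
        return iter(self.densities)

    def __len__(self) -> int:
        return len(self.densities)


@dataclass(frozen=True)
class BinaryGraph:
    """Binarized thresholded graph: node count, edge set, and its density."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    density: float

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loops are not allowed")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class RedundancyProfile:
    """Per-window redundancy labels and the scalar BFR score.

    ``labels`` concatenates windows across sessions in session order.
    ``d_one`` / ``d_two`` hold the minimal grid density at which each window
    is one-/two-connected, or ``None`` where no grid density suffices.
    ``bfr`` is the mean label: the proportion of time in a redundant state.
    """

    labels: tuple[int, ...]
    d_one: tuple[float | None, ...]
    d_two: tuple[float | None, ...]
    bfr: float
    session_ids: tuple[str, ...] = field(default_factory=tuple)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be 0/1")
        for a, b in zip(self.d_one, self.d_two):
            if a is not None and b is not None and b < a:
                raise ValueError("d_two must be >= d_one")

    @property
    def n_windows(self) -> int:
        return len(self.labels)


def _ranked_pairs(corr: np.ndarray, rank_mode: RankMode) -> list[tuple[int, int]]:
    """All off-diagonal pairs sorted strongest-first.

    Ties in correlation are broken by lexicographic (i, j) order, which
    guarantees nested edge sets across the density grid and run-to-run
    determinism even under massive ties.
    """
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = corr[iu, ju]
    if rank_mode == "absolute":
        w = np.abs(w)
    elif rank_mode != "signed":
        raise ValueError(f"unknown rank_mode {rank_mode!r}")
    # lexsort: last key is primary; descending weight, then ascending (i, j)
    order = np.lexsort((ju, iu, -w))
    return list(zip(iu[order].tolist(), ju[order].tolist()))


def _edge_quota(density: float, n_pairs: int) -> int:
    # round half away from zero; density and n_pairs are positive
    return int(math.floor(density * n_pairs + 0.5))


def proportional_threshold(
    corr: np.ndarray, density: float, rank_mode: RankMode = "signed"
) -> BinaryGraph:
    """Keep the strongest fraction ``density`` of edges and binarize.

    The quota is ``round(density * P)`` over the ``P = n(n-1)/2`` possible
    edges, with rounding half away from zero.  By default edges are ranked
    by signed correlation (strongest positive first); ``rank_mode="absolute"``
    ranks by magnitude.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    pairs = _ranked_pairs(corr, rank_mode)
    k = _edge_quota(density, len(pairs))
    return BinaryGraph(
        n_nodes=n, edges=frozenset(pairs[:k]), density=density
    )


def _split_node_digraph(g: nx.Graph) -> nx.DiGraph:
    """Unit-capacity split-node transform for vertex-disjoint path counting.

    Each node v becomes v_in -> v_out with capacity 1; each undirected edge
    {u, v} becomes u_out -> v_in and v_out -> u_in with capacity 1.
    """
    d = nx.DiGraph()
    for v in g.nodes:
        d.add_edge(("in", v), ("out", v), capacity=1)
    for u, v in g.edges:
        d.add_edge(("out", u), ("in", v), capacity=1)
        d.add_edge(("out", v), ("in", u), capacity=1)
    return d


def count_independent_paths(
    g: BinaryGraph | nx.Graph, u, v, mode: PathMode = "vertex"
) -> int:
    """Maximum number of independent u-v pathways.

    ``mode="vertex"`` counts internally vertex-disjoint paths: if (u, v) is
    an edge, this is 1 plus the count in the graph with that edge removed;
    otherwise it is the max-flow through the unit-capacity split-node
    transform (equal to the minimum vertex cut, by Menger's theorem).
    ``mode="edge"`` counts edge-disjoint paths via unit-capacity max-flow on
    the line graph orientation.
    """
    if u == v:
        raise ValueError("u and v must be distinct")
    gx = g.to_networkx() if isinstance(g, BinaryGraph) else g
    if u not in gx or v not in gx:
        raise ValueError("both endpoints must be graph nodes")
    if mode == "edge":
        d = nx.DiGraph()
        for a, b in gx.edges:
            d.add_edge(a, b, capacity=1)
            d.add_edge(b, a, capacity=1)
        if u not in d or v not in d:
            return 0
        return int(nx.maximum_flow_value(d, u, v))
    if mode != "vertex":
        raise ValueError(f"unknown path mode {mode!r}")
    if gx.has_edge(u, v):
        reduced = gx.copy()
        reduced.remove_edge(u, v)
        return 1 + count_independent_paths(reduced, u, v, mode="vertex")
    d = _split_node_digraph(gx)
    return int(nx.maximum_flow_value(d, ("out", u), ("in", v)))


def is_k_connected(
    g: BinaryGraph | nx.Graph, k: int, mode: PathMode = "vertex"
) -> bool:
    """Does every node pair have at least ``k`` independent pathways?

    With vertex-disjoint semantics, k=1 is graph connectedness and k=2 is
    biconnectivity (connected with no cut vertex), both checked in linear
    time; this is the production path that the all-pairs max-flow counter
    cross-checks in the test suite.
    """
    if k not in (1, 2):
        raise ValueError("only k in {1, 2} is supported")
    gx = g.to_networkx() if isinstance(g, BinaryGraph) else g
    if gx.number_of_nodes() < k + 1:
        raise ValueError(f"need at least {k + 1} nodes for k={k}")
    if mode == "vertex":
        if k == 1:
            return nx.is_connected(gx)
        return nx.is_biconnected(gx)
    if mode != "edge":
        raise ValueError(f"unknown path mode {mode!r}")
    if k == 1:
        return nx.is_connected(gx)
    return nx.is_connected(gx) and not list(nx.bridges(gx))


def min_density_k_connected(
    corr: np.ndarray,
    grid: DensityGrid,
    k: int,
    rank_mode: RankMode = "signed",
    mode: PathMode = "vertex",
    start_at: float | None = None,
) -> float | None:
    """Smallest grid density whose thresholded graph is k-connected.

    Returns ``None`` (ABSENT) if no grid density suffices.  Because the
    fixed rank ordering makes edge sets nested across the grid,
    k-connectedness is monotone in density, so the scan may start at
    ``start_at`` (used to resume the k=2 scan at the k=1 answer).
    """
    for density in grid:
        if start_at is not None and density < start_at:
            continue
        g = proportional_threshold(corr, density, rank_mode)
        if is_k_connected(g, k, mode):
            return density
    return None


def label_window(
    corr: np.ndarray,
    grid: DensityGrid | None = None,
    rank_mode: RankMode = "signed",
    mode: PathMode = "vertex",
) -> tuple[int, float | None, float | None]:
    """Redundancy label for one window: (label, d_one, d_two).

    The label is 1 iff the window's network first becomes two-connected at
    the same grid density at which it first becomes one-connected; 0 if the
    densities differ or either state is never reached on the grid.
    """
    grid = grid or DensityGrid()
    d_one = min_density_k_connected(corr, grid, 1, rank_mode, mode)
    if d_one is None:
        logger.warning("window never one-connected up to density %.2f", grid.densities[-1])
        return 0, None, None
    d_two = min_density_k_connected(corr, grid, 2, rank_mode, mode, start_at=d_one)
    label = 1 if d_two == d_one else 0
    return label, d_one, d_two


def bfr_score(
    stacks: Sequence[DynFCStack] | DynFCStack,
    grid: DensityGrid | None = None,
    rank_mode: RankMode = "signed",
    mode: PathMode = "vertex",
) -> RedundancyProfile:
    """Label every window of every session and compute the BFR score.

    Sessions are concatenated in the order given; BFR is the mean label,
    i.e. the proportion of time spent in a redundant state.
    """
    if isinstance(stacks, DynFCStack):
        stacks = [stacks]
    if not stacks:
        raise ValueError("need at least one session stack")
    grid = grid or DensityGrid()
    labels: list[int] = []
    d_ones: list[float | None] = []
    d_twos: list[float | None] = []
    n_unreached = 0
    for stack in stacks:
        if stack.n_windows == 0:
            raise ValueError("empty dynamic FC stack")
        for w in range(stack.n_windows):
            lab, d1, d2 = label_window(stack.matrices[w], grid, rank_mode, mode)
            labels.append(lab)
            d_ones.append(d1)
            d_twos.append(d2)
            if d1 is None:
                n_unreached += 1
    if n_unreached:
        logger.warning(
            "%d of %d windows never reached one-connectedness on the grid",
            n_unreached,
            len(labels),
        )
    return RedundancyProfile(
        labels=tuple(labels),
        d_one=tuple(d_ones),
        d_two=tuple(d_twos),
        bfr=float(np.mean(labels)),
        session_ids=tuple(s.session_id for s in stacks),
        subject_id=stacks[0].subject_id,
    )
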