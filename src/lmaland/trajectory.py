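"""Driver-combination lattice graphs and evolutionary trajectory enumeration.

The lattice over the top-k most frequent drivers of a landscape has one node
per non-empty driver subset (2^k - 1 nodes) and a directed edge from each
subset to every superset with exactly one extra driver (k * 2^(k-1) edges).
Each node carries the LMA score of its combination, so paths through the
lattice model stepwise malignant progression: a clone acquires drivers one at
a time, and a trajectory ends at the first node whose score reaches a
threshold (typically the native cohort's median LMA) — its offspring are not
explored further.

Nodes are represented as bitmasks over the top-k drivers; scoring is exact
and exhaustive for k <= 15.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lmaland.landscape import Landscape
from lmaland.lma import ModelConfig

MAX_DEFAULT_K = 15


def _member_matrix(k: int) -> np.ndarray:
    """(2^k - 1, k) boolean membership matrix; row i describes bitmask i+1."""
    masks = np.arange(1, 2**k, dtype=np.int64)
    return ((masks[:, None] >> np.arange(k)) & 1).astype(bool)


def score_all_subsets(
    drivers: Sequence[str], landscape: Landscape, config: ModelConfig
) -> np.ndarray:
    """LMA scores of every non-empty subset of `drivers`, indexed by
    bitmask - 1 (bit b of the mask = drivers[b]).  Vectorised over all
    2^k - 1 nodes."""
    k = len(drivers)
    m = _member_matrix(k)
    sizes = m.sum(axis=1)
    sa = np.array([landscape.sa[d] for d in drivers], dtype=float)
    ss = np.array([landscape.ss[d] for d in drivers], dtype=float)
    e = landscape.epistasis.loc[list(drivers), list(drivers)].to_numpy(dtype=float)

    if config.model.endswith("_prod"):
        e_work = e.copy()
        np.fill_diagonal(e_work, 1.0)
        if np.any(e_work <= 0):
            raise ValueError("product aggregation needs strictly positive E_ij")
        log_e = np.log(e_work)
        np.fill_diagonal(log_e, 0.0)
        per_driver = np.exp(m @ log_e.T)  # prod over present partners, 1 if none
        agg = (per_driver * m).sum(axis=1)
    else:
        e_work = e.copy()
        np.fill_diagonal(e_work, 0.0)
        sums = m @ e_work.T
        denom = np.maximum(sizes - 1, 1)[:, None]
        per_driver = sums / denom
        agg = np.where(sizes == 1, 1.0, (per_driver * m).sum(axis=1))

    w = config.weights
    if config.model.startswith("combined"):
        intrinsic = (m @ (sa * ss)) * w["intrinsic"]
        interactive = agg * w["interactive"]
    else:
        intrinsic = (m @ sa) * w["sa"] + (m @ ss) * w["ss"]
        interactive = agg * w["epi"]
    return intrinsic + interactive


@dataclass
class LatticeGraph:
    """Scored subset lattice over the top-k drivers of one landscape."""

    drivers: list[str]
    scores: np.ndarray  # scores[mask - 1]
    config: ModelConfig
    tumour_type: str = "NA"

    @property
    def k(self) -> int:
        return len(self.drivers)

    @property
    def n_nodes(self) -> int:
        return len(self.scores)

    @property
    def n_edges(self) -> int:
        """k * 2^(k-1): every node of size m has m in-edges, the singletons'
        one coming from the unaltered root state (mask 0)."""
        return self.k * 2 ** (self.k - 1)

    def node_sizes(self) -> np.ndarray:
        return _member_matrix(self.k).sum(axis=1)

    def mask_of(self, subset: Iterable[str]) -> int:
        mask = 0
        for d in subset:
            mask |= 1 << self.drivers.index(d)
        return mask

    def subset_of(self, mask: int) -> frozenset[str]:
        return frozenset(d for b, d in enumerate(self.drivers) if mask >> b & 1)

    def score_of(self, subset: Iterable[str]) -> float:
        mask = self.mask_of(subset)
        if mask == 0:
            return 0.0
        return float(self.scores[mask - 1])

    def iter_edges(self):
        """Yield (parent_mask, child_mask) for every single-driver addition,
        starting from the unaltered root state (mask 0)."""
        for mask in range(0, 2**self.k):
            for b in range(self.k):
                bit = 1 << b
                if not mask & bit:
                    yield mask, mask | bit

    def to_networkx(self):
        """Export as a networkx DiGraph (node attrs: size, lma); the root
        node 0 is the unaltered cell with score 0."""
        import networkx as nx

        g = nx.DiGraph()
        sizes = self.node_sizes()
        g.add_node(0, size=0, lma=0.0)
        for mask in range(1, 2**self.k):
            g.add_node(mask, size=int(sizes[mask - 1]), lma=float(self.scores[mask - 1]))
        g.add_edges_from(self.iter_edges())
        return g

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mask": np.arange(1, 2**self.k),
                "size": self.node_sizes(),
                "lma": self.scores,
            }
        )


def build_lattice(
    landscape: Landscape,
    config: ModelConfig,
    top_k: int = MAX_DEFAULT_K,
    allow_large: bool = False,
) -> LatticeGraph:
    """Build and exhaustively score the subset lattice of the `top_k` most
    frequent drivers of the landscape (k <= 15 unless `allow_large`)."""
    if top_k > len(landscape.drivers):
        raise ValueError(
            f"top_k={top_k} exceeds the {len(landscape.drivers)} retained drivers"
        )
    if top_k > MAX_DEFAULT_K:
        if not allow_large:
            raise ValueError(
                f"top_k={top_k} > {MAX_DEFAULT_K}; pass allow_large=True to override"
            )
        warnings.warn(f"building a {2**top_k - 1}-node lattice; this may be slow")
    drivers = landscape.top_drivers(top_k)
    scores = score_all_subsets(drivers, landscape, config)
    return LatticeGraph(
        drivers=drivers, scores=scores, config=config, tumour_type=landscape.tumour_type
    )


def level_stats(graph: LatticeGraph) -> pd.DataFrame:
    """Mean and maximum node LMA per number of drivers (lattice level)."""
    sizes = graph.node_sizes()
    df = pd.DataFrame({"size": sizes, "lma": graph.scores})
    out = df.groupby("size")["lma"].agg(["mean", "max"])
    out.index.name = "n_drivers"
    return out


@dataclass
class TrajectoryReport:
    """Terminal nodes of threshold-limited progression trajectories.

    A trajectory starts at any singleton and adds one driver at a time; the
    first node whose LMA reaches `threshold` terminates it and its offspring
    are pruned.  `terminal_sets` lists the unique terminal combinations;
    `driver_count_distribution` counts them by size (ordering-weighted counts
    optionally weigh each terminal by its number of qualifying acquisition
    orders).
    """

    threshold: float
    terminal_sets: list[frozenset[str]]
    driver_count_distribution: Counter = field(default_factory=Counter)
    ordering_weights: dict[frozenset, int] | None = None

    @property
    def mean_terminal_drivers(self) -> float:
        if not self.terminal_sets:
            return float("nan")
        return float(np.mean([len(s) for s in self.terminal_sets]))


def enumerate_trajectories(
    graph: LatticeGraph, threshold: float, weight_orderings: bool = False
) -> TrajectoryReport:
    """All trajectory end points of the lattice under a score threshold.

    A node S is *alive* when its score is below the threshold and it is
    reachable through an all-below-threshold chain from some singleton; S is
    *terminal* when its score meets the threshold and it is a singleton or
    has an alive predecessor.  Implemented as a single pass over bitmasks in
    increasing order (every predecessor mask is smaller than its successor).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    k = graph.k
    n = 2**k
    scores = graph.scores
    alive = np.zeros(n, dtype=bool)
    terminal = np.zeros(n, dtype=bool)
    ways = np.zeros(n, dtype=np.int64) if weight_orderings else None
    term_weight: dict[frozenset, int] = {}

    for mask in range(1, n):
        singleton = mask & (mask - 1) == 0
        if singleton:
            reachable = True
            n_ways = 1
        else:
            reachable = False
            n_ways = 0
            rest = mask
            while rest:
                bit = rest & -rest
                pred = mask ^ bit
                if alive[pred]:
                    reachable = True
                    if ways is None:
                        break
                    n_ways += int(ways[pred])
                rest ^= bit
        if not reachable:
            continue
        if scores[mask - 1] >= threshold:
            terminal[mask] = True
            if ways is not None:
                term_weight[graph.subset_of(mask)] = n_ways
        else:
            alive[mask] = True
            if ways is not None:
                ways[mask] = n_ways

    terminal_masks = np.nonzero(terminal)[0]
    if len(terminal_masks) == 0:
        warnings.warn("no trajectory reaches the threshold")
    terminal_sets = [graph.subset_of(int(m)) for m in terminal_masks]
    if weight_orderings:
        dist = Counter()
        for s in terminal_sets:
            dist[len(s)] += term_weight[s]
    else:
        dist = Counter(len(s) for s in terminal_sets)
    return TrajectoryReport(
        threshold=threshold,
        terminal_sets=terminal_sets,
        driver_count_distribution=dist,
        ordering_weights=term_weight if weight_orderings else None,
    )


def required_vs_observed(
    mean_required: Sequence[float], mean_observed: Sequence[float]
) -> tuple[float, float]:
    """OLS R^2 and p-value relating the mean number of drivers required to
    reach the threshold (per landscape) to the mean number of clonal drivers
    actually observed in the corresponding cohorts."""
    req = np.asarray(mean_required, dtype=float)
    obs = np.asarray(mean_observed, dtype=float)
    if len(req) != len(obs) or len(req) < 3:
        raise ValueError("need matched values for at least three landscapes")
    if np.ptp(req) == 0 or np.ptp(obs) == 0:
        return 0.0, 1.0
    res = stats.linregress(obs, req)
    return float(res.rvalue**2), float(res.pvalue)
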