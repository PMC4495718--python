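"""Chain connectivity of microtubules linked by mesh connectors.

A connector is an uninterrupted density contacting two or more MTs; within
one tomogram section the transitive closure of "shares a connector" groups
MTs into *chains*, while MTs touched by no connector are *singles*.  This
module detects chains from connector hypergraphs, summarises connector
polarity (bipolar / tripolar / quadrupolar), and tests whether chained MTs
sit in locally denser neighbourhoods than single MTs, with a
label-randomisation control.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Hyperedge",
    "ConnectorGraph",
    "ChainPartition",
    "ProximityTestResult",
    "chains_from_connectors",
    "chain_size_histogram",
    "polarity_proportions",
    "chained_vs_single_test",
    "randomize_membership",
    "rank_sum_test",
]


@dataclass(frozen=True)
class Hyperedge:
    """One connector: an uninterrupted density joining ``mt_ids``."""

    connector_id: int
    mt_ids: frozenset
    volume_nm3: float | None = None

    def __post_init__(self):
        if len(self.mt_ids) < 2:
            raise ValueError(
                f"connector {self.connector_id}: needs >= 2 MTs, got {set(self.mt_ids)}"
            )

    @property
    def polarity(self) -> int:
        return len(self.mt_ids)


@dataclass
class ConnectorGraph:
    """Hypergraph of MTs (nodes) and mesh connectors (hyperedges)."""

    fiber_id: str
    nodes: list
    hyperedges: list[Hyperedge] = field(default_factory=list)

    def __post_init__(self):
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate mt_ids in ConnectorGraph nodes")
        for e in self.hyperedges:
            missing = set(e.mt_ids) - node_set
            if missing:
                raise ValueError(
                    f"connector {e.connector_id} references unknown MTs {missing}"
                )

    def two_section(self) -> nx.Graph:
        """Ordinary graph with an edge for every MT pair sharing a connector."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.hyperedges:
            g.add_edges_from(itertools.combinations(sorted(e.mt_ids), 2))
        return g


@dataclass
class ChainPartition:
    """Partition of a fiber's MTs into chains; singles have chain size 1."""

    chain_of: dict          # mt_id -> chain_id (0-based, ordered by min member)
    chain_sizes: dict       # chain_id -> size
    singles: list           # mt_ids in no hyperedge

    def size_of(self, mt_id) -> int:
        return self.chain_sizes[self.chain_of[mt_id]]

    def is_chained(self, mt_id) -> bool:
        return self.size_of(mt_id) >= 2


def chains_from_connectors(graph: ConnectorGraph) -> ChainPartition:
    """Connected components of the connector hypergraph's 2-section.

    Chain ids are assigned deterministically in order of each component's
    smallest member id.
    """
    g = graph.two_section()
    comps = sorted(
        (sorted(c, key=str) for c in nx.connected_components(g)),
        key=lambda c: str(c[0]),
    )
    chain_of, chain_sizes, singles = {}, {}, []
    for cid, members in enumerate(comps):
        chain_sizes[cid] = len(members)
        for m in members:
            chain_of[m] = cid
        if len(members) == 1:
            singles.append(members[0])
    return ChainPartition(chain_of=chain_of, chain_sizes=chain_sizes, singles=singles)


def chain_size_histogram(partitions) -> dict:
    """Frequency table of chain sizes (>= 2) pooled over fibers.

    Single MTs are excluded by definition; an all-singles input yields an
    empty histogram.
    """
    hist: dict[int, int] = {}
    for p in partitions:
        for size in p.chain_sizes.values():
            if size >= 2:
                hist[size] = hist.get(size, 0) + 1
    return dict(sorted(hist.items()))


def polarity_proportions(graphs) -> dict:
    """Proportions of connector polarities pooled over fibers.

    Returns ``{"counts": {k: n_k}, "proportions": {k: n_k / n}, "n": n}``.
    Zero connectors gives ``n == 0`` and empty mappings.
    """
    counts: dict[int, int] = {}
    for g in graphs:
        for e in g.hyperedges:
            counts[e.polarity] = counts.get(e.polarity, 0) + 1
    n = sum(counts.values())
    props = {k: v / n for k, v in counts.items()} if n else {}
    return {
        "counts": dict(sorted(counts.items())),
        "proportions": dict(sorted(props.items())),
        "n": n,
    }


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney two-sample rank test
# ---------------------------------------------------------------------------

def _rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of sample x vs y (ties count half)."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float(np.sum(x > y) + 0.5 * np.sum(x == y))


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p-value of U over all C(n, nx) group assignments.

    Handles ties correctly because the permutation distribution is built
    from the pooled observed values themselves.
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    n, nx_ = len(pooled), len(x)
    u_obs = _rank_sum_statistic(x, y)
    mu = nx_ * (n - nx_) / 2.0
    dev = abs(u_obs - mu)
    # U = (sum of x's midranks) - nx(nx+1)/2, so each assignment costs one sum
    ranks = rankdata(pooled).tolist()
    offset = nx_ * (nx_ + 1) / 2.0
    hits = total = 0
    for comb in itertools.combinations(ranks, nx_):
        u = sum(comb) - offset
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def _normal_approx_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with continuity and tie correction."""
    nx_, ny = len(x), len(y)
    n = nx_ + ny
    u = _rank_sum_statistic(x, y)
    mu = nx_ * ny / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = nx_ * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations tied
        return 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(math.erfc(z / math.sqrt(2.0)))


def rank_sum_test(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns ``(U, p)``.

    method "exact" enumerates all group assignments (valid with ties),
    "approx" uses the tie-corrected normal approximation with continuity
    correction, and "auto" picks exact for pooled n <= 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = _rank_sum_statistic(x, y)
    if method == "auto":
        method = "exact" if len(x) + len(y) <= 20 else "approx"
    if method == "exact":
        p = _exact_two_sided_p(x, y)
    elif method == "approx":
        p = _normal_approx_two_sided_p(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return u, min(p, 1.0)


# ---------------------------------------------------------------------------
# Chained vs single proximity testing
# ---------------------------------------------------------------------------

@dataclass
class ProximityTestResult:
    """Chained-vs-single neighbour-count comparison at one search radius."""

    radius_nm: float
    n_chained: int
    n_single: int
    chained_counts: np.ndarray
    single_counts: np.ndarray
    statistic: float | None
    p_value: float | None
    undefined: bool = False


def _neighbor_counts(points: np.ndarray, radius_nm: float) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    if len(points) < 2:
        return np.zeros(len(points), dtype=int)
    d = squareform(pdist(points))
    np.fill_diagonal(d, np.inf)
    return (d <= radius_nm).sum(axis=1)


def chained_vs_single_test(
    points,
    mt_ids,
    partition: ChainPartition,
    radii_nm=None,
    method: str = "auto",
) -> list[ProximityTestResult]:
    """Compare neighbour counts of chained vs single MTs across radii.

    ``points`` are (n, 2) cross-section MT centers in nm matching ``mt_ids``.
    Default sweep is 20-120 nm in 10 nm steps (center-to-center, closed
    ball).  A radius where either group is empty is returned flagged
    ``undefined`` with no statistic.
    """
    points = np.asarray(points, dtype=float)
    if radii_nm is None:
        radii_nm = np.arange(20.0, 121.0, 10.0)
    chained_mask = np.array([partition.is_chained(m) for m in mt_ids])
    results = []
    for r in radii_nm:
        counts = _neighbor_counts(points, float(r))
        cc, sc = counts[chained_mask], counts[~chained_mask]
        if len(cc) == 0 or len(sc) == 0:
            results.append(
                ProximityTestResult(float(r), len(cc), len(sc), cc, sc, None, None, True)
            )
            continue
        u, p = rank_sum_test(cc, sc, method=method)
        results.append(
            ProximityTestResult(float(r), len(cc), len(sc), cc, sc, u, p)
        )
    return results


def randomize_membership(
    points,
    mt_ids,
    partition: ChainPartition,
    radii_nm=None,
    n_permutations: int = 1000,
    seed: int | None = None,
    method: str = "auto",
) -> dict:
    """Null distribution of the proximity test under shuffled chain labels.

    Chained/single labels are permuted uniformly, preserving group sizes,
    and the sweep re-run per permutation.  Returns per-radius p-value
    arrays and their medians: ``{"radii_nm", "p_values" (n_perm, n_radii),
    "median_p"}``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    points = np.asarray(points, dtype=float)
    if radii_nm is None:
        radii_nm = np.arange(20.0, 121.0, 10.0)
    radii_nm = np.asarray(radii_nm, dtype=float)
    rng = np.random.default_rng(seed)
    chained_mask = np.array([partition.is_chained(m) for m in mt_ids])
    counts_by_radius = [_neighbor_counts(points, float(r)) for r in radii_nm]
    p_values = np.full((n_permutations, len(radii_nm)), np.nan)
    for k in range(n_permutations):
        perm_mask = rng.permutation(chained_mask)
        for j, counts in enumerate(counts_by_radius):
            cc, sc = counts[perm_mask], counts[~perm_mask]
            if len(cc) == 0 or len(sc) == 0:
                continue
            _, p = rank_sum_test(cc, sc, method=method)
            p_values[k, j] = p
    return {
        "radii_nm": radii_nm,
        "p_values": p_values,
        "median_p": np.nanmedian(p_values, axis=0),
    }
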