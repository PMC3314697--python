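"""Haplotype network construction and interpretation.

Builds the minimum spanning network (union of all minimum spanning trees)
over mutational step distances, resolves its loops into a tree with
deterministic frequency/topology/geography criteria, inserts latent
(missing) haplotypes so every edge is a single mutation, splits deeply
divergent lineages, infers each lineage's ancestral haplotype from
abundance and network centrality, and constructs hierarchical nested
clades.

Latent node IDs are auto-generated as ``m1``, ``m2``, ... and carry
``observed=False``; observed nodes carry their total and per-location
counts as attributes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import CrossReferenceError, DegenerateDataError
from .io_formats import DistanceMatrix, SampleTable
from .popgen import haversine_km

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Minimum spanning network
# ---------------------------------------------------------------------------

def build_msn(steps: DistanceMatrix) -> nx.Graph:
    """Minimum spanning network over integer mutation-step distances.

    An edge (u, v, w) is included iff u and v fall in different connected
    components of the graph restricted to edges of weight strictly less
    than w. The result is the union of all minimum spanning trees, so it
    may contain loops where alternative connections tie.
    """
    labels = steps.labels
    if len(labels) < 2:
        raise DegenerateDataError("need at least 2 haplotypes to build a network")
    net = nx.Graph()
    net.add_nodes_from(labels)
    pairs = [
        (int(round(steps.values[i, j])), labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]
    pairs.sort(key=lambda t: t[0])
    # Kruskal-style sweep: at each weight level, test membership against the
    # forest of strictly smaller weights, then merge the whole level.
    uf = nx.utils.UnionFind(labels)
    for w, group in itertools.groupby(pairs, key=lambda t: t[0]):
        group = list(group)
        added = [(u, v) for _, u, v in group if uf[u] != uf[v]]
        for u, v in added:
            net.add_edge(u, v, weight=w)
        for u, v in added:
            uf.union(u, v)
        if w == 0:
            logger.warning("zero-distance haplotype pair(s): %s", added)
    return net


# ---------------------------------------------------------------------------
# Loop resolution
# ---------------------------------------------------------------------------

def _edge_geo_km(u: str, v: str, table: SampleTable | None) -> float:
    """Minimal geographic distance between locations carrying u and v.

    0 if they co-occur in a location; +inf when either is unsampled or no
    table is given.
    """
    if table is None:
        return float("inf")
    locs_u = table.locations_of(u)
    locs_v = table.locations_of(v)
    if not locs_u or not locs_v:
        return float("inf")
    best = float("inf")
    for lu in locs_u:
        ru = table.row(lu)
        for lv in locs_v:
            if lu == lv:
                return 0.0
            rv = table.row(lv)
            best = min(best, haversine_km(ru.lat, ru.lon, rv.lat, rv.lon))
    return best


def resolve_loops(net: nx.Graph, table: SampleTable | None = None) -> nx.Graph:
    """Break network loops until the graph is a tree (or forest).

    While a cycle exists, one of its edges is deleted, chosen by ordered
    criteria: (1) frequency — delete the edge whose endpoint sampled-count
    sum is smallest, keeping connections between abundant haplotypes;
    (2) topology — among ties, delete the edge with the smaller endpoint
    degree sum, keeping edges anchored at interior nodes; (3) geography —
    delete the edge whose endpoint haplotypes are sampled farthest apart
    (co-occurrence counts as distance zero); (4) lexicographic edge label
    as a deterministic fallback.
    """
    g = net.copy()

    def count(h: str) -> int:
        if table is None:
            return 0
        return table.total_count(h)

    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        candidates = []
        for u, v in cycle:
            key = (
                count(u) + count(v),
                g.degree(u) + g.degree(v),
                -_edge_geo_km(u, v, table),
                tuple(sorted((u, v))),
            )
            candidates.append((key, (u, v)))
        candidates.sort()
        (u, v) = candidates[0][1]
        logger.debug("loop resolution: deleting edge %s-%s", u, v)
        g.remove_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# Latent haplotype insertion
# ---------------------------------------------------------------------------

def insert_missing(net: nx.Graph) -> nx.Graph:
    """Subdivide every weight-k edge (k > 1) with k-1 latent haplotypes.

    Each latent node is named ``m1``, ``m2``, ... in deterministic edge
    order, gets ``observed=False`` and count 0; all resulting edges have
    weight 1. Pairwise step distances are preserved exactly.
    """
    g = nx.Graph()
    for node, attrs in net.nodes(data=True):
        g.add_node(node, **{**attrs, "observed": attrs.get("observed", True)})
    counter = itertools.count(1)
    for u, v, attrs in sorted(net.edges(data=True),
                              key=lambda e: tuple(sorted(e[:2]))):
        w = int(attrs.get("weight", 1))
        if w <= 1:
            g.add_edge(u, v, weight=1)
            continue
        chain = [u]
        for _ in range(w - 1):
            mid = f"m{next(counter)}"
            g.add_node(mid, observed=False, count=0)
            chain.append(mid)
        chain.append(v)
        for a, b in zip(chain, chain[1:]):
            g.add_edge(a, b, weight=1)
    return g


def suppress_latent(net: nx.Graph) -> nx.Graph:
    """Inverse-ish of :func:`insert_missing`: contract degree-2 latent chains.

    Used for topology comparisons against a ground-truth colonization tree.
    Latent nodes of degree 2 are smoothed out (their two edges merged, with
    weights summed); other latent nodes are kept.
    """
    g = net.copy()
    changed = True
    while changed:
        changed = False
        for node in list(g.nodes):
            if g.nodes[node].get("observed", True):
                continue
            if g.degree(node) == 2:
                (a, _), (b, _) = ((n, None) for n in g.neighbors(node))
                w = sum(g.edges[node, n].get("weight", 1) for n in (a, b))
                g.remove_node(node)
                if not g.has_edge(a, b):
                    g.add_edge(a, b, weight=w)
                changed = True
    return g


# ---------------------------------------------------------------------------
# Lineages
# ---------------------------------------------------------------------------

@dataclass
class LineageMap:
    """Partition of haplotypes into lineages with optional ancestors.

    ``assignment`` maps every network node (observed and latent) to a
    lineage label; ``ancestors`` maps lineage label to its inferred
    ancestral observed haplotype once :func:`infer_ancestor` has run.
    """

    assignment: dict[str, str]
    ancestors: dict[str, str] = field(default_factory=dict)

    def members(self, lineage: str) -> list[str]:
        return sorted(h for h, l in self.assignment.items() if l == lineage)

    @property
    def lineages(self) -> list[str]:
        return sorted(set(self.assignment.values()))


def split_lineages(net: nx.Graph, min_split_steps: int = 5) -> LineageMap:
    """Partition the resolved (weighted) network at deep edges.

    All edges of weight >= *min_split_steps* are removed; each remaining
    component is a lineage. Labels are ``L1``, ``L2``, ... by decreasing
    component size (ties broken by smallest member ID).
    """
    g = net.copy()
    deep = [(u, v) for u, v, w in g.edges(data="weight", default=1)
            if w >= min_split_steps]
    g.remove_edges_from(deep)
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), min(c)))
    if len(comps) == 1 and not deep:
        logger.warning("no edge reaches %d steps; single lineage", min_split_steps)
    assignment = {}
    for i, comp in enumerate(comps, start=1):
        for node in comp:
            assignment[node] = f"L{i}"
    return LineageMap(assignment)


def infer_ancestor(net: nx.Graph, members, counts: dict[str, int]) -> str:
    """Infer the ancestral haplotype of one lineage.

    Under coalescent reasoning, interior haplotypes are older and abundant
    haplotypes are older. Each observed member h is scored

        score(h) = 0.5 * count_h / max_count + 0.5 * C_min / C_h

    where C_h is h's eccentricity in the unit-step lineage subgraph and
    C_min the minimum eccentricity over members. The highest score wins;
    ties go to the larger raw count, then the lexicographically smaller ID.
    Latent nodes contribute to path lengths but are never candidates.
    """
    members = list(members)
    sub = net.subgraph(members)
    if not nx.is_connected(sub):
        raise DegenerateDataError("lineage subgraph is not connected")
    observed = [h for h in members if net.nodes[h].get("observed", True)]
    if not observed:
        raise DegenerateDataError("lineage has no observed haplotypes")
    ecc = nx.eccentricity(sub)
    cmin = min(ecc[h] for h in observed)
    cmax = max((counts.get(h, 0) for h in observed), default=0)
    if cmax == 0:
        cmax = 1
    best = None
    for h in observed:
        e = ecc[h]
        score = 0.5 * counts.get(h, 0) / cmax + 0.5 * (cmin / e if e > 0 else 1.0)
        key = (-score, -counts.get(h, 0), h)
        if best is None or key < best[0]:
            best = (key, h)
    return best[1]


def assign_ancestors(net: nx.Graph, lmap: LineageMap,
                     counts: dict[str, int]) -> LineageMap:
    """Fill in :attr:`LineageMap.ancestors` for every lineage."""
    for lineage in lmap.lineages:
        lmap.ancestors[lineage] = infer_ancestor(net, lmap.members(lineage), counts)
    return lmap


# ---------------------------------------------------------------------------
# Nested clades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestedClades:
    """Hierarchical nesting of a unit-step tree.

    ``levels[0]`` is the list of singleton haplotype clades (frozensets of
    node IDs, latent included); ``levels[k]`` partitions the level-(k-1)
    clades into k-step clades. Built to level 2.
    """

    levels: tuple[tuple[frozenset, ...], ...]

    def clade_of(self, level: int, node: str) -> frozenset:
        for clade in self.levels[level]:
            if node in clade:
                return clade
        raise CrossReferenceError(f"{node!r} not found at level {level}")


def _nest_once(tree: nx.Graph) -> list[frozenset]:
    """One nesting pass: group tips with their interior neighbor, peel inward.

    Works on a tree whose nodes are hashable clade identifiers. Returns a
    partition of the nodes into (k+1)-step nests. A stranded singleton is
    absorbed into the adjacent nest with fewest members (ties to the nest
    whose member list is lexicographically last, for determinism).
    """
    g = tree.copy()
    nests: list[set] = []
    assigned: dict = {}
    while g.number_of_nodes() > 0:
        tips = sorted((n for n in g.nodes if g.degree(n) <= 1), key=str)
        if not tips:
            # residual cycle cannot occur on trees; guard anyway
            tips = [min(g.nodes, key=str)]
        grouped = set()
        for tip in tips:
            if tip in grouped:
                continue
            nbrs = list(g.neighbors(tip))
            if not nbrs:
                # isolated node: stranded, handled below
                nest = {tip}
                nests.append(nest)
                for m in nest:
                    assigned[m] = nest
                grouped.add(tip)
                continue
            interior = nbrs[0]
            # the nest = interior node plus all its current tip neighbors
            nest = {interior} | {t for t in g.neighbors(interior)
                                 if g.degree(t) <= 1}
            nests.append(nest)
            for m in nest:
                assigned[m] = nest
            grouped |= nest
        g.remove_nodes_from(grouped)
    # absorb stranded singletons into the adjacent nest with fewest members;
    # ties go to the lexicographically later nest (deterministic)
    for nest in [n for n in nests if len(n) == 1]:
        (node,) = nest
        adj_nests = []
        for nbr in tree.neighbors(node):
            other = assigned[nbr]
            if other is not nest and other not in adj_nests:
                adj_nests.append(other)
        if not adj_nests:
            continue
        min_len = min(len(n) for n in adj_nests)
        cands = [n for n in adj_nests if len(n) == min_len]
        target = max(cands, key=lambda n: tuple(sorted(str(x) for x in n)))
        target.add(node)
        assigned[node] = target
        nests.remove(nest)
    return [frozenset(n) for n in nests]


def nest_clades(net: nx.Graph, max_level: int = 2) -> NestedClades:
    """Hierarchical nesting of a resolved unit-step tree.

    At each level, tip clades are grouped with the interior clade one
    mutational connection away, peeling inward; stranded singletons join
    the adjacent nest with fewest members. Latent haplotypes participate
    like observed ones. Levels 1..*max_level* are built on top of the
    singleton level 0.
    """
    if net.number_of_nodes() == 0:
        raise DegenerateDataError("empty network")
    level0 = tuple(frozenset([n]) for n in sorted(net.nodes, key=str))
    levels = [level0]
    # current tree over clade indices of the latest level
    current = {fs: fs for fs in level0}  # clade -> set of original nodes
    tree = nx.Graph()
    tree.add_nodes_from(level0)
    for u, v in net.edges:
        cu = next(fs for fs in level0 if u in fs)
        cv = next(fs for fs in level0 if v in fs)
        if cu != cv:
            tree.add_edge(cu, cv)
    for _ in range(max_level):
        if tree.number_of_nodes() <= 1:
            break
        nests = _nest_once(tree)
        # flatten each nest of clades into a set of original nodes
        flat = tuple(
            frozenset().union(*(current[c] for c in nest)) for nest in nests
        )
        flat = tuple(sorted(flat, key=lambda fs: sorted(fs)[0]))
        levels.append(flat)
        # rebuild contracted tree over the new clades
        newtree = nx.Graph()
        newtree.add_nodes_from(flat)
        lookup = {}
        for fs in flat:
            for node in fs:
                lookup[node] = fs
        for u, v in net.edges:
            cu, cv = lookup[u], lookup[v]
            if cu != cv:
                newtree.add_edge(cu, cv)
        tree = newtree
        current = {fs: fs for fs in flat}
    return NestedClades(tuple(levels))
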