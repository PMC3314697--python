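"""Time-sliced genealogical spread projection.

The relative age of a haplotype can be read off a resolved unit-step
network: interior haplotypes are older, tips younger. Each haplotype's
depth is its graph distance (in single mutations, counting latent
intermediates) from the lineage's ancestral haplotype. Lineage timelines
are aligned at their most recent tips — the deepest tip of every lineage
shares the final slice — so that lineages of unequal depth can be drawn
on a common T axis starting at T = 1 for the deepest lineage's ancestor.
Each slice then maps the sampling locations of the haplotypes that first
appear at that T ("new") together with all earlier ones ("carried").
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import ConsistencyError, CrossReferenceError, DegenerateDataError
from .io_formats import SampleTable
from .network import LineageMap


# ---------------------------------------------------------------------------
# Depth and alignment
# ---------------------------------------------------------------------------

def depth_map(net: nx.Graph, ancestor: str, members=None) -> dict[str, int]:
    """Steps from the ancestor to every node of its lineage component.

    ``net`` must be the resolved unit-step tree (latent nodes inserted);
    depth counts every edge, so latent intermediates advance the clock.
    ``members`` optionally restricts to a lineage's node set.
    """
    if ancestor not in net:
        raise CrossReferenceError(f"ancestor {ancestor!r} not in network")
    g = net.subgraph(members) if members is not None else net
    if ancestor not in g:
        raise CrossReferenceError(f"ancestor {ancestor!r} not in lineage subset")
    return dict(nx.single_source_shortest_path_length(g, ancestor))


def align_timelines(depthmaps: dict[str, dict[str, int]]) -> dict[str, int]:
    """Map every haplotype to its time index T, aligning lineages at tips.

    With G the maximum depth over all lineages and D the maximum depth of a
    haplotype's own lineage, T(h) = 1 + G - (D - depth(h)). The deepest
    lineage's ancestor lands at T = 1 and every lineage's deepest tip at
    T = 1 + G; shallower lineages start later, never earlier.
    """
    if not depthmaps or all(not d for d in depthmaps.values()):
        raise DegenerateDataError("no lineages with haplotypes to align")
    G = max(max(d.values()) for d in depthmaps.values() if d)
    T: dict[str, int] = {}
    for lineage, dm in depthmaps.items():
        if not dm:
            continue
        D = max(dm.values())
        for h, depth in dm.items():
            T[h] = 1 + G - (D - depth)
    return T


# ---------------------------------------------------------------------------
# Timeline object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Appearance:
    """One haplotype drawn on one slice at its sampling locations."""

    haplotype: str
    lineage: str
    locations: tuple[tuple[str, float, float], ...]  # (location, lat, lon)
    status: str  # "new" | "carried"


@dataclass(frozen=True)
class TimeSlice:
    T: int
    appearances: tuple[Appearance, ...]

    def new(self) -> list[Appearance]:
        return [a for a in self.appearances if a.status == "new"]

    def carried(self) -> list[Appearance]:
        return [a for a in self.appearances if a.status == "carried"]


@dataclass(frozen=True)
class SpreadTimeline:
    """Ordered slices T = 1..(1+G) of haplotype appearances."""

    slices: tuple[TimeSlice, ...]

    def first_appearance(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sl in self.slices:
            for a in sl.new():
                out[a.haplotype] = sl.T
        return out

    def __len__(self) -> int:
        return len(self.slices)


def spread_slices(T: dict[str, int], table: SampleTable,
                  lmap: LineageMap) -> SpreadTimeline:
    """Build the per-slice appearance lists from aligned ages.

    Only observed (sampled) haplotypes appear on maps; latent nodes occupy
    depths but are excluded. Each slice lists haplotypes first appearing at
    that T as "new" and repeats every earlier haplotype as "carried", each
    with all sampling locations where its count is positive.
    """
    sampled = set(table.haplotype_ids)
    missing = sampled - set(T)
    if missing:
        raise ConsistencyError(
            f"sampled haplotypes absent from the network/timeline: {sorted(missing)}"
        )
    observed = {h: t for h, t in T.items() if h in sampled}
    if not observed:
        raise DegenerateDataError("no observed haplotypes in the timeline")
    t_max = max(T.values())

    def locs(h: str) -> tuple:
        return tuple(
            (r.location, r.lat, r.lon)
            for r in table.rows
            if r.counts.get(h, 0) > 0
        )

    slices = []
    for t in range(1, t_max + 1):
        apps = []
        for h in sorted(observed):
            if observed[h] == t:
                status = "new"
            elif observed[h] < t:
                status = "carried"
            else:
                continue
            apps.append(
                Appearance(h, lmap.assignment.get(h, "L1"), locs(h), status)
            )
        apps.sort(key=lambda a: (a.status != "new", a.haplotype))
        slices.append(TimeSlice(t, tuple(apps)))
    return SpreadTimeline(tuple(slices))


def build_timeline(net_unit: nx.Graph, lmap: LineageMap,
                   table: SampleTable) -> SpreadTimeline:
    """Convenience: depth maps per lineage -> aligned T -> slices."""
    depthmaps = {}
    for lineage in lmap.lineages:
        anc = lmap.ancestors.get(lineage)
        if anc is None:
            raise ConsistencyError(f"lineage {lineage} has no ancestor assigned")
        depthmaps[lineage] = depth_map(net_unit, anc, lmap.members(lineage))
    T = align_timelines(depthmaps)
    return spread_slices(T, table, lmap)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_LINEAGE_COLORS = ["black", "red", "blue", "green", "purple", "orange"]


def render_maps(timeline: SpreadTimeline, out_dir, dpi: int = 100) -> list[str]:
    """One scatter map per slice; returns the written file paths.

    New appearances are drawn as large open markers, carried haplotypes as
    small filled ones; lineages get distinct colors. Plain lat/lon axes,
    no basemap.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lineages = sorted({a.lineage for sl in timeline.slices for a in sl.appearances})
    color = {l: _LINEAGE_COLORS[i % len(_LINEAGE_COLORS)]
             for i, l in enumerate(lineages)}
    # common extent across slices
    lats = [lat for sl in timeline.slices for a in sl.appearances
            for _, lat, _ in a.locations]
    lons = [lon for sl in timeline.slices for a in sl.appearances
            for _, _, lon in a.locations]
    paths = []
    for sl in timeline.slices:
        fig, ax = plt.subplots(figsize=(5, 5))
        for a in sl.appearances:
            if not a.locations:
                continue
            xs = [lon for _, _, lon in a.locations]
            ys = [lat for _, lat, _ in a.locations]
            if a.status == "new":
                ax.scatter(xs, ys, s=90, facecolors="none",
                           edgecolors=color[a.lineage], linewidths=2, zorder=3)
            else:
                ax.scatter(xs, ys, s=25, color=color[a.lineage], zorder=2)
        if lats and lons:
            ax.set_xlim(min(lons) - 0.5, max(lons) + 0.5)
            ax.set_ylim(min(lats) - 0.5, max(lats) + 0.5)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        ax.set_title(f"T = {sl.T}")
        path = out / f"spread_T{sl.T:02d}.png"
        fig.savefig(path, dpi=dpi, metadata={"Software": None})
        plt.close(fig)
        paths.append(str(path))
    return paths
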