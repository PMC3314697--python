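"""End-to-end analysis orchestration and the run report.

``analyze`` chains the whole pipeline — pooling and filtering, step
matrices, network construction and loop resolution, lineage splitting and
ancestor inference, divergence statistics, isolation-by-distance,
stepwise-colonization tests, clock dating and the spread timeline — and
returns a JSON-serializable report in which every number is traceable to
one library operation. Frequency statistics use the pooled-then-filtered
table; the network, lineages and projection use all sampled locations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import networkx as nx
import numpy as np

from . import __version__
from .colonization import (
    clock_dating,
    good_model_diversity_test,
    good_model_pair_test,
)
from .errors import DegenerateDataError, PhylospreadError
from .io_formats import (
    AnalysisConfig,
    HaplotypeSet,
    SampleTable,
    filter_populations,
    pool_populations,
    write_matrix,
    write_network,
    write_timeline,
)
from .network import (
    assign_ancestors,
    build_msn,
    insert_missing,
    resolve_loops,
    split_lineages,
)
from .popgen import (
    da_matrix,
    expand_individuals,
    fst_matrix,
    gene_diversity,
    geographic_distance,
    ibd_test,
    mismatch,
    sampling_summary,
    step_matrix,
    tajima_d,
)
from .projection import build_timeline, render_maps

logger = logging.getLogger(__name__)


def config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _clean(obj):
    """Make a report JSON-serializable; NaN becomes None."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _clean(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(float(obj)) else float(obj)
    if isinstance(obj, np.ndarray):
        return _clean(obj.tolist())
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def ancestor_location(table: SampleTable, haplotype: str) -> str:
    """Location holding the most copies of the ancestral haplotype."""
    best, best_n = None, -1
    for r in table.rows:
        c = r.counts.get(haplotype, 0)
        if c > best_n:
            best, best_n = r.location, c
    return best


def analyze(hset: HaplotypeSet, table: SampleTable,
            config: AnalysisConfig | None = None,
            out_dir=None, maps: bool = False) -> dict:
    """Run the full pipeline; optionally write all artifacts to *out_dir*."""
    config = config or AnalysisConfig()
    report: dict = {
        "provenance": {
            "seed": config.rng_seed,
            "config_hash": config_hash(config),
            "config": dataclasses.asdict(config),
            "version": __version__,
        }
    }

    # --- table preparation: pool first, then filter ---
    pooled = pool_populations(table, config.pooling)
    stats_table = filter_populations(pooled, config.min_sample_size)
    report["sampling"] = {
        "all_locations": sampling_summary(pooled),
        "filtered_locations": sampling_summary(stats_table),
    }

    # --- network on the full data ---
    steps, indels = step_matrix(hset)
    msn = build_msn(steps)
    resolved = resolve_loops(msn, pooled)
    lmap = split_lineages(resolved, config.lineage_split_steps)
    unit = insert_missing(resolved)
    lmap_unit = _extend_lineages(unit, lmap)
    counts = {h: pooled.total_count(h) for h in hset.ids}
    assign_ancestors(unit, lmap_unit, counts)
    report["network"] = {
        "n_haplotypes": len(hset),
        "n_latent": sum(1 for n in unit if not unit.nodes[n].get("observed", True)),
        "n_lineages": len(lmap_unit.lineages),
        "lineage_sizes": {
            l: sum(1 for h in lmap_unit.members(l) if h in hset)
            for l in lmap_unit.lineages
        },
        "ancestors": dict(lmap_unit.ancestors),
    }

    # --- divergence statistics on the filtered table ---
    fst = fst_matrix(stats_table)
    da = da_matrix(stats_table)
    km = geographic_distance(stats_table)
    per_pop = {
        r.location: {
            "n": r.total,
            "n_haplotypes": len(r.nonzero()),
            "gene_diversity": gene_diversity(r.counts),
        }
        for r in stats_table.rows
    }
    report["per_population"] = per_pop
    report["divergence"] = {
        "mean_pairwise_fst": fst.mean_offdiagonal,
        "mean_pairwise_da": da.mean_offdiagonal,
    }

    loc_lineage = _location_lineages(stats_table, lmap_unit)
    for lineage in lmap_unit.lineages:
        locs = [l for l, lin in loc_lineage.items() if lin == lineage]
        if len(locs) >= 2:
            sub = fst_matrix(stats_table.subset(locs))
            report["divergence"][f"mean_pairwise_fst_{lineage}"] = \
                sub.mean_offdiagonal

    # --- Tajima's D and mismatch ---
    report["tajima"] = {"all": tajima_d(expand_individuals(stats_table, hset))}
    report["mismatch"] = {}
    for lineage in lmap_unit.lineages:
        locs = [l for l, lin in loc_lineage.items() if lin == lineage]
        if not locs:
            continue
        seqs = expand_individuals(stats_table, hset, locs)
        if len(seqs) >= 4:
            report["tajima"][lineage] = tajima_d(seqs)
        if len(seqs) >= 2:
            mm = mismatch(seqs)
            report["mismatch"][lineage] = {
                "counts": mm.counts,
                "n_pairs": mm.n_pairs,
                "mean": mm.mean(),
                "n_modes": mm.n_modes(),
            }

    # --- isolation by distance ---
    report["ibd"] = {}
    try:
        report["ibd"]["all"] = ibd_test(
            stats_table, hset, nperm=config.mantel_permutations,
            seed=config.rng_seed,
        )
    except (DegenerateDataError, PhylospreadError) as exc:
        report["ibd"]["all"] = {"skipped": str(exc)}
    for lineage in lmap_unit.lineages:
        locs = [l for l, lin in loc_lineage.items() if lin == lineage]
        try:
            report["ibd"][lineage] = ibd_test(
                stats_table, hset, subset=locs,
                nperm=config.mantel_permutations, seed=config.rng_seed,
            )
        except PhylospreadError as exc:
            report["ibd"][lineage] = {"skipped": str(exc)}

    # --- stepwise-colonization tests per lineage ---
    report["colonization"] = {}
    for lineage in lmap_unit.lineages:
        anc_hap = lmap_unit.ancestors.get(lineage)
        locs = [l for l, lin in loc_lineage.items() if lin == lineage]
        if anc_hap is None or len(locs) < 4:
            report["colonization"][lineage] = {"skipped": "fewer than 4 populations"}
            continue
        anc_loc = ancestor_location(stats_table.subset(locs), anc_hap)
        entry: dict = {"ancestor_haplotype": anc_hap, "ancestor_location": anc_loc}
        try:
            entry["pairwise"] = good_model_pair_test(
                stats_table, hset, locs, anc_loc,
                nperm=config.mantel_permutations, seed=config.rng_seed,
            )
        except PhylospreadError as exc:
            entry["pairwise"] = {"skipped": str(exc)}
        try:
            entry["diversity"] = good_model_diversity_test(
                stats_table, locs, anc_loc,
            )
        except PhylospreadError as exc:
            entry["diversity"] = {"skipped": str(exc)}
        report["colonization"][lineage] = entry

    # --- molecular clock ---
    report["clock"] = {}
    if len(lmap_unit.lineages) >= 2:
        l1, l2 = lmap_unit.lineages[:2]
        m1 = [h for h in lmap_unit.members(l1) if h in hset]
        m2 = [h for h in lmap_unit.members(l2) if h in hset]
        min_steps = int(
            min(steps.get(a, b) for a in m1 for b in m2)
        )
        report["clock"]["between_lineages"] = clock_dating(
            min_steps, hset.length, config.clock_rate_low, config.clock_rate_high
        )

    # --- projection timeline (full table) ---
    timeline = build_timeline(unit, lmap_unit, pooled)
    report["timeline"] = {
        "n_slices": len(timeline),
        "first_appearance": timeline.first_appearance(),
    }

    # --- artifacts ---
    if out_dir is not None:
        out = Path(out_dir)
        (out / "matrices").mkdir(parents=True, exist_ok=True)
        write_matrix(steps, out / "matrices" / "steps.tsv")
        write_matrix(indels, out / "matrices" / "indels.tsv")
        write_matrix(fst.matrix, out / "matrices" / "fst.tsv")
        write_matrix(da.matrix, out / "matrices" / "da.tsv")
        write_matrix(km, out / "matrices" / "km.tsv")
        _write_network_annotated(unit, lmap_unit, pooled, out / "network.graphml")
        write_timeline(timeline, out / "timeline.geojson")
        _write_stats_tsv(per_pop, out / "stats.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(_clean(report), fh, indent=1)
        if maps:
            render_maps(timeline, out / "maps")
    return report


def _extend_lineages(unit: nx.Graph, lmap):
    """Propagate lineage labels to latent nodes on the subdivided graph."""
    from .network import LineageMap

    assignment = dict(lmap.assignment)
    for comp in nx.connected_components(unit):
        labels = {assignment[n] for n in comp if n in assignment}
        label = min(labels) if labels else "L1"
        for n in comp:
            assignment.setdefault(n, label)
    return LineageMap(assignment, dict(lmap.ancestors))


def _location_lineages(table: SampleTable, lmap) -> dict[str, str]:
    """Assign each location to the lineage of its majority haplotype."""
    out = {}
    for r in table.rows:
        votes: dict[str, int] = {}
        for h, c in r.nonzero().items():
            lin = lmap.assignment.get(h)
            if lin:
                votes[lin] = votes.get(lin, 0) + c
        if votes:
            out[r.location] = max(sorted(votes), key=lambda l: votes[l])
    return out


def _write_network_annotated(unit, lmap, table: SampleTable, path) -> None:
    g = unit.copy()
    for node in g.nodes:
        obs = g.nodes[node].get("observed", True)
        g.nodes[node]["observed"] = bool(obs)
        g.nodes[node]["lineage"] = lmap.assignment.get(node, "")
        if obs:
            g.nodes[node]["count"] = table.total_count(node)
            g.nodes[node]["location_counts"] = {
                l: table.row(l).counts.get(node, 0)
                for l in table.locations_of(node)
            }
        else:
            g.nodes[node]["count"] = 0
    write_network(g, path)


def _write_stats_tsv(per_pop: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("location\tn\tn_haplotypes\tgene_diversity\n")
        for loc, row in per_pop.items():
            h = row["gene_diversity"]
            hs = "NA" if (isinstance(h, float) and math.isnan(h)) else f"{h:.4f}"
            fh.write(f"{loc}\t{row['n']}\t{row['n_haplotypes']}\t{hs}\n")


def clean_report(report: dict) -> dict:
    """JSON-safe copy of a report (dataclasses flattened, NaN -> null)."""
    return _clean(report)
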