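"""Domain types and all external file formats.

The pipeline's data model is small: a set of aligned haplotype sequences
(:class:`HaplotypeSet`), a table of sampling locations with per-haplotype
individual counts (:class:`SampleTable`), square labelled distance matrices
(:class:`DistanceMatrix`) and a run configuration (:class:`AnalysisConfig`).
This module enforces the invariants of each type at the boundary and
reads/writes the external representations: FASTA, tab-separated sample
tables, labelled-matrix TSV, GraphML networks and GeoJSON timelines.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    ConsistencyError,
    CrossReferenceError,
    DegenerateDataError,
    FormatError,
)

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes plus gap; the alphabet contract for all sequences.
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: Unambiguous bases; only these participate in substitution counts.
UNAMBIGUOUS = set("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeSet:
    """Aligned DNA sequences keyed by haplotype ID.

    All sequences share a common alignment length ``L``; IDs are unique,
    non-empty strings. Sequences are stored uppercased.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise FormatError("HaplotypeSet requires at least one sequence")
        lengths = {hid: len(seq) for hid, seq in self.entries.items()}
        distinct = set(lengths.values())
        if len(distinct) > 1:
            ref = next(iter(lengths.values()))  # first record sets the length
            offending = [h for h, n in lengths.items() if n != ref]
            raise AlignmentError(
                f"sequences are not aligned: lengths {sorted(distinct)}; "
                f"offending IDs include {sorted(offending)[:5]}"
            )
        for hid, seq in self.entries.items():
            if not hid:
                raise FormatError("empty haplotype ID")
            bad = set(seq) - IUPAC_DNA
            if bad:
                raise FormatError(
                    f"non-IUPAC characters {sorted(bad)} in haplotype {hid!r}"
                )

    @property
    def length(self) -> int:
        """Alignment length L in sites."""
        return len(next(iter(self.entries.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, hid: str) -> str:
        return self.entries[hid]

    def __contains__(self, hid: str) -> bool:
        return hid in self.entries

    def subset(self, ids) -> "HaplotypeSet":
        return HaplotypeSet({h: self.entries[h] for h in ids})


@dataclass(frozen=True)
class PopulationRow:
    """One sampling location: coordinates, region label and haplotype counts."""

    location: str
    region: str
    lat: float
    lon: float
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def nonzero(self) -> dict[str, int]:
        return {h: c for h, c in self.counts.items() if c > 0}


@dataclass(frozen=True)
class SampleTable:
    """Ordered collection of :class:`PopulationRow`.

    The frequency source for every statistic. Location IDs are unique, every
    row has total count >= 1, and coordinates are valid decimal degrees.
    """

    rows: tuple[PopulationRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise DegenerateDataError("sample table has no rows")
        seen: set[str] = set()
        for row in self.rows:
            if row.location in seen:
                raise FormatError(f"duplicate location ID {row.location!r}")
            seen.add(row.location)
            if row.total < 1:
                raise FormatError(f"location {row.location!r} has total count 0")
            if not (-90.0 <= row.lat <= 90.0):
                raise FormatError(f"latitude {row.lat} out of range at {row.location!r}")
            if not (-180.0 <= row.lon <= 180.0):
                raise FormatError(f"longitude {row.lon} out of range at {row.location!r}")
            for h, c in row.counts.items():
                if c < 0:
                    raise FormatError(
                        f"negative count for haplotype {h!r} at {row.location!r}"
                    )

    @property
    def locations(self) -> list[str]:
        return [r.location for r in self.rows]

    @property
    def haplotype_ids(self) -> list[str]:
        """All haplotype IDs with a positive count somewhere, in first-seen order."""
        out: list[str] = []
        seen: set[str] = set()
        for row in self.rows:
            for h, c in row.counts.items():
                if c > 0 and h not in seen:
                    seen.add(h)
                    out.append(h)
        return out

    def row(self, location: str) -> PopulationRow:
        for r in self.rows:
            if r.location == location:
                return r
        raise CrossReferenceError(f"unknown location {location!r}")

    def total_count(self, haplotype: str) -> int:
        return sum(r.counts.get(haplotype, 0) for r in self.rows)

    def locations_of(self, haplotype: str) -> list[str]:
        return [r.location for r in self.rows if r.counts.get(haplotype, 0) > 0]

    def subset(self, locations) -> "SampleTable":
        keep = set(locations)
        return SampleTable(tuple(r for r in self.rows if r.location in keep))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric labelled matrix with zero diagonal.

    ``kind`` records the metric: ``mutation-steps``, ``indel-events``,
    ``FST``, ``D_A`` or ``geographic-km``. Mutation-step entries are
    integer-valued.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise FormatError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise FormatError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise FormatError("matrix diagonal is not zero")
        if self.kind == "mutation-steps" and not np.allclose(v, np.round(v)):
            raise FormatError("mutation-step distances must be integers")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (unordered pairs), row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def mean_offdiagonal(self) -> float:
        """Mean over unordered pairs, NaN entries excluded."""
        c = self.condensed()
        return float(np.nanmean(c))

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.kind)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    min_sample_size
        populations with fewer sampled individuals are dropped (default 5,
        the usual threshold for per-population frequency statistics).
    pooling
        optional map location -> pooled location, applied before filtering.
    lineage_split_steps
        edges of at least this many mutation steps split the network into
        independent lineages (default 5).
    clock_rate_low, clock_rate_high
        molecular-clock bracket in percent sequence divergence per Myr
        (defaults 0.65 and 0.88, the decapod 16S calibration).
    mantel_permutations
        permutations for Mantel tests (default 9999).
    rng_seed
        master seed for all stochastic steps.
    """

    min_sample_size: int = 5
    pooling: dict[str, str] = field(default_factory=dict)
    lineage_split_steps: int = 5
    clock_rate_low: float = 0.65
    clock_rate_high: float = 0.88
    mantel_permutations: int = 9999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_sample_size < 1:
            raise FormatError("min_sample_size must be >= 1")
        if not self.clock_rate_low < self.clock_rate_high:
            raise FormatError("clock_rate_low must be < clock_rate_high")
        if self.mantel_permutations < 99:
            raise FormatError("mantel_permutations must be >= 99")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_haplotype_fasta(path) -> HaplotypeSet:
    """Read aligned haplotypes from FASTA.

    IDs are the first whitespace-delimited token of each header; sequences
    are uppercased and validated (equal lengths, IUPAC alphabet, unique IDs).
    """
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        hid = rec.id
        if hid in entries:
            raise FormatError(f"duplicate haplotype ID {hid!r} in {path}")
        entries[hid] = str(rec.seq).upper()
    return HaplotypeSet(entries)


def write_haplotype_fasta(hset: HaplotypeSet, path) -> None:
    with open(path, "w") as fh:
        for hid, seq in hset.entries.items():
            fh.write(f">{hid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Sample table TSV
# ---------------------------------------------------------------------------

_META_COLS = ["location", "region", "lat", "lon"]


def read_sample_table(path, haps: HaplotypeSet) -> SampleTable:
    """Read the location x haplotype count table (TSV).

    Columns: ``location  region  lat  lon`` then one column per haplotype
    ID. Every haplotype column must exist in *haps*; the full count matrix
    is required (no omitted columns), though zero counts are permitted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"location": str, "region": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"sample table missing columns {missing}")
    hap_cols = [c for c in df.columns if c not in _META_COLS]
    unknown = [c for c in hap_cols if c not in haps]
    if unknown:
        raise CrossReferenceError(
            f"haplotype columns not present in the FASTA: {unknown}"
        )
    rows = []
    for _, rec in df.iterrows():
        counts = {}
        for c in hap_cols:
            val = rec[c]
            fval = float(val)
            if fval < 0 or fval != int(fval):
                raise FormatError(
                    f"invalid count {val!r} for haplotype {c!r} at {rec['location']!r}"
                )
            counts[c] = int(fval)
        if sum(counts.values()) < 1:
            raise FormatError(f"all-zero count row at location {rec['location']!r}")
        rows.append(
            PopulationRow(
                location=str(rec["location"]),
                region=str(rec["region"]),
                lat=float(rec["lat"]),
                lon=float(rec["lon"]),
                counts=counts,
            )
        )
    return SampleTable(tuple(rows))


def write_sample_table(table: SampleTable, path) -> None:
    haps = sorted({h for r in table.rows for h in r.counts})
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLS + haps) + "\n")
        for r in table.rows:
            cells = [r.location, r.region, repr(float(r.lat)), repr(float(r.lon))]
            cells += [str(r.counts.get(h, 0)) for h in haps]
            fh.write("\t".join(cells) + "\n")


def filter_populations(table: SampleTable, min_n: int) -> SampleTable:
    """Drop rows with total sampled individuals below *min_n*; keep order."""
    if min_n < 1:
        raise FormatError("min_n must be >= 1")
    kept, dropped = [], []
    for r in table.rows:
        (kept if r.total >= min_n else dropped).append(r)
    for r in dropped:
        logger.info("filter: dropping %s (n=%d < %d)", r.location, r.total, min_n)
    if not kept:
        raise DegenerateDataError(
            f"no populations with at least {min_n} individuals remain"
        )
    return SampleTable(tuple(kept))


def pool_populations(table: SampleTable, pooling: dict[str, str]) -> SampleTable:
    """Merge locations mapped to a common pooled ID.

    Counts are summed; pooled coordinates are the count-weighted centroid of
    the members; the region label must agree across members. Unmapped
    locations pass through unchanged, in their original order (a pooled row
    takes the position of its first member).
    """
    if not pooling:
        return table
    out: list[PopulationRow] = []
    groups: dict[str, list[PopulationRow]] = {}
    order: list[tuple[str, str]] = []  # ("row", location) or ("pool", pooled_id)
    for r in table.rows:
        pid = pooling.get(r.location)
        if pid is None:
            order.append(("row", r.location))
        else:
            if pid not in groups:
                order.append(("pool", pid))
                groups[pid] = []
            groups[pid].append(r)
    for kind, key in order:
        if kind == "row":
            out.append(table.row(key))
            continue
        members = groups[key]
        regions = {m.region for m in members}
        if len(regions) > 1:
            raise ConsistencyError(
                f"pooling {key!r} spans regions {sorted(regions)}"
            )
        total = sum(m.total for m in members)
        lat = sum(m.lat * m.total for m in members) / total
        lon = sum(m.lon * m.total for m in members) / total
        counts: dict[str, int] = {}
        for m in members:
            for h, c in m.counts.items():
                counts[h] = counts.get(h, 0) + c
        logger.info(
            "pool: %s <- %s (n=%d)", key, [m.location for m in members], total
        )
        out.append(
            PopulationRow(key, regions.pop(), lat, lon, counts)
        )
    return SampleTable(tuple(out))


# ---------------------------------------------------------------------------
# Distance-matrix TSV
# ---------------------------------------------------------------------------

def write_matrix(m: DistanceMatrix, path) -> None:
    """Labelled square TSV: header row of labels, one labelled row per line."""
    df = pd.DataFrame(m.values, index=list(m.labels), columns=list(m.labels))
    df.to_csv(path, sep="\t", index_label=m.kind)


def read_matrix(path, kind: str | None = None) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("matrix row and column labels differ")
    return DistanceMatrix(
        tuple(df.index), df.to_numpy(dtype=float), kind or str(df.index.name)
    )


# ---------------------------------------------------------------------------
# Network GraphML
# ---------------------------------------------------------------------------

def write_network(net: nx.Graph, path) -> None:
    """GraphML export; dict-valued node attributes are serialized as JSON."""
    g = nx.Graph()
    for node, attrs in net.nodes(data=True):
        flat = {}
        for k, v in attrs.items():
            flat[k] = json.dumps(v) if isinstance(v, (dict, list)) else v
        g.add_node(node, **flat)
    for u, v, attrs in net.edges(data=True):
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, str(path))


def read_network(path) -> nx.Graph:
    g = nx.read_graphml(str(path))
    out = nx.Graph()
    for node, attrs in g.nodes(data=True):
        parsed = {}
        for k, v in attrs.items():
            if isinstance(v, str) and v[:1] in "{[":
                try:
                    parsed[k] = json.loads(v)
                    continue
                except json.JSONDecodeError:
                    pass
            parsed[k] = v
        out.add_node(node, **parsed)
    for u, v, attrs in g.edges(data=True):
        out.add_edge(u, v, **attrs)
    return out


# ---------------------------------------------------------------------------
# Timeline GeoJSON
# ---------------------------------------------------------------------------

def write_timeline(timeline, path) -> None:
    """GeoJSON FeatureCollection: one Point feature per haplotype appearance.

    Feature properties: ``T`` (slice index), ``haplotype``, ``lineage``,
    ``status`` ("new" or "carried") and ``location``.
    """
    features = []
    for sl in timeline.slices:
        for app in sl.appearances:
            for loc, lat, lon in app.locations:
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {"type": "Point", "coordinates": [lon, lat]},
                        "properties": {
                            "T": sl.T,
                            "haplotype": app.haplotype,
                            "lineage": app.lineage,
                            "status": app.status,
                            "location": loc,
                        },
                    }
                )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_timeline(path):
    """Rebuild a :class:`~phylospread.projection.SpreadTimeline` from GeoJSON."""
    from .projection import Appearance, SpreadTimeline, TimeSlice

    with open(path) as fh:
        fc = json.load(fh)
    by_slice: dict[int, dict[tuple[str, str, str], list]] = {}
    for feat in fc["features"]:
        p = feat["properties"]
        lon, lat = feat["geometry"]["coordinates"]
        key = (p["haplotype"], p["lineage"], p["status"])
        by_slice.setdefault(p["T"], {}).setdefault(key, []).append(
            (p["location"], lat, lon)
        )
    slices = []
    for T in sorted(by_slice):
        apps = [
            Appearance(h, lin, tuple(locs), status)
            for (h, lin, status), locs in by_slice[T].items()
        ]
        apps.sort(key=lambda a: (a.status, a.haplotype))
        slices.append(TimeSlice(T, tuple(apps)))
    return SpreadTimeline(tuple(slices))
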