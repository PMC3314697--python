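"""Serial-founder colonization simulators with ground truth.

Two forward models generate haplotype FASTA + sample tables with the
statistical structure the analysis pipeline assumes, plus the true
colonization history, so every stage can be validated without external
data.

fixation-cascade (mode a)
    Populations are founded serially along a one-dimensional coastline;
    each founding copies the parent's fixed haplotype and, with
    probability f, immediately fixes one new infinite-sites substitution.
    Every population is monomorphic. With f = 1 this yields complete
    differentiation (pairwise FST = 1) and a haplotype network identical
    to the colonization tree — the regime of many small, fixed
    populations with private haplotypes.

good-model (mode b)
    Each population holds N haplotype lineages evolving by neutral
    Wright-Fisher resampling with infinite-sites mutation at rate mu per
    lineage per generation. Every g generations the newest population
    founds the next one by copying its full composition (identical allele
    frequencies), after which the two never exchange migrants. This is
    the stepwise colonization model whose predictions (divergence and
    diversity falling with distance from the ancestor) the tests probe.

Both write byte-identical outputs for identical seed and parameters.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .io_formats import HaplotypeSet, PopulationRow, SampleTable

KM_PER_DEG_LAT = 111.195

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults emulate a two-front range expansion.

    ``lineage_split_steps`` (s) seeds a second, deeply divergent lineage s
    substitutions from the root on a disjoint coastline segment; 0 keeps a
    single lineage. Mode-b parameters (pop_size N, mutation_rate mu,
    generations_between_foundings g, total_generations) are ignored by
    mode a and vice versa for fixation_prob. ``mutation_rate`` is per
    haplotype lineage (individual) per generation. ``total_generations``
    defaults to the time of the last founding, (n_pops - 1) * g — the
    survey catches the expansion as the front arrives, as a recent range
    expansion implies. ``propagule_size`` switches mode-b foundings from
    an exact copy of the parent's composition (the stepwise model's
    assumption) to a founder bottleneck of that many individuals. If
    ``sample_size_mean`` is set, per-population sample sizes are drawn as
    2 + Poisson(mean - 2) instead of the fixed ``sample_size``.
    """

    mode: str = "fixation-cascade"  # or "good-model"
    n_pops_per_front: int = 5
    fronts: int = 2
    fixation_prob: float = 1.0
    pop_size: int = 25
    mutation_rate: float = 0.02
    generations_between_foundings: int = 50
    total_generations: int | None = None
    propagule_size: int | None = None
    sample_size: int = 10
    sample_size_mean: float | None = None
    L: int = 490
    lineage_split_steps: int = 0
    second_lineage_pops: int = 0  # populations in lineage 2 (incl. its origin)
    coast_step_km: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fixation-cascade", "good-model"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.fronts not in (1, 2):
            raise ParameterError("fronts must be 1 or 2")
        if not 0.0 <= self.fixation_prob <= 1.0:
            raise ParameterError("fixation_prob must be in [0, 1]")
        if min(self.n_pops_per_front, self.pop_size, self.sample_size,
               self.L) < 1:
            raise ParameterError("counts must be positive")
        if self.lineage_split_steps > 0 and self.second_lineage_pops < 1:
            object.__setattr__(self, "second_lineage_pops", self.n_pops_per_front)


@dataclass
class SimTruth:
    """Ground truth of a simulated colonization history.

    ``founding_order`` counts from 0 at each lineage's origin;
    ``colonization_edges`` form a tree (per lineage) rooted at that
    lineage's origin. ``front`` tags each location with its expansion
    front ("O" for the origin, "N"/"S" for the two directions).
    """

    origin: str
    origins: dict[str, str]
    founding_order: dict[str, int]
    colonization_edges: list[tuple[str, str]]
    population_haplotypes: dict[str, list[str]]
    lineage_of: dict[str, str]
    front: dict[str, str]


def _draw_sizes(rng, n: int, p: SimParams) -> list[int]:
    if p.sample_size_mean is None:
        return [p.sample_size] * n
    lam = max(p.sample_size_mean - 2.0, 0.0)
    return [int(2 + k) for k in rng.poisson(lam, size=n)]


def _new_site(free_sites: list[int]) -> int:
    if not free_sites:
        raise ParameterError(
            "mutation sites exhausted: L too small for the requested history"
        )
    return free_sites.pop()


def _mutate(seq: np.ndarray, site: int, rng) -> np.ndarray:
    out = seq.copy()
    alts = _BASES[_BASES != out[site]]
    out[site] = rng.choice(alts)
    return out


def _seq_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


# ---------------------------------------------------------------------------
# Mode a: fixation cascade
# ---------------------------------------------------------------------------

def simulate_fixation_cascade(p: SimParams):
    """Serial founding with per-founding fixation of new substitutions.

    Returns (HaplotypeSet, SampleTable, SimTruth). Lineage 1 occupies a
    coastline at longitude 141 expanding from (43 N) along ``fronts``
    directions; an optional second lineage (s > 0) sits at longitude 144.
    """
    if p.mode != "fixation-cascade":
        raise ParameterError("params are not in fixation-cascade mode")
    rng = np.random.default_rng(p.seed)
    root = rng.choice(_BASES, size=p.L)
    free_sites = list(rng.permutation(p.L))

    hap_ids: dict[str, str] = {}  # sequence string -> haplotype ID

    def hap_of(seq: np.ndarray) -> str:
        s = _seq_str(seq)
        if s not in hap_ids:
            hap_ids[s] = f"H{len(hap_ids) + 1:02d}"
        return hap_ids[s]

    truth = SimTruth("", {}, {}, [], {}, {}, {})
    rows: list[PopulationRow] = []

    def run_lineage(label: str, prefix: str, origin_seq: np.ndarray,
                    lon: float, n_per_front: int, fronts: int,
                    sizes: list[int]) -> None:
        origin_loc = f"{prefix}00"
        truth.origins[label] = origin_loc
        if not truth.origin:
            truth.origin = origin_loc
        lat0 = 43.0
        dlat = p.coast_step_km / KM_PER_DEG_LAT
        pops: list[tuple[str, float, np.ndarray, str]] = [
            (origin_loc, lat0, origin_seq, "O")
        ]
        truth.founding_order[origin_loc] = 0
        order = itertools.count(1)
        directions = ["N", "S"][:fronts]
        tip = {d: (origin_loc, origin_seq, 0) for d in directions}
        # interleave fronts so global order alternates north/south
        for k in range(1, n_per_front + 1):
            for d in directions:
                parent_loc, parent_seq, steps = tip[d]
                seq = parent_seq
                if rng.random() < p.fixation_prob:
                    seq = _mutate(parent_seq, _new_site(free_sites), rng)
                loc = f"{prefix}{d}{k:02d}"
                lat = lat0 + (dlat * k if d == "N" else -dlat * k)
                pops.append((loc, lat, seq, d))
                truth.founding_order[loc] = next(order)
                truth.colonization_edges.append((parent_loc, loc))
                tip[d] = (loc, seq, steps + 1)
        for (loc, lat, seq, front), n in zip(pops, sizes):
            hid = hap_of(seq)
            rows.append(PopulationRow(loc, prefix, lat, lon, {hid: n}))
            truth.population_haplotypes[loc] = [hid]
            truth.lineage_of[loc] = label
            truth.front[loc] = front

    n1 = 1 + p.fronts * p.n_pops_per_front
    sizes1 = _draw_sizes(rng, n1, p)
    run_lineage("A", "W", root, 141.0, p.n_pops_per_front, p.fronts, sizes1)

    if p.lineage_split_steps > 0:
        seq2 = root
        for _ in range(p.lineage_split_steps):
            seq2 = _mutate(seq2, _new_site(free_sites), rng)
        n2 = p.second_lineage_pops
        per_front2 = n2 - 1
        sizes2 = _draw_sizes(rng, n2, p)
        run_lineage("B", "E", seq2, 144.0, per_front2, 1, sizes2)

    hset = HaplotypeSet({hid: s for s, hid in hap_ids.items()})
    return hset, SampleTable(tuple(rows)), truth


# ---------------------------------------------------------------------------
# Mode b: Good's model (Wright-Fisher with serial founding)
# ---------------------------------------------------------------------------

def simulate_good_model(p: SimParams):
    """Stepwise colonization with within-population Wright-Fisher drift.

    ``n_pops_per_front`` populations (including the origin) along a single
    coastline; a new one is founded every ``generations_between_foundings``
    generations by copying the newest population's full composition.
    Sequences are materialized at sampling time: each surviving mutation
    gets a unique alignment site (infinite sites), so pairwise substitution
    counts equal symmetric differences of mutation sets.
    """
    if p.mode != "good-model":
        raise ParameterError("params are not in good-model mode")
    n_pops = p.n_pops_per_front
    g = p.generations_between_foundings
    need = (n_pops - 1) * g
    total = need if p.total_generations is None else p.total_generations
    if total < need:
        raise ParameterError(
            f"total_generations={total} too small to found "
            f"{n_pops} populations every {g} generations"
        )
    rng = np.random.default_rng(p.seed)
    N = p.pop_size
    mut_counter = itertools.count()
    # individuals are tuples of mutation IDs; tuples share structure cheaply
    pops: list[list[tuple]] = [[() for _ in range(N)]]

    for t in range(1, total + 1):
        for pop in pops:
            parents = rng.integers(0, N, size=N)
            nmut = rng.poisson(p.mutation_rate, size=N)
            newpop = []
            for k in range(N):
                ind = pop[parents[k]]
                for _ in range(nmut[k]):
                    ind = ind + (next(mut_counter),)
                newpop.append(ind)
            pop[:] = newpop
        if t % g == 0 and len(pops) < n_pops:
            if p.propagule_size is None:
                # Good's assumption: the daughter starts with the parent's
                # exact composition (same allele frequencies)
                pops.append(list(pops[-1]))
            else:
                founders = rng.choice(N, size=p.propagule_size, replace=False)
                pool = [pops[-1][i] for i in founders]
                draws = rng.integers(0, p.propagule_size, size=N)
                pops.append([pool[i] for i in draws])

    if p.sample_size > N:
        raise ParameterError("sample_size cannot exceed pop_size")
    samples: list[list[tuple]] = []
    for pop in pops:
        idx = rng.choice(N, size=p.sample_size, replace=False)
        samples.append([pop[i] for i in sorted(idx)])

    # materialize: unique site per surviving mutation (infinite sites)
    surviving = sorted({m for s in samples for ind in s for m in ind})
    if len(surviving) > p.L:
        raise ParameterError(
            f"mutation sites exhausted: {len(surviving)} surviving mutations "
            f"exceed L={p.L}"
        )
    root = rng.choice(_BASES, size=p.L)
    sites = rng.choice(p.L, size=len(surviving), replace=False)
    site_of = dict(zip(surviving, sites))
    derived = {}
    for m in surviving:
        s = site_of[m]
        derived[m] = rng.choice(_BASES[_BASES != root[s]])

    hap_ids: dict[str, str] = {}
    lat0 = 43.0
    dlat = p.coast_step_km / KM_PER_DEG_LAT
    rows = []
    truth = SimTruth("P00", {"A": "P00"}, {}, [], {}, {}, {})
    for i, sample in enumerate(samples):
        loc = f"P{i:02d}"
        counts: Counter = Counter()
        haps_here = []
        for ind in sample:
            seq = root.copy()
            for m in ind:
                seq[site_of[m]] = derived[m]
            s = _seq_str(seq)
            if s not in hap_ids:
                hap_ids[s] = f"H{len(hap_ids) + 1:02d}"
            counts[hap_ids[s]] += 1
            haps_here.append(hap_ids[s])
        rows.append(
            PopulationRow(loc, "W", lat0 + i * dlat, 141.0, dict(counts))
        )
        truth.founding_order[loc] = i
        truth.population_haplotypes[loc] = sorted(set(haps_here))
        truth.lineage_of[loc] = "A"
        truth.front[loc] = "O" if i == 0 else "N"
        if i > 0:
            truth.colonization_edges.append((f"P{i - 1:02d}", loc))

    hset = HaplotypeSet({hid: s for s, hid in hap_ids.items()})
    return hset, SampleTable(tuple(rows)), truth


def simulate(p: SimParams):
    """Dispatch on ``p.mode``."""
    if p.mode == "fixation-cascade":
        return simulate_fixation_cascade(p)
    return simulate_good_model(p)


# ---------------------------------------------------------------------------
# Study-shaped preset
# ---------------------------------------------------------------------------

def study_shape_preset(seed: int = 0) -> SimParams:
    """Parameters emulating the shape of a range-wide mtDNA survey.

    Two deep lineages split by 7 substitutions; the larger one expands
    along two fronts (49 populations), the smaller along one (21), for 70
    locations total. Per-population sample sizes are drawn with mean 8.5
    individuals, and the per-founding fixation probability 0.65 yields on
    the order of 45 distinct haplotypes — most of them private to one
    location, with the bulk of populations monomorphic.
    """
    return SimParams(
        mode="fixation-cascade",
        n_pops_per_front=24,
        fronts=2,
        fixation_prob=0.65,
        sample_size_mean=8.5,
        L=490,
        lineage_split_steps=7,
        second_lineage_pops=21,
        coast_step_km=12.0,
        seed=seed,
    )
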