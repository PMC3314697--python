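"""Sequence- and frequency-based population statistics.

Mutational step distances, gene diversity, pairwise FST and Nei's D_A over
haplotype frequencies, Tajima's D, mismatch distributions, great-circle
geographic distances, and Mantel matrix-permutation tests for
isolation-by-distance.

Haplotypes are treated as unordered alleles: FST here is the
haplotype-identity (frequency-based) estimator 1 - Hw/Hb with unbiased
within-population gene diversities, not a distance-weighted PhiST.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DegenerateDataError, FormatError
from .io_formats import DistanceMatrix, HaplotypeSet, SampleTable, UNAMBIGUOUS

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Mutational distances
# ---------------------------------------------------------------------------

def mutation_steps(a: str, b: str) -> tuple[int, int]:
    """Count substitutions and indel events between two aligned sequences.

    Substitutions are sites where both sequences carry unambiguous bases
    (A, C, G, T) that differ; sites with N or other ambiguity codes are
    ignored. An indel event is a maximal run of sites where exactly one of
    the two sequences is gapped; the run breaks when the gapped side
    switches, so ``A-`` against ``-A`` is two events, not one.
    """
    if len(a) != len(b):
        raise AlignmentError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    subs = 0
    indels = 0
    prev_side = 0  # 0 = no gap here, 1 = gap in a, 2 = gap in b
    for ca, cb in zip(a.upper(), b.upper()):
        ga, gb = ca == "-", cb == "-"
        if ga != gb:
            side = 1 if ga else 2
            if side != prev_side:
                indels += 1
            prev_side = side
        else:
            prev_side = 0
            if ca != cb and ca in UNAMBIGUOUS and cb in UNAMBIGUOUS:
                subs += 1
    return subs, indels


def _encode(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Byte-encode sequences; returns (codes, unambiguous-site mask)."""
    arr = np.frombuffer("".join(seqs).upper().encode(), dtype=np.uint8)
    arr = arr.reshape(len(seqs), -1)
    mask = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    return arr, mask


def substitution_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise substitution counts; vectorized over alignment columns."""
    if len({len(s) for s in seqs}) > 1:
        raise AlignmentError("sequences have unequal lengths")
    arr, mask = _encode(seqs)
    n = len(seqs)
    out = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = mask[i] & mask[i + 1:]
        diff = (arr[i] != arr[i + 1:]) & both
        out[i, i + 1:] = diff.sum(axis=1)
    return out + out.T


def step_matrix(hset: HaplotypeSet) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Pairwise mutation-step (substitution) and indel-event matrices.

    Returns the substitution matrix (kind ``mutation-steps``), used for
    network construction, and the companion indel matrix (kind
    ``indel-events``).
    """
    ids = hset.ids
    if len(ids) < 2:
        raise DegenerateDataError("need at least 2 haplotypes for a step matrix")
    seqs = [hset[h] for h in ids]
    subs = substitution_matrix(seqs)
    n = len(ids)
    indels = np.zeros((n, n), dtype=int)
    any_gap = any("-" in s for s in seqs)
    if any_gap:
        for i in range(n):
            for j in range(i + 1, n):
                _, ev = mutation_steps(seqs[i], seqs[j])
                indels[i, j] = indels[j, i] = ev
    return (
        DistanceMatrix(tuple(ids), subs, "mutation-steps"),
        DistanceMatrix(tuple(ids), indels, "indel-events"),
    )


# ---------------------------------------------------------------------------
# Frequency statistics
# ---------------------------------------------------------------------------

def _freqs(counts: dict[str, int]) -> tuple[dict[str, float], int]:
    nz = {h: c for h, c in counts.items() if c > 0}
    n = sum(nz.values())
    if n == 0:
        raise DegenerateDataError("empty count vector")
    return {h: c / n for h, c in nz.items()}, n


def gene_diversity(counts: dict[str, int]) -> float:
    """Unbiased gene diversity h = n(1 - sum p_i^2)/(n - 1).

    The probability that two individuals drawn without replacement carry
    different haplotypes. NaN when fewer than two individuals.
    """
    p, n = _freqs(counts)
    if n < 2:
        return math.nan
    return n * (1.0 - sum(f * f for f in p.values())) / (n - 1)


def pairwise_fst(counts_a: dict[str, int], counts_b: dict[str, int]) -> float:
    """Haplotype-identity FST = 1 - Hw/Hb between two populations.

    Hw is the mean of the two unbiased within-population gene diversities;
    Hb is the probability that two haplotypes, one drawn from each
    population, differ. Returns 0 when Hb = 0 (identical monomorphic
    populations) and NaN when either population has fewer than two
    individuals. Negative estimates are reported as computed.
    """
    pa, na = _freqs(counts_a)
    pb, nb = _freqs(counts_b)
    if na < 2 or nb < 2:
        return math.nan
    hw = 0.5 * (gene_diversity(counts_a) + gene_diversity(counts_b))
    hb = 1.0 - sum(pa.get(h, 0.0) * pb.get(h, 0.0) for h in set(pa) | set(pb))
    if hb <= 0.0:
        return 0.0
    return min(1.0, 1.0 - hw / hb)


def nei_da(counts_a: dict[str, int], counts_b: dict[str, int]) -> float:
    """Nei's D_A = 1 - sum_i sqrt(x_i * y_i) over haplotype frequencies."""
    pa, _ = _freqs(counts_a)
    pb, _ = _freqs(counts_b)
    s = sum(math.sqrt(pa.get(h, 0.0) * pb.get(h, 0.0)) for h in set(pa) | set(pb))
    return min(1.0, max(0.0, 1.0 - s))


@dataclass(frozen=True)
class PairwiseStatResult:
    """A pairwise statistic matrix plus its mean over unordered pairs."""

    matrix: DistanceMatrix
    mean_offdiagonal: float


def _pairwise_table_stat(table: SampleTable, fn, kind: str) -> PairwiseStatResult:
    locs = table.locations
    n = len(locs)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = fn(table.rows[i].counts, table.rows[j].counts)
            vals[i, j] = vals[j, i] = v
    m = DistanceMatrix(tuple(locs), vals, kind)
    return PairwiseStatResult(m, m.mean_offdiagonal())


def fst_matrix(table: SampleTable) -> PairwiseStatResult:
    """Pairwise FST over all populations in the table."""
    return _pairwise_table_stat(table, pairwise_fst, "FST")


def da_matrix(table: SampleTable) -> PairwiseStatResult:
    """Pairwise Nei's D_A over all populations in the table."""
    return _pairwise_table_stat(table, nei_da, "D_A")


# ---------------------------------------------------------------------------
# Tajima's D and mismatch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaResult:
    """Tajima's D with its ingredients; D is NaN when undefined (S=0 or n<4)."""

    D: float
    S: int
    pi: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.D)


def tajima_d(seqs: list[str]) -> TajimaResult:
    """Tajima's D for a sample of aligned sequences (individuals).

    S counts segregating sites (two or more distinct unambiguous bases at a
    site; gap/ambiguous entries ignored). pi is the mean pairwise
    substitution difference with pairwise-complete site handling.
    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard constants
    a1, a2, b1, b2, c1, c2, e1, e2 for sample size n.
    """
    n = len(seqs)
    if n < 2:
        raise DegenerateDataError("Tajima's D needs at least 2 sequences")
    if len({len(s) for s in seqs}) > 1:
        raise AlignmentError("sequences have unequal lengths")
    arr, mask = _encode(seqs)
    S = 0
    for col in range(arr.shape[1]):
        bases = set(arr[mask[:, col], col].tolist())
        if len(bases) >= 2:
            S += 1
    subs = substitution_matrix(seqs)
    iu = np.triu_indices(n, k=1)
    pi = float(subs[iu].mean())
    if S == 0 or n < 4:
        return TajimaResult(math.nan, S, pi, n)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    D = (pi - S / a1) / math.sqrt(var)
    return TajimaResult(D, S, pi, n)


@dataclass(frozen=True)
class MismatchDistribution:
    """Histogram of pairwise substitution differences within a population."""

    counts: dict[int, int]
    n_pairs: int

    def mean(self) -> float:
        return sum(k * c for k, c in self.counts.items()) / self.n_pairs

    def n_modes(self) -> int:
        """Number of local maxima over the 0..max(k) support (descriptive)."""
        kmax = max(self.counts)
        y = [self.counts.get(k, 0) for k in range(kmax + 1)]
        modes = 0
        for i, v in enumerate(y):
            left = y[i - 1] if i > 0 else -1
            right = y[i + 1] if i < kmax else -1
            if v > 0 and v >= left and v >= right and (v > left or v > right or kmax == 0):
                modes += 1
        return max(modes, 1)


def mismatch(seqs: list[str]) -> MismatchDistribution:
    """Mismatch distribution over all unordered pairs of individuals."""
    n = len(seqs)
    if n < 2:
        raise DegenerateDataError("mismatch needs at least 2 sequences")
    subs = substitution_matrix(seqs)
    iu = np.triu_indices(n, k=1)
    hist = Counter(int(k) for k in subs[iu])
    return MismatchDistribution(dict(sorted(hist.items())), n * (n - 1) // 2)


def expand_individuals(table: SampleTable, hset: HaplotypeSet,
                       locations=None) -> list[str]:
    """Materialize one sequence per sampled individual (count copies)."""
    rows = table.rows if locations is None else [table.row(l) for l in locations]
    out: list[str] = []
    for r in rows:
        for h, c in sorted(r.counts.items()):
            out.extend([hset[h]] * c)
    return out


# ---------------------------------------------------------------------------
# Geographic distance
# ---------------------------------------------------------------------------

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, sphere radius 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geographic_distance(table: SampleTable) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between sampling locations."""
    locs = table.locations
    n = len(locs)
    vals = np.zeros((n, n))
    for i in range(n):
        ri = table.rows[i]
        for j in range(i + 1, n):
            rj = table.rows[j]
            d = haversine_km(ri.lat, ri.lon, rj.lat, rj.lon)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(tuple(locs), vals, "geographic-km")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    """Mantel matrix-correlation result.

    ``p_value`` follows the requested alternative; the two-sided and both
    one-sided permutation p-values are always reported. ``adjusted_r_squared``
    is 1 - (1 - r^2)(m - 1)/(m - 2) with m the number of unordered pairs; it
    can be negative when r is near zero.
    """

    r: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    p_two_sided: float
    p_greater: float
    p_less: float
    permutations: int
    seed: int
    n_pairs: int = 0
    alternative: str = "two-sided"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def _pair_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def _undefined_mantel(nperm: int, seed: int, m: int, alternative: str) -> MantelResult:
    nan = math.nan
    return MantelResult(nan, nan, nan, nan, nan, nan, nan, nperm, seed, m, alternative)


def mantel(ma: DistanceMatrix, mb: DistanceMatrix, nperm: int = 9999,
           seed: int = 0, alternative: str = "two-sided") -> MantelResult:
    """Mantel test between two distance matrices over the same labels.

    r is the Pearson correlation over unordered off-diagonal pairs. The null
    distribution is built by simultaneous row/column relabelling of the
    second matrix; p = (count{r_perm as or more extreme than r_obs} + 1) /
    (nperm + 1). ``alternative`` selects which p lands in ``p_value``:
    "two-sided" (|r_perm| >= |r_obs|), "greater" or "less".
    """
    if ma.labels != mb.labels:
        mb = mb.reorder(ma.labels)
    if nperm < 99:
        raise FormatError("nperm must be >= 99")
    if alternative not in ("two-sided", "greater", "less"):
        raise FormatError(f"unknown alternative {alternative!r}")
    n = len(ma.labels)
    if n < 3:
        raise DegenerateDataError("Mantel test needs at least 3 labels")
    iu = np.triu_indices(n, k=1)
    x = ma.values[iu]
    m = len(x)
    r_obs = _pair_corr(x, mb.values[iu])
    if math.isnan(r_obs):
        return _undefined_mantel(nperm, seed, m, alternative)
    rng = np.random.default_rng(seed)
    tol = 1e-12
    n_abs = n_ge = n_le = 0
    B = mb.values
    for _ in range(nperm):
        perm = rng.permutation(n)
        r_p = _pair_corr(x, B[np.ix_(perm, perm)][iu])
        if math.isnan(r_p):
            r_p = 0.0
        if abs(r_p) >= abs(r_obs) - tol:
            n_abs += 1
        if r_p >= r_obs - tol:
            n_ge += 1
        if r_p <= r_obs + tol:
            n_le += 1
    p_two = (n_abs + 1) / (nperm + 1)
    p_gt = (n_ge + 1) / (nperm + 1)
    p_lt = (n_le + 1) / (nperm + 1)
    p = {"two-sided": p_two, "greater": p_gt, "less": p_lt}[alternative]
    r2 = r_obs * r_obs
    adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2) if m > 2 else math.nan
    return MantelResult(r_obs, r2, adj, p, p_two, p_gt, p_lt, nperm, seed, m,
                        alternative)


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------

def ibd_test(table: SampleTable, hset: HaplotypeSet | None = None,
             subset=None, nperm: int = 9999, seed: int = 0,
             alternative: str = "two-sided") -> dict[str, MantelResult]:
    """Isolation-by-distance: Mantel tests of FST and D_A against km.

    ``subset`` restricts to the given locations (e.g. one lineage's
    populations). Populations with fewer than two individuals are dropped
    because their FST is undefined.
    """
    if subset is not None:
        table = table.subset(subset)
    table = SampleTable(tuple(r for r in table.rows if r.total >= 2))
    if len(table) < 4:
        raise DegenerateDataError("isolation-by-distance needs >= 4 populations")
    km = geographic_distance(table)
    fst = fst_matrix(table).matrix
    da = da_matrix(table).matrix
    return {
        "fst_vs_km": mantel(km, fst, nperm, seed, alternative),
        "da_vs_km": mantel(km, da, nperm, seed, alternative),
    }


# ---------------------------------------------------------------------------
# Descriptive sampling summary
# ---------------------------------------------------------------------------

def sampling_summary(table: SampleTable) -> dict[str, float]:
    """Descriptive counts: haplotype privacy and location monomorphism.

    Reports the number and percentage of haplotypes confined to a single
    location and to a single region, and of locations carrying a single
    haplotype. Percentages are rounded to whole percent, as customarily
    reported.
    """
    haps = table.haplotype_ids
    n_h = len(haps)
    private_loc = sum(1 for h in haps if len(table.locations_of(h)) == 1)
    private_reg = 0
    for h in haps:
        regions = {table.row(l).region for l in table.locations_of(h)}
        if len(regions) == 1:
            private_reg += 1
    mono = sum(1 for r in table.rows if len(r.nonzero()) == 1)
    n_loc = len(table)
    total = sum(r.total for r in table.rows)
    return {
        "n_locations": n_loc,
        "n_individuals": total,
        "n_haplotypes": n_h,
        "mean_sample_size": total / n_loc,
        "n_private_to_location": private_loc,
        "pct_private_to_location": round(100.0 * private_loc / n_h),
        "n_private_to_region": private_reg,
        "pct_private_to_region": round(100.0 * private_reg / n_h),
        "n_monomorphic_locations": mono,
        "pct_monomorphic_locations": round(100.0 * mono / n_loc),
    }
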