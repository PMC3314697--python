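"""Stepwise-colonization tests and molecular-clock dating.

Under the serial (stepwise) colonization model, each new population is
founded from the newest existing one and then evolves in isolation. The
model predicts that pairwise gene flow M = (1/FST - 1)/4 rises, and
genetic divergence falls, with the distance of the pair's older member
from the ancestral population, and that within-population gene diversity
falls with distance from the ancestor. Both predictions are tested here:
a Mantel-style pair test on Nei's D_A and a per-population Pearson test
on gene diversity.

Clock dating converts mutation steps on an alignment of L sites into a
time bracket using a percent-divergence-per-Myr rate interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CrossReferenceError, DegenerateDataError
from .io_formats import HaplotypeSet, SampleTable
from .popgen import (
    MantelResult,
    gene_diversity,
    haversine_km,
    nei_da,
)


def gene_flow_M(fst: float) -> float:
    """Gene flow M = (1/FST - 1)/4 from pairwise FST.

    Undefined (NaN) for FST <= 0: M cannot be calculated when FST is zero,
    and negative estimates are treated the same way.
    """
    if math.isnan(fst) or fst <= 0.0:
        return math.nan
    return (1.0 / fst - 1.0) / 4.0


def distance_from_ancestor(table: SampleTable,
                           ancestor_location: str) -> dict[str, float]:
    """Great-circle km from the ancestral location to every location."""
    anc = table.row(ancestor_location)  # raises CrossReferenceError if absent
    return {
        r.location: haversine_km(anc.lat, anc.lon, r.lat, r.lon)
        for r in table.rows
    }


def good_model_pair_test(table: SampleTable, hset: HaplotypeSet | None,
                         lineage_locations, ancestor_location: str,
                         nperm: int = 9999, seed: int = 0,
                         alternative: str = "less",
                         pair_distance: str = "older") -> MantelResult:
    """Divergence-vs-ancestor-distance test of stepwise colonization.

    For every unordered pair of populations in the lineage, x is the
    distance from the ancestral location of the pair's older member (the
    member closer to the ancestor; ``pair_distance="mean"`` uses the pair
    mean instead) and y is Nei's D_A between the pair. r is the Pearson
    correlation over pairs; because pairs share populations, significance
    comes from Mantel-style permutation of population labels (the
    distance-from-ancestor assignment is shuffled and x recomputed). The
    model predicts negative r, so the default alternative is "less".
    """
    table = table.subset(lineage_locations)
    locs = table.locations
    n = len(locs)
    if n < 4:
        raise DegenerateDataError("pair test needs >= 4 populations in the lineage")
    if ancestor_location not in locs:
        raise CrossReferenceError(
            f"ancestor location {ancestor_location!r} not in lineage subset"
        )
    dist = distance_from_ancestor(table, ancestor_location)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    y = np.array([
        nei_da(table.rows[i].counts, table.rows[j].counts) for i, j in pairs
    ])
    d0 = np.array([dist[l] for l in locs])
    ii = np.array([i for i, _ in pairs])
    jj = np.array([j for _, j in pairs])
    if pair_distance not in ("older", "mean"):
        raise ValueError(f"unknown pair distance mode {pair_distance!r}")

    def xs(d: np.ndarray) -> np.ndarray:
        if pair_distance == "older":
            return np.minimum(d[ii], d[jj])
        return 0.5 * (d[ii] + d[jj])

    x = xs(d0)
    m = len(pairs)
    if y.std() == 0 or x.std() == 0:
        nan = math.nan
        return MantelResult(nan, nan, nan, nan, nan, nan, nan, nperm, seed, m,
                            alternative)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    tol = 1e-12
    n_abs = n_ge = n_le = 0
    for _ in range(nperm):
        xp = xs(d0[rng.permutation(n)])
        if xp.std() == 0:
            r_p = 0.0
        else:
            r_p = float(np.corrcoef(xp, y)[0, 1])
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
    adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
    return MantelResult(r_obs, r2, adj, p, p_two, p_gt, p_lt, nperm, seed, m,
                        alternative)


@dataclass(frozen=True)
class DiversityTestResult:
    """Pearson test of gene diversity against distance from the ancestor."""

    r: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n_pops: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def good_model_diversity_test(table: SampleTable, lineage_locations,
                              ancestor_location: str) -> DiversityTestResult:
    """Gene diversity vs distance-from-ancestor (Pearson, two-sided t-test).

    Stepwise colonization predicts older (closer) populations hold more
    diversity. When every population is monomorphic (all diversities zero,
    the fully fixed regime) the correlation is undefined and NaN is
    returned.
    """
    table = table.subset(lineage_locations)
    rows = [r for r in table.rows if r.total >= 2]
    if len(rows) < 4:
        raise DegenerateDataError("diversity test needs >= 4 populations with n >= 2")
    sub = SampleTable(tuple(rows))
    dist = distance_from_ancestor(sub, ancestor_location)
    x = np.array([dist[r.location] for r in rows])
    y = np.array([gene_diversity(r.counts) for r in rows])
    n = len(rows)
    if y.std() == 0 or x.std() == 0:
        return DiversityTestResult(math.nan, math.nan, math.nan, math.nan, n)
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    r2 = r * r
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return DiversityTestResult(r, r2, adj, float(res.pvalue), n)


# ---------------------------------------------------------------------------
# Molecular clock
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockEstimate:
    """Time bracket for a divergence of ``steps`` mutations on L sites.

    ``percent_divergence`` = 100 * steps / L. The younger bound ``t_low``
    uses the faster rate, the older bound ``t_high`` the slower one, both
    in Myr. Presentation helpers round percent to 2 decimals, times to one
    decimal Myr and to two significant figures in years.
    """

    steps: int
    alignment_length: int
    percent_divergence: float
    t_low: float
    t_high: float
    rate_low: float
    rate_high: float

    @property
    def percent_rounded(self) -> float:
        return round(self.percent_divergence, 2)

    @property
    def t_myr_rounded(self) -> tuple[float, float]:
        return round(self.t_low, 1), round(self.t_high, 1)

    @property
    def t_years_rounded(self) -> tuple[int, int]:
        return _round_sig(self.t_low * 1e6, 2), _round_sig(self.t_high * 1e6, 2)


def _round_sig(x: float, sig: int) -> int:
    if x == 0:
        return 0
    mag = math.floor(math.log10(abs(x)))
    return int(round(x, -(mag - sig + 1)))


def clock_dating(steps: int, L: int, rate_low: float = 0.65,
                 rate_high: float = 0.88) -> ClockEstimate:
    """Convert mutation steps to a divergence-time bracket.

    rates are percent sequence divergence per Myr; the default bracket
    0.65-0.88 is the decapod 16S calibration. t_low = percent/rate_high,
    t_high = percent/rate_low.
    """
    if steps < 0 or L <= 0:
        raise DegenerateDataError("steps must be >= 0 and L positive")
    if not 0 < rate_low < rate_high:
        raise DegenerateDataError("need 0 < rate_low < rate_high")
    percent = 100.0 * steps / L
    return ClockEstimate(
        steps=steps,
        alignment_length=L,
        percent_divergence=percent,
        t_low=percent / rate_high,
        t_high=percent / rate_low,
        rate_low=rate_low,
        rate_high=rate_high,
    )
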