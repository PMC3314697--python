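import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylospread import (
    DistanceMatrix,
    HaplotypeSet,
    PopulationRow,
    SampleTable,
    gene_diversity,
    geographic_distance,
    haversine_km,
    ibd_test,
    mantel,
    mismatch,
    mutation_steps,
    nei_da,
    pairwise_fst,
    step_matrix,
    tajima_d,
)
from phylospread.errors import AlignmentError, DegenerateDataError
from phylospread.simulate import SimParams, simulate_fixation_cascade

from conftest import random_hapset

# ---------------------------------------------------------------------------
# oracles: deliberately naive enumerations, independent of the implementation
# ---------------------------------------------------------------------------


def oracle_subs(a: str, b: str) -> int:
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x in "ACGT" and y in "ACGT"
    )


def oracle_diversity(counts: dict[str, int]) -> float:
    """Probability two individuals drawn without replacement differ."""
    inds = [h for h, c in counts.items() for _ in range(c)]
    pairs = list(itertools.combinations(range(len(inds)), 2))
    return sum(inds[i] != inds[j] for i, j in pairs) / len(pairs)


def oracle_hb(ca: dict[str, int], cb: dict[str, int]) -> float:
    a = [h for h, c in ca.items() for _ in range(c)]
    b = [h for h, c in cb.items() for _ in range(c)]
    return sum(x != y for x in a for y in b) / (len(a) * len(b))


def oracle_fst(ca, cb) -> float:
    hw = 0.5 * (oracle_diversity(ca) + oracle_diversity(cb))
    hb = oracle_hb(ca, cb)
    return 0.0 if hb == 0 else min(1.0, 1 - hw / hb)


def oracle_tajima(seqs):
    """Straight-from-formula Tajima's D: independent dual implementation."""
    n = len(seqs)
    L = len(seqs[0])
    S = 0
    for site in range(L):
        col = {s[site] for s in seqs if s[site] in "ACGT"}
        if len(col) >= 2:
            S += 1
    pairs = list(itertools.combinations(seqs, 2))
    pi = sum(oracle_subs(a, b) for a, b in pairs) / len(pairs)
    if S == 0 or n < 4:
        return math.nan, S, pi
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)), S, pi


# ---------------------------------------------------------------------------
# mutation steps and step matrices
# ---------------------------------------------------------------------------


class TestMutationSteps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (0, 0)),
            ("AC--GT", "ACTTGA", (1, 1)),
            ("ACGT", "TCGA", (2, 0)),
            ("ACNT", "ACGT", (0, 0)),   # N ignored
            ("A--A", "AG-A", (0, 1)),   # gap-vs-gap site does not extend event
            ("A-GA", "AG-A", (0, 2)),   # side switch = two events
        ],
    )
    def test_examples(self, a, b, expected):
        assert mutation_steps(a, b) == expected

    def test_unequal_lengths(self):
        with pytest.raises(AlignmentError):
            mutation_steps("ACG", "AC")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 30
        a = "".join(rng.choice(list("ACGT-N"), size=L))
        b = "".join(rng.choice(list("ACGT-N"), size=L))
        sa, ia = mutation_steps(a, b)
        sb, ib = mutation_steps(b, a)
        assert (sa, ia) == (sb, ib)
        assert sa == oracle_subs(a, b)

    def test_step_matrix_tiny(self):
        hs = HaplotypeSet({"A": "AAA", "B": "AAT", "C": "ATT"})
        m, _ = step_matrix(hs)
        assert m.get("A", "B") == 1 and m.get("B", "C") == 1 and m.get("A", "C") == 2

    def test_step_matrix_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        hs = random_hapset(rng, 10, 50)
        m, _ = step_matrix(hs)
        for a in hs.ids:
            for b in hs.ids:
                assert m.get(a, b) == oracle_subs(hs[a], hs[b])


# ---------------------------------------------------------------------------
# frequency statistics
# ---------------------------------------------------------------------------


class TestGeneDiversity:
    def test_monomorphic(self):
        assert gene_diversity({"A": 5}) == 0.0

    def test_two_singletons(self):
        assert gene_diversity({"A": 1, "B": 1}) == pytest.approx(1.0)

    def test_even_split(self):
        assert gene_diversity({"A": 5, "B": 5}) == pytest.approx(10 / 9 * 0.5)

    def test_undefined_below_two(self):
        assert math.isnan(gene_diversity({"A": 1}))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        counts = {f"h{i}": int(rng.integers(1, 6)) for i in range(rng.integers(1, 6))}
        if sum(counts.values()) < 2:
            counts["h0"] += 1
        assert gene_diversity(counts) == pytest.approx(oracle_diversity(counts))


class TestPairwiseFst:
    def test_fixed_difference(self):
        assert pairwise_fst({"X": 5}, {"Y": 5}) == 1.0

    def test_identical_monomorphic(self):
        assert pairwise_fst({"X": 5}, {"X": 5}) == 0.0

    def test_hand_example(self):
        # Hw = 0.5, Hb = 0.625 -> FST = 0.2
        assert pairwise_fst({"X": 3, "Y": 1}, {"X": 1, "Y": 3}) == pytest.approx(0.2)

    def test_undefined_small_n(self):
        assert math.isnan(pairwise_fst({"X": 1}, {"Y": 5}))

    def test_self_is_zero_for_polymorphic(self):
        c = {"A": 3, "B": 2}
        assert pairwise_fst(c, c) <= 0.0 + 1e-12  # unbiased Hw can exceed Hb

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        haps = [f"h{i}" for i in range(4)]
        ca = {h: int(rng.integers(0, 5)) for h in haps}
        cb = {h: int(rng.integers(0, 5)) for h in haps}
        ca["h0"] += 2
        cb["h1"] += 2
        assert pairwise_fst(ca, cb) == pytest.approx(oracle_fst(ca, cb))


class TestNeiDa:
    def test_identical(self):
        assert nei_da({"A": 1, "B": 1}, {"A": 2, "B": 2}) == pytest.approx(0.0)

    def test_disjoint(self):
        assert nei_da({"A": 3}, {"B": 4}) == 1.0

    def test_half_overlap(self):
        assert nei_da({"A": 2}, {"A": 1, "B": 1}) == pytest.approx(1 - math.sqrt(0.5))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        haps = [f"h{i}" for i in range(5)]
        ca = {h: int(rng.integers(0, 4)) for h in haps}
        cb = {h: int(rng.integers(0, 4)) for h in haps}
        ca["h0"] += 1
        cb["h0"] += 1
        d1, d2 = nei_da(ca, cb), nei_da(cb, ca)
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0
        assert nei_da(ca, ca) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# Tajima's D and mismatch
# ---------------------------------------------------------------------------


class TestTajima:
    def test_monomorphic_undefined(self):
        r = tajima_d(["AAA"] * 4)
        assert math.isnan(r.D) and r.S == 0 and r.pi == 0.0

    def test_hand_example(self):
        r = tajima_d(["AAA", "AAA", "AAT", "AAT"])
        assert r.S == 1
        assert r.pi == pytest.approx(4 / 6)
        d_exp, _, _ = oracle_tajima(["AAA", "AAA", "AAT", "AAT"])
        assert r.D == pytest.approx(d_exp)

    def test_small_n_undefined_but_reports(self):
        r = tajima_d(["AAT", "ATA", "AAA"])
        assert math.isnan(r.D) and r.S == 2 and r.pi > 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_independent_formula(self, seed):
        rng = np.random.default_rng(seed)
        base = list("ACGT")
        seqs = ["".join(rng.choice(base, size=20)) for _ in range(10)]
        r = tajima_d(seqs)
        d_exp, s_exp, pi_exp = oracle_tajima(seqs)
        assert r.S == s_exp
        assert r.pi == pytest.approx(pi_exp)
        assert r.D == pytest.approx(d_exp, nan_ok=True)


class TestMismatch:
    def test_three_individual_enumeration(self):
        # individuals A, A, B with d(A,B)=3
        seqs = ["AAAA", "AAAA", "TTTA"]
        m = mismatch(seqs)
        assert m.counts == {0: 1, 3: 2}
        assert m.n_pairs == 3

    def test_monomorphic(self):
        m = mismatch(["ACGT"] * 5)
        assert m.counts == {0: 10} and m.n_pairs == 10

    def test_totals_conserved_and_pi_equals_mean(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=15)) for _ in range(8)]
        m = mismatch(seqs)
        assert sum(m.counts.values()) == m.n_pairs == 8 * 7 // 2
        assert m.mean() == pytest.approx(tajima_d(seqs).pi)

    def test_mode_count_descriptive(self):
        assert mismatch(["AAAA"] * 3).n_modes() == 1


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------


class TestGeography:
    def test_zero_distance(self):
        assert haversine_km(43.0, 141.0, 43.0, 141.0) == 0.0

    def test_one_degree_longitude(self):
        # closed form: 2R asin(cos(43 deg) * sin(0.5 deg))
        expected = 2 * 6371.0 * math.asin(
            math.cos(math.radians(43.0)) * math.sin(math.radians(0.5))
        )
        assert haversine_km(43.0, 141.0, 43.0, 142.0) == pytest.approx(expected)
        assert expected == pytest.approx(81.3, abs=0.2)

    def test_matrix_symmetric(self, tiny_table):
        m = geographic_distance(tiny_table)
        np.testing.assert_allclose(m.values, m.values.T)
        assert m.kind == "geographic-km"


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def _random_dm(rng, labels):
    n = len(labels)
    a = rng.random((n, n))
    return DistanceMatrix(tuple(labels), (a + a.T) * (1 - np.eye(n)))


def oracle_mantel_p(ma, mb):
    """Exhaustive enumeration over all label permutations (two-sided)."""
    n = len(ma.labels)
    iu = np.triu_indices(n, k=1)
    x = ma.values[iu]
    r_obs = np.corrcoef(x, mb.values[iu])[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        rp = np.corrcoef(x, mb.values[np.ix_(perm, perm)][iu])[0, 1]
        total += 1
        if abs(rp) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


class TestMantel:
    def test_identity(self):
        rng = np.random.default_rng(0)
        m = _random_dm(rng, list("abcdefgh"))
        res = mantel(m, m, nperm=999, seed=11)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        m = _random_dm(rng, list("abcdef"))
        m2 = DistanceMatrix(m.labels, 3.0 * m.values, m.kind)
        assert mantel(m, m2, nperm=99, seed=0).r == pytest.approx(1.0)

    def test_constant_matrix_undefined(self):
        labels = tuple("abcd")
        c = DistanceMatrix(labels, np.ones((4, 4)) - np.eye(4))
        rng = np.random.default_rng(2)
        m = _random_dm(rng, labels)
        assert not mantel(m, c, nperm=99, seed=0).defined

    def test_permutation_p_converges_to_exhaustive(self):
        rng = np.random.default_rng(5)
        labels = list("abcde")
        ma, mb = _random_dm(rng, labels), _random_dm(rng, labels)
        p_exact = oracle_mantel_p(ma, mb)
        nperm = 4999
        res = mantel(ma, mb, nperm=nperm, seed=3)
        se = math.sqrt(p_exact * (1 - p_exact) / nperm)
        assert abs(res.p_two_sided - p_exact) <= 3 * se + 1 / nperm

    def test_r_squared_fields(self):
        rng = np.random.default_rng(9)
        labels = list("abcdef")
        res = mantel(_random_dm(rng, labels), _random_dm(rng, labels),
                     nperm=99, seed=0)
        assert res.r_squared == pytest.approx(res.r**2)
        m = res.n_pairs
        assert res.adjusted_r_squared == pytest.approx(
            1 - (1 - res.r_squared) * (m - 1) / (m - 2)
        )


class TestIbd:
    def test_positive_on_stepwise_turnover(self):
        p = SimParams(mode="fixation-cascade", n_pops_per_front=8, fronts=1,
                      fixation_prob=0.5, seed=4, L=490)
        hset, table, _ = simulate_fixation_cascade(p)
        res = ibd_test(table, hset, nperm=199, seed=1)
        assert res["fst_vs_km"].r > 0
        assert res["da_vs_km"].r > 0

    def test_too_few_populations(self, tiny_table):
        with pytest.raises(DegenerateDataError):
            ibd_test(tiny_table.subset(["p1", "p2"]))

    def test_null_p_not_extreme(self):
        """Shuffled geography should rarely give small p (calibration spot-check)."""
        p = SimParams(mode="fixation-cascade", n_pops_per_front=8, fronts=1,
                      fixation_prob=0.5, seed=4, L=490)
        hset, table, _ = simulate_fixation_cascade(p)
        rng = np.random.default_rng(0)
        ps = []
        rows = list(table.rows)
        from phylospread import PopulationRow, SampleTable
        for rep in range(10):
            perm = rng.permutation(len(rows))
            shuffled = SampleTable(tuple(
                PopulationRow(r.location, r.region,
                              rows[perm[i]].lat, rows[perm[i]].lon, r.counts)
                for i, r in enumerate(rows)
            ))
            ps.append(ibd_test(shuffled, hset, nperm=99, seed=rep)
                      ["fst_vs_km"].p_two_sided)
        # under the null, p ~ uniform: not all 10 should be < 0.2
        assert sum(1 for q in ps if q < 0.2) < 8
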