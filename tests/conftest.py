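import numpy as np
import pytest

from phylospread import HaplotypeSet, PopulationRow, SampleTable


@pytest.fixture
def tiny_haps() -> HaplotypeSet:
    """Four haplotypes on a step chain A-B-C plus a distant D."""
    return HaplotypeSet(
        {
            "A": "AAAAAAAAAA",
            "B": "AAAAAAAAAT",
            "C": "AAAAAAAATT",
            "D": "TTTTTAAATT",
        }
    )


@pytest.fixture
def tiny_table(tiny_haps) -> SampleTable:
    return SampleTable(
        (
            PopulationRow("p1", "west", 43.0, 141.0, {"A": 8, "B": 2}),
            PopulationRow("p2", "west", 43.5, 141.0, {"B": 6}),
            PopulationRow("p3", "west", 44.0, 141.0, {"C": 5}),
            PopulationRow("p4", "east", 43.0, 144.0, {"D": 7}),
        )
    )


def random_counts(rng: np.random.Generator, haps: list[str],
                  min_total: int = 2) -> dict[str, int]:
    """Random count vector over a subset of haplotypes, total >= min_total."""
    k = rng.integers(1, len(haps) + 1)
    chosen = rng.choice(haps, size=k, replace=False)
    counts = {h: int(rng.integers(1, 8)) for h in chosen}
    while sum(counts.values()) < min_total:
        counts[chosen[0]] += 1
    return counts


def random_hapset(rng: np.random.Generator, n: int, L: int) -> HaplotypeSet:
    """Random distinct sequences (IDs h0..h{n-1})."""
    while True:
        seqs = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]
        if len(set(seqs)) == n:
            return HaplotypeSet({f"h{i}": s for i, s in enumerate(seqs)})
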