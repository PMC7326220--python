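import numpy as np
import pytest

from sspbench.reduction import pairwise_identity
from sspbench.synth import gen_dataset_of_families


@pytest.fixture
def memo_identity():
    """Identity engine with symmetric memoization, so greedy construction,
    divide-and-conquer reduction and the all-pairs oracle share alignments."""
    cache: dict[tuple[str, str], float] = {}

    def engine(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = pairwise_identity(*key)
        return cache[key]

    return engine


@pytest.fixture
def four_family_dataset():
    """12 sequences in 4 families at 95% within-family identity; cross-family
    identity sits near random background, far below 80%."""
    return gen_dataset_of_families(
        n_families=4, members_per_family=3, length=60,
        within_identity=95.0, seed=42,
    )


def all_pairs_max_identity(dataset, engine) -> float:
    """Brute-force oracle: maximum pairwise identity within a dataset."""
    worst = 0.0
    recs = dataset.records
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            worst = max(worst, engine(recs[i].residues, recs[j].residues))
    return worst


def sov_brute_force(observed: str, predicted: str) -> float:
    """Independent segment-overlap computation on explicit position sets.

    Segments are discovered with itertools.groupby and overlaps measured by
    set intersection/union, avoiding the range arithmetic of the library
    implementation.
    """
    from itertools import groupby

    def segments(s):
        segs, pos = [], 0
        for state, run in groupby(s):
            n = len(list(run))
            segs.append((state, frozenset(range(pos, pos + n))))
            pos += n
        return segs

    obs_segs = segments(observed)
    pred_segs = segments(predicted)
    num, den = 0.0, 0.0
    for state, s1 in obs_segs:
        partners = [s2 for st, s2 in pred_segs if st == state and s1 & s2]
        if not partners:
            den += len(s1)
            continue
        den += len(partners) * len(s1)
        for s2 in partners:
            minov = len(s1 & s2)
            maxov = max(s1 | s2) - min(s1 | s2) + 1
            delta = min(maxov - minov, minov, len(s1) // 2, len(s2) // 2)
            num += (minov + delta) / maxov * len(s1)
    if den == 0:
        raise ValueError("empty observed string")
    return num / den


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
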