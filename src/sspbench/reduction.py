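"""Target dataset shrinking: seeded random sampling and homology reduction.

Two ways to shrink a PSSM target dataset:

* **Random sampling** — uniform subsets of 1/2^k the original size (or an
  explicit target size), repeated with independent seeds.  Repeats may share
  entries (inter-subset replacement); a strict mode draws pairwise-disjoint
  repeats when feasible.

* **Homology reduction** — build a non-redundant (NR) set in which every
  retained pair of sequences shares less than h% identity.  The core is a
  greedy longest-first incremental clustering (the CD-HIT/USEARCH family
  strategy).  For collections too large to cluster in one pass, a
  divide-and-conquer wrapper sorts by length, partitions into subsets of
  capacity m, reduces each subset internally, and then sweeps subset pairs:
  the current head subset is held invariable while every later (body) subset
  is purged of sequences with >= h% identity to any head member.  The
  original procedure performs this purge in two steps (a merged screen
  followed by re-querying sequences dropped from the head) only because its
  external clustering engine cannot hold the head fixed; purging the body
  directly against the invariable head realises the identical postcondition
  and is what this module implements.

Percent identity between two sequences is defined as the number of identical
aligned positions under global alignment divided by the length of the
shorter sequence, in percent — the convention of the greedy-clustering tool
family.  The built-in engine scores match +1, mismatch -1, gap open -2, gap
extend -1; any callable with the same contract can be substituted (e.g. an
adapter around an external clustering tool for multi-million-sequence runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from Bio import Align

from .seqio import SequenceDataset, SequenceRecord

__all__ = [
    "ReductionConfig",
    "IdentityEngine",
    "pairwise_identity",
    "greedy_nr",
    "reduce_homology",
    "random_sample",
    "sample_size_from_k",
]

#: An identity engine maps two residue strings to percent identity in [0, 100].
IdentityEngine = Callable[[str, str], float]


@dataclass(frozen=True)
class ReductionConfig:
    """Parameters of a homology reduction run.

    h : identity threshold in percent; every output pair shares < h% identity.
    m : subset capacity of the divide-and-conquer partition (number of
        proteins per subset; production default 100,000).
    seed : RNG seed for operations that sample.
    """

    h: float
    m: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.h <= 100):
            raise ValueError("identity threshold h must be in (0, 100]")
        if self.m < 1:
            raise ValueError("subset capacity m must be >= 1")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of two sequences under global alignment.

    identity = 100 * (identical aligned positions) / min(len(a), len(b)),
    capped at 100.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _ALIGNER.align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        matches += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    return min(100.0, 100.0 * matches / min(len(a), len(b)))


def _length_sorted(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    # longest first; ties broken by id so runs are reproducible
    return sorted(records, key=lambda r: (-len(r), r.id))


def greedy_nr(
    dataset: SequenceDataset,
    h: float,
    engine: IdentityEngine = pairwise_identity,
) -> SequenceDataset:
    """Greedy incremental NR construction at identity threshold h.

    Sequences are visited longest-first; a sequence is retained iff its
    identity with every already-retained sequence is below h.  Every
    discarded sequence therefore has >= h% identity to some retained one.
    """
    if not (0 < h <= 100):
        raise ValueError("identity threshold h must be in (0, 100]")
    retained: list[SequenceRecord] = []
    for rec in _length_sorted(dataset.records):
        if all(engine(rec.residues, kept.residues) < h for kept in retained):
            retained.append(rec)
    return SequenceDataset(records=retained, label=f"{dataset.label}|nr{h:g}")


def reduce_homology(
    dataset: SequenceDataset,
    config: ReductionConfig,
    engine: IdentityEngine = pairwise_identity,
) -> SequenceDataset:
    """Divide-and-conquer homology reduction to < h% pairwise identity.

    Procedure: (1) sort all sequences by length descending; (2) partition in
    order into N = ceil(n/m) subsets; (3) reduce each subset internally with
    :func:`greedy_nr`; (4) sweep heads: with subset S_x held invariable,
    drop from every later subset any sequence with >= h identity to a member
    of S_x, then emit S_x.  The output is a subset of the input, every
    output pair shares < h% identity, and the result is deterministic given
    the input, h and m.
    """
    sorted_records = _length_sorted(dataset.records)
    n = len(sorted_records)
    if n == 0:
        return SequenceDataset(records=[], label=f"{dataset.label}|nr{config.h:g}")
    m = config.m
    subsets = [sorted_records[i:i + m] for i in range(0, n, m)]

    # intra-subset reduction
    reduced: list[list[SequenceRecord]] = []
    for part in subsets:
        nr = greedy_nr(SequenceDataset(records=list(part)), config.h, engine)
        reduced.append(list(nr.records))

    # inter-subset sweep: purge bodies against the invariable head
    output: list[SequenceRecord] = []
    for x in range(len(reduced)):
        head = reduced[x]
        for y in range(x + 1, len(reduced)):
            reduced[y] = [
                rec for rec in reduced[y]
                if all(engine(rec.residues, hrec.residues) < config.h
                       for hrec in head)
            ]
        output.extend(head)
    return SequenceDataset(records=output, label=f"{dataset.label}|nr{config.h:g}")


def sample_size_from_k(n: int, k: int) -> int:
    """Size of a 1/2^k subset of n entries, rounded half-up."""
    if k < 0:
        raise ValueError("halving exponent k must be >= 0")
    return int(math.floor(n / 2 ** k + 0.5))


def random_sample(
    dataset: SequenceDataset,
    *,
    k: int | None = None,
    target_size: int | None = None,
    repeats: int = 1,
    seed: int = 0,
    strict: bool = False,
) -> list[SequenceDataset]:
    """Seeded uniform subsampling of a dataset, without replacement within
    each repeat.

    Exactly one of ``k`` (halving exponent; sample size is n/2^k rounded
    half-up) or ``target_size`` must be given.  By default different repeats
    are drawn independently and may share entries (inter-subset
    replacement); ``strict=True`` draws pairwise-disjoint repeats, which
    requires ``repeats * size <= n``.  Repeat r uses seed ``seed + r`` so
    each repeat is individually reproducible.
    """
    if (k is None) == (target_size is None):
        raise ValueError("specify exactly one of k or target_size")
    n = len(dataset)
    size = sample_size_from_k(n, k) if k is not None else int(target_size)
    if size < 0 or size > n:
        raise ValueError(f"sample size {size} outside [0, {n}]")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")

    samples: list[SequenceDataset] = []
    if strict:
        if repeats * size > n:
            raise ValueError(
                f"strict mode infeasible: {repeats} x {size} > {n} entries"
            )
        perm = np.random.default_rng(seed).permutation(n)
        for r in range(repeats):
            idx = sorted(perm[r * size:(r + 1) * size])
            samples.append(_take(dataset, idx, r))
    else:
        for r in range(repeats):
            rng = np.random.default_rng(seed + r)
            idx = sorted(rng.choice(n, size=size, replace=False))
            samples.append(_take(dataset, idx, r))
    return samples


def _take(dataset: SequenceDataset, indices, r: int) -> SequenceDataset:
    return SequenceDataset(
        records=[dataset.records[i] for i in indices],
        label=f"{dataset.label}|sample{r}",
    )
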