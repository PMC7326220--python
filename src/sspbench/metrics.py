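"""Secondary structure prediction accuracy: Q, SOV, correlation, significance.

Q accuracy is the fraction of residues whose predicted conformational state
matches the observed one.  Aggregates over a query set are micro-averaged:
total correct residues divided by total residues, so large proteins are not
under-weighted (the classic per-protein arithmetic mean is provided as
``macro`` for comparison).

SOV (segment overlap) scores agreement at the level of secondary structure
segments rather than individual residues, using the 1999 revision of the
measure: for every observed segment s1 of a state, each overlapping predicted
segment s2 of the same state contributes

    ((minov + delta) / maxov) * len(s1)

where minov is the number of shared positions, maxov the span of the union,
and delta = min(maxov - minov, minov, len(s1)//2, len(s2)//2) forgives small
boundary disagreements.  The normalizer counts len(s1) once per overlapping
pair (or once if the segment is entirely missed).  Set-level SOV is averaged
over proteins with protein length as the weight:

    SOV_bar = sum_i size_i * SOV_i / sum_i size_i
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "THREE_STATE",
    "EIGHT_STATE",
    "SSAnnotation",
    "SSPair",
    "EvaluationResult",
    "GroupComparison",
    "map_8to3",
    "q_accuracy",
    "sov",
    "weighted_sov",
    "evaluate_set",
    "pearson_correlation",
    "compare_groups",
    "read_pairs_tsv",
]

THREE_STATE = frozenset("HEC")
EIGHT_STATE = frozenset("HGIEBTSC")

#: DSSP 8-state to 3-state mapping (Rost–Sander convention):
#: helices (H, G, I) -> H; strands and bridges (E, B) -> E; the rest -> C.
EIGHT_TO_THREE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C",
}


@dataclass(frozen=True)
class SSAnnotation:
    """Per-residue secondary structure states for one protein."""

    protein_id: str
    states: str
    alphabet_size: Literal[3, 8] = 3

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError(f"{self.protein_id}: empty state string")
        alphabet = THREE_STATE if self.alphabet_size == 3 else EIGHT_STATE
        bad = set(self.states) - alphabet
        if bad:
            raise ValueError(
                f"{self.protein_id}: states {sorted(bad)} outside the "
                f"{self.alphabet_size}-state alphabet"
            )

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class SSPair:
    """Observed/predicted annotation pair for one protein."""

    observed: SSAnnotation
    predicted: SSAnnotation

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.predicted):
            raise ValueError(
                f"{self.observed.protein_id}: observed and predicted strings "
                f"have different lengths "
                f"({len(self.observed)} vs {len(self.predicted)})"
            )
        if self.observed.alphabet_size != self.predicted.alphabet_size:
            raise ValueError(f"{self.observed.protein_id}: mixed alphabets")

    @property
    def protein_id(self) -> str:
        return self.observed.protein_id

    def __len__(self) -> int:
        return len(self.observed)


def map_8to3(annotation: SSAnnotation) -> SSAnnotation:
    """Collapse an 8-state annotation to 3 states (H/G/I->H, E/B->E, T/S/C->C)."""
    if annotation.alphabet_size != 8:
        raise ValueError("map_8to3 requires an 8-state annotation")
    return SSAnnotation(
        protein_id=annotation.protein_id,
        states="".join(EIGHT_TO_THREE[s] for s in annotation.states),
        alphabet_size=3,
    )


def _pair_correct(pair: SSPair) -> int:
    return sum(o == p for o, p in zip(pair.observed.states, pair.predicted.states))


def q_accuracy(
    pairs: Sequence[SSPair], mode: Literal["micro", "macro"] = "micro"
) -> tuple[float, dict[str, float]]:
    """Q accuracy of a query set.

    Returns ``(aggregate, per_protein)``.  ``micro`` pools residues across
    proteins (sum of correct / sum of lengths); ``macro`` is the unweighted
    mean of per-protein fractions.
    """
    if not pairs:
        raise ValueError("need at least one observed/predicted pair")
    per_protein = {
        p.protein_id: _pair_correct(p) / len(p) for p in pairs
    }
    if mode == "micro":
        aggregate = sum(_pair_correct(p) for p in pairs) / sum(len(p) for p in pairs)
    elif mode == "macro":
        aggregate = float(np.mean(list(per_protein.values())))
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return aggregate, per_protein


def _segments(states: str) -> list[tuple[str, int, int]]:
    """Maximal runs as (state, start, end) with inclusive ends."""
    segs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            segs.append((states[start], start, i - 1))
            start = i
    return segs


def sov(pair: SSPair) -> tuple[float, dict[str, float]]:
    """Segment overlap score of one protein (1999 definition).

    Returns ``(sov, per_state)`` where ``per_state`` maps each state present
    in the observed string to its own SOV.  Scores are on the [0, 1] scale.
    """
    obs, pred = pair.observed.states, pair.predicted.states
    obs_segs = _segments(obs)
    pred_segs = _segments(pred)
    states = {s for s, _, _ in obs_segs}

    total_num = 0.0
    total_den = 0.0
    per_state: dict[str, float] = {}
    for state in sorted(states):
        s1_list = [(a, b) for s, a, b in obs_segs if s == state]
        s2_list = [(a, b) for s, a, b in pred_segs if s == state]
        num = 0.0
        den = 0.0
        for a1, b1 in s1_list:
            len1 = b1 - a1 + 1
            overlapping = [
                (a2, b2) for a2, b2 in s2_list if a2 <= b1 and b2 >= a1
            ]
            if not overlapping:
                den += len1
                continue
            den += len(overlapping) * len1
            for a2, b2 in overlapping:
                len2 = b2 - a2 + 1
                minov = min(b1, b2) - max(a1, a2) + 1
                maxov = max(b1, b2) - min(a1, a2) + 1
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                num += (minov + delta) / maxov * len1
        per_state[state] = num / den if den > 0 else 0.0
        total_num += num
        total_den += den
    if total_den == 0:
        raise ValueError(f"{pair.protein_id}: empty observed string")
    return total_num / total_den, per_state


def weighted_sov(per_protein: Sequence[tuple[int, float]]) -> float:
    """Length-weighted average of per-protein SOV values.

    ``per_protein`` holds ``(size_i, SOV_i)`` entries; the result is
    ``sum(size_i * SOV_i) / sum(size_i)``.
    """
    if not per_protein:
        raise ValueError("need at least one protein")
    sizes = np.array([s for s, _ in per_protein], dtype=float)
    sovs = np.array([v for _, v in per_protein], dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("protein sizes must be positive")
    return float((sizes * sovs).sum() / sizes.sum())


@dataclass
class EvaluationResult:
    """Per-protein and aggregate accuracy of a query set at one alphabet size."""

    alphabet_size: Literal[3, 8]
    aggregate_q: float
    aggregate_sov: float
    per_protein: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        k = self.alphabet_size
        return {
            f"Q{k}": self.aggregate_q,
            f"SOV{k}": self.aggregate_sov,
            "per_protein": self.per_protein,
        }


def _evaluate_alphabet(pairs: Sequence[SSPair]) -> EvaluationResult:
    q_micro, q_per = q_accuracy(pairs, mode="micro")
    sov_entries = []
    per_protein: dict[str, dict[str, float]] = {}
    for pair in pairs:
        s, _ = sov(pair)
        sov_entries.append((len(pair), s))
        per_protein[pair.protein_id] = {
            "length": len(pair),
            "Q": q_per[pair.protein_id],
            "SOV": s,
        }
    return EvaluationResult(
        alphabet_size=pairs[0].observed.alphabet_size,
        aggregate_q=q_micro,
        aggregate_sov=weighted_sov(sov_entries),
        per_protein=per_protein,
    )


def evaluate_set(pairs8: Sequence[SSPair]) -> dict[int, EvaluationResult]:
    """Evaluate 8-state pairs at both alphabet sizes.

    Returns ``{8: EvaluationResult, 3: EvaluationResult}``; the 3-state
    result is computed after collapsing both strings with :func:`map_8to3`.
    """
    if not pairs8:
        raise ValueError("need at least one pair")
    if pairs8[0].observed.alphabet_size != 8:
        raise ValueError("evaluate_set expects 8-state pairs")
    pairs3 = [
        SSPair(observed=map_8to3(p.observed), predicted=map_8to3(p.predicted))
        for p in pairs8
    ]
    return {8: _evaluate_alphabet(pairs8), 3: _evaluate_alphabet(pairs3)}


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class GroupComparison:
    """Outcome of the normality / variance / t-test cascade."""

    p_value: float
    branch: Literal["student", "welch"]
    shapiro_p: tuple[float, float]
    f_test_p: float | None
    t_statistic: float


def compare_groups(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """Two-sided comparison of group means with an audited decision path.

    Shapiro-Wilk checks normality of each group; if both pass at ``alpha``,
    an F-test checks equality of variances.  Equal variances select the
    Student's t-test, unequal variances the Welch's t-test.  If either group
    fails the normality check the comparison falls back to Welch's t-test
    (robust to the variance assumption), and the branch taken is recorded.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Shapiro-Wilk test undefined for constant values")
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue

    f_p: float | None = None
    if sw_a > alpha and sw_b > alpha:
        # two-sided F-test for variance equality
        f_stat = np.var(a, ddof=1) / np.var(b, ddof=1)
        dfn, dfd = len(a) - 1, len(b) - 1
        cdf = stats.f.cdf(f_stat, dfn, dfd)
        f_p = 2 * min(cdf, 1 - cdf)
        equal_var = f_p > alpha
    else:
        equal_var = False
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        p_value=float(res.pvalue),
        branch="student" if equal_var else "welch",
        shapiro_p=(float(sw_a), float(sw_b)),
        f_test_p=f_p,
        t_statistic=float(res.statistic),
    )


def read_pairs_tsv(path, alphabet_size: Literal[3, 8] = 3) -> list[SSPair]:
    """Read observed/predicted pairs from a TSV with columns
    protein_id, observed, predicted (header optional)."""
    pairs: list[SSPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            pid, obs, pred = fields
            if lineno == 1 and {obs.lower(), pred.lower()} & {"observed", "predicted"}:
                continue  # header row
            pairs.append(
                SSPair(
                    observed=SSAnnotation(pid, obs, alphabet_size),
                    predicted=SSAnnotation(pid, pred, alphabet_size),
                )
            )
    return pairs
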