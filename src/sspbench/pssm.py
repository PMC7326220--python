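"""PSI-BLAST ASCII PSSM parsing and Shannon entropy of sequence profiles.

A position-specific scoring matrix (PSSM) stores, for every residue of a
query protein, the observed substitution probabilities of the 20 standard
amino acids derived from aligned homologs.  Because each row is a probability
distribution over a 20-state variable, its Shannon entropy

    S = -sum_c p_c * log2(p_c)        (bits, 0 <= S <= log2 20)

quantifies the complexity of the profile at that position: near-zero for a
strictly conserved column, log2(20) ~ 4.32 bits for a maximally diverse one.
The mean entropy over a profile (or over a whole query set) serves as a
proxy for PSSM quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "MAX_ENTROPY_BITS",
    "PSSMRow",
    "PSSMProfile",
    "EntropyProfile",
    "parse_pssm",
    "pssm_entropy",
    "dataset_mean_entropy",
]

#: Column order used by PSI-BLAST ``-out_ascii_pssm`` output.
AMINO_ACIDS = tuple("ARNDCQEGHILKMFPSTWYV")

#: Entropy of the uniform 20-state distribution, in bits.
MAX_ENTROPY_BITS = float(np.log2(20.0))


@dataclass(frozen=True)
class PSSMRow:
    """One residue position of a PSSM."""

    position: int                 # 1-based
    residue: str                  # query amino acid at this position
    log_odds: tuple[int, ...]     # 20 integer log-odds scores
    probabilities: tuple[float, ...]  # 20 observed probabilities, sum to 1
    information: float = 0.0      # PSI-BLAST "information per position" (unused downstream)
    weight: float = 0.0           # relative weight of gapless matches


@dataclass
class PSSMProfile:
    """Per-residue probability profile parsed from a PSI-BLAST ASCII PSSM."""

    query_id: str
    rows: list[PSSMRow]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def probability_matrix(self) -> np.ndarray:
        """(L, 20) array of observed probabilities."""
        return np.array([r.probabilities for r in self.rows], dtype=float)


@dataclass
class EntropyProfile:
    """Per-residue Shannon entropies (bits) of one PSSM, with their mean."""

    query_id: str
    per_residue: np.ndarray
    mean: float

    def __len__(self) -> int:
        return len(self.per_residue)


def _normalize_row(percentages: Sequence[float], residue: str) -> tuple[float, ...]:
    """Percentages -> probabilities summing to 1.

    PSI-BLAST prints integer percentages, so rows rarely sum to exactly 100;
    they are renormalized by their sum.  All-zero rows (emitted when no
    homolog aligns to the position) fall back to a one-hot distribution on
    the query residue.
    """
    arr = np.asarray(percentages, dtype=float) / 100.0
    if np.any(arr < 0):
        raise ValueError("negative probability in PSSM row")
    total = arr.sum()
    if total == 0:
        if residue not in AMINO_ACIDS:
            # non-standard query residue: fall back to uniform
            arr = np.full(20, 1.0 / 20.0)
        else:
            arr = np.zeros(20)
            arr[AMINO_ACIDS.index(residue)] = 1.0
    else:
        arr = arr / total
    return tuple(arr.tolist())


def parse_pssm(path: str | Path, query_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` dialect).

    The matrix body has one line per query residue: position, residue
    letter, 20 integer log-odds, 20 integer observed percentages and,
    optionally, the per-position information content and relative weight.
    The trailing K/lambda block is ignored.

    Percentages are converted to fractions and renormalized (see
    :func:`_normalize_row`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[PSSMRow] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens or not tokens[0].isdigit():
                continue
            if len(tokens) not in (42, 44):
                raise ValueError(
                    f"{path}: row {tokens[0]}: expected 42 or 44 columns, "
                    f"got {len(tokens)}"
                )
            try:
                position = int(tokens[0])
                residue = tokens[1]
                log_odds = tuple(int(t) for t in tokens[2:22])
                percentages = [float(t) for t in tokens[22:42]]
                info = float(tokens[42]) if len(tokens) == 44 else 0.0
                weight = float(tokens[43]) if len(tokens) == 44 else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric cell in row {tokens[0]}") from exc
            rows.append(
                PSSMRow(
                    position=position,
                    residue=residue,
                    log_odds=log_odds,
                    probabilities=_normalize_row(percentages, residue),
                    information=info,
                    weight=weight,
                )
            )
    if not rows:
        raise ValueError(f"{path}: no PSSM matrix rows found")
    return PSSMProfile(query_id=query_id or path.stem, rows=rows)


def shannon_entropy(probabilities: np.ndarray) -> np.ndarray:
    """Row-wise Shannon entropy in bits with the 0*log2(0) = 0 convention."""
    p = np.asarray(probabilities, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=-1)


def pssm_entropy(profile: PSSMProfile) -> EntropyProfile:
    """Per-residue and mean Shannon entropy (bits) of a PSSM profile."""
    if len(profile) == 0:
        raise ValueError("empty PSSM profile")
    per_residue = shannon_entropy(profile.probability_matrix)
    return EntropyProfile(
        query_id=profile.query_id,
        per_residue=per_residue,
        mean=float(per_residue.mean()),
    )


def dataset_mean_entropy(
    profiles: Iterable[EntropyProfile],
    weighting: Literal["residue", "protein"] = "residue",
) -> float:
    """Average PSSM entropy of a query set, in bits.

    ``residue`` weighting (default) pools every residue of every protein —
    the same philosophy as micro-averaged Q accuracy.  ``protein`` weighting
    averages the per-protein means, weighting each protein equally.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one entropy profile")
    if weighting == "residue":
        total = sum(float(p.per_residue.sum()) for p in profiles)
        n = sum(len(p) for p in profiles)
        return total / n
    if weighting == "protein":
        return float(np.mean([p.mean for p in profiles]))
    raise ValueError(f"unknown weighting: {weighting!r}")
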