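"""Synthetic inputs with known ground truth.

Real inputs to this toolkit — UniRef-style sequence collections, PSI-BLAST
PSSMs, secondary structure annotations — are gigabytes of downloads and
hours of compute.  These generators emulate their testable features at desk
scale:

* sequence families with controlled within-family identity (substitution
  mutants of a random root), mimicking the redundancy structure homology
  reduction removes;
* secondary structure observed/predicted pairs with an exact number of
  wrong residues and geometric segment lengths;
* PSSM profiles with Dirichlet rows whose concentration dials the Shannon
  entropy from near 0 (one-hot) to near log2(20) (uniform);
* exact or noisy samples of the performance model curves for fit-recovery
  tests.

Every generator is deterministic given its seed.  What these fixtures do not
emulate: realistic amino-acid composition, insertions/deletions within a
family, evolutionary correlation between profile columns, or predictor-
specific error structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .metrics import SSAnnotation, SSPair
from .models import HomologyPerformanceModel, SizePerformanceModel
from .pssm import AMINO_ACIDS, PSSMProfile, PSSMRow
from .seqio import SequenceDataset, SequenceRecord

__all__ = [
    "FamilySpec",
    "gen_family",
    "gen_dataset_of_families",
    "gen_ss_pair",
    "gen_pssm",
    "write_pssm_ascii",
    "gen_perf_points",
]

_STATES3 = "HEC"
_STATES8 = "HGIEBTSC"


@dataclass(frozen=True)
class FamilySpec:
    """One family of homologous sequences.

    n_members root-derived mutants of the given length whose identity to the
    root is ``within_identity`` percent (exact number of substituted
    positions: round((1 - within_identity/100) * length)).
    """

    n_members: int
    length: int
    within_identity: float
    seed: int = 0
    family_id: str = "fam"

    def __post_init__(self) -> None:
        if not (0 < self.within_identity <= 100):
            raise ValueError("within_identity must be in (0, 100]")
        if self.n_members < 1 or self.length < 1:
            raise ValueError("n_members and length must be >= 1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_family(spec: FamilySpec) -> SequenceDataset:
    """Generate a root sequence plus substitution mutants at a target identity.

    Each member substitutes exactly ``round((1 - id/100) * length)``
    positions of the root with a different residue drawn uniformly from the
    other 19 standard amino acids, so the member-vs-root identity matches
    the target to within one position's worth.
    """
    rng = np.random.default_rng(spec.seed)
    root = _random_sequence(rng, spec.length)
    n_sub = int(math.floor((1 - spec.within_identity / 100) * spec.length + 0.5))
    records = [SequenceRecord(id=f"{spec.family_id}_root", description="",
                              residues=root)]
    for i in range(spec.n_members - 1):
        positions = rng.choice(spec.length, size=n_sub, replace=False)
        member = list(root)
        for pos in positions:
            choices = [a for a in AMINO_ACIDS if a != root[pos]]
            member[pos] = choices[rng.integers(len(choices))]
        records.append(
            SequenceRecord(id=f"{spec.family_id}_m{i}", description="",
                           residues="".join(member))
        )
    return SequenceDataset(records=records, label=f"synthetic:{spec.family_id}")


def gen_dataset_of_families(
    n_families: int,
    members_per_family: int,
    length: int,
    within_identity: float,
    seed: int = 0,
) -> SequenceDataset:
    """Concatenate several independent families into one dataset.

    Roots of different families are independent random sequences, so
    cross-family identity sits near the random background (~5% expected
    matches per position, somewhat higher after optimal alignment).
    """
    records: list[SequenceRecord] = []
    for f in range(n_families):
        fam = gen_family(FamilySpec(
            n_members=members_per_family, length=length,
            within_identity=within_identity, seed=seed + f,
            family_id=f"fam{f}",
        ))
        records.extend(fam.records)
    return SequenceDataset(records=records, label="synthetic:families")


def gen_ss_pair(
    length: int,
    q_target: float,
    mean_segment: float = 7.0,
    alphabet: Literal[3, 8] = 3,
    seed: int = 0,
    protein_id: str = "synth",
) -> SSPair:
    """Generate an observed/predicted annotation pair with exact accuracy.

    The observed string is a chain of segments with geometric lengths
    (mean ``mean_segment``, minimum 1) whose states alternate (no two
    adjacent segments share a state).  The predicted string corrupts exactly
    ``round((1 - q_target) * length)`` positions to a different state, so the
    realized per-protein Q equals ``q_target`` to within 1/length.
    """
    if not (0 <= q_target <= 1):
        raise ValueError("q_target must be in [0, 1]")
    if alphabet not in (3, 8):
        raise ValueError("alphabet must be 3 or 8")
    if length < 1:
        raise ValueError("length must be >= 1")
    states = _STATES3 if alphabet == 3 else _STATES8
    rng = np.random.default_rng(seed)
    p = min(1.0, 1.0 / mean_segment)

    observed: list[str] = []
    prev = None
    while len(observed) < length:
        choices = [s for s in states if s != prev]
        state = choices[rng.integers(len(choices))]
        seg_len = int(rng.geometric(p))
        observed.extend(state * min(seg_len, length - len(observed)))
        prev = state
    obs = "".join(observed)

    n_wrong = int(math.floor((1 - q_target) * length + 0.5))
    wrong_positions = rng.choice(length, size=n_wrong, replace=False)
    predicted = list(obs)
    for pos in wrong_positions:
        choices = [s for s in states if s != obs[pos]]
        predicted[pos] = choices[rng.integers(len(choices))]
    return SSPair(
        observed=SSAnnotation(protein_id, obs, alphabet),
        predicted=SSAnnotation(protein_id, "".join(predicted), alphabet),
    )


def gen_pssm(
    length: int,
    concentration: float,
    seed: int = 0,
    query_id: str = "synth",
) -> PSSMProfile:
    """Generate a PSSM profile with Dirichlet probability rows.

    Rows are drawn from a symmetric Dirichlet with the given concentration:
    small values give near-one-hot rows (entropy -> 0), large values give
    near-uniform rows (entropy -> log2 20 ~ 4.32 bits).
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    query = _random_sequence(rng, length)
    rows: list[PSSMRow] = []
    for j in range(length):
        p = rng.dirichlet(np.full(20, concentration))
        # integer log-odds on a half-bit scale relative to uniform background,
        # mirroring the PSI-BLAST output convention
        with np.errstate(divide="ignore"):
            lo = np.where(p > 0, 2 * np.log2(np.maximum(p, 1e-12) / 0.05), -8)
        log_odds = tuple(int(v) for v in np.clip(np.round(lo), -9, 13))
        rows.append(PSSMRow(
            position=j + 1,
            residue=query[j],
            log_odds=log_odds,
            probabilities=tuple(p.tolist()),
        ))
    return PSSMProfile(query_id=query_id, rows=rows)


def write_pssm_ascii(profile: PSSMProfile, path: str | Path) -> Path:
    """Write a profile in the PSI-BLAST ASCII PSSM dialect.

    Probabilities are printed as integer percentages (as PSI-BLAST does),
    so a parsed round trip reproduces each row only to within rounding;
    rows are renormalized by the parser.
    """
    path = Path(path)
    aa = " ".join(f"{a:>3}" for a in AMINO_ACIDS)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"        {aa} {aa}",
    ]
    for row in profile.rows:
        pct = np.asarray(row.probabilities) * 100
        # largest-remainder rounding: integers that sum to exactly 100 with
        # per-cell error below one percentage unit
        ints = np.floor(pct).astype(int)
        shortfall = 100 - int(ints.sum())
        order = np.argsort(-(pct - ints))
        ints[order[:shortfall]] += 1
        cells = "".join(f"{v:4d}" for v in row.log_odds)
        pcts = "".join(f"{v:4d}" for v in ints)
        lines.append(
            f"{row.position:5d} {row.residue}  {cells} {pcts}  "
            f"{row.information:5.2f} {row.weight:5.2f}"
        )
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1347     0.3176",
        "Standard Gapped      0.0410     0.2670",
        "PSI Ungapped         0.1550     0.3179",
        "PSI Gapped           0.0410     0.2670",
        "",
    ]
    path.write_text("\n".join(lines))
    return path


def gen_perf_points(
    model: SizePerformanceModel | HomologyPerformanceModel,
    quantity: str,
    xs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Sample (x, y) points from a performance model curve, optionally noisy.

    ``quantity`` is TC/Q3/Q8 for a size model, TC_h/Q3_h/Q8_h for a
    homology model.  ``noise_sd = 0`` gives exact curve samples.
    """
    from .models import eval_homology_model, eval_size_model

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for x in xs:
        if isinstance(model, SizePerformanceModel):
            y = eval_size_model(model, quantity, x)
        else:
            y = eval_homology_model(model, quantity, x)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd)
        points.append((float(x), float(y)))
    return points
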