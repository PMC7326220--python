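# Methods

## Problem setting

Modern protein secondary structure predictors (Psipred, SpineX, RaptorX,
DeepCNF, ...) derive their feature set from a PSI-BLAST position-specific
scoring matrix (PSSM), built by searching the query against a large *target
dataset* such as UniRef90. The search dominates the running time and scales
linearly with the dataset size `n_t`, while prediction accuracy saturates:
beyond a few million target sequences the gain is marginal. Shrinking the
target dataset — by random sampling and/or by homology (sequence-identity)
reduction — therefore trades a large speed-up for a small, and in the
homology case sometimes negative, accuracy cost. `sspbench` packages the
machinery needed to study and apply that trade-off: dataset reduction,
PSSM-entropy quality measurement, rigorous accuracy evaluation, and the
fitted speed/accuracy models.

## Performance models (`sspbench.models`)

Size-dependent models, fitted on a 115-protein query benchmark against
random subsets of UniRef90 (identity level fixed near 90%):

* `TC(n_t) = 2.8658e-5 * n_t + 5.8248` seconds — linear, because PSI-BLAST
  search time is O(n_t) and per-query prediction time is roughly constant.
* `Q3(n_t) = A / (1 + exp((M − log2 n_t)/s))^g + B` with
  A = 0.1363, M = 17.0963, s = 2.1447, g = 0.6205, B = 0.6716.
* `Q8(n_t)` is the same logistic form without the asymmetry exponent
  (A = 0.1281, M = 15.6095, s = 2.5405, B = 0.5621).

The printed form of the Q3 curve is typographically ambiguous about where
the asymmetry exponent binds; the reading implemented here —
`amplitude / (1 + exp(·))^asymmetry + baseline` — is the only one
consistent with the published prediction of 0.807 at `n_t = 87.3e6`, which
the test suite checks. Alternative linear time-cost coefficient sets fitted
on the CASP12/CASP13 query sets are shipped as constants of the same form
(`CASP12_TC`, `CASP13_TC`), not as a separate code path.

Homology-series models, fitted on non-redundant datasets whose size and
identity cutoff `c_t` (percent) both vary:

* `TC_h(n_t)`: quadratic `(-4.0386e-14, 3.2338e-05, -73.9573)`;
* `Q3_h(c_t)`, `Q8_h(c_t)`: cubics
  `(-1.0552e-7, 1.4931e-5, -0.0006, 0.8152)` and
  `(-9.3552e-8, 1.5515e-5, -0.0008, 0.7000)`.

Time-cost constants are hardware-specific (single search thread on a
3.33 GHz CPU); only the functional trends transfer, and the model carries a
note to that effect. Evaluation outside the fitted ranges (`c_t` in
[20, 100], `n_t >= 1`) emits an `ExtrapolationWarning` but still returns the
polynomial value. The fitted SOV curves of the original benchmark are not
reproduced: their functional forms were never published.

Refitting: the linear and polynomial forms use ordinary least squares
(`numpy.polyfit`); the sigmoids use bounded trust-region least squares
(`scipy.optimize.curve_fit`) with deterministic initialization — baseline =
min(y), amplitude = max(y) − min(y), midpoint = the log2 size nearest the
half-rise, scale = 2, asymmetry = 1 — and tolerances of 1e-10. Noiseless
samples of every form refit to well within 1% per parameter (tested); the
asymmetric five-parameter sigmoid needs at least 5 points spanning the rise.

## Accuracy measures (`sspbench.metrics`)

Q3/Q8 are micro-averaged: total correct residues over total residues, so a
1,000-residue protein counts 20 times a 50-residue one. The per-protein
(macro) mean is provided only for comparison. SOV cannot be pooled by
residue, so set-level SOV is the length-weighted mean of per-protein scores.

SOV uses the 1999 revision of the segment-overlap definition: per observed
segment s1 and same-state overlapping predicted segment s2,
`(minov + delta)/maxov * len(s1)` with
`delta = min(maxov − minov, minov, len(s1)//2, len(s2)//2)`, the normalizer
counting `len(s1)` once per overlapping pair, or once for an entirely
missed segment. Identical strings score exactly 1; scores are reported on
[0, 1] (multiply by 100 for display only). The implementation is validated
against an independent position-set enumerator on random strings.

The 8-to-3-state collapse follows the standard Rost–Sander convention
(H, G, I → H; E, B → E; T, S, C → C). Collapsing cannot create errors, so
Q3 >= Q8 on the same pairs (a tested invariant). Inputs must be fully
annotated strings; undefined observed states are not supported.

Group comparisons follow a fixed cascade: Shapiro-Wilk normality on each
group; if both pass at alpha, a two-sided F-test for variance equality;
equal variances select Student's t, unequal Welch's t. When normality
fails, the cascade falls back to Welch's t (robust to unequal variances)
rather than a rank test, and the branch taken is always reported so the
decision path is auditable.

## PSSM entropy (`sspbench.pssm`)

The parser reads the PSI-BLAST `-out_ascii_pssm` dialect (BLAST+ 2.6-era):
per-residue rows of 20 integer log-odds and 20 integer observed
percentages, plus optional information/weight columns and a trailing
K/lambda block. Percentages are divided by 100 and renormalized by their
row sum (integer printing rarely sums to exactly 100); all-zero rows —
emitted when no homolog aligns — fall back to a one-hot distribution on the
query residue (uniform if the query residue is non-standard). Entropy is
computed from the observed-probability block, never the log-odds block,
because only the former is a probability distribution; PSI-BLAST's own
"information per position" column is parsed but ignored (it is a
relative-entropy-against-background quantity, not the Shannon entropy used
here).

Row entropy is `S = −sum_c p_c log2 p_c` bits with `0*log2 0 = 0`, bounded
by `[0, log2 20 ≈ 4.3219]`. Dataset-level averages default to residue
weighting (pooling all residues, consistent with micro-averaged Q); a
protein-weighted mode is provided because published dataset-level entropy
figures do not state their weighting.

## Dataset reduction (`sspbench.reduction`)

Percent identity is defined as identical aligned positions under global
alignment divided by the length of the shorter sequence — the convention of
the greedy-clustering tool family (CD-HIT/USEARCH). The built-in engine
uses Biopython's `PairwiseAligner` with match +1, mismatch −1, gap open −2,
gap extend −1; the scoring is a documented constant and the engine argument
is pluggable for production-scale adapters. Ambiguity letters pass through
parsing and count as mismatches.

`greedy_nr` visits sequences longest-first (ties broken by id ascending for
reproducibility) and retains a sequence iff it shares < h% identity with
every already-retained sequence. `reduce_homology` wraps this in the
divide-and-conquer scheme needed when the collection exceeds what one
clustering pass can hold: sort by length, partition into subsets of
capacity m (production default 100,000), reduce each subset internally,
then sweep heads — the current head subset is invariable while every later
subset is purged of sequences with >= h% identity to any head member. The
two-step merge-and-screen/re-query dance of engines that cannot hold a head
set fixed is collapsed here into the equivalent direct purge; the
postcondition (output ⊆ input, all pairs < h%, deterministic given input,
h, m) is identical, and the test suite verifies on randomized inputs that
the result equals single-pass greedy clustering as a set for every m.

Random sampling draws each repeat independently (repeat r uses seed + r),
uniformly without replacement within the repeat; repeats may overlap, which
mirrors how repeated benchmark subsets larger than 1/repeats of the source
must be drawn. A strict mode forbids overlap when `repeats * size <= n`.
The 1/2^k subset sizes round half-up.

## Synthetic data (`sspbench.synth`)

The generators emulate exactly the features the algorithms consume:

* **Families** — a random root (uniform over the 20 standard residues) plus
  members with exactly `round((1 − id/100) * length)` substituted positions,
  substitutes drawn from the other 19 residues. Cross-family identity sits
  near the random-alignment background (roughly 10–30% for short
  sequences), far below the thresholds used in tests. Uniform composition
  is deliberate: nothing downstream depends on realistic amino-acid
  frequencies. No insertions/deletions are simulated.
* **SS pairs** — observed strings as alternating-state segments with
  geometric lengths (mean 7 residues by default, the typical scale of a
  helix or strand) and predictions corrupted at exactly
  `round((1 − q_target) * length)` positions, so realized Q is exact to
  1/length. Real predictor errors cluster at segment boundaries; these do
  not, so SOV values of synthetic pairs are not calibrated — only Q is.
* **PSSMs** — rows from a symmetric Dirichlet whose concentration dials the
  expected entropy from ~0 (near one-hot) to log2 20 (near uniform).
  Columns are independent, unlike real profiles.
* **Performance points** — exact or Gaussian-noised samples of any model
  curve, for fit-recovery tests.

All generators are deterministic given their seed. Passing tests on these
fixtures demonstrate the correctness of the implemented algorithms and
formulas, not the biological realism of the inputs.

## Problem sizes and numerical choices

Test fixtures use tens of sequences of length 30–60 with subset capacities
m <= 50, which exercise every code path of the reduction algorithm
(partitioning, intra- and inter-subset phases) at a scale where a
brute-force all-pairs oracle is feasible; randomized checks run on 100
datasets. SOV agreement with the independent enumerator is checked on
1,000 random string pairs (length <= 30) at 1e-12. Entropy bounds are
checked on 10,000 Dirichlet rows. The acceptance script refits every model
form from noiseless curve samples on a seed-jittered grid before
evaluating, so its reported numbers exercise the fitting machinery as well
as the stored coefficients.

## Known limitations

* The built-in alignment engine is quadratic per pair and the greedy
  clustering quadratic in dataset size; multi-million-sequence reductions
  need an external engine behind the `IdentityEngine` contract.
* Absolute time-cost predictions are meaningless off the original benchmark
  hardware; use the linear/quadratic *forms* and refit.
* SOV is implemented in its 1999 revision only; predictors assessed with
  the 1994 variant will score slightly differently.
* Percent identity over the shorter sequence length differs from
  alignment-length or longer-sequence conventions; NR sets built under
  different definitions are not interchangeable.
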