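# Methods

This note documents the model conventions, numerical choices and
statistical procedures implemented in `profhmm`, including the places
where the design space was genuinely open and a convention had to be
fixed.

## The profile architecture

A model with M nodes stores, in probability space, a match-emission
distribution and an insert-emission distribution per node (over the 20
canonical amino acids, alphabet order `ACDEFGHIKLMNPQRSTVWY`) and seven
per-node transition probabilities in the order M→M, M→I, M→D, I→M,
I→I, D→M, D→D.  Probability space is the storage format of the HMMER3
ASCII dialect and keeps models mutable and inspectable; log-odds scores
are derived at configuration time.  The last node's row encodes the
exit convention (M→M carries the exit; M→D and D→D are zero).

A search *profile* is the log-odds view of a model configured for
multihit or unihit local alignment against a target of length L:

* **Local entry** is uniform: B→M_k with probability 1/M for every
  node.  (The main alternative, entry mass proportional to the number
  of alignments passing through a node, 2(M−k+1)/(M(M+1)), changes
  scores by at most a few tenths of a bit; uniform was chosen for
  simplicity and is applied consistently in scoring and calibration,
  so p-values are unaffected by the choice.)
* **Local exit** is free: M_k→E with score 0 from every node, the
  standard implicit-probabilistic-model convention.  Delete states
  cannot exit; paths stranded in D_M are simply not part of the path
  ensemble.
* **Flanking states** N, C and J emit background residues (log-odds 0)
  with loop probability L/(L+3) and move probability 3/(L+3), in both
  modes.
* **Multihit vs unihit.**  Multihit mode sets E→J = E→C = 0.5.  Unihit
  mode sets E→J = 0 and *leaves E→C at 0.5*, rather than renormalizing
  it to 1.  With this convention the unihit path ensemble is an
  equal-weight subset of the multihit ensemble, which makes "multihit
  Forward ≥ unihit Forward" an exact theorem (verified in the property
  suite).  Renormalizing would break that ordering for sequences
  dominated by a single strong hit.  Since the exit convention already
  makes the profile an improper probability model, the constant factor
  has no effect on score differences, rankings, or calibrated
  p-values.

The null model emits i.i.d. background residues (Swiss-Prot-derived
frequencies) under a geometric length model with p1 = L/(L+1).  A
reported bit score is (log-odds of the path ensemble − null length
term) / ln 2.

**Ambiguity codes** (B, Z, X, U, O, J) are accepted on input and scored
as the log of the background-weighted average odds ratio over their
canonical sets; this keeps X-rich sequences near score 0 rather than
letting them inherit the best-case residue score.

**Empty sequences** have no legal B..E excursion (a local hit must
consume at least one residue) and score through the N and C flanks
only, which yields a finite value (0 bits at L = 0).

## Dynamic programming

All three kernels run in natural-log space with log-sum-exp; there is
no SIMD rescaling and no 8/16-bit score quantization.  Consequently the
MSV and Viterbi scores here are exact full-precision quantities, not
the saturated approximations a vectorized implementation produces.

* **MSV** scores the best multihit arrangement of ungapped match-state
  diagonals: within-diagonal match-match moves are free, inserts and
  deletes are forbidden, and the flanking/special states are shared
  with the full model.
* **Viterbi** returns the best path and its traceback.  Ties are broken
  by a fixed priority (M over I over D over B-entry; lowest node at the
  exit), so tracebacks are deterministic.
* **Forward** sums over all paths.

Correctness is anchored by brute-force oracles: an independent
recursive enumerator of *every* legal path (feasible for M ≤ 3, L ≤ 4)
must match Forward within 1e-6 bits and Viterbi within 1e-9 bits on
hundreds of random instances, and an exhaustive diagonal-placement
enumerator must match MSV.  Domain segments are recomposed against the
total Viterbi score to 1e-9 bits.

No bias-composition filter and no null2 correction are applied; the
bias columns of the tabular outputs are fixed at 0.0.  This is a known,
documented divergence from HMMER's reported scores.

## Significance statistics

MSV and Viterbi null scores follow Gumbel laws; Forward null scores
get an exponential tail.  Calibration scores `n` i.i.d. background
sequences of length `L` (defaults n = 200, L = 100, seed 42 — desk
scale, deterministic) and fits:

* Gumbel (μ, λ) by maximum likelihood: λ solves the standard
  stationarity condition `1/λ = mean(x) − Σ x e^{−λx} / Σ e^{−λx}`
  (bracketed from the moment estimate λ₀ = π/(sd·√6), root located to
  1e-10), then μ = −ln(mean e^{−λx})/λ.  The fit agrees with an
  independent ML implementation to 1e-6.
* The Forward tail rate is fixed at λ = ln 2, the natural value for
  bit-valued scores; the location τ is anchored so that the survival
  function equals 0.04 at the empirical 96th percentile of the null
  Forward scores.  p-values above the anchor are clipped to 1.

Survival functions use the `expm1` path so the extreme tail does not
underflow.  E-values are Bonferroni corrections E = p·Z with Z
defaulting to the number of targets searched (hmmsearch/phmmer) or
models scanned (hmmscan), overridable like a `-Z` flag.  Both the
uncorrected p-value and the E-value are kept on every hit and every
domain, and the p-value is an explicit column in the tabular output.

Calibration accuracy scales as 1/√n: the default n = 200 gives
p-values good to roughly a factor of two in the tail, which is
adequate for ranking; the statistical-soundness checks calibrate at
n = 2000, where null p-values pass a Kolmogorov–Smirnov uniformity
test at the 1% level on an independent 2000-sequence sample.

## The search pipeline

Per target, the classic acceleration cascade: MSV, dropped if its null
p-value exceeds 0.02; Viterbi, dropped above 1e-3; Forward, dropped
above 1e-5; survivors are reported if E ≤ 10 and included if E ≤ 0.01
(all thresholds overridable; `max_mode` disables the gates).  These are
the reference defaults, and the hard Forward-stage gate reproduces the
reference pipeline's behavior — on very small databases a marginal
true hit with Forward p between 1e-5 and the reporting threshold is
filtered, which was verified against the reference implementation on
an equivalent synthetic case.  When a model carries GA/TC/NC bit-score
cutoffs, thresholding can switch to them (sequence cutoff for
reporting; domain cutoff for inclusion).

Domains are one segment per B..E excursion of the Viterbi traceback;
the domain score is the excursion's own log-odds, and its p-value uses
the Forward exponential tail (a package convention; posterior-decoding
envelope definition is out of scope).  The profile's length model is
re-parameterized to each target's length before scoring, as the
reference pipeline does.

**Parallel dispatch.**  Queries are read and decoded by the producing
thread into a bounded queue (depth 2 × workers); workers take whole
queries from the shared queue (work stealing — the scheduler is
deliberately simple since per-query costs dominate); a reordering
buffer yields results strictly in submission order.  Because every
worker computes a pure function of (query, targets) with all
randomness seeded, serialized results are bit-identical for every
worker count; this is asserted for 1/2/4/8 workers and is the
package's determinism contract.  The default worker count is the
physical core count (from /proc/cpuinfo, falling back to logical/2,
minimum 1).  A worker or reader failure is raised to the consumer as a
`QueryError` carrying the 1-based query ordinal, after all earlier
results have been delivered.

**Streaming fallback.**  When targets cannot be pre-fetched
(`search_files(..., max_targets_in_memory=...)`), they are re-streamed
from the file for each query; because `search_one` consumes any
iterable and computes Z from the count it saw, both routes produce
identical output.

## Building models

Columns whose gap fraction is strictly below the threshold (default
0.5) become match columns.  Weighted residue counts plus background
pseudocounts (default weight 0.1) give match emissions; insert
emissions are the background; transitions come from per-row state
paths through the column mask, with the same pseudocount weight on
uniform within-group priors.  A transition group that collects no
counts and no pseudocounts falls back to "stay on consensus"
(M→M = I→M = D→M = 1).  Sequence weighting is uniform by default with
Henikoff position-based weighting opt-in (gaps count as a symbol
type).  Effective-sequence-number (entropy) weighting is not
implemented; `effn` records `nseq`.  These build defaults are package
conventions — the classical rule set, not a reproduction of any
specific builder's prior library.

Single-sequence query profiles use BLOSUM62 conditionals
P(b|a) ∝ f_b·2^{S_ab/2} for match emissions and gap-open/extend
probabilities 0.02/0.4 for transitions.

## Synthetic data

The generators are pure functions of (parameters, seed):

* `random_hmm` — emissions from symmetric Dirichlet(0.5); transitions
  from match-favoring Dirichlets (M→· ~ Dir(10,1,1), I→· ~ Dir(3,1),
  D→· ~ Dir(2,1)), so random models have realistic ~90% match-match
  mass.
* `random_sequences` — i.i.d. background residues (the calibration
  null and the negative class everywhere).
* `emit_from_hmm` — single core-model traversals starting in match
  state 1 (the model stores no begin transitions, so the first node is
  never deleted) with multihit off; used as planted positives.
* `planted_msa` — emitted sequences with state annotations, match
  states columnized, insert runs gap-padded.

What these emulate: family membership as "generated by the profile"
and non-membership as "generated by the background".  What they do not
emulate: real protein composition bias, repeat structure, correlated
sites, or realistic domain architecture in longer proteins.  Passing
the planted-signal tests therefore demonstrates that the scoring and
ranking machinery separates model-generated from background sequences
at the stated sizes (M = 50, 20 + 20 targets); it does not certify
sensitivity on real remote homologs, where composition bias (not
modelled here — no null2) matters.

## Problem sizes in the checks

The acceptance script and test suite run at desk scale, chosen to give
stable statistics: 200 enumeration instances (M ≤ 3, L ≤ 4); 20
queries × 50 targets for worker-count invariance; calibration at
n = 2000, L = 100 with an independent 2000-sequence KS sample; 100
random models for file round trips; M = 50 with 20 + 20 targets for
planted power; 2000 null targets for filter-soundness (where the MSV
stage loses < 1% of targets that max mode would have reported).

## Known limitations

* No bias filter / null2: scores on low-complexity or biased-
  composition sequences are anti-conservative relative to HMMER.
* Score parity with HMMER binaries is *not* a goal: entry distribution,
  calibration and the absence of corrections all differ; the contract
  is internal consistency (oracle equivalence, thread invariance,
  calibrated p-value uniformity).
* Glocal/uniglocal modes, posterior-decoded domain envelopes, DNA
  search, pressed binary databases and MPI are out of scope.
* Viterbi memory is O(M·L) for the traceback matrices; fine for
  protein-scale inputs, not for chromosome-length targets.
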