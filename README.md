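# profhmm

Profile hidden Markov model homology search for protein sequences, in
pure scientific Python.

Profile HMMs (pHMMs) are the standard way to describe a protein family:
each consensus column of a family alignment becomes a *match* state
with its own residue emission distribution, flanked by *insert* and
*delete* states that absorb extra residues and skipped columns.
Databases such as Pfam distribute families in this form, and annotating
a proteome means comparing every protein against every family model.
`profhmm` implements that comparison stack end to end for users who
want to build, inspect, calibrate and search pHMMs from Python — each
piece is an ordinary Python object (models are mutable, scores and
p-values are plain floats, hit tables are sortable containers) rather
than output text to be parsed.

## What is inside

* **Digital sequences and alphabets** — residues encoded as small
  integers under the 20-letter amino alphabet, with ambiguity codes
  (B, Z, X, U, O, J) scored as background-weighted mixtures; FASTA
  streaming I/O.
* **Plan7 models** — per-node match/insert emissions and the seven
  per-node transitions, with GA/TC/NC bit-score cutoffs and E-value
  statistics as mutable attributes; read and written in the HMMER3
  ASCII format (`HMMER3/f` dialect), interchangeable with other
  HMMER3 tooling.
* **Scoring kernels** — the MSV ungapped-diagonal filter score, local
  Viterbi with traceback and per-domain segments, and the full Forward
  score, all computed in log space.  For a target of length *L* the
  reported bit score is

  ```
  S = log2 [ P(x | profile) / P(x | null) ]
  ```

  where the null emits i.i.d. background residues under a geometric
  length model.
* **Significance statistics** — null score distributions are calibrated
  by scoring random sequences: Gumbel laws `P(S >= s) =
  1 - exp(-exp(-lambda (s - mu)))` fitted by maximum likelihood for MSV
  and Viterbi, and an exponential tail `P(S >= s) = exp(-lambda (s -
  tau))` with `lambda = ln 2` for Forward.  Every hit carries both the
  uncorrected p-value and the Bonferroni-corrected E-value `E = p * Z`.
* **Search pipeline** — the `hmmsearch` / `hmmscan` / `phmmer`
  equivalents as plain functions, with the classic three-stage
  acceleration cascade (MSV -> Viterbi -> Forward, each gated on its
  null p-value) and a `--max` mode that disables it.  Queries run on
  worker threads with query pre-fetching and an order-restoring stage:
  results are **bit-identical for every worker count**.  A file-reader
  fallback re-streams targets per query when they are too large to
  pre-fetch.
* **Model building** — `hmmbuild`-style estimation from aligned FASTA
  (gap-threshold column marking, uniform or Henikoff position-based
  weights, background pseudocounts) and BLOSUM62-based single-sequence
  query profiles for `phmmer`.
* **Synthetic data** — seeded generators for random models, background
  sequences, model-emitted (planted) sequences and planted alignments,
  so the whole stack is testable without any downloads.

## Worked example

```python
import profhmm as P

# a family model and a target database, generated synthetically
hmm = P.random_hmm(50, seed=7, name="fam50")
P.calibrate(hmm, seed=42)                 # attach E-value statistics
targets = (P.emit_from_hmm(hmm, 3, seed=1, prefix="member")   # true family members
           + P.random_sequences(200, 80, seed=2))             # unrelated proteins

profile = P.configure(hmm)                # multihit local mode
hits = P.search_one(profile, targets,
                    P.PipelineOptions(max_mode=True))   # like --max
for hit in hits.reported[:4]:
    print(f"{hit.target_name:12s} {hit.full_score:7.1f} bits  "
          f"E={hit.full_evalue:.2g}  p={hit.full_pvalue:.2g}")
```

prints

```
member00000     40.2 bits  E=3.9e-07  p=1.9e-09
member00001     26.2 bits  E=0.0066  p=3.2e-05
null00057       18.6 bits  E=1.2  p=0.0061
member00002     17.1 bits  E=3.7  p=0.018
```

The planted family members rank at or near the top: the E-value is the
expected count of false hits at that score over Z = 203 comparisons,
so `member00000` and `member00001` are unambiguous while `member00002`
sits among the strongest background fluctuations, as a weakly emitted
43-residue sample should.  With the default filter cascade instead of
`max_mode`, borderline hits like these are subject to the same hard
Forward-stage p-value gate (1e-5) the reference pipeline applies.  The
same search through `hmmsearch(queries, targets, n_workers=8)` returns
exactly these numbers in query order, regardless of the worker count.

The same functionality is available from the shell:

```sh
profhmm hmmbuild --calibrate family.afa family.hmm
profhmm hmmsearch --tblout hits.tbl family.hmm proteins.faa
```

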