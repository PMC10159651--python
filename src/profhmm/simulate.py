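"""Deterministic synthetic data: random models, null sequences, planted
positives and planted alignments.

Every generator is a pure function of its parameters and an explicit
seed — there is no hidden global randomness, which is what makes the
thread-count-invariance contract of the search pipeline testable.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .alphabet import Alphabet
from .model import HMM, Background
from .sequence import DigitalSequence

__all__ = [
    "random_hmm",
    "random_sequences",
    "emit_from_hmm",
    "planted_msa",
]

# Transition Dirichlet concentrations: match-favoring, like real
# profiles.  Order within groups: (MM, MI, MD), (IM, II), (DM, DD).
_DIR_M = (10.0, 1.0, 1.0)
_DIR_I = (3.0, 1.0)
_DIR_D = (2.0, 1.0)


def random_hmm(M: int, alphabet: Optional[Alphabet] = None, seed: int = 0,
               name: Optional[str] = None) -> HMM:
    """A random valid Plan7 model with Dirichlet-sampled parameters."""
    if M < 1:
        raise ValueError("M must be >= 1")
    abc = alphabet or Alphabet.amino()
    rng = np.random.default_rng(seed)
    K = abc.size
    match = rng.dirichlet(np.full(K, 0.5), size=M)
    insert = rng.dirichlet(np.full(K, 0.5), size=M)
    trans = np.empty((M, 7))
    trans[:, 0:3] = rng.dirichlet(_DIR_M, size=M)
    trans[:, 3:5] = rng.dirichlet(_DIR_I, size=M)
    trans[:, 5:7] = rng.dirichlet(_DIR_D, size=M)
    # Last node: exit convention (no further core transitions).
    trans[M - 1] = (1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0)
    hmm = HMM(
        name=name or f"random-M{M}-s{seed}",
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        alphabet=abc,
    )
    hmm.validate()
    return hmm


def random_sequences(n: int, L: int, background: Optional[Background] = None,
                     seed: int = 0, alphabet: Optional[Alphabet] = None,
                     prefix: str = "null") -> List[DigitalSequence]:
    """``n`` i.i.d. background sequences of length ``L``."""
    if n < 1 or L < 1:
        raise ValueError("n and L must be >= 1")
    abc = alphabet or Alphabet.amino()
    bg = background or Background.amino()
    rng = np.random.default_rng(seed)
    codes = rng.choice(abc.size, size=(n, L), p=bg.frequencies)
    return [
        DigitalSequence(name=f"{prefix}{i:05d}", residues=codes[i], alphabet=abc)
        for i in range(n)
    ]


def _emit_one(hmm: HMM, rng: np.random.Generator) -> Tuple[List[int], List[Tuple[str, int]]]:
    """Sample one core-model traversal; returns residues and the state
    annotation (state, node) per emitted/visited core state.

    Traversals start in match state 1 (the model stores no begin
    transitions) and end after node M.
    """
    K = hmm.alphabet.size
    residues: List[int] = []
    states: List[Tuple[str, int]] = []
    k = 1
    state = "M"
    while True:
        if state == "M":
            residues.append(int(rng.choice(K, p=hmm.match_emissions[k - 1])))
            states.append(("M", k))
        elif state == "D":
            states.append(("D", k))
        if k == hmm.M:
            break
        row = hmm.transitions[k - 1]
        if state == "M":
            nxt = rng.choice(3, p=row[0:3] / row[0:3].sum())
            if nxt == 1:  # into insert state k
                while True:
                    residues.append(int(rng.choice(K, p=hmm.insert_emissions[k - 1])))
                    states.append(("I", k))
                    move = rng.choice(2, p=row[3:5] / row[3:5].sum())
                    if move == 0:
                        break
                state, k = "M", k + 1
            else:
                state, k = ("M", k + 1) if nxt == 0 else ("D", k + 1)
        else:  # from D
            nxt = rng.choice(2, p=row[5:7] / row[5:7].sum())
            state, k = ("M", k + 1) if nxt == 0 else ("D", k + 1)
    return residues, states


def emit_from_hmm(hmm: HMM, n: int, seed: int = 0,
                  prefix: str = "emit") -> List[DigitalSequence]:
    """Sample ``n`` sequences from the core model (single traversal,
    multihit off); deterministic given the seed."""
    hmm.validate()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        residues, _ = _emit_one(hmm, rng)
        out.append(DigitalSequence(
            name=f"{prefix}{i:05d}",
            residues=np.array(residues, dtype=np.int16),
            alphabet=hmm.alphabet,
        ))
    return out


def planted_msa(hmm: HMM, nseq: int, seed: int = 0):
    """Sample sequences from the model and columnize their match states
    into an alignment with exactly ``hmm.M`` match columns.

    Insert runs between consecutive match columns are padded with gaps
    to the longest run observed.  Returns a :class:`profhmm.build.MSA`.
    """
    from .build import MSA

    if nseq < 2:
        raise ValueError("nseq must be >= 2")
    hmm.validate()
    rng = np.random.default_rng(seed)
    M = hmm.M
    abc = hmm.alphabet
    rows_events = []
    for _ in range(nseq):
        residues, states = _emit_one(hmm, rng)
        # match_char[k] and insert_run[k] (residues emitted by I_k).
        match_char = ["-"] * (M + 1)
        insert_run = [""] * (M + 1)
        ri = 0
        for state, k in states:
            if state == "M":
                match_char[k] = abc.decode_code(residues[ri]); ri += 1
            elif state == "I":
                insert_run[k] += abc.decode_code(residues[ri]); ri += 1
        rows_events.append((match_char, insert_run))

    max_ins = [max(len(ev[1][k]) for ev in rows_events) for k in range(M + 1)]
    names, rows = [], []
    for i, (match_char, insert_run) in enumerate(rows_events):
        parts = []
        for k in range(1, M + 1):
            parts.append(match_char[k])
            parts.append(insert_run[k].ljust(max_ins[k], "-"))
        names.append(f"planted{i:05d}")
        rows.append("".join(parts))
    return MSA(names=names, rows=rows, alphabet=abc)
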