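"""Independent brute-force oracles for tiny problem instances.

These enumerate every legal state path (or every ungapped diagonal
placement, for the filter score) explicitly and score it from the
profile's score tables, sharing no traversal logic with the dynamic
programming under test.  Feasible for M <= ~4 and L <= ~6.
"""

from __future__ import annotations

import math
from typing import Iterator, List, Tuple

import numpy as np

from profhmm.model import Profile
from profhmm.sequence import DigitalSequence

_LN2 = math.log(2.0)


def enumerate_path_scores(profile: Profile, seq: DigitalSequence) -> List[float]:
    """Natural-log weights of every legal S..T path for the pair."""
    L = len(seq)
    M = profile.M
    x = seq.residues
    t = profile.t
    out: List[float] = []

    def m_emit(k: int, i: int) -> float:
        return float(profile.msc[k, x[i - 1]])

    def i_emit(k: int, i: int) -> float:
        return float(profile.isc[k, x[i - 1]])

    # state encodings: ("N",), ("B",), ("M", k), ("I", k), ("D", k),
    # ("E",), ("J",), ("C",)
    def step(state: Tuple, c: int, acc: float) -> None:
        kind = state[0]
        if kind == "N":
            if c < L:
                step(("N",), c + 1, acc + profile.xN_loop)
            step(("B",), c, acc + profile.xN_move)
        elif kind == "B":
            if c < L:
                for k in range(1, M + 1):
                    step(("M", k), c + 1,
                         acc + float(profile.entry[k]) + m_emit(k, c + 1))
        elif kind == "M":
            k = state[1]
            step(("E",), c, acc)  # free local exit from any match state
            if k < M:
                if c < L:
                    step(("M", k + 1), c + 1,
                         acc + float(t["MM"][k]) + m_emit(k + 1, c + 1))
                    step(("I", k), c + 1,
                         acc + float(t["MI"][k]) + i_emit(k, c + 1))
                step(("D", k + 1), c, acc + float(t["MD"][k]))
        elif kind == "I":
            k = state[1]
            if c < L:
                step(("M", k + 1), c + 1,
                     acc + float(t["IM"][k]) + m_emit(k + 1, c + 1))
                step(("I", k), c + 1,
                     acc + float(t["II"][k]) + i_emit(k, c + 1))
        elif kind == "D":
            k = state[1]
            if k < M:
                if c < L:
                    step(("M", k + 1), c + 1,
                         acc + float(t["DM"][k]) + m_emit(k + 1, c + 1))
                step(("D", k + 1), c, acc + float(t["DD"][k]))
            # D_M is a dead end: no exit from delete states.
        elif kind == "E":
            step(("C",), c, acc + profile.xE_C)
            if profile.xE_J > -math.inf:
                step(("J",), c, acc + profile.xE_J)
        elif kind == "J":
            if c < L:
                step(("J",), c + 1, acc + profile.xJ_loop)
            step(("B",), c, acc + profile.xJ_move)
        elif kind == "C":
            if c < L:
                step(("C",), c + 1, acc + profile.xC_loop)
            if c == L:
                out.append(acc + profile.xC_move)

    step(("N",), 0, 0.0)
    return out


def forward_oracle(profile: Profile, seq: DigitalSequence) -> float:
    """log2 sum over all enumerated paths, minus the null length model."""
    ws = enumerate_path_scores(profile, seq)
    if not ws:
        return -math.inf
    m = max(ws)
    total = m + math.log(sum(math.exp(w - m) for w in ws))
    return (total - profile.null_score) / _LN2


def viterbi_oracle(profile: Profile, seq: DigitalSequence) -> float:
    ws = enumerate_path_scores(profile, seq)
    if not ws:
        return -math.inf
    return (max(ws) - profile.null_score) / _LN2


# -- MSV: exhaustive enumeration of ungapped diagonal placements -------

def msv_oracle(profile: Profile, seq: DigitalSequence) -> float:
    """Best multihit placement of non-overlapping ungapped diagonals.

    A diagonal starting at sequence position i (1-based) and node k
    with length ell scores entry[k] plus the sum of match log-odds;
    within-diagonal moves are free.  Residues outside diagonals are
    paid for by N/J/C loop transitions; diagonals are joined by
    E->J->B, preceded by N->B and followed by E->C.
    """
    L = len(seq)
    M = profile.M
    x = seq.residues

    def diag_score(i: int, k: int, ell: int) -> float:
        s = float(profile.entry[k])
        for d in range(ell):
            s += float(profile.msc[k + d, x[i - 1 + d]])
        return s

    diagonals = [
        (i, k, ell)
        for i in range(1, L + 1)
        for k in range(1, M + 1)
        for ell in range(1, min(M - k, L - i) + 2)
    ]

    best = -math.inf

    def extend(start_pos: int, acc: float, n_used: int) -> None:
        nonlocal best
        # Option: no further diagonals; pay C loops for the tail.
        tail = L - start_pos + 1
        total = acc + profile.xE_C + tail * profile.xC_loop + profile.xC_move
        if n_used > 0:
            best = max(best, total)
        for (i, k, ell) in diagonals:
            if i < start_pos:
                continue
            gap = i - start_pos  # residues emitted by N (first) or J
            if n_used == 0:
                pre = gap * profile.xN_loop + profile.xN_move
            else:
                if profile.xE_J == -math.inf:
                    continue
                pre = profile.xE_J + gap * profile.xJ_loop + profile.xJ_move
            extend(i + ell, acc + pre + diag_score(i, k, ell), n_used + 1)

    extend(1, 0.0, 0)
    if L == 0:
        return (profile.xN_move + profile.xC_move - profile.null_score) / _LN2
    return (best - profile.null_score) / _LN2
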