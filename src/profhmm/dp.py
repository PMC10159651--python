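"""Dynamic-programming kernels for Plan7 local alignment.

Three scoring passes over a (profile, digital sequence) pair:

``msv_score``
    The ungapped multi-diagonal filter score: the best multihit
    placement of match-state diagonals, with match-match moves free and
    inserts/deletes forbidden (HMMER's MSV acceleration stage).
``viterbi``
    The maximum-probability path score, with a traceback achieving it.
``forward_score``
    The log-sum over all legal paths.

All recursions run in natural-log space with log-sum-exp (no SIMD
rescaling tricks); bits appear only at the reporting boundary.  Every
score is the log2 likelihood ratio against the background null with its
geometric length model.  No bias-composition filter and no null2
correction are applied: the reported score is the plain log-odds.

Empty sequences score through the N and C flanks only (a local hit must
consume at least one residue); the returned value is finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .model import Profile
from .sequence import DigitalSequence

__all__ = [
    "Path",
    "DomainSegment",
    "forward_score",
    "viterbi",
    "msv_score",
    "path_score",
    "domains_from_path",
]

_LN2 = np.log(2.0)
_NINF = -np.inf


@dataclass(frozen=True)
class Path:
    """A state path: (state, node, consumed) triples from S to T.

    ``node`` is 0 for non-core states; ``consumed`` is the number of
    residues consumed after the step, so M/I steps (and N/J/C loop
    emissions) increase it by one and silent steps leave it unchanged.
    """

    steps: Tuple[Tuple[str, int, int], ...]
    score: float  # nats, relative to background emission (null length model excluded)


@dataclass(frozen=True)
class DomainSegment:
    """One B..E excursion of a path, in 1-based inclusive coordinates."""

    seq_from: int
    seq_to: int
    hmm_from: int
    hmm_to: int
    score_bits: float

    def __post_init__(self) -> None:
        if self.seq_from > self.seq_to or self.hmm_from > self.hmm_to:
            raise ValueError("segment coordinates must be non-decreasing")


def _check_pair(profile: Profile, seq: DigitalSequence) -> None:
    if seq.alphabet is not profile.alphabet and seq.alphabet != profile.alphabet:
        raise ValueError(
            f"sequence {seq.name!r} alphabet does not match the profile's"
        )


def _lse(*arrs: np.ndarray) -> np.ndarray:
    out = arrs[0]
    for a in arrs[1:]:
        out = np.logaddexp(out, a)
    return out


def forward_score(profile: Profile, seq: DigitalSequence) -> float:
    """Forward log-odds score in bits (sum over all paths)."""
    _check_pair(profile, seq)
    L = len(seq)
    if L == 0:
        return float((profile.xN_move + profile.xC_move - profile.null_score) / _LN2)
    M = profile.M
    t = profile.t
    em_m = profile.msc[:, seq.residues]  # (M+1, L)
    em_i = profile.isc[:, seq.residues]

    vM = np.full(M + 1, _NINF)
    vI = np.full(M + 1, _NINF)
    vD = np.full(M + 1, _NINF)
    N = 0.0
    B = profile.xN_move
    J = C = _NINF

    tMM, tMI, tMD = t["MM"], t["MI"], t["MD"]
    tIM, tII = t["IM"], t["II"]
    tDM, tDD = t["DM"], t["DD"]

    for i in range(1, L + 1):
        newM = np.full(M + 1, _NINF)
        newM[1:] = em_m[1:, i - 1] + _lse(
            vM[:-1] + tMM[:-1],
            vI[:-1] + tIM[:-1],
            vD[:-1] + tDM[:-1],
            B + profile.entry[1:],
        )
        newI = np.full(M + 1, _NINF)
        newI[1:] = em_i[1:, i - 1] + np.logaddexp(
            vM[1:] + tMI[1:], vI[1:] + tII[1:]
        )
        newD = np.full(M + 1, _NINF)
        nm = newM.tolist()
        tmd = tMD.tolist()
        tdd = tDD.tolist()
        d_prev = _NINF
        for k in range(2, M + 1):
            a = nm[k - 1] + tmd[k - 1]
            b = d_prev + tdd[k - 1]
            if a < b:
                a, b = b, a
            d_prev = a if b == _NINF else a + math.log1p(math.exp(b - a))
            newD[k] = d_prev
        E = float(_reduce_lse(newM[1:]))
        J = np.logaddexp(J + profile.xJ_loop, E + profile.xE_J)
        C = np.logaddexp(C + profile.xC_loop, E + profile.xE_C)
        N = N + profile.xN_loop
        B = np.logaddexp(N + profile.xN_move, J + profile.xJ_move)
        vM, vI, vD = newM, newI, newD

    total = C + profile.xC_move
    return float((total - profile.null_score) / _LN2)


def _reduce_lse(a: np.ndarray) -> float:
    m = np.max(a)
    if not np.isfinite(m):
        return _NINF
    return float(m + np.log(np.exp(a - m).sum()))


def viterbi(profile: Profile, seq: DigitalSequence) -> Tuple[float, Path]:
    """Best-path log-odds score in bits, with its traceback.

    Ties are broken by a fixed state priority (M over I over D, then
    entry from B; lowest node index at the exit) so tracebacks are
    deterministic.
    """
    _check_pair(profile, seq)
    L = len(seq)
    if L == 0:
        score_nats = profile.xN_move + profile.xC_move
        bits = (score_nats - profile.null_score) / _LN2
        path = Path(steps=(("S", 0, 0), ("N", 0, 0), ("C", 0, 0), ("T", 0, 0)),
                    score=float(score_nats))
        return float(bits), path

    M = profile.M
    t = profile.t
    em_m = profile.msc[:, seq.residues]
    em_i = profile.isc[:, seq.residues]
    tMM, tMI, tMD = t["MM"], t["MI"], t["MD"]
    tIM, tII = t["IM"], t["II"]
    tDM, tDD = t["DM"], t["DD"]

    VM = np.full((L + 1, M + 1), _NINF)
    VI = np.full((L + 1, M + 1), _NINF)
    VD = np.full((L + 1, M + 1), _NINF)
    bM = np.zeros((L + 1, M + 1), dtype=np.int8)
    bI = np.zeros((L + 1, M + 1), dtype=np.int8)
    bD = np.zeros((L + 1, M + 1), dtype=np.int8)
    bE = np.zeros(L + 1, dtype=np.int32)
    bJ = np.zeros(L + 1, dtype=np.int8)
    bC = np.zeros(L + 1, dtype=np.int8)
    bB = np.zeros(L + 1, dtype=np.int8)

    N = np.full(L + 1, _NINF); N[0] = 0.0
    B = np.full(L + 1, _NINF); B[0] = profile.xN_move
    E = np.full(L + 1, _NINF)
    J = np.full(L + 1, _NINF)
    C = np.full(L + 1, _NINF)

    for i in range(1, L + 1):
        # Candidates stacked in priority order: M, I, D, B (first max wins).
        cand = np.stack([
            VM[i - 1, :-1] + tMM[:-1],
            VI[i - 1, :-1] + tIM[:-1],
            VD[i - 1, :-1] + tDM[:-1],
            B[i - 1] + profile.entry[1:],
        ])
        choice = np.argmax(cand, axis=0)
        VM[i, 1:] = em_m[1:, i - 1] + np.max(cand, axis=0)
        bM[i, 1:] = choice

        candI = np.stack([VM[i - 1, 1:] + tMI[1:], VI[i - 1, 1:] + tII[1:]])
        bI[i, 1:] = np.argmax(candI, axis=0)
        VI[i, 1:] = em_i[1:, i - 1] + np.max(candI, axis=0)

        vmi = VM[i].tolist()
        tmd = tMD.tolist()
        tdd = tDD.tolist()
        d_prev = _NINF
        for k in range(2, M + 1):
            a = vmi[k - 1] + tmd[k - 1]
            b = d_prev + tdd[k - 1]
            if a >= b:
                d_prev = a
                bD[i, k] = 0
            else:
                d_prev = b
                bD[i, k] = 1
            VD[i, k] = d_prev

        kbest = int(np.argmax(VM[i, 1:])) + 1
        E[i] = VM[i, kbest]
        bE[i] = kbest

        je = E[i] + profile.xE_J
        jl = J[i - 1] + profile.xJ_loop
        J[i], bJ[i] = (je, 0) if je >= jl else (jl, 1)
        ce = E[i] + profile.xE_C
        cl = C[i - 1] + profile.xC_loop
        C[i], bC[i] = (ce, 0) if ce >= cl else (cl, 1)
        N[i] = N[i - 1] + profile.xN_loop
        bn = N[i] + profile.xN_move
        bj = J[i] + profile.xJ_move
        B[i], bB[i] = (bn, 0) if bn >= bj else (bj, 1)

    total = C[L] + profile.xC_move
    bits = float((total - profile.null_score) / _LN2)
    if not np.isfinite(total):
        return bits, Path(steps=(), score=float(total))

    # -- traceback -----------------------------------------------------
    rev: List[Tuple[str, int, int]] = [("T", 0, L)]
    state, node, i = "C", 0, L
    while True:
        rev.append((state, node, i))
        if state == "C":
            if bC[i] == 0:
                state = "E"
            else:
                i -= 1  # this C visit consumed residue i
        elif state == "E":
            state, node = "M", int(bE[i])
        elif state == "M":
            code = bM[i, node]
            if code == 0:
                state, node, i = "M", node - 1, i - 1
            elif code == 1:
                state, node, i = "I", node - 1, i - 1
            elif code == 2:
                state, node, i = "D", node - 1, i - 1
            else:
                state, node, i = "B", 0, i - 1
        elif state == "I":
            state = "M" if bI[i, node] == 0 else "I"
            i -= 1
        elif state == "D":
            state = "M" if bD[i, node] == 0 else "D"
            node -= 1
        elif state == "B":
            state = "N" if bB[i] == 0 else "J"
        elif state == "J":
            if bJ[i] == 0:
                state = "E"
            else:
                i -= 1
        elif state == "N":
            if i == 0:
                rev.append(("S", 0, 0))
                break
            i -= 1
    steps = tuple(reversed(rev))
    return bits, Path(steps=steps, score=float(total))


def msv_score(profile: Profile, seq: DigitalSequence) -> float:
    """Ungapped multi-diagonal filter score in bits."""
    _check_pair(profile, seq)
    L = len(seq)
    if L == 0:
        return float((profile.xN_move + profile.xC_move - profile.null_score) / _LN2)
    M = profile.M
    em_m = profile.msc[:, seq.residues]

    vM = np.full(M + 1, _NINF)
    N = 0.0
    B = profile.xN_move
    J = C = _NINF
    for i in range(1, L + 1):
        newM = np.full(M + 1, _NINF)
        # Within-diagonal moves are free; entry from B as configured.
        newM[1:] = em_m[1:, i - 1] + np.maximum(vM[:-1], B + profile.entry[1:])
        E = float(np.max(newM[1:]))
        J = max(J + profile.xJ_loop, E + profile.xE_J)
        C = max(C + profile.xC_loop, E + profile.xE_C)
        N = N + profile.xN_loop
        B = max(N + profile.xN_move, J + profile.xJ_move)
        vM = newM
    total = C + profile.xC_move
    return float((total - profile.null_score) / _LN2)


# -- path utilities ----------------------------------------------------

def _transition_score(profile: Profile, s1: str, n1: int, s2: str, n2: int) -> float:
    t = profile.t
    key = (s1, s2)
    if key == ("S", "N"):
        return 0.0
    if key == ("N", "N"):
        return profile.xN_loop
    if key == ("N", "B"):
        return profile.xN_move
    if key == ("B", "M"):
        return float(profile.entry[n2])
    if key == ("M", "M"):
        return float(t["MM"][n1])
    if key == ("M", "I"):
        return float(t["MI"][n1])
    if key == ("M", "D"):
        return float(t["MD"][n1])
    if key == ("I", "M"):
        return float(t["IM"][n1])
    if key == ("I", "I"):
        return float(t["II"][n1])
    if key == ("D", "M"):
        return float(t["DM"][n1])
    if key == ("D", "D"):
        return float(t["DD"][n1])
    if key == ("M", "E"):
        return 0.0  # free local exit
    if key == ("E", "J"):
        return profile.xE_J
    if key == ("E", "C"):
        return profile.xE_C
    if key == ("J", "J"):
        return profile.xJ_loop
    if key == ("J", "B"):
        return profile.xJ_move
    if key == ("C", "C"):
        return profile.xC_loop
    if key == ("C", "T"):
        return profile.xC_move
    raise ValueError(f"illegal transition {s1}->{s2}")


def path_score(profile: Profile, seq: DigitalSequence, path: Path) -> float:
    """Re-score a path independently of the DP; returns bits."""
    total = 0.0
    steps = path.steps
    for (s1, n1, c1), (s2, n2, c2) in zip(steps, steps[1:]):
        total += _transition_score(profile, s1, n1, s2, n2)
        if s2 == "M" and c2 == c1 + 1:
            total += float(profile.msc[n2, seq.residues[c2 - 1]])
        elif s2 == "I" and c2 == c1 + 1:
            total += float(profile.isc[n2, seq.residues[c2 - 1]])
        # N/J/C loop emissions score 0 against the background.
    return float((total - profile.null_score) / _LN2)


def domains_from_path(profile: Profile, seq: DigitalSequence, path: Path) -> List[DomainSegment]:
    """Extract one scored segment per B..E excursion of a path."""
    segments: List[DomainSegment] = []
    steps = path.steps
    in_excursion = False
    acc = 0.0
    seq_from = hmm_from = hmm_to = seq_to = 0
    for (s1, n1, c1), (s2, n2, c2) in zip(steps, steps[1:]):
        if s1 == "B":
            in_excursion = True
            acc = 0.0
            seq_from = c2
            hmm_from = n2
        if in_excursion:
            acc += _transition_score(profile, s1, n1, s2, n2)
            if s2 == "M" and c2 == c1 + 1:
                acc += float(profile.msc[n2, seq.residues[c2 - 1]])
            elif s2 == "I" and c2 == c1 + 1:
                acc += float(profile.isc[n2, seq.residues[c2 - 1]])
            if s2 == "M":
                hmm_to = n2
                seq_to = c2
            if s2 == "E":
                in_excursion = False
                segments.append(DomainSegment(
                    seq_from=seq_from, seq_to=seq_to,
                    hmm_from=hmm_from, hmm_to=hmm_to,
                    score_bits=float(acc / _LN2),
                ))
    return segments
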