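"""Building profile HMMs from alignments and from single sequences.

The build rule set is the classical one: columns whose gap fraction is
below a threshold become consensus (match) columns; weighted residue
counts plus background pseudocounts give the match emissions; per-row
state paths through the match-column mask give the transition counts.
Insert emissions are fixed to the background.  Sequence weighting is
uniform by default with Henikoff position-based weighting opt-in.

Effective-sequence-number (entropy) weighting is not implemented; the
recorded ``effn`` equals ``nseq``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import IO, Dict, List, Optional, Sequence, Union

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import Alphabet, AlphabetError
from .model import HMM, Background
from .sequence import DigitalSequence, FastaFormatError

__all__ = [
    "MSA",
    "BuildOptions",
    "read_msa",
    "write_msa",
    "mark_columns",
    "sequence_weights",
    "build_from_msa",
    "single_seq_profile",
    "BLOSUM62",
]

Source = Union[str, PathLike, IO[str]]

GAP = "-"


@dataclass
class MSA:
    """An alignment: equal-length rows over residues and ``-`` gaps."""

    names: List[str]
    rows: List[str]
    alphabet: Alphabet = field(default_factory=Alphabet.amino)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one sequence")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("alignment rows must have equal length")
        if len(self.names) != len(self.rows):
            raise ValueError("one name per row required")

    @property
    def nseq(self) -> int:
        return len(self.rows)

    @property
    def ncol(self) -> int:
        return len(self.rows[0])


@dataclass
class BuildOptions:
    gap_threshold: float = 0.5
    pseudocount_weight: float = 0.1
    weighting_scheme: str = "uniform"
    calibrate: bool = False
    calibration_n: int = 200
    calibration_L: int = 100
    calibration_seed: int = 42

    def __post_init__(self) -> None:
        if not (0.0 < self.gap_threshold <= 1.0):
            raise ValueError("gap_threshold must lie in (0, 1]")
        if self.pseudocount_weight < 0:
            raise ValueError("pseudocount_weight must be >= 0")
        if self.weighting_scheme not in ("uniform", "position-based"):
            raise ValueError(f"unknown weighting scheme {self.weighting_scheme!r}")


def read_msa(source: Source, alphabet: Optional[Alphabet] = None) -> MSA:
    """Read an aligned-FASTA alignment ('-' gaps; '.' normalized to '-')."""
    abc = alphabet or Alphabet.amino()
    own = not hasattr(source, "read")
    handle = open(source, "r") if own else source
    try:
        names, rows = [], []
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            names.append(parts[0] if parts else "")
            row = seq.upper().replace(".", GAP)
            for ch in row:
                if ch != GAP and ch.upper() not in "".join(
                    [abc.symbols, *abc.degeneracy_map]
                ):
                    raise FastaFormatError(
                        f"record {names[-1]!r}: illegal alignment character {ch!r}"
                    )
            rows.append(row)
        if not rows:
            raise FastaFormatError("no alignment records found")
        return MSA(names=names, rows=rows, alphabet=abc)
    finally:
        if own:
            handle.close()


def write_msa(msa: MSA, sink: Source) -> int:
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    try:
        for name, row in zip(msa.names, msa.rows):
            handle.write(f">{name}\n{row}\n")
    finally:
        if own:
            handle.close()
    return msa.nseq


def mark_columns(msa: MSA, gap_threshold: float = 0.5) -> np.ndarray:
    """Boolean mask over columns: True where the gap fraction is
    strictly below the threshold (consensus/match columns)."""
    mask = np.empty(msa.ncol, dtype=bool)
    for c in range(msa.ncol):
        gaps = sum(1 for r in msa.rows if r[c] == GAP)
        mask[c] = (gaps / msa.nseq) < gap_threshold
    return mask


def sequence_weights(msa: MSA, scheme: str = "uniform") -> np.ndarray:
    """Row weights normalized to unit mean (they sum to nseq).

    Position-based weighting follows Henikoff & Henikoff: in each
    column a row earns ``1 / (r * c)`` where ``r`` is the number of
    distinct symbols in the column and ``c`` the count of the row's own
    symbol; gaps count as a symbol type.
    """
    n = msa.nseq
    if scheme == "uniform":
        return np.ones(n)
    if scheme != "position-based":
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    w = np.zeros(n)
    for c in range(msa.ncol):
        col = [row[c] for row in msa.rows]
        counts: Dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for i, ch in enumerate(col):
            w[i] += 1.0 / (r * counts[ch])
    total = w.sum()
    if total == 0:
        return np.ones(n)
    return w * (n / total)


def _count_residue(vec: np.ndarray, ch: str, weight: float,
                   abc: Alphabet, bg: np.ndarray) -> None:
    """Add a weighted observation, splitting ambiguity codes over their
    canonical members proportionally to the background."""
    code = abc.encode_char(ch)
    members = abc.degenerate_members(code)
    if len(members) == 1:
        vec[members[0]] += weight
    else:
        f = bg[list(members)]
        vec[list(members)] += weight * f / f.sum()


# Transition-group fallbacks when a node collects no counts and no
# pseudocounts: keep the path on the consensus line.
_FALLBACK = {"M": (1.0, 0.0, 0.0), "I": (1.0, 0.0), "D": (1.0, 0.0)}
_PRIOR = {"M": (1 / 3, 1 / 3, 1 / 3), "I": (0.5, 0.5), "D": (0.5, 0.5)}


def build_from_msa(msa: MSA, background: Optional[Background] = None,
                   options: Optional[BuildOptions] = None) -> HMM:
    """Estimate a Plan7 model from an alignment.

    Raises if the column mask leaves no match column.
    """
    opts = options or BuildOptions()
    bg = background or Background.amino()
    abc = msa.alphabet
    K = abc.size

    mask = mark_columns(msa, opts.gap_threshold)
    match_cols = [c for c in range(msa.ncol) if mask[c]]
    M = len(match_cols)
    if M == 0:
        raise ValueError("no match columns under the gap threshold")
    node_of_col = {c: k + 1 for k, c in enumerate(match_cols)}

    weights = sequence_weights(msa, opts.weighting_scheme)
    pc = opts.pseudocount_weight

    em_counts = np.zeros((M, K))
    tr_counts = {name: np.zeros(M + 1) for name in
                 ("MM", "MI", "MD", "IM", "II", "DM", "DD")}

    for row, w in zip(msa.rows, weights):
        # Emission counts.
        for c in match_cols:
            if row[c] != GAP:
                _count_residue(em_counts[node_of_col[c] - 1], row[c], w, abc, bg.frequencies)
        # State path: M_k / D_k at match columns, I_k at insert columns.
        path: List[tuple] = []
        k = 0
        for c in range(msa.ncol):
            if mask[c]:
                k += 1
                path.append(("M" if row[c] != GAP else "D", k))
            elif row[c] != GAP:
                path.append(("I", k))
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if k1 == 0 or k1 >= M:
                continue  # inserts before node 1 / after node M-1 exits
            if s1 == "M" and s2 == "M":
                tr_counts["MM"][k1] += w
            elif s1 == "M" and s2 == "I":
                tr_counts["MI"][k1] += w
            elif s1 == "M" and s2 == "D":
                tr_counts["MD"][k1] += w
            elif s1 == "I" and s2 == "M":
                tr_counts["IM"][k1] += w
            elif s1 == "I" and s2 == "I":
                tr_counts["II"][k1] += w
            elif s1 == "D" and s2 == "M":
                tr_counts["DM"][k1] += w
            elif s1 == "D" and s2 == "D":
                tr_counts["DD"][k1] += w

    match_em = em_counts + pc * bg.frequencies[None, :]
    sums = match_em.sum(axis=1, keepdims=True)
    zero = (sums[:, 0] == 0)
    match_em[zero] = bg.frequencies
    sums[zero] = 1.0
    match_em = match_em / match_em.sum(axis=1, keepdims=True)

    trans = np.zeros((M, 7))
    for k in range(1, M):
        for gi, (group, names) in enumerate(
            (("M", ("MM", "MI", "MD")), ("I", ("IM", "II")), ("D", ("DM", "DD")))
        ):
            counts = np.array([tr_counts[nm][k] for nm in names])
            prior = np.array(_PRIOR[group])
            total = counts.sum() + pc
            if total == 0:
                probs = np.array(_FALLBACK[group])
            else:
                probs = (counts + pc * prior) / total
            off = (0, 3, 5)[gi]
            trans[k - 1, off : off + len(probs)] = probs
    trans[M - 1] = (1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0)

    cons = "".join(abc.symbols[int(i)] for i in match_em.argmax(axis=1))
    hmm = HMM(
        name="aligned-family",
        match_emissions=match_em,
        insert_emissions=np.tile(bg.frequencies, (M, 1)),
        transitions=trans,
        alphabet=abc,
        nseq=msa.nseq,
        effn=float(msa.nseq),
        cons=cons,
        map_=tuple(c + 1 for c in match_cols),
    )
    hmm.validate()
    if opts.calibrate:
        from .stats import calibrate
        calibrate(hmm, bg, n=opts.calibration_n, L=opts.calibration_L,
                  seed=opts.calibration_seed)
    return hmm


# --------------------------------------------------------------------
# Single-sequence profiles (phmmer support)

# NCBI BLOSUM62 in half-bit units, row/column order ARNDCQEGHILKMFPSTWYV.
_BLOSUM62_ORDER = "ARNDCQEGHILKMFPSTWYV"
_BLOSUM62_TEXT = """
 4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0
-1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3
-2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3
-2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3
 0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1
-1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2
-1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2
 0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3
-2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3
-1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3
-1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1
-1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2
-1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1
-2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1
-1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2
 1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2
 0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0
-3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3
-2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1
 0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4
"""


def _blosum62(alphabet: Alphabet) -> np.ndarray:
    raw = np.array([[float(v) for v in line.split()]
                    for line in _BLOSUM62_TEXT.strip().splitlines()])
    idx = [_BLOSUM62_ORDER.index(s) for s in alphabet.symbols]
    return raw[np.ix_(idx, idx)]


BLOSUM62 = _blosum62(Alphabet.amino())

# Single-sequence gap costs (open 0.02, extend 0.4), the conventional
# phmmer-style parameterization.
_SINGLE_POPEN = 0.02
_SINGLE_PEXTEND = 0.4


def single_seq_profile(seq: DigitalSequence, matrix: Optional[np.ndarray] = None,
                       background: Optional[Background] = None) -> HMM:
    """A one-node-per-residue query model from a substitution matrix.

    Node ``k`` emits with the conditional distribution implied by the
    matrix row of residue ``k``: ``P(b|a) ∝ f_b * 2^(S_ab / 2)`` for a
    half-bit matrix (BLOSUM62 by default).
    """
    if len(seq) == 0:
        raise ValueError("query sequence is empty")
    abc = seq.alphabet
    bg = background or Background.amino()
    S = BLOSUM62 if matrix is None else np.asarray(matrix, dtype=float)
    if S.shape != (abc.size, abc.size):
        raise ValueError("substitution matrix must be K x K")

    M = len(seq)
    match_em = np.empty((M, abc.size))
    for k, code in enumerate(seq.residues):
        members = abc.degenerate_members(int(code))
        if int(code) >= abc.size and len(members) == abc.size:
            # X: no usable matrix row; emit the background.
            match_em[k] = bg.frequencies
            continue
        f = bg.frequencies[list(members)]
        row = (S[list(members)] * (f / f.sum())[:, None]).sum(axis=0)
        cond = bg.frequencies * np.power(2.0, row / 2.0)
        match_em[k] = cond / cond.sum()

    trans = np.tile(
        (1.0 - 2 * _SINGLE_POPEN, _SINGLE_POPEN, _SINGLE_POPEN,
         1.0 - _SINGLE_PEXTEND, _SINGLE_PEXTEND,
         1.0 - _SINGLE_PEXTEND, _SINGLE_PEXTEND),
        (M, 1),
    )
    trans[M - 1] = (1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0)
    hmm = HMM(
        name=seq.name or "query",
        description=seq.description,
        match_emissions=match_em,
        insert_emissions=np.tile(bg.frequencies, (M, 1)),
        transitions=trans,
        alphabet=abc,
        nseq=1,
        effn=1.0,
        cons=seq.decode(),
    )
    hmm.validate()
    return hmm
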