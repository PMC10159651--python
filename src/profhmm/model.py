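"""The Plan7 core model and its search-configured profile.

An :class:`HMM` stores per-node match/insert emission distributions and
the seven per-node transition probabilities in probability space, which
keeps the model mutable and inspectable and mirrors what the HMMER3
ASCII format stores.  A :class:`Profile` is the immutable, log-odds view
of an HMM configured for local search against a target of length *L*:

* local entry ``B -> M_k`` is uniform, probability ``1/M`` per node;
* local exit ``M_k -> E`` is free (score 0) from every node — the
  standard implicit-model convention for local alignment;
* the flanking states N, C and J emit background residues with a
  geometric length model, loop probability ``L/(L+3)``;
* multihit mode sets ``E -> J = 0.5``; unihit mode sets it to 0 and
  leaves ``E -> C`` at 0.5 unchanged, so the unihit path ensemble is an
  equal-weight subset of the multihit ensemble (this makes the multihit
  Forward score provably >= the unihit score on every sequence).

The null model is i.i.d. background emission with a geometric length
distribution of parameter ``p1 = L/(L+1)``.  Scores are computed in nats
internally and reported in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .alphabet import Alphabet

__all__ = [
    "AMINO_BACKGROUND",
    "Background",
    "EvalueParams",
    "HMM",
    "ModelError",
    "Profile",
    "TRANSITION_NAMES",
    "configure",
    "set_cutoffs",
    "clear_cutoffs",
]

#: Order of the seven per-node transitions, matching the HMMER3 file
#: column order.
TRANSITION_NAMES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")

# Background amino-acid frequencies (Swiss-Prot derived, the set HMMER
# uses for its null model), in alphabet order ACDEFGHIKLMNPQRSTVWY.
AMINO_BACKGROUND = np.array(
    [
        0.0787945, 0.0151600, 0.0535222, 0.0668298, 0.0397062,
        0.0695071, 0.0229198, 0.0590092, 0.0594422, 0.0963728,
        0.0237718, 0.0414386, 0.0482904, 0.0395639, 0.0557789,
        0.0714640, 0.0568742, 0.0652012, 0.0108695, 0.0303542,
    ]
)


class ModelError(ValueError):
    """Raised when a model violates its invariants."""


@dataclass
class Background:
    """Null model: residue frequencies plus geometric length parameter."""

    frequencies: np.ndarray
    p1: float = 350.0 / 351.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        total = float(self.frequencies.sum())
        if abs(total - 1.0) > 1e-6:
            raise ModelError(f"background frequencies sum to {total}, not 1")
        if not (0.0 < self.p1 < 1.0):
            raise ModelError("length parameter p1 must lie in (0, 1)")

    @classmethod
    def amino(cls) -> "Background":
        return cls(AMINO_BACKGROUND / AMINO_BACKGROUND.sum())


@dataclass
class EvalueParams:
    """Null score distribution parameters stored with a calibrated HMM.

    MSV and Viterbi null scores follow a Gumbel law with location ``mu``
    and scale ``lambda``; the Forward null score tail is approximated by
    an exponential with location ``tau``.  All scores are in bits.
    """

    msv_mu: float
    msv_lambda: float
    vit_mu: float
    vit_lambda: float
    fwd_tau: float
    fwd_lambda: float

    def __post_init__(self) -> None:
        for lam in (self.msv_lambda, self.vit_lambda, self.fwd_lambda):
            if not lam > 0:
                raise ModelError("Gumbel/exponential lambda must be positive")


@dataclass
class HMM:
    """A Plan7 core model in probability space.

    ``match_emissions`` and ``insert_emissions`` have shape (M, K) with
    row ``k-1`` describing node ``k``; ``transitions`` has shape (M, 7)
    in :data:`TRANSITION_NAMES` order.  The last node's outgoing match
    transition plays the role of the exit (``MD`` and ``DD`` are 0 and
    ``DM`` is 1 there, the file-dialect convention).
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    alphabet: Alphabet = field(default_factory=Alphabet.amino)
    accession: str = ""
    description: str = ""
    compo: Optional[np.ndarray] = None
    cutoffs: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    stats: Optional[EvalueParams] = None
    nseq: Optional[int] = None
    effn: Optional[float] = None
    checksum: Optional[int] = None
    # Optional per-node annotation columns, stored verbatim for file
    # round-trips: consensus residue, reference/mask/structure marks,
    # and alignment-column map.
    cons: Optional[str] = None
    rf: Optional[str] = None
    mm: Optional[str] = None
    cs: Optional[str] = None
    map_: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)

    @property
    def M(self) -> int:
        return int(self.match_emissions.shape[0])

    def validate(self, tol: float = 1e-6) -> None:
        """Check all model invariants; raises :class:`ModelError`."""
        M, K = self.match_emissions.shape
        if M < 1:
            raise ModelError("model must have at least one node")
        if K != self.alphabet.size:
            raise ModelError("emission width does not match alphabet size")
        if self.insert_emissions.shape != (M, K):
            raise ModelError("insert emission shape mismatch")
        if self.transitions.shape != (M, 7):
            raise ModelError("transition table must be M x 7")
        for label, rows in (
            ("match emission", self.match_emissions),
            ("insert emission", self.insert_emissions),
        ):
            bad = np.abs(rows.sum(axis=1) - 1.0) > tol
            if bad.any():
                raise ModelError(
                    f"{label} row {int(np.nonzero(bad)[0][0]) + 1} does not sum to 1"
                )
        groups = {"M": slice(0, 3), "I": slice(3, 5), "D": slice(5, 7)}
        for label, sl in groups.items():
            sums = self.transitions[:, sl].sum(axis=1)
            bad = np.abs(sums - 1.0) > tol
            if bad.any():
                raise ModelError(
                    f"{label}-state transitions at node "
                    f"{int(np.nonzero(bad)[0][0]) + 1} do not sum to 1"
                )
        if (self.match_emissions < -tol).any() or (self.transitions < -tol).any():
            raise ModelError("probabilities must be non-negative")


def set_cutoffs(hmm: HMM, kind: str, seq_bits: float, dom_bits: float) -> HMM:
    """Attach a GA/TC/NC bit-score cutoff pair to a model (in place).

    HMMER convention has the domain cutoff <= the sequence cutoff; a
    violation triggers a warning, not a rejection.
    """
    kind = kind.upper()
    if kind not in ("GA", "TC", "NC"):
        raise ModelError(f"unknown cutoff kind {kind!r}")
    if not (np.isfinite(seq_bits) and np.isfinite(dom_bits)):
        raise ModelError("cutoff values must be finite")
    if dom_bits > seq_bits:
        warnings.warn(
            f"{kind} domain cutoff {dom_bits} exceeds sequence cutoff {seq_bits}",
            stacklevel=2,
        )
    hmm.cutoffs[kind] = (float(seq_bits), float(dom_bits))
    return hmm


def clear_cutoffs(hmm: HMM, kind: str) -> HMM:
    hmm.cutoffs.pop(kind.upper(), None)
    return hmm


_NINF = -np.inf


def _safe_log(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(p > 0, np.log(np.maximum(p, 1e-300)), _NINF)


@dataclass(frozen=True)
class Profile:
    """Log-odds score tables (nats) for local search at target length L.

    Emission rows are indexed by node (row 0 unused); columns cover the
    canonical codes plus ambiguity codes, scored as background-weighted
    mixtures of the canonical odds ratios.  Configuration is a pure
    function of (HMM, background, mode, L).
    """

    hmm: HMM
    background: Background
    mode: str
    L: int
    M: int
    msc: np.ndarray          # (M+1, n_codes) match log-odds
    isc: np.ndarray          # (M+1, n_codes) insert log-odds
    t: Dict[str, np.ndarray]  # each (M+1,), index = source node
    entry: np.ndarray        # (M+1,) ln B->M_k
    xN_loop: float
    xN_move: float
    xJ_loop: float
    xJ_move: float
    xC_loop: float
    xC_move: float
    xE_J: float
    xE_C: float
    null_score: float        # ln of the length-model factor at L

    @property
    def alphabet(self) -> Alphabet:
        return self.hmm.alphabet

    @property
    def multihit(self) -> bool:
        return self.mode == "multihit"

    def with_length(self, L: int) -> "Profile":
        """Re-parameterize the length model only (emissions unchanged)."""
        if L == self.L:
            return self
        x = _length_params(L)
        return replace(self, L=L, **x)


def _length_params(L: int) -> Dict[str, float]:
    if L < 0:
        raise ModelError("target length must be non-negative")
    loop = np.log(L / (L + 3.0)) if L > 0 else _NINF
    move = np.log(3.0 / (L + 3.0))
    if L > 0:
        p1 = L / (L + 1.0)
        null = L * np.log(p1) + np.log(1.0 - p1)
    else:
        null = 0.0
    return dict(
        xN_loop=loop, xN_move=move,
        xJ_loop=loop, xJ_move=move,
        xC_loop=loop, xC_move=move,
        null_score=null,
    )


def _degenerate_columns(scores: np.ndarray, alphabet: Alphabet, bg: np.ndarray) -> np.ndarray:
    """Extend per-node canonical log-odds with ambiguity-code columns.

    The score of a degenerate residue is the log of the background-
    weighted average odds ratio over its canonical set, which keeps
    p-values conservative for X-rich sequences.
    """
    M1, K = scores.shape
    out = np.full((M1, alphabet.n_codes), _NINF)
    out[:, :K] = scores
    for code in range(K, alphabet.n_codes):
        members = list(alphabet.degenerate_members(code))
        w = bg[members]
        with np.errstate(over="ignore"):
            odds = np.exp(scores[:, members])
        out[:, code] = _safe_log((odds * w).sum(axis=1) / w.sum())
    return out


def configure(hmm: HMM, background: Background | None = None,
              mode: str = "multihit", L: int = 100) -> Profile:
    """Build the local-search profile of *hmm* for target length *L*."""
    if mode not in ("multihit", "unihit"):
        raise ModelError(f"unknown search mode {mode!r}")
    if L < 1:
        raise ModelError("configured length must be >= 1")
    # Tolerance admits models recovered from 5-decimal file storage.
    hmm.validate(tol=1e-4)
    bg = background or Background.amino()
    M = hmm.M
    f = bg.frequencies

    with np.errstate(divide="ignore", invalid="ignore"):
        m_odds = _safe_log(hmm.match_emissions) - np.log(f)[None, :]
        i_odds = _safe_log(hmm.insert_emissions) - np.log(f)[None, :]
    pad = np.full((1, hmm.alphabet.size), _NINF)
    msc = _degenerate_columns(np.vstack([pad, m_odds]), hmm.alphabet, f)
    isc = _degenerate_columns(np.vstack([pad, i_odds]), hmm.alphabet, f)

    t: Dict[str, np.ndarray] = {}
    logt = _safe_log(hmm.transitions)
    for j, name in enumerate(TRANSITION_NAMES):
        col = np.full(M + 1, _NINF)
        col[1:] = logt[:, j]
        # The last node has no outgoing core transitions; its stored row
        # encodes the exit convention and is not used by the DP.
        col[M] = _NINF
        t[name] = col

    entry = np.full(M + 1, _NINF)
    entry[1:] = -np.log(M)

    xe_j = np.log(0.5) if mode == "multihit" else _NINF
    params = _length_params(L)
    return Profile(
        hmm=hmm, background=bg, mode=mode, L=L, M=M,
        msc=msc, isc=isc, t=t, entry=entry,
        xE_J=xe_j, xE_C=np.log(0.5),
        **params,
    )
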