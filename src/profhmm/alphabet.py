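"""Biological alphabets and digital residue encoding.

Residues are stored as small integers ("digital" sequences) so that all
scoring code can index emission tables directly.  Canonical residues get
codes ``0 .. size-1`` in the order of :attr:`Alphabet.symbols`; ambiguity
characters get reserved codes past the canonical range and are scored as
background-weighted mixtures of their canonical sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

__all__ = ["Alphabet", "AlphabetError"]


class AlphabetError(ValueError):
    """Raised when a character cannot be encoded under an alphabet."""


# Amino symbol order is fixed to the one-letter codes in alphabetical
# order, which is also the column order of HMMER3 profile files.
_AMINO_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"

# Ambiguity characters accepted in unaligned protein sequence input.
# U (selenocysteine) and O (pyrrolysine) are folded onto their closest
# canonical residue; X means "any residue".
_AMINO_DEGENERACY: Dict[str, str] = {
    "B": "DN",
    "J": "IL",
    "O": "K",
    "U": "C",
    "X": _AMINO_SYMBOLS,
    "Z": "EQ",
}


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with ambiguity-code support.

    Parameters
    ----------
    symbols:
        Canonical residue characters, in encoding order.
    degeneracy_map:
        Mapping from ambiguity character to the non-empty string of
        canonical symbols it may stand for.
    """

    symbols: str
    degeneracy_map: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        for ch, members in self.degeneracy_map.items():
            if not members or any(m not in self.symbols for m in members):
                raise ValueError(
                    f"degeneracy code {ch!r} must map to a non-empty "
                    "subset of the canonical symbols"
                )
        # Degenerate codes are assigned after the canonical range, in
        # sorted order so the encoding is reproducible.
        code_of = {s: i for i, s in enumerate(self.symbols)}
        for i, ch in enumerate(sorted(self.degeneracy_map)):
            code_of[ch] = len(self.symbols) + i
        object.__setattr__(self, "_code_of", code_of)
        object.__setattr__(
            self, "_symbol_of", {c: s for s, c in code_of.items()}
        )

    # -- basic queries -------------------------------------------------

    @property
    def size(self) -> int:
        """Number of canonical symbols (20 for amino acids)."""
        return len(self.symbols)

    @property
    def n_codes(self) -> int:
        """Total number of valid codes, canonical plus degenerate."""
        return len(self.symbols) + len(self.degeneracy_map)

    def encode_char(self, ch: str) -> int:
        code = self._code_of.get(ch.upper())
        if code is None:
            raise AlphabetError(f"unknown residue character {ch!r}")
        return code

    def decode_code(self, code: int) -> str:
        try:
            return self._symbol_of[code]
        except KeyError:
            raise AlphabetError(f"invalid residue code {code}") from None

    def degenerate_members(self, code: int) -> Tuple[int, ...]:
        """Canonical codes an encoded residue may stand for."""
        sym = self.decode_code(code)
        if code < self.size:
            return (code,)
        return tuple(self._code_of[m] for m in self.degeneracy_map[sym])

    @classmethod
    def amino(cls) -> "Alphabet":
        """The standard 20-letter protein alphabet."""
        return cls(_AMINO_SYMBOLS, dict(_AMINO_DEGENERACY))
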