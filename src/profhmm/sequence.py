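"""Digital sequences and FASTA streaming I/O.

All user-facing coordinates are 1-based inclusive (the HMMER report
convention); internal arrays are 0-based.  Unaligned sequence input must
not contain ``*`` or ``-`` — gaps belong to alignments, which are read
by :mod:`profhmm.build`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from os import PathLike
from typing import IO, Iterable, Iterator, List, Union

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import Alphabet, AlphabetError

__all__ = [
    "DigitalSequence",
    "FastaFormatError",
    "FastaReader",
    "digitize",
    "read_fasta",
    "write_fasta",
]

Source = Union[str, PathLike, IO[str]]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass
class DigitalSequence:
    """A named sequence with residues encoded as alphabet codes."""

    name: str
    residues: np.ndarray
    alphabet: Alphabet
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=np.int16)
        if self.residues.ndim != 1:
            raise ValueError("residues must be one-dimensional")
        if self.residues.size and (
            self.residues.min() < 0 or self.residues.max() >= self.alphabet.n_codes
        ):
            raise ValueError("residue codes out of range for the alphabet")

    def __len__(self) -> int:
        return int(self.residues.shape[0])

    def decode(self) -> str:
        """Textual residues (uppercase canonical/ambiguity characters)."""
        return "".join(self.alphabet.decode_code(int(c)) for c in self.residues)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DigitalSequence):
            return NotImplemented
        return (
            self.name == other.name
            and self.description == other.description
            and np.array_equal(self.residues, other.residues)
        )


def digitize(text: str, alphabet: Alphabet, name: str = "", description: str = "") -> DigitalSequence:
    """Encode a residue string under *alphabet* (case-insensitive).

    Raises
    ------
    AlphabetError
        If a character is neither canonical nor a known ambiguity code;
        the message names the character and its 1-based position.
    """
    if not text:
        raise ValueError("cannot digitize an empty sequence")
    codes = np.empty(len(text), dtype=np.int16)
    for i, ch in enumerate(text):
        try:
            codes[i] = alphabet.encode_char(ch)
        except AlphabetError:
            raise AlphabetError(
                f"unknown residue character {ch!r} at position {i + 1}"
            ) from None
    return DigitalSequence(name=name, residues=codes, alphabet=alphabet, description=description)


class FastaReader:
    """Iterate digital sequences from a FASTA source.

    Supports the context-manager and iterator protocols; closing is
    deterministic (files opened here are closed on exit or exhaustion).
    """

    def __init__(self, source: Source, alphabet: Alphabet) -> None:
        self.alphabet = alphabet
        if hasattr(source, "read"):
            self._handle: IO[str] = source  # caller-owned stream
            self._owns = False
            self._name = getattr(source, "name", "<stream>")
        else:
            self._handle = open(source, "r")
            self._owns = True
            self._name = str(source)
        self._iter = self._records()

    def _records(self) -> Iterator[DigitalSequence]:
        # Reject non-FASTA leading bytes before delegating: the stock
        # parser silently skips garbage ahead of the first '>'.
        pos = self._handle.tell() if self._handle.seekable() else None
        head = self._handle.read(1)
        while head in ("\n", "\r", " ", "\t"):
            head = self._handle.read(1)
        if head == "":
            return
        if head != ">":
            raise FastaFormatError(
                f"{self._name}: not FASTA input (expected '>' , found {head!r})"
            )
        if pos is not None:
            self._handle.seek(pos)
            stream = self._handle
        else:  # non-seekable stream: re-prepend the consumed byte
            stream = io.StringIO(">" + self._handle.read())
        for title, seq in SimpleFastaParser(stream):
            parts = title.split(None, 1)
            name = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            if not seq:
                raise FastaFormatError(f"record {name!r} has an empty sequence body")
            if any(ch in "*-." for ch in seq):
                raise FastaFormatError(
                    f"record {name!r} contains gap or stop characters; "
                    "unaligned sequence input only"
                )
            yield digitize(seq, self.alphabet, name=name, description=desc)

    def __iter__(self) -> Iterator[DigitalSequence]:
        return self

    def __next__(self) -> DigitalSequence:
        try:
            return next(self._iter)
        except StopIteration:
            self.close()
            raise

    def __enter__(self) -> "FastaReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        if self._owns and not self._handle.closed:
            self._handle.close()


def read_fasta(source: Source, alphabet: Alphabet | None = None) -> FastaReader:
    """Open a FASTA source for streaming digital-sequence reads."""
    return FastaReader(source, alphabet or Alphabet.amino())


def write_fasta(seqs: Iterable[DigitalSequence], sink: Source, width: int = 60) -> int:
    """Write sequences as FASTA; returns the number of records written."""
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    n = 0
    try:
        for seq in seqs:
            header = seq.name if not seq.description else f"{seq.name} {seq.description}"
            handle.write(f">{header}\n")
            text = seq.decode()
            for i in range(0, len(text), width):
                handle.write(text[i : i + width] + "\n")
            n += 1
    finally:
        if own:
            handle.close()
    return n
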