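"""Reading and writing profile HMMs in HMMER3 ASCII format.

The write dialect is ``HMMER3/f``; the reader also accepts the earlier
``HMMER3/a`` .. ``HMMER3/e`` headers.  Probabilities are stored as
negative natural logs with five decimals, with ``*`` denoting
probability zero.  The writer emits the conventional node-0 block
(insert-0 emissions and begin transitions) so files are digestible by
other HMMER3 parsers; the reader tolerates and skips that block, since
the :class:`~profhmm.model.HMM` type does not model node 0.
"""

from __future__ import annotations

import datetime
import math
from os import PathLike
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Union

import numpy as np

from .alphabet import Alphabet
from .model import HMM, EvalueParams, ModelError

__all__ = ["HmmFormatError", "HmmFileReader", "read_hmm_file", "write_hmm_file"]

Source = Union[str, PathLike, IO[str]]

_MANDATORY = ("NAME", "LENG", "ALPH")


class HmmFormatError(ValueError):
    """Raised for malformed HMMER3 ASCII input."""


def _decode(token: str, lineno: int) -> float:
    if token == "*":
        return 0.0
    try:
        return math.exp(-float(token))
    except ValueError:
        raise HmmFormatError(f"line {lineno}: bad probability field {token!r}") from None


def _encode(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{max(0.0, -math.log(p)):.5f}"


class HmmFileReader:
    """Iterate HMM records from a HMMER3 ASCII source."""

    def __init__(self, source: Source, alphabet: Optional[Alphabet] = None) -> None:
        self.alphabet = alphabet or Alphabet.amino()
        if hasattr(source, "read"):
            self._handle: IO[str] = source
            self._owns = False
        else:
            self._handle = open(source, "r")
            self._owns = True
        self._lineno = 0
        self._iter = self._records()

    def _readline(self) -> Optional[str]:
        line = self._handle.readline()
        if line == "":
            return None
        self._lineno += 1
        return line.rstrip("\n")

    def _records(self) -> Iterator[HMM]:
        while True:
            line = self._readline()
            if line is None:
                return
            if not line.strip():
                continue
            if not line.startswith("HMMER3/"):
                raise HmmFormatError(
                    f"line {self._lineno}: expected a HMMER3 format header, got {line[:30]!r}"
                )
            dialect = line[7]
            if dialect not in "abcdef":
                raise HmmFormatError(
                    f"line {self._lineno}: unsupported dialect HMMER3/{dialect}"
                )
            yield self._read_record()

    # -- one record ----------------------------------------------------

    def _read_record(self) -> HMM:
        header: dict = {}
        cutoffs: dict = {}
        stats: dict = {}
        # Header key-value section, freely ordered, until the HMM line.
        while True:
            line = self._readline()
            if line is None:
                raise HmmFormatError(f"line {self._lineno}: truncated record header")
            if not line.strip():
                continue
            fields = line.split(None, 1)
            key = fields[0]
            rest = fields[1] if len(fields) > 1 else ""
            if key == "HMM":
                break
            if key == "STATS":
                toks = rest.split()
                if len(toks) != 4 or toks[0] != "LOCAL":
                    raise HmmFormatError(f"line {self._lineno}: malformed STATS line")
                stats[toks[1]] = (float(toks[2]), float(toks[3]))
            elif key in ("GA", "TC", "NC"):
                toks = rest.replace(";", "").split()
                if len(toks) != 2:
                    raise HmmFormatError(f"line {self._lineno}: malformed {key} line")
                cutoffs[key] = (float(toks[0]), float(toks[1]))
            else:
                header[key] = rest.strip()

        for key in _MANDATORY:
            if key not in header:
                raise HmmFormatError(
                    f"line {self._lineno}: mandatory key {key} missing from record header"
                )
        if header["ALPH"].lower() != "amino":
            raise HmmFormatError(
                f"line {self._lineno}: unsupported alphabet {header['ALPH']!r}"
            )
        try:
            leng = int(header["LENG"])
        except ValueError:
            raise HmmFormatError(f"LENG value {header['LENG']!r} is not an integer") from None

        # Transition-name header line (content not interpreted).
        if self._readline() is None:
            raise HmmFormatError(f"line {self._lineno}: truncated record body")

        K = self.alphabet.size
        compo: Optional[np.ndarray] = None
        match_rows: List[np.ndarray] = []
        insert_rows: List[np.ndarray] = []
        trans_rows: List[np.ndarray] = []
        maps: List[str] = []
        cons: List[str] = []
        rf: List[str] = []
        mm: List[str] = []
        cs: List[str] = []

        line = self._readline()
        if line is not None and line.split()[:1] == ["COMPO"]:
            toks = line.split()[1:]
            if len(toks) != K:
                raise HmmFormatError(f"line {self._lineno}: COMPO needs {K} fields")
            compo = np.array([_decode(t, self._lineno) for t in toks])
            line = self._readline()

        # Optional node-0 block: two lines that do not start with a node
        # index (insert-0 emissions, then begin transitions).  Skipped.
        if line is not None and not _starts_with_int(line):
            line = self._readline()  # the node-0 transition line
            if line is None:
                raise HmmFormatError(f"line {self._lineno}: truncated node-0 block")
            line = self._readline()

        while line is not None and line.strip() != "//":
            toks = line.split()
            if not _starts_with_int(line):
                raise HmmFormatError(
                    f"line {self._lineno}: expected a node index, got {toks[0]!r}"
                )
            node = int(toks[0])
            if node != len(match_rows) + 1:
                raise HmmFormatError(
                    f"line {self._lineno}: node {node} out of order"
                )
            vals = toks[1 : 1 + K]
            if len(vals) != K:
                raise HmmFormatError(f"line {self._lineno}: match line needs {K} fields")
            match_rows.append(np.array([_decode(t, self._lineno) for t in vals]))
            ann = toks[1 + K :]
            ann = (ann + ["-"] * 5)[:5]
            maps.append(ann[0]); cons.append(ann[1]); rf.append(ann[2])
            mm.append(ann[3]); cs.append(ann[4])

            line = self._readline()
            if line is None:
                raise HmmFormatError(f"line {self._lineno}: truncated node block")
            toks = line.split()
            if len(toks) != K:
                raise HmmFormatError(f"line {self._lineno}: insert line needs {K} fields")
            insert_rows.append(np.array([_decode(t, self._lineno) for t in toks]))

            line = self._readline()
            if line is None:
                raise HmmFormatError(f"line {self._lineno}: truncated node block")
            toks = line.split()
            if len(toks) != 7:
                raise HmmFormatError(f"line {self._lineno}: transition line needs 7 fields")
            trans_rows.append(np.array([_decode(t, self._lineno) for t in toks]))
            line = self._readline()

        if line is None:
            raise HmmFormatError(
                f"line {self._lineno}: record not terminated by '//'"
            )
        if len(match_rows) != leng:
            raise HmmFormatError(
                f"LENG says {leng} nodes but {len(match_rows)} were found"
            )

        def _ann(values: List[str]) -> Optional[str]:
            return None if all(v == "-" for v in values) else "".join(values)

        map_vals: Optional[tuple] = None
        if any(v != "-" for v in maps):
            try:
                map_vals = tuple(int(v) for v in maps)
            except ValueError:
                raise HmmFormatError("MAP column contains non-integer values") from None

        ev = None
        if stats:
            for kind in ("MSV", "VITERBI", "FORWARD"):
                if kind not in stats:
                    raise HmmFormatError(f"incomplete STATS lines: {kind} missing")
            ev = EvalueParams(
                msv_mu=stats["MSV"][0], msv_lambda=stats["MSV"][1],
                vit_mu=stats["VITERBI"][0], vit_lambda=stats["VITERBI"][1],
                fwd_tau=stats["FORWARD"][0], fwd_lambda=stats["FORWARD"][1],
            )

        hmm = HMM(
            name=header["NAME"],
            match_emissions=np.vstack(match_rows),
            insert_emissions=np.vstack(insert_rows),
            transitions=np.vstack(trans_rows),
            alphabet=self.alphabet,
            accession=header.get("ACC", ""),
            description=header.get("DESC", ""),
            compo=compo,
            cutoffs=cutoffs,
            stats=ev,
            nseq=int(header["NSEQ"]) if "NSEQ" in header else None,
            effn=float(header["EFFN"]) if "EFFN" in header else None,
            checksum=int(header["CKSUM"]) if "CKSUM" in header else None,
            cons=_ann(cons), rf=_ann(rf), mm=_ann(mm), cs=_ann(cs),
            map_=map_vals,
        )
        try:
            hmm.validate(tol=1e-4)
        except ModelError as exc:
            raise HmmFormatError(f"record {hmm.name!r}: {exc}") from exc
        return hmm

    # -- protocols -----------------------------------------------------

    def __iter__(self) -> Iterator[HMM]:
        return self

    def __next__(self) -> HMM:
        try:
            return next(self._iter)
        except StopIteration:
            self.close()
            raise

    def __enter__(self) -> "HmmFileReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        if self._owns and not self._handle.closed:
            self._handle.close()


def _starts_with_int(line: str) -> bool:
    tok = line.split()
    if not tok:
        return False
    try:
        int(tok[0])
        return True
    except ValueError:
        return False


def read_hmm_file(source: Source, alphabet: Optional[Alphabet] = None) -> HmmFileReader:
    """Open a HMMER3 ASCII file for streaming HMM reads."""
    return HmmFileReader(source, alphabet)


def _fmt_row(values: Iterable[float]) -> str:
    return "  ".join(f"{_encode(v):>7s}" for v in values)


def write_hmm_file(models: Sequence[HMM], sink: Source, include_date: bool = True) -> int:
    """Write models in the HMMER3/f dialect; returns the record count.

    Each model is validated before any of its bytes are written.  A
    COMPO line is always present: when the model carries none, the
    average match-emission composition is computed on the fly.
    """
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    n = 0
    try:
        for hmm in models:
            try:
                # Tolerance matches the 5-decimal storage precision, so
                # a file that was just read always writes back cleanly.
                hmm.validate(tol=1e-4)
            except ModelError as exc:
                raise ModelError(f"model {hmm.name!r} failed validation: {exc}") from exc
            _write_one(hmm, handle, include_date)
            n += 1
    finally:
        if own:
            handle.close()
    return n


def _write_one(hmm: HMM, out: IO[str], include_date: bool) -> None:
    K = hmm.alphabet.size
    out.write("HMMER3/f [profhmm]\n")
    out.write(f"NAME  {hmm.name}\n")
    if hmm.accession:
        out.write(f"ACC   {hmm.accession}\n")
    if hmm.description:
        out.write(f"DESC  {hmm.description}\n")
    out.write(f"LENG  {hmm.M}\n")
    out.write("ALPH  amino\n")
    out.write(f"RF    {'yes' if hmm.rf else 'no'}\n")
    out.write(f"MM    {'yes' if hmm.mm else 'no'}\n")
    out.write(f"CONS  {'yes' if hmm.cons else 'no'}\n")
    out.write(f"CS    {'yes' if hmm.cs else 'no'}\n")
    out.write(f"MAP   {'yes' if hmm.map_ else 'no'}\n")
    if include_date:
        out.write(f"DATE  {datetime.datetime.now().strftime('%a %b %d %H:%M:%S %Y')}\n")
    if hmm.nseq is not None:
        out.write(f"NSEQ  {hmm.nseq}\n")
    if hmm.effn is not None:
        out.write(f"EFFN  {hmm.effn:.6f}\n")
    if hmm.checksum is not None:
        out.write(f"CKSUM {hmm.checksum}\n")
    for kind in ("GA", "TC", "NC"):
        if kind in hmm.cutoffs:
            seq_c, dom_c = hmm.cutoffs[kind]
            out.write(f"{kind}    {seq_c:.2f} {dom_c:.2f};\n")
    if hmm.stats is not None:
        s = hmm.stats
        out.write(f"STATS LOCAL MSV      {s.msv_mu:9.5f}  {s.msv_lambda:8.5f}\n")
        out.write(f"STATS LOCAL VITERBI  {s.vit_mu:9.5f}  {s.vit_lambda:8.5f}\n")
        out.write(f"STATS LOCAL FORWARD  {s.fwd_tau:9.5f}  {s.fwd_lambda:8.5f}\n")

    out.write("HMM      " + "        ".join(hmm.alphabet.symbols) + "\n")
    out.write(
        "         "
        + "     ".join(("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d"))
        + "\n"
    )
    compo = hmm.compo if hmm.compo is not None else hmm.match_emissions.mean(axis=0)
    out.write(f"  COMPO  {_fmt_row(compo)}\n")
    # Node-0 block: insert-0 emissions mirror node 1; begin transitions
    # are the degenerate B->M1 = 1 distribution.
    out.write(f"         {_fmt_row(hmm.insert_emissions[0])}\n")
    out.write(f"         {_fmt_row([1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0])}\n")
    for k in range(hmm.M):
        ann = [
            str(hmm.map_[k]) if hmm.map_ else "-",
            hmm.cons[k] if hmm.cons else "-",
            hmm.rf[k] if hmm.rf else "-",
            hmm.mm[k] if hmm.mm else "-",
            hmm.cs[k] if hmm.cs else "-",
        ]
        out.write(
            f"{k + 1:7d}  {_fmt_row(hmm.match_emissions[k])}  {'  '.join(ann)}\n"
        )
        out.write(f"         {_fmt_row(hmm.insert_emissions[k])}\n")
        out.write(f"         {_fmt_row(hmm.transitions[k])}\n")
    out.write("//\n")
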