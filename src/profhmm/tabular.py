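"""Whitespace-separated result tables (tblout / domtblout style).

Column order follows the HMMER conventions where fields exist.  The
bias columns are fixed at 0.0 (no composition correction is applied in
this pipeline) and one extra column carries the uncorrected full
p-value, which the classic tables never exposed.  Only whitespace
separation is promised, not byte-exact column alignment.
"""

from __future__ import annotations

from os import PathLike
from typing import IO, Iterable, Union

from .pipeline import TopHits

__all__ = ["write_tblout", "write_domtblout"]

Sink = Union[str, PathLike, IO[str]]

_TBL_HEADER = (
    "#target_name target_accession query_name query_accession "
    "full_evalue full_score full_bias best_dom_evalue best_dom_score "
    "best_dom_bias ndom full_pvalue description"
)
_DOMTBL_HEADER = (
    "#target_name target_accession target_len query_name query_accession "
    "qlen full_evalue full_score dom_num dom_total dom_score dom_pvalue "
    "dom_evalue hmm_from hmm_to ali_from ali_to description"
)


def _sci(x: float) -> str:
    return f"{x:.1e}"


def write_tblout(tophits_stream: Iterable[TopHits], sink: Sink) -> int:
    """One row per reported hit; returns the row count."""
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    n = 0
    try:
        handle.write(_TBL_HEADER + "\n")
        for th in tophits_stream:
            for hit in th.reported:
                best = hit.best_domain
                row = [
                    hit.target_name,
                    hit.target_accession or "-",
                    th.query_name,
                    th.query_accession or "-",
                    _sci(hit.full_evalue),
                    f"{hit.full_score:.1f}",
                    "0.0",
                    _sci(best.dom_evalue) if best else "-",
                    f"{best.dom_score:.1f}" if best else "-",
                    "0.0",
                    str(len(hit.domains)),
                    _sci(hit.full_pvalue),
                    hit.description or "-",
                ]
                handle.write(" ".join(row) + "\n")
                n += 1
    finally:
        if own:
            handle.close()
    return n


def write_domtblout(tophits_stream: Iterable[TopHits], sink: Sink) -> int:
    """One row per domain of each reported hit; returns the row count."""
    own = not hasattr(sink, "write")
    handle = open(sink, "w") if own else sink
    n = 0
    try:
        handle.write(_DOMTBL_HEADER + "\n")
        for th in tophits_stream:
            for hit in th.reported:
                total = len(hit.domains)
                for d_i, dom in enumerate(hit.domains, start=1):
                    seg = dom.segment
                    row = [
                        hit.target_name,
                        hit.target_accession or "-",
                        str(hit.target_length),
                        th.query_name,
                        th.query_accession or "-",
                        "-",
                        _sci(hit.full_evalue),
                        f"{hit.full_score:.1f}",
                        str(d_i),
                        str(total),
                        f"{dom.dom_score:.1f}",
                        _sci(dom.dom_pvalue),
                        _sci(dom.dom_evalue),
                        str(seg.hmm_from),
                        str(seg.hmm_to),
                        str(seg.seq_from),
                        str(seg.seq_to),
                        hit.description or "-",
                    ]
                    handle.write(" ".join(row) + "\n")
                    n += 1
    finally:
        if own:
            handle.close()
    return n
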