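"""The one-to-many comparison pipeline and query-parallel dispatch.

Each query (a profile HMM, or a single sequence turned into one) is
compared against every target sequence through the accelerated filter
cascade — MSV, then Viterbi, then Forward, each gated on its null
p-value — and surviving targets become :class:`Hit` objects with
bit scores, uncorrected p-values and Bonferroni-corrected E-values
(``E = p * Z``, Z defaulting to the number of comparisons actually
performed).

Multiple queries run on worker threads while the producing thread
pre-fetches and decodes queries ahead of consumption; a reordering
stage emits results strictly in query submission order, so the output
is bit-identical for every worker count.
"""

from __future__ import annotations

import os
import queue
import threading
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, List, Optional, Sequence, TypeVar

from . import dp
from .model import HMM, Background, Profile, configure
from .sequence import DigitalSequence, read_fasta
from .hmmfile import read_hmm_file
from .stats import (
    SignificanceOptions,
    calibrate,
    evalue,
    pvalue_exp_tail,
    pvalue_gumbel,
)

__all__ = [
    "Domain",
    "Hit",
    "TopHits",
    "PipelineOptions",
    "QueryError",
    "search_one",
    "scan_one",
    "hmmsearch",
    "hmmscan",
    "phmmer",
    "dispatch",
    "streaming_fallback",
    "physical_cores",
]

Q = TypeVar("Q")
R = TypeVar("R")


@dataclass
class PipelineOptions:
    """Filter thresholds and significance options for one search."""

    significance: SignificanceOptions = field(default_factory=SignificanceOptions)
    mode: str = "multihit"
    msv_p: float = 0.02
    vit_p: float = 1e-3
    fwd_p: float = 1e-5
    max_mode: bool = False

    def __post_init__(self) -> None:
        for name in ("msv_p", "vit_p", "fwd_p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class Domain:
    """One aligned segment of a hit, with its own significance."""

    segment: dp.DomainSegment
    dom_score: float
    dom_pvalue: float
    dom_evalue: float


@dataclass
class Hit:
    """One target that survived the filter cascade."""

    target_name: str
    target_accession: str
    target_length: int
    full_score: float
    full_pvalue: float
    full_evalue: float
    domains: List[Domain]
    description: str = ""
    reported: bool = False
    included: bool = False

    @property
    def best_domain(self) -> Optional[Domain]:
        if not self.domains:
            return None
        return min(self.domains, key=lambda d: (d.dom_pvalue, -d.dom_score))


class TopHits:
    """Ranked hits of one query, sorted by (E-value, -score, name)."""

    def __init__(self, query_name: str, query_accession: str, Z: float,
                 hits: List[Hit], options: PipelineOptions) -> None:
        self.query_name = query_name
        self.query_accession = query_accession
        self.Z = Z
        self.options = options
        self.hits = sorted(
            hits, key=lambda h: (h.full_evalue, -h.full_score, h.target_name)
        )

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self.hits)

    def __getitem__(self, i):
        return self.hits[i]

    @property
    def reported(self) -> List[Hit]:
        return [h for h in self.hits if h.reported]

    @property
    def included(self) -> List[Hit]:
        return [h for h in self.hits if h.included]


class QueryError(RuntimeError):
    """A worker or reader failure, tagged with the 1-based query ordinal."""

    def __init__(self, query_index: int, cause: BaseException) -> None:
        super().__init__(f"query {query_index} failed: {cause!r}")
        self.query_index = query_index
        self.cause = cause


def ensure_calibrated(hmm: HMM, background: Optional[Background] = None,
                      seed: int = 42) -> HMM:
    """Attach calibration statistics when absent (deterministic seed)."""
    if hmm.stats is None:
        calibrate(hmm, background, seed=seed)
    return hmm


def _compare(profile: Profile, seq: DigitalSequence, opts: PipelineOptions):
    """Run the filter cascade for one (profile, target) pair.

    Returns (full_score, p, domains) or None when a filter drops the
    target.  The profile's length model is re-parameterized to the
    target length first.
    """
    stats = profile.hmm.stats
    prof = profile.with_length(len(seq)) if len(seq) > 0 else profile
    msv = dp.msv_score(prof, seq)
    p_msv = pvalue_gumbel(msv, stats.msv_mu, stats.msv_lambda)
    if not opts.max_mode and p_msv > opts.msv_p:
        return None
    vit, path = dp.viterbi(prof, seq)
    p_vit = pvalue_gumbel(vit, stats.vit_mu, stats.vit_lambda)
    if not opts.max_mode and p_vit > opts.vit_p:
        return None
    fwd = dp.forward_score(prof, seq)
    p_fwd = pvalue_exp_tail(fwd, stats.fwd_tau, stats.fwd_lambda)
    if not opts.max_mode and p_fwd > opts.fwd_p:
        return None
    segments = dp.domains_from_path(prof, seq, path) if path.steps else []
    return fwd, p_fwd, segments


def _make_hit(name: str, accession: str, description: str, length: int,
              score: float, p: float, segments, stats) -> Hit:
    domains = []
    for seg in segments:
        dp_p = pvalue_exp_tail(seg.score_bits, stats.fwd_tau, stats.fwd_lambda)
        domains.append(Domain(segment=seg, dom_score=seg.score_bits,
                              dom_pvalue=dp_p, dom_evalue=dp_p))
    return Hit(
        target_name=name, target_accession=accession, target_length=length,
        full_score=score, full_pvalue=p, full_evalue=p,
        domains=domains, description=description,
    )


def _finalize(query_name: str, query_accession: str, hits: List[Hit],
              n_targets: int, opts: PipelineOptions, hmm: HMM) -> TopHits:
    sig = opts.significance
    Z = sig.Z if sig.Z is not None else float(max(n_targets, 1))
    cutoffs = None
    if sig.cutoff_source != "none":
        cutoffs = hmm.cutoffs.get(sig.cutoff_source)
        if cutoffs is None:
            raise ValueError(
                f"model {hmm.name!r} carries no {sig.cutoff_source} cutoff"
            )
    for h in hits:
        h.full_evalue = evalue(h.full_pvalue, Z)
        for d in h.domains:
            d.dom_evalue = evalue(d.dom_pvalue, Z)
        if cutoffs is not None:
            seq_c, dom_c = cutoffs
            h.reported = h.full_score >= seq_c
            h.included = h.reported and any(
                d.dom_score >= dom_c for d in h.domains
            )
        else:
            h.reported = h.full_evalue <= sig.report_E
            h.included = h.full_evalue <= sig.include_E
        h.included = h.included and h.reported
    return TopHits(query_name, query_accession,
                   Z, [h for h in hits], opts)


def search_one(profile: Profile, targets: Iterable[DigitalSequence],
               options: Optional[PipelineOptions] = None) -> TopHits:
    """Compare one configured profile against many target sequences.

    ``targets`` may be any iterable (a pre-fetched list or a streaming
    reader); it is consumed exactly once and the number of targets seen
    becomes the default Z.
    """
    opts = options or PipelineOptions()
    hmm = profile.hmm
    if hmm.stats is None:
        raise ValueError(f"model {hmm.name!r} is not calibrated; run calibrate() first")
    hits: List[Hit] = []
    n = 0
    for seq in targets:
        n += 1
        res = _compare(profile, seq, opts)
        if res is None:
            continue
        score, p, segments = res
        hits.append(_make_hit(seq.name, "", seq.description, len(seq),
                              score, p, segments, hmm.stats))
    return _finalize(hmm.name, hmm.accession, hits, n, opts, hmm)


def scan_one(seq: DigitalSequence, profiles: Sequence[Profile],
             options: Optional[PipelineOptions] = None) -> TopHits:
    """Compare one sequence against many models (roles transposed)."""
    opts = options or PipelineOptions()
    hits: List[Hit] = []
    stats_by_hit = []
    for prof in profiles:
        hmm = prof.hmm
        if hmm.stats is None:
            raise ValueError(f"model {hmm.name!r} is not calibrated")
        res = _compare(prof, seq, opts)
        if res is None:
            continue
        score, p, segments = res
        hits.append(_make_hit(hmm.name, hmm.accession, hmm.description, hmm.M,
                              score, p, segments, hmm.stats))
        stats_by_hit.append(hmm)
    sig = opts.significance
    Z = sig.Z if sig.Z is not None else float(max(len(profiles), 1))
    # Cutoff thresholding per hit uses each hit's own model.
    for h, hmm in zip(hits, stats_by_hit):
        h.full_evalue = evalue(h.full_pvalue, Z)
        for d in h.domains:
            d.dom_evalue = evalue(d.dom_pvalue, Z)
        if sig.cutoff_source != "none":
            co = hmm.cutoffs.get(sig.cutoff_source)
            if co is None:
                raise ValueError(f"model {hmm.name!r} carries no {sig.cutoff_source} cutoff")
            h.reported = h.full_score >= co[0]
            h.included = h.reported and any(d.dom_score >= co[1] for d in h.domains)
        else:
            h.reported = h.full_evalue <= sig.report_E
            h.included = h.reported and h.full_evalue <= sig.include_E
    return TopHits(seq.name, "", Z, hits, opts)


# --------------------------------------------------------------------
# Parallel dispatch

_SENTINEL = object()


def physical_cores() -> int:
    """Physical core count; falls back to logical/2, minimum 1."""
    try:
        cores = set()
        with open("/proc/cpuinfo") as fh:
            phys = core = None
            for line in fh:
                if line.startswith("physical id"):
                    phys = line.split(":")[1].strip()
                elif line.startswith("core id"):
                    core = line.split(":")[1].strip()
                elif not line.strip():
                    if phys is not None and core is not None:
                        cores.add((phys, core))
                    phys = core = None
            if phys is not None and core is not None:
                cores.add((phys, core))
        if cores:
            return max(1, len(cores))
    except OSError:
        pass
    return max(1, (os.cpu_count() or 2) // 2)


def dispatch(query_stream: Iterable[Q], worker_fn: Callable[[Q], R],
             n_workers: Optional[int] = None,
             prefetch_depth: Optional[int] = None) -> Iterator[R]:
    """Run ``worker_fn`` over queries on worker threads, yielding
    results strictly in submission order.

    The producing thread reads and decodes queries ahead of consumption
    up to ``prefetch_depth`` (default ``2 * n_workers``); workers take
    whole queries from a shared queue (work stealing); a reordering
    buffer restores submission order.  A worker or reader failure is
    raised as :class:`QueryError` carrying the 1-based query ordinal,
    after all earlier results have been delivered.
    """
    if n_workers is None:
        n_workers = physical_cores()
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if prefetch_depth is None:
        prefetch_depth = 2 * n_workers

    if n_workers == 1:
        def _serial() -> Iterator[R]:
            it = iter(query_stream)
            idx = 0
            while True:
                try:
                    item = next(it)
                except StopIteration:
                    return
                except Exception as exc:
                    raise QueryError(idx + 1, exc) from exc
                try:
                    result = worker_fn(item)
                except Exception as exc:
                    raise QueryError(idx + 1, exc) from exc
                yield result
                idx += 1
        return _serial()

    in_q: "queue.Queue" = queue.Queue(maxsize=max(1, prefetch_depth))
    out_q: "queue.Queue" = queue.Queue()
    stop = threading.Event()

    def producer() -> None:
        idx = 0
        try:
            for item in query_stream:
                while not stop.is_set():
                    try:
                        in_q.put((idx, item), timeout=0.1)
                        break
                    except queue.Full:
                        continue
                if stop.is_set():
                    return
                idx += 1
        except Exception as exc:
            out_q.put((idx, exc, True))
        finally:
            for _ in range(n_workers):
                while not stop.is_set():
                    try:
                        in_q.put(_SENTINEL, timeout=0.1)
                        break
                    except queue.Full:
                        continue
            out_q.put((None, idx, False))  # total query count marker

    def worker() -> None:
        while True:
            task = in_q.get()
            if task is _SENTINEL:
                break
            idx, item = task
            try:
                out_q.put((idx, worker_fn(item), False))
            except Exception as exc:
                out_q.put((idx, exc, True))

    threads = [threading.Thread(target=producer, daemon=True)]
    threads += [threading.Thread(target=worker, daemon=True) for _ in range(n_workers)]

    def _consume() -> Iterator[R]:
        for t in threads:
            t.start()
        pending: dict = {}
        next_idx = 0
        total: Optional[int] = None
        try:
            while total is None or next_idx < total:
                idx, payload, is_err = out_q.get()
                if idx is None:
                    total = payload
                else:
                    pending[idx] = (payload, is_err)
                while next_idx in pending:
                    payload, is_err = pending.pop(next_idx)
                    next_idx += 1
                    if is_err:
                        raise QueryError(next_idx, payload) from payload
                    yield payload
        finally:
            stop.set()

    return _consume()


# --------------------------------------------------------------------
# The rewritten CLI-equivalent entry points

def hmmsearch(queries: Iterable[HMM], targets: Sequence[DigitalSequence],
              options: Optional[PipelineOptions] = None,
              n_workers: Optional[int] = None,
              background: Optional[Background] = None,
              calibration_seed: int = 42) -> Iterator[TopHits]:
    """Search each query model against pre-fetched target sequences.

    Yields one :class:`TopHits` per query, in query order, identically
    for every worker count.
    """
    opts = options or PipelineOptions()
    bg = background or Background.amino()

    def work(hmm: HMM) -> TopHits:
        ensure_calibrated(hmm, bg, calibration_seed)
        profile = configure(hmm, bg, mode=opts.mode)
        return search_one(profile, targets, opts)

    return dispatch(queries, work, n_workers=n_workers)


def hmmscan(seqs: Iterable[DigitalSequence], models: Sequence[HMM],
            options: Optional[PipelineOptions] = None,
            n_workers: Optional[int] = None,
            background: Optional[Background] = None,
            calibration_seed: int = 42) -> Iterator[TopHits]:
    """Scan each sequence against a pre-loaded model collection."""
    opts = options or PipelineOptions()
    bg = background or Background.amino()
    profiles = []
    for hmm in models:
        ensure_calibrated(hmm, bg, calibration_seed)
        profiles.append(configure(hmm, bg, mode=opts.mode))

    def work(seq: DigitalSequence) -> TopHits:
        return scan_one(seq, profiles, opts)

    return dispatch(seqs, work, n_workers=n_workers)


def phmmer(query_seq: DigitalSequence, targets: Sequence[DigitalSequence],
           options: Optional[PipelineOptions] = None,
           background: Optional[Background] = None,
           calibration_seed: int = 42) -> TopHits:
    """Search a single protein sequence against target sequences."""
    from .build import single_seq_profile

    opts = options or PipelineOptions()
    bg = background or Background.amino()
    hmm = single_seq_profile(query_seq, background=bg)
    ensure_calibrated(hmm, bg, calibration_seed)
    profile = configure(hmm, bg, mode=opts.mode)
    return search_one(profile, targets, opts)


def search_files(query_file, target_file,
                 options: Optional[PipelineOptions] = None,
                 n_workers: Optional[int] = None,
                 background: Optional[Background] = None,
                 max_targets_in_memory: Optional[int] = None,
                 calibration_seed: int = 42) -> Iterator[TopHits]:
    """File-based hmmsearch: pre-fetch targets when they fit, otherwise
    fall back to re-streaming them from disk per query.

    ``max_targets_in_memory`` bounds the pre-fetch (None = always
    pre-fetch; 0 forces the streaming fallback).  Both routes produce
    identical results on identical inputs.
    """
    if max_targets_in_memory is not None:
        n = 0
        with read_fasta(target_file) as reader:
            for _ in reader:
                n += 1
                if n > max_targets_in_memory:
                    break
        if n > max_targets_in_memory:
            yield from streaming_fallback(query_file, target_file, options,
                                          background, calibration_seed)
            return
    with read_fasta(target_file) as reader:
        targets = list(reader)
    with read_hmm_file(query_file) as queries:
        yield from hmmsearch(queries, targets, options, n_workers=n_workers,
                             background=background,
                             calibration_seed=calibration_seed)


def streaming_fallback(query_file, target_file,
                       options: Optional[PipelineOptions] = None,
                       background: Optional[Background] = None,
                       calibration_seed: int = 42) -> Iterator[TopHits]:
    """File-reader fallback for target sets too large to pre-fetch.

    Targets are re-streamed from ``target_file`` for every query; the
    results are identical to the in-memory pipeline on the same inputs.
    """
    opts = options or PipelineOptions()
    bg = background or Background.amino()
    with read_hmm_file(query_file) as queries:
        for i, hmm in enumerate(queries):
            ensure_calibrated(hmm, bg, calibration_seed)
            profile = configure(hmm, bg, mode=opts.mode)
            try:
                with read_fasta(target_file, hmm.alphabet) as targets:
                    yield search_one(profile, targets, opts)
            except OSError as exc:
                raise OSError(
                    f"while streaming targets from {target_file!s} "
                    f"for query {i + 1}: {exc}"
                ) from exc
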