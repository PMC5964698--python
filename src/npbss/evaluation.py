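"""Fidelity diagnostics for simulated reads.

Three views of the same question — did the simulator inject the errors it
was asked to inject?

- :func:`summarize_rates`: event-derived match/sub/ins/del percentages over
  aligned columns, plus mean read length (the style of a simulator summary
  table).
- :func:`error_rate_by_qv`: per-QV observed error rate against the
  calibrated model curve (error rate tracks quality value).
- :func:`realign_rates`: an independent oracle that ignores the recorded
  events and re-measures error rates by unit-cost global alignment of each
  read against its error-free truth record.

Rate denominator convention: aligned columns = matches + substitutions +
insertions + deletions, so the four percentages sum to 100.  Error-rate
denominators are a classic ambiguity; this one is stated explicitly and
used everywhere in the package.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Union

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InputError
from .error_model import ErrorConfig
from .read_generator import (
    KIND_DEL,
    KIND_INS,
    KIND_MATCH,
    KIND_SUB,
    SimulatedRead,
)
from .reference_io import MAX_QV, _open_text, read_events_sidecar

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class RateSummary:
    """Event- or alignment-derived rate table for a read set.

    All rates are percentages of aligned columns; ``total_error_rate`` is
    the sum of the three error rates, and the four rates sum to 100.
    """

    match_rate: float
    ins_rate: float
    del_rate: float
    sub_rate: float
    total_error_rate: float
    mean_length: float
    n_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "match_rate_pct": [self.match_rate],
                "insertion_rate_pct": [self.ins_rate],
                "deletion_rate_pct": [self.del_rate],
                "substitution_rate_pct": [self.sub_rate],
                "total_error_rate_pct": [self.total_error_rate],
                "mean_length_bp": [self.mean_length],
                "n_reads": [self.n_reads],
            }
        )


def _summary_from_counts(
    n_match: int, n_sub: int, n_ins: int, n_del: int, total_len: int, n_reads: int
) -> RateSummary:
    columns = n_match + n_sub + n_ins + n_del
    if columns == 0 or n_reads == 0:
        raise ValueError("no aligned columns: empty input")
    pct = 100.0 / columns
    return RateSummary(
        match_rate=n_match * pct,
        ins_rate=n_ins * pct,
        del_rate=n_del * pct,
        sub_rate=n_sub * pct,
        total_error_rate=(n_sub + n_ins + n_del) * pct,
        mean_length=total_len / n_reads,
        n_reads=n_reads,
    )


ReadsOrSidecar = Union[Iterable[SimulatedRead], str, os.PathLike]


def summarize_rates(reads: ReadsOrSidecar) -> RateSummary:
    """Event-derived rate summary from reads or a truth-events sidecar."""
    counts = np.zeros(4, dtype=np.int64)
    total_len = 0
    n_reads = 0
    if isinstance(reads, (str, os.PathLike)):
        kind_code = {"match": 0, "substitution": 1, "insertion": 2, "deletion": 3}
        for _, group in groupby(read_events_sidecar(reads), key=lambda t: t[0]):
            n_reads += 1
            for _, kind, _ in group:
                counts[kind_code[kind]] += 1
        total_len = int(counts[KIND_MATCH] + counts[KIND_SUB] + counts[KIND_INS])
        if n_reads == 0:
            raise ValueError("events sidecar contains no reads")
        return _summary_from_counts(
            counts[0], counts[1], counts[2], counts[3], total_len, n_reads
        )
    for read in reads:
        counts += read.event_counts()
        total_len += len(read.sequence)
        n_reads += 1
    if n_reads == 0:
        raise ValueError("no reads supplied")
    return _summary_from_counts(
        int(counts[KIND_MATCH]),
        int(counts[KIND_SUB]),
        int(counts[KIND_INS]),
        int(counts[KIND_DEL]),
        total_len,
        n_reads,
    )


def error_rate_by_qv(
    reads: Iterable[SimulatedRead],
    error_config: ErrorConfig | None = None,
    min_bases_per_bin: int = 500,
) -> pd.DataFrame:
    """Observed vs model error rate per integer QV bin.

    Bins every aligned column by the QV drawn at that step (deletion
    columns keep the QV that governed their draw), observed = non-match
    fraction in the bin; bins with fewer than ``min_bases_per_bin`` columns
    are dropped.  ``model_error_rate`` is the calibrated, clamped model
    value for ``error_config`` (default configuration when omitted).
    """
    cfg = error_config if error_config is not None else ErrorConfig()
    n_cols = np.zeros(MAX_QV + 1, dtype=np.int64)
    n_err = np.zeros(MAX_QV + 1, dtype=np.int64)
    for read in reads:
        qv = read.step_qvs
        err = (read.step_kinds != KIND_MATCH).astype(np.int64)
        n_cols += np.bincount(qv, minlength=MAX_QV + 1)
        n_err += np.bincount(qv, weights=err, minlength=MAX_QV + 1).astype(np.int64)
    keep = n_cols >= max(1, min_bases_per_bin)
    qvs = np.nonzero(keep)[0]
    return pd.DataFrame(
        {
            "qv": qvs,
            "n_bases": n_cols[keep],
            "observed_error_rate": n_err[keep] / n_cols[keep],
            "model_error_rate": [cfg.per_base_error_prob(int(q)) for q in qvs],
        }
    )


def length_quality_scatter(reads: Iterable[SimulatedRead]) -> pd.DataFrame:
    """(read_length, mean per-base QV) pairs, one row per read."""
    rows = [(len(r.sequence), r.mean_qv) for r in reads]
    return pd.DataFrame(rows, columns=["read_length", "mean_read_qv"])


def _parse_cigar(cigar: str) -> tuple[int, int, int, int]:
    """(match, mismatch, read-insertion, deletion) column counts.

    edlib extended cigar: '=' match, 'X' mismatch, 'I' extra base in the
    query (read insertion), 'D' base missing from the query (deletion).
    """
    n_eq = n_x = n_i = n_d = 0
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        n = int(m.group(1))
        op = m.group(2)
        if op == "=":
            n_eq += n
        elif op in ("X", "M"):
            n_x += n
        elif op == "I":
            n_i += n
        else:
            n_d += n
        pos = m.end()
    if pos != len(cigar):
        raise ValueError(f"unparseable cigar: {cigar!r}")
    return n_eq, n_x, n_i, n_d


def align_read_to_truth(read_seq: str, truth_seq: str) -> tuple[int, int, int, int]:
    """Unit-cost global alignment; returns (match, sub, ins, del) columns."""
    res = edlib.align(read_seq, truth_seq, mode="NW", task="path")
    return _parse_cigar(res["cigar"])


def realign_rates(
    reads: Union[Iterable[SimulatedRead], str, os.PathLike],
    truth: Union[str, os.PathLike, None] = None,
) -> RateSummary:
    """Alignment-derived rate summary (the independent oracle).

    ``reads`` is either an iterable of :class:`SimulatedRead` (truth taken
    from each read's own template when ``truth`` is omitted) or a FASTQ
    path, in which case ``truth`` must be the matching truth FASTA.  Ids
    must pair up exactly.
    """
    pairs: Iterable[tuple[str, str, str]]
    if isinstance(reads, (str, os.PathLike)):
        if truth is None:
            raise InputError("a truth FASTA is required when reads come from FASTQ")
        with _open_text(truth) as handle:
            truth_map = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}

        def _iter_pairs():
            with _open_text(reads) as fq:
                for rec in SeqIO.parse(fq, "fastq"):
                    if rec.id not in truth_map:
                        raise InputError(f"read {rec.id} missing from truth FASTA")
                    yield rec.id, str(rec.seq), truth_map[rec.id]

        pairs = _iter_pairs()
    elif truth is not None:
        with _open_text(truth) as handle:
            truth_map = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}

        def _iter_pairs():
            for read in reads:
                if read.id not in truth_map:
                    raise InputError(f"read {read.id} missing from truth FASTA")
                yield read.id, read.sequence, truth_map[read.id]

        pairs = _iter_pairs()
    else:
        pairs = ((r.id, r.sequence, r.template) for r in reads)

    n_eq = n_x = n_i = n_d = 0
    total_len = 0
    n_reads = 0
    for _, seq, tr in pairs:
        a, b, c, d = align_read_to_truth(seq, tr)
        n_eq += a
        n_x += b
        n_i += c
        n_d += d
        total_len += len(seq)
        n_reads += 1
    if n_reads == 0:
        raise ValueError("no read/truth pairs supplied")
    return _summary_from_counts(n_eq, n_x, n_i, n_d, total_len, n_reads)


def error_rate_by_qv_from_alignment(
    fastq: str | os.PathLike,
    truth: str | os.PathLike,
    min_bases_per_bin: int = 500,
) -> pd.DataFrame:
    """Per-QV error rates measured from alignments, as one would on real data.

    Walks each read-vs-truth cigar and bins emitted read bases by their
    FASTQ QV; observed = (mismatch + insertion) fraction among emissions at
    that QV.  Deletions carry no read base and are excluded here, so these
    observed rates sit slightly below the event-based
    :func:`error_rate_by_qv` values.
    """
    n_cols = np.zeros(MAX_QV + 1, dtype=np.int64)
    n_err = np.zeros(MAX_QV + 1, dtype=np.int64)
    with _open_text(truth) as handle:
        truth_map = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    with _open_text(fastq) as fq:
        for rec in SeqIO.parse(fq, "fastq"):
            if rec.id not in truth_map:
                raise InputError(f"read {rec.id} missing from truth FASTA")
            qvs = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64)
            res = edlib.align(str(rec.seq), truth_map[rec.id], mode="NW", task="path")
            rpos = 0
            for m in _CIGAR_RE.finditer(res["cigar"]):
                n, op = int(m.group(1)), m.group(2)
                if op == "D":
                    continue
                block = qvs[rpos : rpos + n]
                n_cols += np.bincount(block, minlength=MAX_QV + 1)
                if op in ("X", "I", "M"):
                    n_err += np.bincount(block, minlength=MAX_QV + 1)
                rpos += n
    keep = n_cols >= max(1, min_bases_per_bin)
    qvs_kept = np.nonzero(keep)[0]
    return pd.DataFrame(
        {
            "qv": qvs_kept,
            "n_bases": n_cols[keep],
            "observed_error_rate": n_err[keep] / n_cols[keep],
        }
    )
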