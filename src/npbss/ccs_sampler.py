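"""Sampling-based generation of CCS-like (high-accuracy) reads.

Circular consensus (CCS) reads are short and highly accurate, and their
joint (length, quality) structure is easiest to reproduce by resampling:
donor reads are drawn with replacement from a real CCS FASTQ, and each
simulated read inherits its donor's length and per-base QV vector.  Errors
are injected per base with the Phred-defined probability 10^(-qv/10) taken
at face value — in the high-accuracy CCS regime the nominal QV is treated
as honest, unlike the empirical CLR model.  The error-type split reuses the
configured substitution/insertion/deletion ratios.

Because insertions and deletions shift the read relative to its donor, the
emitted QV vector is the donor's QVs read off step by step rather than a
literal copy; at CCS error rates the difference is a handful of bases per
read and the (length, mean QV) scatter of the output bootstraps the donor
set's.
"""

from __future__ import annotations

import logging
import os
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

from .error_model import ErrorConfig, theoretical_error_prob
from .read_generator import (
    SimulatedRead,
    _BASE_TO_CODE,
    _template_window,
    _walk_template,
    sample_read_origin,
)
from .reference_io import ReferenceSet, _open_text, format_read_id

log = logging.getLogger(__name__)


class CCSProfile(NamedTuple):
    """A donor read's length and per-base quality vector."""

    length: int
    qvs: np.ndarray


def extract_profiles(
    fastq_path: str | os.PathLike, rng: np.random.Generator, n: int
) -> list[CCSProfile]:
    """Draw ``n`` donor profiles uniformly with replacement from a FASTQ."""
    donors: list[np.ndarray] = []
    with _open_text(fastq_path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            donors.append(
                np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64)
            )
    if not donors:
        raise ValueError(f"{fastq_path}: no FASTQ records found")
    picks = rng.integers(0, len(donors), size=n)
    return [CCSProfile(len(donors[i]), donors[i]) for i in picks]


def simulate_ccs(
    refs: ReferenceSet,
    profiles: Sequence[CCSProfile],
    rng: np.random.Generator,
    error_config: ErrorConfig | None = None,
) -> Iterator[SimulatedRead]:
    """Synthesize one read per profile at the profile's length and QVs.

    Profiles longer than every reference record are skipped with a warning.
    ``error_config`` supplies only the sub/ins/del ratios (default 6:3:6);
    per-base error probabilities come from the donor QVs via 10^(-qv/10).
    """
    cfg = error_config if error_config is not None else ErrorConfig()
    total = cfg.total_rate
    if total > 0:
        fracs = (cfg.sub_rate / total, cfg.ins_rate / total, cfg.del_rate / total)
    else:
        fracs = (0.0, 0.0, 0.0)
    max_record = max(len(seq) for _, seq in refs.records)
    for k, prof in enumerate(profiles):
        if prof.length > max_record:
            log.warning(
                "profile %d (%d bp) longer than every reference record; skipped",
                k,
                prof.length,
            )
            continue
        rid, start, strand = sample_read_origin(refs, prof.length, rng)
        seq = refs[rid]
        window, anchor = _template_window(seq, start, prof.length, strand)
        # step j reads the donor QV at emission position j; deletions shift
        # the cursor, so pad by repeating the final donor QV
        cursor = 0

        def draw_qvs(m: int) -> np.ndarray:
            nonlocal cursor
            idx = np.minimum(np.arange(cursor, cursor + m), prof.length - 1)
            cursor += m
            return prof.qvs[idx]

        applied = _walk_template(
            _BASE_TO_CODE[np.frombuffer(window.encode("ascii"), dtype=np.uint8)],
            *fracs,
            draw_qvs=draw_qvs,
            p_fn=theoretical_error_prob,
            target_len=prof.length,
            rng=rng,
        )
        if strand == "+":
            r_start, r_end = anchor, anchor + applied.consumed
        else:
            r_start, r_end = anchor - applied.consumed, anchor
        yield SimulatedRead(
            id=format_read_id(k, rid, r_start, r_end, strand),
            sequence=applied.sequence,
            qvs=applied.qvs,
            ref_id=rid,
            start=r_start,
            end=r_end,
            strand=strand,
            template=window[: applied.consumed],
            step_kinds=applied.step_kinds,
            step_qvs=applied.step_qvs,
        )
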