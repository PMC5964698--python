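"""Read synthesis: origin sampling and per-base error injection.

A simulated read is produced by walking an error-free template sampled from
the reference.  At each step a quality value is drawn from the QV table,
converted to a calibrated per-base error probability, split into
substitution/insertion/deletion parts, and one of four events is drawn:

- match: emit the template base, consume it
- substitution: emit one of the 3 other bases (uniform), consume
- insertion: emit a uniform random base, do NOT consume (the inserted base
  precedes the current template base)
- deletion: consume the template base, emit nothing

Emission stops once the read reaches its target length, so the sampled
log-normal length is the FINAL read length and the template span consumed
varies per read (about target_len * (1 + del - ins) on average).  The
template window is taken from the reference with generous slack; if
deletions exhaust it at a record end the read is truncated with a warning.

Every step is recorded, giving an exact ground-truth edit script per read.
One root seed drives per-read spawned substreams, so output is invariant to
emission order and byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterator, NamedTuple, Optional

import numpy as np

from .errors import ConfigError
from .error_model import ErrorConfig
from .length_model import (
    DEFAULT_MEAN_LEN,
    CountSpec,
    LengthParams,
    params_from_mean,
    resolve_read_count,
    sample_lengths,
)
from .qv_model import QVTable, load_qv_table
from .reference_io import ReferenceSet, format_read_id, reverse_complement

log = logging.getLogger(__name__)

KIND_MATCH, KIND_SUB, KIND_INS, KIND_DEL = 0, 1, 2, 3
KIND_NAMES = ("match", "substitution", "insertion", "deletion")

_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _BASE_TO_CODE[_c] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ORIGIN_REDRAW_CAP = 1000


class EditEvent(NamedTuple):
    """One ground-truth edit-script step.

    ``template_pos``/``read_pos`` are 0-based offsets in the error-free
    template and the emitted read; ``read_pos`` is None for deletions,
    ``base_template`` is None for insertions, ``base_emitted`` is None for
    deletions.  ``qv`` is the quality value drawn at this step (it governs
    the error draw; for emitting steps it is also the base's FASTQ QV).
    """

    kind: str
    template_pos: int
    read_pos: Optional[int]
    base_template: Optional[str]
    base_emitted: Optional[str]
    qv: int


class AppliedErrors(NamedTuple):
    """Raw output of :func:`apply_errors` before read assembly."""

    sequence: str
    qvs: np.ndarray  # per emitted base
    step_kinds: np.ndarray  # per aligned column, KIND_* codes
    step_qvs: np.ndarray  # per aligned column
    consumed: int  # template bases consumed
    truncated: bool


@dataclass(frozen=True)
class SimulatedRead:
    """An error-containing read plus its full ground truth.

    ``template`` is the error-free, strand-adjusted reference substring the
    read was generated from (exactly the truth FASTA record);
    ``[start, end)`` are 0-based half-open coordinates on ``ref_id``.
    ``step_kinds``/``step_qvs`` record every aligned column of the injected
    edit script; :attr:`events` materialises them as :class:`EditEvent`s.
    """

    id: str
    sequence: str
    qvs: np.ndarray
    ref_id: str
    start: int
    end: int
    strand: str
    template: str
    step_kinds: np.ndarray = field(repr=False)
    step_qvs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.bincount(self.step_kinds, minlength=4)
        if len(self.sequence) != len(self.qvs):
            raise ValueError(f"{self.id}: sequence/QV length mismatch")
        if counts[KIND_MATCH] + counts[KIND_SUB] + counts[KIND_DEL] != self.end - self.start:
            raise ValueError(f"{self.id}: template not fully consumed by events")
        if counts[KIND_MATCH] + counts[KIND_SUB] + counts[KIND_INS] != len(self.sequence):
            raise ValueError(f"{self.id}: emissions do not add up to read length")
        if len(self.template) != self.end - self.start:
            raise ValueError(f"{self.id}: template length != end - start")

    @property
    def n_aligned_columns(self) -> int:
        return len(self.step_kinds)

    def event_counts(self) -> np.ndarray:
        """Counts of (match, substitution, insertion, deletion) columns."""
        return np.bincount(self.step_kinds, minlength=4)

    @cached_property
    def events(self) -> list[EditEvent]:
        return events_from_steps(
            self.template, self.sequence, self.step_kinds, self.step_qvs
        )

    @property
    def mean_qv(self) -> float:
        return float(np.mean(self.qvs))


def events_from_steps(
    template: str,
    sequence: str,
    step_kinds: np.ndarray,
    step_qvs: np.ndarray,
) -> list[EditEvent]:
    """Reconstruct the explicit edit script from compact per-step arrays."""
    events: list[EditEvent] = []
    tpos = 0
    rpos = 0
    for kind, qv in zip(step_kinds, step_qvs):
        if kind == KIND_MATCH:
            events.append(
                EditEvent("match", tpos, rpos, template[tpos], sequence[rpos], int(qv))
            )
            tpos += 1
            rpos += 1
        elif kind == KIND_SUB:
            events.append(
                EditEvent(
                    "substitution", tpos, rpos, template[tpos], sequence[rpos], int(qv)
                )
            )
            tpos += 1
            rpos += 1
        elif kind == KIND_INS:
            events.append(
                EditEvent("insertion", tpos, rpos, None, sequence[rpos], int(qv))
            )
            rpos += 1
        else:
            events.append(EditEvent("deletion", tpos, None, template[tpos], None, int(qv)))
            tpos += 1
    return events


def sample_read_origin(
    refs: ReferenceSet, read_len: int, rng: np.random.Generator
) -> tuple[str, int, str]:
    """Draw (ref_id, start, strand) for a read of target length ``read_len``.

    Among records long enough to host the initial template span, one is
    chosen with probability proportional to its length; the start is uniform
    over valid positions and the strand uniform over {+,-}.  Raises
    :class:`ConfigError` when no record is long enough (the caller redraws
    the length).
    """
    eligible = [(rid, seq) for rid, seq in refs.records if len(seq) >= read_len]
    if not eligible:
        raise ConfigError(f"no reference record is >= {read_len} bp")
    weights = np.array([len(seq) for _, seq in eligible], dtype=float)
    idx = int(rng.choice(len(eligible), p=weights / weights.sum()))
    rid, seq = eligible[idx]
    start = int(rng.integers(0, len(seq) - read_len + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    return rid, start, strand


def _walk_template(
    codes: np.ndarray,
    frac_sub: float,
    frac_ins: float,
    frac_del: float,
    draw_qvs,
    p_fn,
    target_len: int,
    rng: np.random.Generator,
) -> AppliedErrors:
    """Vectorised core walk over a template given as base codes (0-4)."""
    tlen = len(codes)
    seq_parts: list[np.ndarray] = []
    eqv_parts: list[np.ndarray] = []
    kind_parts: list[np.ndarray] = []
    sqv_parts: list[np.ndarray] = []
    tpos = 0
    emitted = 0
    truncated = False
    while emitted < target_len:
        m = int((target_len - emitted) * 1.15) + 64
        qv = np.asarray(draw_qvs(m), dtype=np.int64)
        pe = np.asarray(p_fn(qv), dtype=float)
        u = rng.random(m)
        ps = pe * frac_sub
        pi = pe * frac_ins
        pd = pe * frac_del
        kinds = np.full(m, KIND_MATCH, dtype=np.uint8)
        kinds[u < ps + pi + pd] = KIND_DEL
        kinds[u < ps + pi] = KIND_INS
        kinds[u < ps] = KIND_SUB
        emits = kinds != KIND_DEL
        consumes = kinds != KIND_INS
        cum_e = np.cumsum(emits)
        cum_c = np.cumsum(consumes)
        ie = int(np.searchsorted(cum_e, target_len - emitted))
        ic = int(np.searchsorted(cum_c, tlen - tpos))
        if ie < m and (ic >= m or ie <= ic):
            cut, done = ie + 1, True
        elif ic < m:
            cut, done = ic + 1, True
            truncated = True
        else:
            cut, done = m, False
        kinds = kinds[:cut]
        qv = qv[:cut]
        emits = emits[:cut]
        consumes = consumes[:cut]
        cum_c = cum_c[:cut]

        step_t_code = np.zeros(cut, dtype=np.uint8)
        step_t_code[consumes] = codes[tpos + cum_c[consumes] - 1]
        base = np.empty(cut, dtype=np.uint8)
        is_match = kinds == KIND_MATCH
        is_sub = kinds == KIND_SUB
        is_ins = kinds == KIND_INS
        base[is_match] = step_t_code[is_match]
        n_sub = int(is_sub.sum())
        if n_sub:
            tc = step_t_code[is_sub]
            # uniform over the 3 other bases; an N template base re-draws
            # uniformly from all 4
            new = (tc + 1 + rng.integers(0, 3, size=n_sub).astype(np.uint8)) % 4
            n_mask = tc == 4
            if n_mask.any():
                new[n_mask] = rng.integers(0, 4, size=int(n_mask.sum())).astype(np.uint8)
            base[is_sub] = new
        n_ins = int(is_ins.sum())
        if n_ins:
            base[is_ins] = rng.integers(0, 4, size=n_ins).astype(np.uint8)

        seq_parts.append(_CODE_TO_BASE[base[emits]])
        eqv_parts.append(qv[emits])
        kind_parts.append(kinds)
        sqv_parts.append(qv)
        emitted += int(emits.sum())
        if cut:
            tpos += int(cum_c[-1])
        if done:
            break

    sequence = (
        np.concatenate(seq_parts).tobytes().decode("ascii") if seq_parts else ""
    )
    return AppliedErrors(
        sequence=sequence,
        qvs=np.concatenate(eqv_parts) if eqv_parts else np.empty(0, dtype=np.int64),
        step_kinds=(
            np.concatenate(kind_parts) if kind_parts else np.empty(0, dtype=np.uint8)
        ),
        step_qvs=np.concatenate(sqv_parts) if sqv_parts else np.empty(0, dtype=np.int64),
        consumed=tpos,
        truncated=truncated,
    )


def apply_errors(
    template: str,
    cfg: ErrorConfig,
    table: QVTable,
    target_len: int,
    rng: np.random.Generator,
) -> AppliedErrors:
    """Inject errors into ``template``, emitting ``target_len`` bases.

    ``cfg`` must already be calibrated against ``table`` (see
    :meth:`ErrorConfig.calibrated_against`).  Returns the emitted sequence,
    its per-base QVs, and the per-column event record; ``truncated`` is True
    when the template ran out before ``target_len`` emissions (the caller
    logs a warning).
    """
    if not template:
        raise ValueError("template must be non-empty")
    total = cfg.total_rate
    if total > 0:
        frac_sub = cfg.sub_rate / total
        frac_ins = cfg.ins_rate / total
        frac_del = cfg.del_rate / total
    else:
        frac_sub = frac_ins = frac_del = 0.0
    codes = _BASE_TO_CODE[np.frombuffer(template.encode("ascii"), dtype=np.uint8)]
    return _walk_template(
        codes,
        frac_sub,
        frac_ins,
        frac_del,
        draw_qvs=lambda m: table.sample(m, rng),
        p_fn=cfg.per_base_error_prob,
        target_len=target_len,
        rng=rng,
    )


def _template_window(
    seq: str, start: int, read_len: int, strand: str
) -> tuple[str, int]:
    """Strand-adjusted template window with slack for deletion overshoot.

    Returns (window, anchor): for '+', the window starts at ``start`` and
    ``anchor`` is ``start`` (consumption grows rightward); for '-', the
    window is the reverse complement ending at ``start + read_len`` and
    ``anchor`` is that end (consumption grows leftward from it).
    """
    slack = max(64, read_len // 4)
    if strand == "+":
        return seq[start : min(len(seq), start + read_len + slack)], start
    end0 = start + read_len
    lo = max(0, end0 - (read_len + slack))
    return reverse_complement(seq[lo:end0]), end0


def simulate(
    refs: ReferenceSet,
    count_spec: CountSpec,
    *,
    length_params: LengthParams | None = None,
    qv_table: QVTable | None = None,
    error_config: ErrorConfig | None = None,
    seed: int = 1,
    resample_empirical: bool = False,
    recalibrate: bool = True,
) -> Iterator[SimulatedRead]:
    """Yield simulated reads one at a time (constant memory in read count).

    Length parameters are resolved in this order: an explicit
    ``length_params``; a log-normal fit to ``count_spec.source_lengths``
    (resample_file mode; with ``resample_empirical`` raw lengths are
    bootstrap-resampled instead); otherwise the default log-normal targeting
    ``count_spec.mean_len`` (default 8500 bp).  ``error_config`` is
    calibrated against the QV table unless ``recalibrate`` is False.
    """
    from .length_model import fit_lognormal  # local to avoid cycle at import

    table = qv_table if qv_table is not None else load_qv_table()
    cfg = error_config if error_config is not None else ErrorConfig()
    if recalibrate:
        cfg = cfg.calibrated_against(table)

    source = None
    if count_spec.mode == "resample_file":
        source = np.asarray(count_spec.source_lengths, dtype=np.int64)
    if length_params is None:
        if source is not None and not resample_empirical:
            length_params = fit_lognormal(source)
        elif source is None:
            length_params = params_from_mean(count_spec.mean_len or DEFAULT_MEAN_LEN)

    n_reads = resolve_read_count(count_spec, refs.total_length)
    max_record = max(len(seq) for _, seq in refs.records)
    log.info(
        "simulate: n=%d seed=%d rates=(%.3g,%.3g,%.3g) scale=%.4g mode=%s",
        n_reads,
        seed,
        cfg.sub_rate,
        cfg.ins_rate,
        cfg.del_rate,
        cfg.calibration_scale,
        count_spec.mode,
    )

    children = np.random.SeedSequence(seed).spawn(n_reads)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        origin = None
        for _ in range(_ORIGIN_REDRAW_CAP):
            if source is not None and resample_empirical:
                read_len = int(source[rng.integers(0, len(source))])
            else:
                read_len = int(sample_lengths(length_params, 1, rng)[0])
            if read_len <= max_record:
                origin = sample_read_origin(refs, read_len, rng)
                break
        if origin is None:
            raise ConfigError(
                f"could not draw a read length fitting any reference record "
                f"(max record {max_record} bp) after {_ORIGIN_REDRAW_CAP} tries"
            )
        rid, start, strand = origin
        seq = refs[rid]
        window, anchor = _template_window(seq, start, read_len, strand)
        applied = apply_errors(window, cfg, table, read_len, rng)
        if applied.truncated:
            log.warning(
                "read %d truncated at %d/%d bases (record end on %s)",
                k,
                len(applied.sequence),
                read_len,
                rid,
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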