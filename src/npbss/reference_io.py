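"""Sequence I/O: reference FASTA input, simulated FASTQ / truth FASTA output.

The simulator consumes one reference genome in FASTA format (plain or
gzip-compressed) and emits a 4-line FASTQ of error-containing reads plus a
FASTA of the corresponding error-free templates ("truth" reads).  Truth
records are written in the read orientation, i.e. already strand-adjusted,
so a read aligned against its truth record directly measures the injected
errors.

Read identifiers follow a stable, parseable contract::

    npbss_read_<k>/<refId>/<start>_<end>/<strand>

with 0-based half-open [start, end) reference coordinates and strand in
``{+,-}``.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple, Sequence, TYPE_CHECKING

from Bio import SeqIO

from .errors import EncodingError, FormatError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .read_generator import SimulatedRead

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
# IUPAC ambiguity codes other than N; collapsed to N on input because the
# error model is defined only over concrete bases.
_AMBIGUOUS = set("RYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MAX_QV = 93  # Phred+33 ceiling: chr(33 + 93) == '~'


@dataclass(frozen=True)
class ReferenceSet:
    """Named nucleotide sequences the simulator samples reads from.

    Sequences are uppercase strings over ``{A,C,G,T,N}``; ids are unique.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("reference set contains no records")
        seen: set[str] = set()
        for rid, seq in self.records:
            if rid in seen:
                raise FormatError(f"duplicate reference id {rid!r}")
            seen.add(rid)
            if not seq:
                raise FormatError(f"record {rid!r} has an empty sequence")
            bad = set(seq) - _VALID
            if bad:
                raise FormatError(
                    f"record {rid!r} contains non-nucleotide characters {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, ref_id: str) -> str:
        for rid, seq in self.records:
            if rid == ref_id:
                return seq
        raise KeyError(ref_id)


def _open_text(path: str | os.PathLike[str]) -> IO[str]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | os.PathLike[str]) -> ReferenceSet:
    """Load a (optionally gzipped) FASTA file into a :class:`ReferenceSet`.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N with a logged warning.  Empty files, empty sequences and
    non-nucleotide characters raise :class:`FormatError`.
    """
    records: list[tuple[str, str]] = []
    n_ambiguous = 0
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            extra = set(seq) & _AMBIGUOUS
            if extra:
                n_ambiguous += 1
                seq = seq.translate(str.maketrans({c: "N" for c in _AMBIGUOUS}))
            records.append((rec.id, seq))
    if n_ambiguous:
        log.warning(
            "%d record(s) in %s contained IUPAC ambiguity codes; mapped to N",
            n_ambiguous,
            path,
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceSet(tuple(records))


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over ``{A,C,G,T,N}`` (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def format_read_id(k: int, ref_id: str, start: int, end: int, strand: str) -> str:
    return f"npbss_read_{k}/{ref_id}/{start}_{end}/{strand}"


class ReadOrigin(NamedTuple):
    index: int
    ref_id: str
    start: int
    end: int
    strand: str


def parse_read_id(read_id: str) -> ReadOrigin:
    """Invert :func:`format_read_id`; tolerates '/' inside the reference id."""
    parts = read_id.split("/")
    if len(parts) < 4 or not parts[0].startswith("npbss_read_"):
        raise FormatError(f"unparseable read id: {read_id!r}")
    strand = parts[-1]
    if strand not in "+-":
        raise FormatError(f"bad strand in read id: {read_id!r}")
    try:
        start_s, end_s = parts[-2].split("_")
        k = int(parts[0][len("npbss_read_"):])
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"unparseable read id: {read_id!r}") from exc
    ref_id = "/".join(parts[1:-2])
    return ReadOrigin(k, ref_id, start, end, strand)


def qvs_to_ascii(qvs: Sequence[int]) -> str:
    """Phred+33 encode a QV vector; QVs outside [0, 93] raise."""
    out = []
    for q in qvs:
        q = int(q)
        if q < 0 or q > MAX_QV:
            raise EncodingError(f"QV {q} outside the Phred+33 range [0, {MAX_QV}]")
        out.append(chr(33 + q))
    return "".join(out)


def write_fastq(reads: Iterable["SimulatedRead"], path: str | os.PathLike[str]) -> int:
    """Write simulated reads as Sanger (Phred+33) 4-line FASTQ.

    Returns the number of records written.  An empty iterable yields a valid
    empty file.
    """
    n = 0
    with open(path, "wt") as out:
        for read in reads:
            if len(read.sequence) != len(read.qvs):
                raise EncodingError(
                    f"{read.id}: sequence/QV length mismatch "
                    f"({len(read.sequence)} vs {len(read.qvs)})"
                )
            out.write(f"@{read.id}\n{read.sequence}\n+\n{qvs_to_ascii(read.qvs)}\n")
            n += 1
    return n


def write_truth_fasta(
    reads: Iterable["SimulatedRead"], path: str | os.PathLike[str]
) -> int:
    """Write the error-free, strand-adjusted templates as FASTA.

    Ids match the FASTQ ids one-to-one and in the same order.
    """
    n = 0
    with open(path, "wt") as out:
        for read in reads:
            out.write(f">{read.id}\n{read.template}\n")
            n += 1
    return n


SIDECAR_HEADER = "#read_id\tkind\ttemplate_pos\tread_pos\tbase_template\tbase_emitted\tqv"


def write_events_sidecar(
    reads: Iterable["SimulatedRead"], path: str | os.PathLike[str]
) -> int:
    """Write the ground-truth edit events as a tab-separated sidecar.

    One line per event; absent fields (e.g. read_pos of a deletion) are '.'.
    """
    n = 0
    with open(path, "wt") as out:
        out.write(SIDECAR_HEADER + "\n")
        for read in reads:
            for ev in read.events:
                out.write(
                    "\t".join(
                        (
                            read.id,
                            ev.kind,
                            str(ev.template_pos),
                            "." if ev.read_pos is None else str(ev.read_pos),
                            ev.base_template or ".",
                            ev.base_emitted or ".",
                            str(ev.qv),
                        )
                    )
                    + "\n"
                )
            n += 1
    return n


def read_events_sidecar(
    path: str | os.PathLike[str],
) -> Iterator[tuple[str, str, int]]:
    """Yield (read_id, kind, qv) triples from an events sidecar."""
    with _open_text(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise FormatError(f"malformed sidecar line: {line!r}")
            yield fields[0], fields[1], int(fields[6])
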