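"""Empirical distribution of per-base quality values (QVs).

Each base of a simulated CLR read receives an integer Phred quality value
drawn i.i.d. from a discrete proportion table.  A default table ships with
the package; users may supply their own two-column ``QV proportion`` text
file.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import FormatError
from .reference_io import MAX_QV, _open_text

log = logging.getLogger(__name__)

_NORMALISE_WARN_TOL = 1e-6


@dataclass(frozen=True)
class QVTable:
    """Discrete probability distribution over integer quality values."""

    qvs: tuple[int, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.qvs) != len(self.proportions) or not self.qvs:
            raise FormatError("QV table must have matching, non-empty columns")
        if list(self.qvs) != sorted(set(self.qvs)):
            raise FormatError("QV values must be unique and sorted ascending")
        if any(q < 0 or q > MAX_QV for q in self.qvs):
            raise FormatError(f"QV values must lie in [0, {MAX_QV}]")
        if any(p < 0 for p in self.proportions):
            raise FormatError("proportions must be non-negative")
        total = float(sum(self.proportions))
        if abs(total - 1.0) > 1e-9:
            raise FormatError(f"proportions must sum to 1, got {total!r}")
        if not any(p > 0 for p in self.proportions):
            raise ValueError("QV table needs at least one positive proportion")

    @property
    def entries(self) -> list[tuple[int, float]]:
        return list(zip(self.qvs, self.proportions))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. QVs from the table."""
        return rng.choice(
            np.asarray(self.qvs, dtype=np.int64), size=n, p=self.proportions
        )

    @classmethod
    def from_arrays(cls, qvs, proportions) -> "QVTable":
        qvs = [int(q) for q in qvs]
        props = np.asarray(proportions, dtype=float)
        total = props.sum()
        if total <= 0:
            raise ValueError("all proportions are zero")
        if abs(total - 1.0) > _NORMALISE_WARN_TOL:
            log.warning(
                "QV proportions sum to %.6g; renormalising to 1", float(total)
            )
        props = props / total
        return cls(tuple(qvs), tuple(float(p) for p in props))


def load_qv_table(path: str | os.PathLike[str] | None = None) -> QVTable:
    """Load a QV proportion table, or the bundled default when path is None.

    File format: whitespace-separated ``QV proportion`` lines; '#' starts a
    comment.  Proportions are renormalised to sum to 1 (with a warning when
    they are off by more than 1e-6).  Duplicate QV rows, out-of-range QVs
    and negative proportions raise :class:`FormatError`.
    """
    if path is None:
        ref = resources.files("npbss").joinpath("data/default_qv_table.txt")
        text = ref.read_text()
        lines = text.splitlines()
    else:
        with _open_text(path) as handle:
            lines = handle.read().splitlines()
    qvs: list[int] = []
    props: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected 'QV proportion', got {raw!r}")
        try:
            q = int(fields[0])
            p = float(fields[1])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: unparseable numbers in {raw!r}") from exc
        if q in qvs:
            raise FormatError(f"line {lineno}: duplicate QV {q}")
        if q < 0 or q > MAX_QV:
            raise FormatError(f"line {lineno}: QV {q} outside [0, {MAX_QV}]")
        if p < 0:
            raise FormatError(f"line {lineno}: negative proportion {p}")
        qvs.append(q)
        props.append(p)
    if not qvs:
        raise FormatError("QV table file contains no data rows")
    order = np.argsort(qvs)
    return QVTable.from_arrays(
        [qvs[i] for i in order], [props[i] for i in order]
    )


def sample_qvs(table: QVTable, length: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``length`` i.i.d. quality values for one read."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return table.sample(length, rng)
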