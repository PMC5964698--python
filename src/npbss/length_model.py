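"""Log-normal read-length model.

Continuous long reads (CLR) have heavy-tailed length distributions that are
well described by a log-normal law: if X is the read length, ln X is
Gaussian with mean ``mu`` and standard deviation ``sigma``.  This module
fits those parameters from observed lengths, derives them from a target
mean length, samples integer lengths with rejection against [min_len,
max_len] bounds, and resolves the read count for the four supported count
modes (explicit count, sequencing depth, explicit log-normal parameters,
resampling from a user read file).
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConfigError, FormatError
from .reference_io import _open_text

log = logging.getLogger(__name__)

DEFAULT_MEAN_LEN = 8500  # bp, default target average read length
DEFAULT_SIGMA = 0.5  # sd of ln(length); gives a realistic long right tail
DEFAULT_MIN_LEN = 50
DEFAULT_MAX_LEN = 100_000
_REJECTION_CAP = 1000  # redraw rounds before clamping to the nearer bound


@dataclass(frozen=True)
class LengthParams:
    """Parameters of the log-normal read-length distribution.

    ``mu`` and ``sigma`` are the mean and standard deviation of the natural
    logarithm of read length (dimensionless); ``min_len``/``max_len`` bound
    the emitted lengths in bp.
    """

    mu: float
    sigma: float
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError(
                f"need 0 < min_len <= max_len, got [{self.min_len}, {self.max_len}]"
            )
        if not math.isfinite(self.mean_length) or self.mean_length < self.min_len:
            raise ValueError(
                f"implied mean length {self.mean_length:.1f} below min_len {self.min_len}"
            )

    @property
    def mean_length(self) -> float:
        """Expectation of the (unbounded) log-normal: exp(mu + sigma^2 / 2)."""
        return math.exp(self.mu + self.sigma**2 / 2.0)


@dataclass(frozen=True)
class CountSpec:
    """How the number of simulated reads is determined.

    mode:
        - ``explicit_n``: simulate exactly ``n`` reads
        - ``depth``: reads = ceil(depth * genome_length / mean_len)
        - ``lognormal_params``: lengths from user (mu, sigma); count from ``n``
        - ``resample_file``: lengths from ``source_lengths``; count from ``n``
    """

    mode: str
    n: int | None = None
    depth: float | None = None
    mean_len: float | None = None
    source_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"explicit_n", "depth", "lognormal_params", "resample_file"}:
            raise ConfigError(f"unknown count mode {self.mode!r}")
        if self.mode == "explicit_n" and (self.n is None or self.n < 1):
            raise ConfigError("explicit_n mode requires n >= 1")
        if self.mode == "depth":
            if self.depth is None or self.depth <= 0:
                raise ConfigError("depth mode requires depth > 0")
            if self.mean_len is None or self.mean_len < 1:
                raise ConfigError("depth mode requires mean_len >= 1")
        if self.mode == "resample_file" and not self.source_lengths:
            raise ConfigError("resample_file mode requires source_lengths")


def fit_lognormal(lengths: Sequence[int]) -> LengthParams:
    """Maximum-likelihood fit of (mu, sigma) from observed read lengths.

    mu is the sample mean of ln(length), sigma the sample standard deviation
    (MLE, ddof=0); min_len/max_len are taken from the observed range.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 lengths to estimate sigma")
    if np.any(arr <= 0):
        raise ValueError("all lengths must be positive")
    logs = np.log(arr)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("degenerate input: all lengths equal, sigma would be 0")
    return LengthParams(
        mu=mu, sigma=sigma, min_len=int(arr.min()), max_len=int(arr.max())
    )


def params_from_mean(
    mean_len: float,
    sigma: float = DEFAULT_SIGMA,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> LengthParams:
    """Length parameters whose distribution mean equals ``mean_len``.

    Uses mu = ln(mean_len) - sigma^2/2 so that E[X] = exp(mu + sigma^2/2)
    = mean_len.
    """
    if mean_len < 1:
        raise ValueError(f"mean_len must be >= 1, got {mean_len}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    mu = math.log(mean_len) - sigma**2 / 2.0
    return LengthParams(mu=mu, sigma=sigma, min_len=min_len, max_len=max_len)


def sample_lengths(
    params: LengthParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` integer read lengths from the bounded log-normal.

    Lengths are round(exp(N(mu, sigma))); draws outside [min_len, max_len]
    are redrawn (rejection).  After a bounded number of rejection rounds any
    stragglers are clamped to the nearer bound with a logged warning, which
    guarantees termination for degenerate bounds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty(n, dtype=np.int64)
    pending = np.arange(n)
    for _ in range(_REJECTION_CAP):
        draws = np.rint(
            np.exp(rng.normal(params.mu, params.sigma, size=pending.size))
        ).astype(np.int64)
        ok = (draws >= params.min_len) & (draws <= params.max_len)
        out[pending[ok]] = draws[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    log.warning(
        "%d length draw(s) still outside [%d, %d] after %d rejection rounds; clamping",
        pending.size,
        params.min_len,
        params.max_len,
        _REJECTION_CAP,
    )
    draws = np.rint(
        np.exp(rng.normal(params.mu, params.sigma, size=pending.size))
    ).astype(np.int64)
    out[pending] = np.clip(draws, params.min_len, params.max_len)
    return out


def resolve_read_count(spec: CountSpec, genome_length: int) -> int:
    """Number of reads to simulate for a given genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if spec.mode == "explicit_n":
        return int(spec.n)  # type: ignore[arg-type]
    if spec.mode == "depth":
        return int(math.ceil(spec.depth * genome_length / spec.mean_len))
    # lognormal_params / resample_file: the count must come from n
    if spec.n is None or spec.n < 1:
        raise ConfigError(f"{spec.mode} mode requires an explicit read count n")
    return int(spec.n)


def lengths_from_file(path: str | os.PathLike[str]) -> list[int]:
    """Record lengths from a FASTA or FASTQ file (optionally gzipped)."""
    with _open_text(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise FormatError(f"{path}: not recognisable as FASTA or FASTQ")
        lengths = [len(rec.seq) for rec in SeqIO.parse(handle, fmt)]
    if not lengths:
        raise ValueError(f"{path}: no sequence records found")
    return lengths
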