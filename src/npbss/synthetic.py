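"""Seeded synthetic fixtures: random genomes and pseudo-CCS donor reads.

Every code path of the simulator can be exercised without external data:
reference genomes are i.i.d. uniform A/C/G/T strings, and the CCS sampler's
donor FASTQ is produced by running the CLR engine itself at high quality /
low error.  These fixtures capture none of the compositional structure of
real genomes (GC skew, repeats, homopolymers), which is irrelevant to the
simulator's error process but matters for downstream tools consuming its
output.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

from .error_model import ErrorConfig
from .length_model import CountSpec, params_from_mean
from .qv_model import QVTable
from .read_generator import SimulatedRead, simulate
from .reference_io import ReferenceSet, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(
    length: int,
    seed: int | np.random.Generator = 0,
    n_records: int = 1,
    id_prefix: str = "synthetic_contig",
) -> ReferenceSet:
    """An i.i.d. uniform-base genome split evenly into ``n_records`` records."""
    if length < n_records:
        raise ValueError("length must be >= n_records")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per = [length // n_records] * n_records
    per[-1] += length - sum(per)
    records = []
    for i, n in enumerate(per):
        seq = _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
        records.append((f"{id_prefix}_{i}", seq))
    return ReferenceSet(tuple(records))


def write_genome_fasta(refs: ReferenceSet, path: str | os.PathLike) -> None:
    with open(path, "wt") as out:
        for rid, seq in refs.records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i : i + 80] + "\n")


def pseudo_ccs_reads(
    n_reads: int = 200,
    seed: int = 0,
    mean_len: int = 1800,
    genome_length: int = 100_000,
) -> list[SimulatedRead]:
    """Synthetic high-accuracy reads usable as a CCS donor set.

    Generated by the CLR engine with a high-QV table (QV 20-40) and a ~1%
    total error target, emulating the short, accurate shape of CCS data.
    This is a synthetic stand-in for a real CCS FASTQ, not a model of one.
    """
    refs = random_genome(genome_length, seed=seed + 1)
    qv_range = np.arange(20, 41)
    weights = np.exp(-0.5 * ((qv_range - 30) / 4.0) ** 2)
    table = QVTable.from_arrays(qv_range, weights / weights.sum())
    cfg = ErrorConfig(sub_rate=0.004, ins_rate=0.002, del_rate=0.004)
    params = params_from_mean(mean_len, sigma=0.3, min_len=200, max_len=10_000)
    return list(
        simulate(
            refs,
            CountSpec(mode="explicit_n", n=n_reads, mean_len=mean_len),
            length_params=params,
            qv_table=table,
            error_config=cfg,
            seed=seed,
        )
    )


def pseudo_ccs_fastq(path: str | os.PathLike, **kwargs) -> int:
    """Write :func:`pseudo_ccs_reads` output as a donor FASTQ; returns count."""
    return write_fastq(pseudo_ccs_reads(**kwargs), path)
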