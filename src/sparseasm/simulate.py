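"""Seeded synthetic data: random reference genomes and uniformly sampled
short reads with uniform substitution errors.

The read protocol mirrors the standard simulation setup: ``round(c*G/r)``
reads of fixed length ``r``, start positions uniform on ``[0, G-r]``, each
read drawn from either strand with probability 1/2 (configurable), and each
base substituted with probability ``e`` to one of the three other bases
uniformly.  No indels, no quality model; FASTQ output uses constant
quality 'I'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .seqio import Read

__all__ = ["SimulationConfig", "random_genome", "simulate_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHUNK = 10_000  # reads per vectorised batch (fixed: keeps RNG stream stable)

# base -> 0..3 for error arithmetic; non-ACGT (e.g. N) mapped to 4
_IDX = np.full(256, 4, dtype=np.uint8)
for _b, _v in zip(b"ACGT", range(4)):
    _IDX[_b] = _v

_COMP = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGT", b"TGCA"):
    _COMP[_x] = _y


@dataclass(frozen=True)
class SimulationConfig:
    """Read-simulation settings: mean depth, read length, per-base
    substitution probability, RNG seed, and whether reads come from both
    strands."""

    coverage: float
    read_len: int
    error_rate: float = 0.0
    seed: int = 0
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def random_genome(length: int, seed: int, gc_fraction: float = 0.5) -> str:
    """I.i.d. random nucleotide string with the requested GC content."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[idx].tobytes().decode("ascii")


def simulate_reads(genome: str, config: SimulationConfig) -> List[Read]:
    """Sample reads uniformly from *genome* according to *config*.

    Deterministic for a given config (including the internal batch size).
    Reads never wrap the genome end.
    """
    G = len(genome)
    r = config.read_len
    if G < r:
        raise ValueError(f"genome length {G} shorter than read length {r}")
    n = round(config.coverage * G / r)
    rng = np.random.default_rng(config.seed)
    starts = rng.integers(0, G - r + 1, size=n)
    if config.both_strands:
        strands = rng.integers(0, 2, size=n)
    else:
        strands = np.zeros(n, dtype=np.int64)

    gbytes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    reads: List[Read] = []
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        m = hi - lo
        window = gbytes[starts[lo:hi, None] + np.arange(r)]
        rev = np.nonzero(strands[lo:hi])[0]
        if len(rev):
            window[rev] = _COMP[window[rev, ::-1]]
        if config.error_rate > 0:
            mask = rng.random((m, r)) < config.error_rate
            # never "substitute" an ambiguous base into ACGT
            mask &= _IDX[window] != 4
            n_err = int(mask.sum())
            if n_err:
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                idx = _IDX[window[mask]]
                window[mask] = _BASES[(idx + shift) % 4]
        for j in range(m):
            i = lo + j
            reads.append(
                Read(
                    f"read_{i}_pos_{starts[i]}_{'r' if strands[i] else 'f'}",
                    window[j].tobytes().decode("ascii"),
                    "I" * r,
                )
            )
    return reads
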