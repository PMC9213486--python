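"""Synthetic nucleotide/protein sequence generators for the test bench.

Companion to :mod:`sipseq.sipsim`: where that module simulates the SIP
experiment at the count level, this one fabricates the sequence-level
inputs (genomes, proteomes, reads) consumed by the relatedness and marker
screening stages, with controllable divergence so parameter recovery can
be checked against known truth.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "random_genome",
    "mutate_nt",
    "random_protein",
    "random_proteome",
    "mutate_protein",
    "sample_reads",
]

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


def random_genome(length: int, gc: float = 0.5, seed=0) -> str:
    """I.i.d. random genome with the requested GC content."""
    rng = np.random.default_rng(seed)
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    codes = rng.choice(_NT, size=length, p=[p_at, p_gc, p_gc, p_at])
    return codes.tobytes().decode("ascii")


def mutate_nt(seq: str, divergence: float, seed=0) -> str:
    """Substitute a ``divergence`` fraction of positions with a different base."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < divergence)[0]
    for i in hit:
        choices = _NT[_NT != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def random_protein(length: int, seed=0) -> str:
    rng = np.random.default_rng(seed)
    return rng.choice(_AA, size=length).tobytes().decode("ascii")


def random_proteome(n: int, length: int = 150, seed=0) -> dict:
    rng = np.random.default_rng(seed)
    return {f"prot{i + 1:04d}": random_protein(length, rng.integers(2**31)) for i in range(n)}


def mutate_protein(seq: str, divergence: float, seed=0) -> str:
    """Substitute a ``divergence`` fraction of residues with a different one."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < divergence)[0]
    for i in hit:
        choices = _AA[_AA != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def sample_reads(genome: str, n: int, read_len: int = 500, seed=0, prefix: str = "read") -> dict:
    """Error-free reads at uniform random positions (forward strand)."""
    if read_len > len(genome):
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(genome) - read_len + 1, size=n)
    return {f"{prefix}{i + 1:04d}": genome[s : s + read_len] for i, s in enumerate(starts)}
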