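"""Genome mappability: per-position multi-mapping counts at read length L.

The count at position i is the number of genomic L-mer start positions
whose L-mer lies within Hamming distance m of the L-mer starting at i
(always >= 1: an L-mer matches itself).  The implementation uses a
pigeonhole seed index (split each L-mer into m+1 chunks; two L-mers within
m mismatches must agree exactly on at least one chunk) with vectorized
Hamming verification, so it stays independent of the brute-force all-pairs
oracle used in the tests.

L-mers containing N match nothing: they keep count 1 and are flagged
low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from polymirts.config import PipelineConfig
from polymirts.core_io import SNPRecord, reverse_complement

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class MappabilityTrack:
    """Per-contig multi-mapping counts, one per L-mer start position."""

    counts: dict[str, np.ndarray]
    read_length: int
    mismatches: int
    both_strands: bool = False
    #: per-contig boolean vectors marking N-containing (low confidence) L-mers
    n_flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig, vec in self.counts.items():
            if len(vec) and vec.min() < 1:
                raise ValueError(f"contig {contig}: mappability count < 1")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _lmer_matrix(encoded: np.ndarray, L: int) -> np.ndarray:
    """View of all L-mers of one contig as an (n-L+1, L) byte matrix."""
    n = len(encoded) - L + 1
    return np.lib.stride_tricks.as_strided(
        encoded, shape=(n, L), strides=(encoded.strides[0],) * 2
    )


def compute_mappability(genome: Mapping[str, str], L: int, m: int,
                        both_strands: bool = False) -> MappabilityTrack:
    """Count, for every position, how many genomic positions its L-mer hits.

    With ``both_strands`` the reverse complements of all genomic L-mers are
    additional match targets (a palindromic L-mer then matches itself twice).
    """
    if m < 0:
        raise ValueError("mismatches must be non-negative")
    contigs = list(genome)
    for contig in contigs:
        if L > len(genome[contig]):
            raise ValueError(
                f"read length {L} exceeds contig {contig} length {len(genome[contig])}"
            )

    # target L-mers: forward strand of every contig (+ reverse complements)
    target_rows = []
    for contig in contigs:
        target_rows.append(_lmer_matrix(_encode(genome[contig]), L))
        if both_strands:
            target_rows.append(_lmer_matrix(_encode(reverse_complement(genome[contig])), L))
    targets = np.ascontiguousarray(np.vstack(target_rows))
    target_ok = ~(targets == ord("N")).any(axis=1)

    # pigeonhole index: m+1 chunks; any match within m mismatches agrees
    # exactly on at least one chunk
    n_chunks = m + 1
    bounds = np.linspace(0, L, n_chunks + 1, dtype=int)
    index: dict[tuple[int, bytes], list[int]] = {}
    for t in np.flatnonzero(target_ok):
        row = targets[t]
        for c in range(n_chunks):
            chunk = row[bounds[c]:bounds[c + 1]].tobytes()
            index.setdefault((c, chunk), []).append(t)

    counts: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for contig in contigs:
        lmers = _lmer_matrix(_encode(genome[contig]), L)
        n = lmers.shape[0]
        vec = np.ones(n, dtype=np.int64)
        flag = (lmers == ord("N")).any(axis=1)
        for i in range(n):
            if flag[i]:
                continue
            row = np.ascontiguousarray(lmers[i])
            cand: set[int] = set()
            for c in range(n_chunks):
                chunk = row[bounds[c]:bounds[c + 1]].tobytes()
                cand.update(index.get((c, chunk), ()))
            cand_idx = np.fromiter(cand, dtype=np.int64, count=len(cand))
            hits = int(
                ((targets[cand_idx] != row).sum(axis=1) <= m).sum()
            )
            # the position's own L-mer is always among the forward targets
            vec[i] = max(hits, 1)
        counts[contig] = vec
        flags[contig] = flag
    return MappabilityTrack(counts=counts, read_length=L, mismatches=m,
                            both_strands=both_strands, n_flags=flags)


def snp_window_mappability(track: MappabilityTrack, contig: str,
                           position0: int, L: int | None = None) -> float:
    """Mean mappability count over the 2L window around a SNP.

    The window is ``[position0 - L, position0 + L)`` in 0-based L-mer start
    space, clipped to the valid start positions of the contig.
    """
    if contig not in track.counts:
        raise KeyError(f"contig {contig!r} not in mappability track")
    L = track.read_length if L is None else L
    vec = track.counts[contig]
    lo = max(0, position0 - L)
    hi = min(len(vec), position0 + L)
    if hi <= lo:
        raise ValueError(
            f"no valid L-mer start in window around {contig}:{position0}"
        )
    return float(vec[lo:hi].mean())


def filter_by_mappability(
    snps: Sequence[SNPRecord], track: MappabilityTrack,
    config: PipelineConfig | None = None,
) -> tuple[list[SNPRecord], list[tuple[SNPRecord, float]]]:
    """Keep SNPs whose window-averaged mappability equals the retain value
    (1.0: reads over the site map back uniquely); others are returned with
    the computed average attached."""
    config = config or PipelineConfig()
    retained: list[SNPRecord] = []
    rejected: list[tuple[SNPRecord, float]] = []
    for snp in snps:
        value = snp_window_mappability(track, snp.contig, snp.position0)
        if value == config.mappability_retain_value:
            retained.append(snp)
        else:
            rejected.append((snp, value))
    return retained, rejected


def write_bedgraph(path: str | Path, track: MappabilityTrack) -> None:
    """Write the track as BedGraph, merging runs of equal counts."""
    lines = []
    for contig in track.counts:
        vec = track.counts[contig]
        if len(vec) == 0:
            continue
        run_start = 0
        for i in range(1, len(vec) + 1):
            if i == len(vec) or vec[i] != vec[run_start]:
                lines.append(f"{contig}\t{run_start}\t{i}\t{int(vec[run_start])}")
                run_start = i
    Path(path).write_text("\n".join(lines) + "\n")
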