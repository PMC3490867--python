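"""Independent oracles used by the test suite.

Each function here deliberately re-derives its result by brute force or
closed form, without calling the implementation path it is used to check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def revcomp_dna(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def brute_force_seed_sites(utr: str, mirna_seq: str) -> set[tuple[int, int, str]]:
    """Exhaustive scan: try all four canonical patterns at every offset,
    keeping the maximal (most specific) type per core occurrence."""
    utr = utr.upper()
    rna = mirna_seq.upper().replace("T", "U")
    seed7 = rna[1:8]
    seed6 = rna[1:7]
    p8 = revcomp_dna(seed7) + "A"
    p7m8 = revcomp_dna(seed7)
    p7a1 = revcomp_dna(seed6) + "A"
    p6 = revcomp_dna(seed6)
    hits: set[tuple[int, int, str]] = set()
    n = len(utr)
    for i in range(n):
        for pattern, kind in ((p8, "8mer"), (p7m8, "7mer-m8"),
                              (p7a1, "7mer-A1"), (p6, "6mer")):
            j = i + len(pattern)
            if j > n or utr[i:j] != pattern or "N" in utr[i:j]:
                continue
            hits.add((i, j, kind))
    # maximality: per seed-core occurrence keep only the longest site type
    by_core: dict[int, tuple[int, int, str]] = {}
    for start, end, kind in hits:
        core = start + 1 if kind in ("8mer", "7mer-m8") else start
        best = by_core.get(core)
        if best is None or end - start > best[1] - best[0]:
            by_core[core] = (start, end, kind)
    return set(by_core.values())


def brute_force_mappability(genome: dict[str, str], L: int, m: int) -> dict[str, np.ndarray]:
    """All-pairs Hamming comparison over every L-mer of the genome."""
    rows = []
    spans = {}
    offset = 0
    for contig, seq in genome.items():
        enc = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        n = len(enc) - L + 1
        lmers = np.lib.stride_tricks.sliding_window_view(enc, L)
        rows.append(lmers)
        spans[contig] = (offset, offset + n)
        offset += n
    allrows = np.vstack(rows)
    total = allrows.shape[0]
    has_n = (allrows == ord("N")).any(axis=1)
    counts = np.ones(total, dtype=np.int64)
    for i in range(total):
        if has_n[i]:
            continue
        dist = (allrows != allrows[i]).sum(axis=1)
        counts[i] = int(((dist <= m) & ~has_n).sum())
    return {c: counts[a:b] for c, (a, b) in spans.items()}


def binomial_two_sided_oracle(a: int, b: int) -> float:
    """Closed-form doubled-tail p-value for the symmetric exact binomial."""
    n = a + b
    lo = min(a, b)
    tail = sum(comb(n, k) for k in range(lo + 1))
    p = Fraction(2 * tail, 2 ** n)
    return float(min(p, Fraction(1)))


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Full hypergeometric enumeration with exact rational arithmetic."""
    r1, r2, col1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, col1)
    observed = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, col1 - r2), min(r1, col1) + 1):
        w = comb(r1, k) * comb(r2, col1 - k)
        if w <= observed:
            total += w
    return float(min(Fraction(total, denom), Fraction(1)))
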