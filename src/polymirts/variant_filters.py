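"""Candidate SNP filters, novel/known merging, and UTR coverage.

Quality and depth minima are inclusive (>=); the UTR coverage rule is
strict (a UTR qualifies as covered only when *more than* half of its bases
see at least one read).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from polymirts.config import PipelineConfig
from polymirts.core_io import SNPRecord, UTRRecord


@dataclass
class DepthTrack:
    """Per-base read depth for each contig."""

    depths: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for contig, vec in self.depths.items():
            vec = np.asarray(vec)
            if len(vec) and vec.min() < 0:
                raise ValueError(f"contig {contig}: negative depth")
            self.depths[contig] = vec


def filter_candidate_snps(
    snps: Sequence[SNPRecord],
    utrs: Sequence[UTRRecord],
    config: PipelineConfig | None = None,
) -> list[SNPRecord]:
    """Retain SNPs with quality >= minimum, depth >= minimum, and position
    inside at least one annotated 3'-UTR interval."""
    config = config or PipelineConfig()
    intervals: dict[str, list[tuple[int, int]]] = {}
    for utr in utrs:
        intervals.setdefault(utr.contig, []).append((utr.start, utr.end))
    retained = []
    for snp in snps:
        if snp.quality < config.min_snp_quality:
            continue
        if snp.depth < config.min_depth:
            continue
        pos0 = snp.position0
        if any(start <= pos0 < end for start, end in intervals.get(snp.contig, ())):
            retained.append(snp)
    return retained


def merge_with_known(novel_snps: Sequence[SNPRecord],
                     known_snps: Sequence[SNPRecord]) -> list[SNPRecord]:
    """Union of novel and known SNPs keyed by (contig, position, ref, alt).

    A key present in both lists collapses to a single record (the novel
    record's call metadata) with provenance ``both``.
    """
    merged: dict[tuple, SNPRecord] = {}
    for snp in novel_snps:
        merged[snp.key] = replace(snp, provenance="novel")
    for snp in known_snps:
        if snp.key in merged:
            merged[snp.key] = replace(merged[snp.key], provenance="both")
        else:
            merged[snp.key] = replace(snp, provenance="known")
    return sorted(merged.values(), key=lambda s: s.key)


def utr_coverage_fraction(depth: DepthTrack, utr: UTRRecord,
                          threshold: float = 0.5) -> tuple[float, bool]:
    """Fraction of UTR bases with depth >= 1, and the strict coverage call."""
    if utr.contig not in depth.depths:
        raise KeyError(f"contig {utr.contig!r} missing from depth track")
    vec = depth.depths[utr.contig]
    if utr.end > len(vec):
        raise ValueError(
            f"UTR {utr.transcript_id} [{utr.start}, {utr.end}) exceeds depth "
            f"track length {len(vec)}"
        )
    window = vec[utr.start:utr.end]
    fraction = float((window >= 1).sum() / len(window))
    return fraction, fraction > threshold


def region_read_proportion(region_read_count: int, total_mapped: int) -> float:
    """Percentage of mapped reads in a region, half-up rounded to 1 decimal."""
    if total_mapped <= 0:
        raise ZeroDivisionError("total mapped read count must be positive")
    if region_read_count > total_mapped:
        raise ValueError("region read count exceeds total mapped")
    pct = Decimal(100 * region_read_count) / Decimal(total_mapped)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Depth track I/O (BedGraph) and coverage report
# ---------------------------------------------------------------------------

def read_depth_bedgraph(path: str | Path,
                        contig_lengths: Mapping[str, int]) -> DepthTrack:
    """Load a per-base depth track from BedGraph (absent intervals = 0)."""
    depths = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        contig, start, end, value = line.split("\t")[:4]
        if contig not in depths:
            raise KeyError(f"{path}:{line_no}: unknown contig {contig!r}")
        depths[contig][int(start):int(end)] = int(value)
    return DepthTrack(depths=depths)


def write_depth_bedgraph(path: str | Path, track: DepthTrack) -> None:
    lines = []
    for contig, vec in track.depths.items():
        run_start = 0
        for i in range(1, len(vec) + 1):
            if i == len(vec) or vec[i] != vec[run_start]:
                if vec[run_start] != 0:
                    lines.append(f"{contig}\t{run_start}\t{i}\t{int(vec[run_start])}")
                run_start = i
    Path(path).write_text("\n".join(lines) + "\n")


def write_coverage_report(path: str | Path, depth: DepthTrack,
                          utrs: Sequence[UTRRecord],
                          threshold: float = 0.5) -> None:
    lines = ["gene\ttranscript\tfraction_covered\tcovered"]
    for utr in utrs:
        fraction, covered = utr_coverage_fraction(depth, utr, threshold)
        lines.append(
            f"{utr.gene_id}\t{utr.transcript_id}\t{fraction:.4f}\t{str(covered).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
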