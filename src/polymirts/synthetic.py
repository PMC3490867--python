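"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of their arguments (including the seed).
Scenario ground truth is verified at generation time with an internal
pattern scanner that is written independently of the prediction module, so
recovery tests isolate pipeline defects from generator defects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from polymirts.coexpression import AllelicCounts
from polymirts.core_io import (
    MatureMiRNA,
    SNPRecord,
    UTRRecord,
    extract_utr_sequences,
    write_bed6_utrs,
    write_fasta,
    write_vcf,
)

_BASES = "ACGT"
_RNA_BASES = "ACGU"
MAX_RETRIES = 1000


class GenerationError(RuntimeError):
    """Raised when collision-free placement fails within the retry budget."""


# ---------------------------------------------------------------------------
# Internal canonical-site scanner (independent of the prediction module)
# ---------------------------------------------------------------------------

def _canonical_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """Target-strand DNA patterns per canonical type, via Biopython."""
    seed7_dna = str(Seq(mirna.seed7).back_transcribe().reverse_complement())
    seed6_dna = str(Seq(mirna.seed6).back_transcribe().reverse_complement())
    return {
        "8mer": seed7_dna + "A",
        "7mer-m8": seed7_dna,
        "7mer-A1": seed6_dna + "A",
        "6mer": seed6_dna,
    }


def scan_canonical_sites(sequence: str,
                         mirnas: Sequence[MatureMiRNA]) -> set[tuple[str, int, int, str]]:
    """All maximal canonical sites as (mirna, start, end, type) tuples.

    Pattern-match based: each core-6 occurrence is promoted to the most
    specific type supported by its flanking bases.
    """
    seq = sequence.upper()
    found = set()
    for mirna in mirnas:
        patterns = _canonical_patterns(mirna)
        core = patterns["6mer"]
        m8 = patterns["7mer-m8"][0]
        pos = seq.find(core)
        while pos != -1:
            left = pos > 0 and seq[pos - 1] == m8
            right = pos + 6 < len(seq) and seq[pos + 6] == "A"
            if left and right:
                hit = (mirna.name, pos - 1, pos + 7, "8mer")
            elif left:
                hit = (mirna.name, pos - 1, pos + 6, "7mer-m8")
            elif right:
                hit = (mirna.name, pos, pos + 7, "7mer-A1")
            else:
                hit = (mirna.name, pos, pos + 6, "6mer")
            if "N" not in seq[hit[1]:hit[2]]:
                found.add(hit)
            pos = seq.find(core, pos + 1)
    return found


# ---------------------------------------------------------------------------
# miRNAs
# ---------------------------------------------------------------------------

def synth_mirnas(n: int, rng_seed: int) -> list[MatureMiRNA]:
    """n random 22-nt miRNAs with pairwise-distinct seed7 sequences."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 4 ** 7:
        raise ValueError(f"cannot draw {n} distinct seed7 sequences (capacity {4**7})")
    rng = np.random.default_rng(rng_seed)
    mirnas: list[MatureMiRNA] = []
    seeds: set[str] = set()
    for _ in range(MAX_RETRIES * max(1, n)):
        if len(mirnas) == n:
            break
        seq = "".join(rng.choice(list(_RNA_BASES), size=22))
        mirna = MatureMiRNA(f"mir-{len(mirnas) + 1:03d}", seq)
        if mirna.seed7 in seeds:
            continue
        seeds.add(mirna.seed7)
        mirnas.append(mirna)
    else:
        raise GenerationError(f"could not draw {n} distinct seeds")
    return mirnas


# ---------------------------------------------------------------------------
# Poly-miRTS scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted created or disrupted site."""

    snp_label: str
    gene_id: str
    mirna_name: str
    start: int  # UTR sequence offsets of the intended canonical site
    end: int
    site_type: str


@dataclass
class ScenarioTruth:
    """What the generator planted, for recovery scoring."""

    created: list[PlantedSite] = field(default_factory=list)
    disrupted: list[PlantedSite] = field(default_factory=list)
    neutral_snps: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "created": [asdict(s) for s in self.created],
                "disrupted": [asdict(s) for s in self.disrupted],
                "neutral_snps": list(self.neutral_snps),
            },
            indent=2,
        )


_PAD = 10  # flank of genome sequence around each UTR interval
_SLOT_SPACING = 40
_DEFECT_OFFSET = 3  # position inside the 8mer pattern carrying the SNP


def synth_polymirts_scenario(
    n_genes: int,
    mirnas: Sequence[MatureMiRNA],
    n_created: int,
    n_disrupted: int,
    n_neutral: int,
    utr_len: int = 200,
    rng_seed: int = 0,
) -> tuple[dict[str, str], list[UTRRecord], list[SNPRecord], ScenarioTruth]:
    """Generate a genome of 3'-UTRs with planted site-affecting SNPs.

    Each created SNP turns a near-miss into an 8mer present only in the
    variant allele; each disrupted SNP breaks a planted reference 8mer;
    neutral SNPs change no site for any scenario miRNA.  Every allele pair
    is verified by the internal scanner before being accepted.

    Returns ``(genome, utrs, snps, truth)``.
    """
    if utr_len < 60:
        raise ValueError("utr_len must be >= 60")
    slots = list(range(20, utr_len - 20 - _SLOT_SPACING + 1, _SLOT_SPACING)) or [20]
    capacity = n_genes * len(slots)
    n_features = n_created + n_disrupted + n_neutral
    if n_features > capacity:
        raise GenerationError(
            f"{n_features} features exceed capacity {capacity} "
            f"({n_genes} genes x {len(slots)} slots)"
        )
    if not mirnas:
        raise ValueError("at least one miRNA is required")

    rng = np.random.default_rng(rng_seed)
    # feature plan: kind + miRNA per (gene, slot), round-robin over genes
    plan: list[list[tuple[str, MatureMiRNA | None]]] = [[] for _ in range(n_genes)]
    kinds = ["created"] * n_created + ["disrupted"] * n_disrupted + ["neutral"] * n_neutral
    for i, kind in enumerate(kinds):
        mirna = mirnas[int(rng.integers(len(mirnas)))] if kind != "neutral" else None
        plan[i % n_genes].append((kind, mirna))

    genome: dict[str, str] = {}
    annotation = []
    snps: list[SNPRecord] = []
    truth = ScenarioTruth()
    for g in range(n_genes):
        contig = f"g{g:03d}"
        gene_id = f"gene{g:03d}"
        for attempt in range(MAX_RETRIES):
            result = _build_gene(contig, gene_id, plan[g], slots, utr_len,
                                 mirnas, rng)
            if result is not None:
                break
        else:
            raise GenerationError(f"could not place features in gene {gene_id}")
        seq, gene_snps, gene_truth = result
        pad_left = "".join(rng.choice(list(_BASES), size=_PAD))
        pad_right = "".join(rng.choice(list(_BASES), size=_PAD))
        genome[contig] = pad_left + seq + pad_right
        annotation.append((contig, _PAD, _PAD + utr_len, gene_id, gene_id, "+"))
        snps.extend(gene_snps)
        truth.created.extend(gene_truth.created)
        truth.disrupted.extend(gene_truth.disrupted)
        truth.neutral_snps.extend(gene_truth.neutral_snps)
    utrs = extract_utr_sequences(genome, annotation)
    return genome, utrs, snps, truth


def _build_gene(
    contig: str,
    gene_id: str,
    features: list[tuple[str, MatureMiRNA | None]],
    slots: list[int],
    utr_len: int,
    mirnas: Sequence[MatureMiRNA],
    rng: np.random.Generator,
):
    """One attempt at building a gene; returns None when the scan rejects it."""
    utr = list(rng.choice(list(_BASES), size=utr_len))
    planted: list[tuple[str, MatureMiRNA | None, int, str, str]] = []
    for (kind, mirna), slot in zip(features, slots):
        if kind == "neutral":
            offset = slot + _DEFECT_OFFSET
            ref_base = utr[offset]
            alt_base = str(rng.choice([b for b in _BASES if b != ref_base]))
            planted.append((kind, None, offset, ref_base, alt_base))
            continue
        pattern = _canonical_patterns(mirna)["8mer"]
        site_base = pattern[_DEFECT_OFFSET]
        other = str(rng.choice([b for b in _BASES if b != site_base]))
        if kind == "created":
            ref_pattern = (pattern[:_DEFECT_OFFSET] + other
                           + pattern[_DEFECT_OFFSET + 1:])
            ref_base, alt_base = other, site_base
        else:
            ref_pattern = pattern
            ref_base, alt_base = site_base, other
        utr[slot:slot + len(pattern)] = list(ref_pattern)
        planted.append((kind, mirna, slot + _DEFECT_OFFSET, ref_base, alt_base))

    ref_seq = "".join(utr)
    gene_snps = []
    gene_truth = ScenarioTruth()
    ref_sites = scan_canonical_sites(ref_seq, mirnas)
    for kind, mirna, offset, ref_base, alt_base in planted:
        var_seq = ref_seq[:offset] + alt_base + ref_seq[offset + 1:]
        var_sites = scan_canonical_sites(var_seq, mirnas)
        gained = var_sites - ref_sites
        lost = ref_sites - var_sites
        position = _PAD + offset + 1  # 1-based genome coordinate (+ strand)
        label = f"{contig}:{position}{ref_base}>{alt_base}"
        site_start = offset - _DEFECT_OFFSET
        intended = None
        if mirna is not None:
            intended = (mirna.name, site_start, site_start + 8, "8mer")
        if kind == "created" and not (gained == {intended} and not lost):
            return None
        if kind == "disrupted" and not (lost == {intended} and not gained):
            return None
        if kind == "neutral" and (gained or lost):
            return None
        snp = SNPRecord(
            contig=contig, position=position, ref_allele=ref_base,
            alt_allele=alt_base, quality=99.0, depth=30,
            allele_counts={"s1": (15, 15)}, provenance="novel",
        )
        gene_snps.append(snp)
        if kind == "created":
            gene_truth.created.append(
                PlantedSite(snp.label, gene_id, mirna.name, site_start,
                            site_start + 8, "8mer"))
        elif kind == "disrupted":
            gene_truth.disrupted.append(
                PlantedSite(snp.label, gene_id, mirna.name, site_start,
                            site_start + 8, "8mer"))
        else:
            gene_truth.neutral_snps.append(snp.label)
    return ref_seq, gene_snps, gene_truth


# ---------------------------------------------------------------------------
# Repeat genome for mappability testing
# ---------------------------------------------------------------------------

def synth_repeat_genome(
    unique_len: int,
    repeat_len: int,
    n_copies: int,
    divergence: int = 0,
    rng_seed: int = 0,
    L: int = 35,
    m: int = 0,
) -> tuple[str, list[tuple[int, int]]]:
    """A genome of spacer-interleaved repeat copies with known multi-mapping.

    Layout: ``spacer + copy_1 + spacer + copy_2 + ...`` where every copy of
    the master repeat carries ``divergence`` private substitutions.  The
    returned intervals merge the positions whose L-mer (fully inside a copy)
    matches the aligned L-mer of another copy within ``m`` mismatches.
    """
    if repeat_len < L:
        raise ValueError("repeat_len must be >= L")
    rng = np.random.default_rng(rng_seed)
    spacer_lens = [unique_len] * (n_copies + 1)
    master = rng.choice(list(_BASES), size=repeat_len)
    copies = []
    diff_offsets: list[set[int]] = []
    for _ in range(n_copies):
        copy = master.copy()
        offsets = set()
        if divergence:
            offsets = set(rng.choice(repeat_len, size=divergence, replace=False).tolist())
            for off in offsets:
                copy[off] = rng.choice([b for b in _BASES if b != copy[off]])
        copies.append(copy)
        diff_offsets.append(offsets)

    parts = []
    copy_starts = []
    cursor = 0
    for i in range(n_copies):
        spacer = "".join(rng.choice(list(_BASES), size=spacer_lens[i]))
        parts.append(spacer)
        cursor += len(spacer)
        copy_starts.append(cursor)
        parts.append("".join(copies[i]))
        cursor += repeat_len
    parts.append("".join(rng.choice(list(_BASES), size=spacer_lens[-1])))
    genome = "".join(parts)

    positions = []
    for i in range(n_copies):
        for off in range(repeat_len - L + 1):
            window_i = copies[i][off:off + L]
            for j in range(n_copies):
                if j == i:
                    continue
                window_j = copies[j][off:off + L]
                if int((window_i != window_j).sum()) <= m:
                    positions.append(copy_starts[i] + off)
                    break
    intervals: list[tuple[int, int]] = []
    for pos in sorted(positions):
        if intervals and pos == intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], pos + 1)
        else:
            intervals.append((pos, pos + 1))
    return genome, intervals


# ---------------------------------------------------------------------------
# Expression / allelic counts
# ---------------------------------------------------------------------------

def synth_allelic_counts(
    true_proportions: Mapping[tuple[str, str], float],
    depth: int,
    rng_seed: int = 0,
) -> dict[tuple[str, str], AllelicCounts]:
    """Binomially sampled ref/var read counts at the given true reference
    proportions (one cell per (snp, tissue) key)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out = {}
    for (snp_id, tissue), p in sorted(true_proportions.items()):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
        ref = int(rng.binomial(depth, p))
        out[(snp_id, tissue)] = AllelicCounts(snp_id, tissue, ref, depth - ref)
    return out


@dataclass(frozen=True)
class ExpressionPair:
    """One (SNP, miRNA, gene) trio entering the co-expression analysis."""

    snp_id: str
    mirna_name: str
    gene_id: str
    status: str  # created | disrupted

    @property
    def pair_id(self) -> str:
        return f"{self.snp_id}|{self.mirna_name}"


def synth_expression_pairs(n_pairs: int, n_inverse: int,
                           rng_seed: int = 0) -> tuple[list[ExpressionPair], set[str]]:
    """n_pairs disjoint trios; a seeded subset of size n_inverse is marked
    for inverse-expression planting."""
    if n_inverse > n_pairs:
        raise ValueError("n_inverse cannot exceed n_pairs")
    rng = np.random.default_rng(rng_seed)
    pairs = [
        ExpressionPair(
            snp_id=f"snp{i:03d}", mirna_name=f"mirX-{i:03d}",
            gene_id=f"geneX{i:03d}",
            status="created" if i % 2 == 0 else "disrupted",
        )
        for i in range(n_pairs)
    ]
    chosen = rng.choice(n_pairs, size=n_inverse, replace=False)
    inverse_ids = {pairs[i].pair_id for i in chosen}
    return pairs, inverse_ids


def synth_expression_matrix(
    pairs: Sequence[ExpressionPair],
    n_tissues: int,
    inverse_pairs: set[str],
    rng_seed: int = 0,
    depth: int = 300,
) -> tuple[
    dict[tuple[str, str], float],
    dict[tuple[str, str], float],
    dict[tuple[str, str], AllelicCounts],
]:
    """Tissue expression with planted inverse miRNA/targeted-allele structure.

    Planted pairs get strictly increasing miRNA expression across tissues
    and strictly decreasing targeted-allele proportions (0.8 -> 0.2 at the
    given depth, large enough for Fisher significance); non-planted pairs
    are rank-concordant instead.  Returns (miRNA read counts, mRNA FPKM,
    allelic counts), all keyed by (feature, tissue).
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    rng = np.random.default_rng(rng_seed)
    tissues = [f"tissue{t}" for t in range(n_tissues)]
    mirna_counts: dict[tuple[str, str], float] = {}
    mrna_fpkm: dict[tuple[str, str], float] = {}
    allelic: dict[tuple[str, str], AllelicCounts] = {}
    proportions = np.linspace(0.8, 0.2, n_tissues)
    for pair in pairs:
        base = float(rng.integers(20, 40))
        levels = [base * (2 ** t) for t in range(n_tissues)]  # strictly increasing
        planted = pair.pair_id in inverse_pairs
        for t, tissue in enumerate(tissues):
            mirna_counts[(pair.mirna_name, tissue)] = levels[t]
            mrna_fpkm[(pair.gene_id, tissue)] = 5.0 + float(rng.random())
            targeted = proportions[t] if planted else proportions[n_tissues - 1 - t]
            targeted_reads = int(round(depth * targeted))
            other_reads = depth - targeted_reads
            if pair.status == "created":  # targeted allele is the variant
                ref_reads, var_reads = other_reads, targeted_reads
            else:
                ref_reads, var_reads = targeted_reads, other_reads
            allelic[(pair.snp_id, tissue)] = AllelicCounts(
                pair.snp_id, tissue, ref_reads, var_reads)
    return mirna_counts, mrna_fpkm, allelic


# ---------------------------------------------------------------------------
# Scenario directory writer
# ---------------------------------------------------------------------------

def write_scenario(
    out_dir: str | Path,
    genome: Mapping[str, str],
    utrs: Sequence[UTRRecord],
    snps: Sequence[SNPRecord],
    truth: ScenarioTruth,
    mirnas: Sequence[MatureMiRNA],
    depth: int = 30,
) -> None:
    """Write a complete scenario directory in the dialects the pipeline
    reads: genome.fa, utrs.bed, mirnas.fa, snps.vcf, depth.bedgraph and
    truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", genome)
    write_bed6_utrs(out / "utrs.bed", utrs)
    write_fasta(out / "mirnas.fa", {m.name: m.sequence for m in mirnas})
    write_vcf(out / "snps.vcf", snps,
              contig_lengths={c: len(s) for c, s in genome.items()})
    depth_lines = [f"{c}\t0\t{len(s)}\t{depth}" for c, s in genome.items()]
    (out / "depth.bedgraph").write_text("\n".join(depth_lines) + "\n")
    (out / "truth.json").write_text(truth.to_json() + "\n")
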