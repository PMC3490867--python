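"""Domain types, standard-format I/O and 3'-UTR allele construction.

Coordinates are 0-based half-open internally; VCF positions are 1-based and
converted exactly once at the parsing boundary.  All site prediction operates
on the sense-orientation UTR sequence, so minus-strand records store the
reverse complement of the genomic slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGU")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_DNA_COMPLEMENT)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA with its derived seed subsequences.

    ``seed6`` spans miRNA nucleotides 2-7 and ``seed7`` nucleotides 2-8
    (1-based numbering from the 5' end).  miRNAs sharing ``seed7`` belong to
    the same targeting family.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not set(seq) <= RNA_ALPHABET:
            bad = sorted(set(seq) - RNA_ALPHABET)
            raise ValueError(f"miRNA {self.name}: non-RNA characters {bad}")
        if not 18 <= len(seq) <= 25:
            raise ValueError(
                f"miRNA {self.name}: length {len(seq)} outside [18, 25]"
            )

    @property
    def seed6(self) -> str:
        return self.sequence[1:7]

    @property
    def seed7(self) -> str:
        return self.sequence[1:8]

    @property
    def family_key(self) -> str:
        return self.seed7


@dataclass(frozen=True)
class UTRRecord:
    """A 3'-UTR allele: genomic interval plus sense-orientation sequence.

    ``known_mask`` holds sequence offsets whose base is *unknown* (e.g. a
    truncated allele); downstream classification must not call a reference
    site disrupted when it overlaps unknown sequence.
    """

    gene_id: str
    transcript_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    known_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "known_mask", frozenset(self.known_mask))
        if self.end <= self.start:
            raise ValueError(f"UTR {self.transcript_id}: end <= start")
        if self.strand not in "+-":
            raise ValueError(f"UTR {self.transcript_id}: bad strand {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"UTR {self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start}"
            )
        if not set(self.sequence) <= DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise ValueError(f"UTR {self.transcript_id}: non-DNA characters {bad}")
        if self.known_mask and max(self.known_mask) >= len(self.sequence):
            raise ValueError(f"UTR {self.transcript_id}: known_mask offset out of range")

    def __len__(self) -> int:
        return self.end - self.start

    def genome_offset(self, position0: int) -> int:
        """Map a 0-based genome position to a sense-sequence offset."""
        if not self.start <= position0 < self.end:
            raise ValueError(
                f"position {position0} outside UTR {self.transcript_id} "
                f"[{self.start}, {self.end})"
            )
        if self.strand == "+":
            return position0 - self.start
        return self.end - 1 - position0


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic substitution with call metadata and allele read counts.

    ``position`` follows the VCF convention (1-based).  ``allele_counts``
    maps sample name to ``(ref_reads, alt_reads)``.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    quality: float = 0.0
    depth: int = 0
    allele_counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    provenance: str = "novel"
    snp_id: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele_counts", dict(self.allele_counts))
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"SNP at {self.contig}:{self.position}: alleles must be single bases")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP at {self.contig}:{self.position}: ref == alt")
        if self.quality < 0:
            raise ValueError(f"SNP at {self.contig}:{self.position}: negative quality")
        if self.provenance not in ("novel", "known", "both"):
            raise ValueError(f"SNP at {self.contig}:{self.position}: bad provenance")
        for sample, (r, a) in self.allele_counts.items():
            if r < 0 or a < 0:
                raise ValueError(
                    f"SNP at {self.contig}:{self.position}: negative read count for {sample}"
                )

    @property
    def position0(self) -> int:
        """0-based genome position."""
        return self.position - 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)

    @property
    def label(self) -> str:
        if self.snp_id != ".":
            return self.snp_id
        return f"{self.contig}:{self.position}{self.ref_allele}>{self.alt_allele}"


# ---------------------------------------------------------------------------
# Allele construction
# ---------------------------------------------------------------------------

def extract_utr_sequences(
    genome: Mapping[str, str],
    annotation: Iterable[tuple[str, int, int, str, str, str]],
) -> list[UTRRecord]:
    """Slice 3'-UTR sequences out of a genome.

    ``annotation`` yields ``(contig, start, end, gene_id, transcript_id,
    strand)`` tuples with 0-based half-open coordinates.  Minus-strand
    records receive the reverse complement (sense orientation).
    """
    records = []
    for contig, start, end, gene_id, transcript_id, strand in annotation:
        if contig not in genome:
            raise KeyError(f"UTR {transcript_id}: contig {contig!r} not in genome")
        contig_seq = genome[contig]
        if start < 0 or end > len(contig_seq):
            raise ValueError(
                f"UTR {transcript_id}: interval [{start}, {end}) exceeds "
                f"contig {contig} bounds [0, {len(contig_seq)})"
            )
        seq = contig_seq[start:end].upper()
        if strand == "-":
            seq = reverse_complement(seq)
        records.append(
            UTRRecord(
                gene_id=gene_id, transcript_id=transcript_id, contig=contig,
                start=start, end=end, strand=strand, sequence=seq,
            )
        )
    return records


def apply_variant(utr: UTRRecord, snp: SNPRecord) -> UTRRecord:
    """Build the variant allele sequence by applying a single substitution.

    The SNP alleles are given on the genome forward strand; for minus-strand
    UTRs they are complemented onto the sense sequence.  Raises if the SNP
    falls outside the UTR or if the reference base does not match.
    """
    if snp.contig != utr.contig:
        raise ValueError(
            f"SNP {snp.label} on contig {snp.contig}, UTR {utr.transcript_id} "
            f"on {utr.contig}"
        )
    if not utr.start <= snp.position0 < utr.end:
        raise ValueError(
            f"SNP {snp.label} at {snp.position0} outside UTR "
            f"{utr.transcript_id} [{utr.start}, {utr.end})"
        )
    offset = utr.genome_offset(snp.position0)
    if utr.strand == "+":
        ref_sense, alt_sense = snp.ref_allele, snp.alt_allele
    else:
        ref_sense = complement_base(snp.ref_allele)
        alt_sense = complement_base(snp.alt_allele)
    if utr.sequence[offset] != ref_sense:
        raise ValueError(
            f"SNP {snp.label}: UTR {utr.transcript_id} has "
            f"{utr.sequence[offset]!r} at offset {offset}, expected {ref_sense!r}"
        )
    seq = utr.sequence[:offset] + alt_sense + utr.sequence[offset + 1:]
    return replace(utr, sequence=seq)


def deduplicate_utrs(
    records: Sequence[UTRRecord],
) -> tuple[list[UTRRecord], dict[str, int]]:
    """Collapse records with identical full sequences (first seen wins).

    Returns the non-redundant list plus a map from representative
    transcript_id to multiplicity; multiplicities sum to ``len(records)``.
    """
    unique: list[UTRRecord] = []
    by_seq: dict[str, UTRRecord] = {}
    multiplicity: dict[str, int] = {}
    for rec in records:
        rep = by_seq.get(rec.sequence)
        if rep is None:
            by_seq[rec.sequence] = rec
            unique.append(rec)
            multiplicity[rec.transcript_id] = 1
        else:
            multiplicity[rep.transcript_id] += 1
    return unique, multiplicity


def nucleotide_variation(aligned: Sequence[str]) -> float:
    """Column-wise polymorphism fraction of an alignment.

    fraction = (# columns with >=2 distinct non-gap, non-N characters)
             / (# columns with >=2 non-gap characters); 0.0 when no column
    is eligible.  Gap characters are ``-`` and ``.``.
    """
    if len(aligned) < 2:
        raise ValueError("nucleotide_variation needs at least two sequences")
    length = len(aligned[0])
    for i, seq in enumerate(aligned):
        if len(seq) != length:
            raise ValueError(
                f"alignment error: sequence {i} length {len(seq)} != {length}"
            )
    eligible = 0
    polymorphic = 0
    gaps = {"-", "."}
    for col in zip(*[s.upper() for s in aligned]):
        residues = [c for c in col if c not in gaps]
        if len(residues) < 2:
            continue
        eligible += 1
        if len({c for c in residues if c != "N"}) >= 2:
            polymorphic += 1
    return polymorphic / eligible if eligible else 0.0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    return [MatureMiRNA(name, seq) for name, seq in read_fasta(path).items()]


# ---------------------------------------------------------------------------
# 3'-UTR annotation: 6-column BED or GFF3
# ---------------------------------------------------------------------------

def read_utr_annotation(path: str | Path) -> list[tuple[str, int, int, str, str, str]]:
    """Read 3'-UTR intervals from BED6 or GFF3.

    Returns ``(contig, start0, end, gene_id, transcript_id, strand)`` tuples.
    GFF3 rows are filtered to ``three_prime_UTR`` features; BED names are
    used for both gene and transcript id unless they contain ``gene|tx``.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3_utrs(path)
    return _read_bed6_utrs(path)


def _read_bed6_utrs(path: Path) -> list[tuple[str, int, int, str, str, str]]:
    out = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{line_no}: BED6 needs 6 columns, got {len(parts)}")
        contig, start, end, name, _score, strand = parts[:6]
        gene_id, _, transcript_id = name.partition("|")
        out.append((contig, int(start), int(end), gene_id, transcript_id or name, strand))
    return out


def _read_gff3_utrs(path: Path) -> list[tuple[str, int, int, str, str, str]]:
    out = []
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{line_no}: GFF3 needs 9 columns, got {len(parts)}")
        contig, _src, feature, start, end, _score, strand, _frame, attrs = parts
        if feature != "three_prime_UTR":
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        transcript_id = attr.get("ID") or attr.get("Parent") or f"utr_{line_no}"
        gene_id = attr.get("gene_id") or attr.get("gene") or transcript_id
        out.append((contig, int(start) - 1, int(end), gene_id, transcript_id, strand))
    return out


def write_bed6_utrs(path: str | Path, utrs: Sequence[UTRRecord]) -> None:
    lines = []
    for u in utrs:
        name = f"{u.gene_id}|{u.transcript_id}"
        lines.append(f"{u.contig}\t{u.start}\t{u.end}\t{name}\t0\t{u.strand}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=PROV,Number=1,Type=String,Description="SNP provenance: novel, known or both">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">
"""


def read_vcf(path: str | Path) -> list[SNPRecord]:
    """Read biallelic SNPs from a VCF; multi-allelic rows are split.

    Quality is taken from QUAL, depth from INFO/DP and per-sample allele
    counts from FORMAT/AD.  Non-SNP alleles (indels) are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[SNPRecord] = []
    for var in vcf:
        if len(var.REF) != 1:
            continue
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        for alt_index, alt in enumerate(var.ALT):
            if len(alt) != 1 or alt not in "ACGT":
                continue
            counts = {}
            if ad is not None:
                for si, sample in enumerate(samples):
                    ref_reads = max(int(ad[si][0]), 0)
                    alt_reads = max(int(ad[si][1 + alt_index]), 0)
                    counts[sample] = (ref_reads, alt_reads)
            records.append(
                SNPRecord(
                    contig=var.CHROM,
                    position=var.POS,
                    ref_allele=var.REF,
                    alt_allele=alt,
                    quality=float(var.QUAL) if var.QUAL is not None else 0.0,
                    depth=int(var.INFO.get("DP", 0)),
                    allele_counts=counts,
                    provenance=str(var.INFO.get("PROV", "novel")),
                    snp_id=var.ID or ".",
                )
            )
    vcf.close()
    return records


def write_vcf(path: str | Path, snps: Sequence[SNPRecord],
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write SNPs as an uncompressed VCF v4.2 text file."""
    samples: list[str] = []
    for snp in snps:
        for sample in snp.allele_counts:
            if sample not in samples:
                samples.append(sample)
    lines = [_VCF_HEADER.rstrip("\n")]
    if contig_lengths:
        for contig, length in contig_lengths.items():
            lines.append(f"##contig=<ID={contig},length={length}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        header_cols += ["FORMAT"] + samples
    lines.append("\t".join(header_cols))
    for snp in sorted(snps, key=lambda s: (s.contig, s.position, s.alt_allele)):
        qual = f"{snp.quality:g}"
        info = f"DP={snp.depth};PROV={snp.provenance}"
        row = [snp.contig, str(snp.position), snp.snp_id, snp.ref_allele,
               snp.alt_allele, qual, ".", info]
        if samples:
            row.append("AD")
            for sample in samples:
                r, a = snp.allele_counts.get(sample, (0, 0))
                row.append(f"{r},{a}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
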