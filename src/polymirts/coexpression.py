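"""Co-expression gating, allelic-proportion tests and allele-specific
expression.

Both exact tests are implemented with integer arithmetic (``math.comb``), so
the two-sided minimum-likelihood summation is exact: an outcome enters the
p-value iff its point probability is <= the observed one, decided by integer
comparison of binomial coefficients.  No multiple-testing correction is
applied anywhere: the raw thresholds (0.001 for ASE, 0.05 for cross-tissue
allelic proportions) are used as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from polymirts.classify import PolyMiRTS
from polymirts.config import PipelineConfig


@dataclass(frozen=True)
class AllelicCounts:
    """Reference/variant read counts for one SNP in one tissue."""

    snp_id: str
    tissue: str
    ref_reads: int
    var_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.var_reads < 0:
            raise ValueError(f"{self.snp_id}/{self.tissue}: negative read count")

    @property
    def total(self) -> int:
        return self.ref_reads + self.var_reads

    @property
    def ref_proportion(self) -> float:
        if self.total == 0:
            raise ValueError(f"{self.snp_id}/{self.tissue}: no reads")
        return self.ref_reads / self.total


def compute_fpkm(count: float, effective_length_bp: float, total_mapped: float) -> float:
    """Fragments per kilobase of exon model per million mapped reads."""
    if effective_length_bp <= 0:
        raise ValueError("effective length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped read count must be positive")
    return count * 1e9 / (effective_length_bp * total_mapped)


def is_coexpressed(mirna_reads: float, mrna_fpkm: float,
                   config: PipelineConfig | None = None) -> bool:
    """miRNA reads > 10 and mRNA FPKM > 1 (both strict)."""
    config = config or PipelineConfig()
    return mirna_reads > config.coexpr_min_mirna_reads and mrna_fpkm > config.coexpr_min_fpkm


def binomial_ase_test(ref_reads: int, var_reads: int) -> float:
    """Two-sided exact binomial p-value at success probability 0.5.

    Minimum-likelihood summation: every outcome k whose point probability
    is <= that of the observed count contributes.  At p = 0.5 the point
    probabilities reduce to binomial coefficients, so the tie comparison is
    exact integer arithmetic.
    """
    if ref_reads < 0 or var_reads < 0:
        raise ValueError("read counts must be non-negative")
    n = ref_reads + var_reads
    if n == 0:
        raise ValueError("undefined test: zero total reads")
    observed = comb(n, ref_reads)
    numerator = sum(c for k in range(n + 1) if (c := comb(n, k)) <= observed)
    return min(1.0, numerator / 2 ** n)


def fisher_allelic_proportion_test(counts_a: AllelicCounts,
                                   counts_b: AllelicCounts) -> float:
    """Two-sided Fisher exact test on [[ref_a, var_a], [ref_b, var_b]].

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability is <= the observed table's, using exact
    integer comparisons of the coefficient products.
    """
    a, b = counts_a.ref_reads, counts_a.var_reads
    c, d = counts_b.ref_reads, counts_b.var_reads
    r1, r2 = a + b, c + d
    col1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or col1 == 0 or col1 == n:
        raise ValueError("undefined test: a table margin is zero")
    lo = max(0, col1 - r2)
    hi = min(r1, col1)
    observed = comb(r1, a) * comb(r2, c)
    numerator = 0
    for k in range(lo, hi + 1):
        weight = comb(r1, k) * comb(r2, col1 - k)
        if weight <= observed:
            numerator += weight
    return min(1.0, numerator / comb(n, col1))


@dataclass(frozen=True)
class InverseExpressionFlag:
    """A (SNP, miRNA) pair showing the inverse-expression pattern."""

    snp_id: str
    mirna_name: str
    utr_id: str
    status: str
    tissues: tuple[str, ...]
    min_fisher_p: float


def flag_inverse_expression(
    polymirts: Iterable[PolyMiRTS],
    allelic_counts: Mapping[tuple[str, str], AllelicCounts],
    mirna_expression: Mapping[tuple[str, str], float],
    mrna_fpkm: Mapping[tuple[str, str], float],
    config: PipelineConfig | None = None,
) -> list[InverseExpressionFlag]:
    """Flag created/disrupted sites whose targeted allele drops where the
    miRNA is high.

    Keys: ``allelic_counts[(snp_id, tissue)]``,
    ``mirna_expression[(mirna, tissue)]`` (read counts) and
    ``mrna_fpkm[(gene, tissue)]``.  A pair must be co-expressed in >= 2
    tissues.  The targeted allele is the variant for created sites and the
    reference for disrupted sites.  Flagged iff (a) at least one tissue pair
    differs significantly in allelic proportion (Fisher p < 0.05) and (b)
    across every co-expressed tissue pair the tissue with strictly higher
    miRNA expression shows a strictly lower targeted-allele proportion.
    """
    config = config or PipelineConfig()
    flags = []
    seen: set[tuple[str, str, str]] = set()
    for rec in polymirts:
        if rec.status not in ("created", "disrupted"):
            continue
        pair_id = (rec.snp.label, rec.mirna_name, rec.utr_id)
        if pair_id in seen:
            continue
        seen.add(pair_id)
        tissues = sorted({
            t for (mirna, t) in mirna_expression if mirna == rec.mirna_name
        })
        usable = []
        for tissue in tissues:
            counts = allelic_counts.get((rec.snp.label, tissue))
            if counts is None or counts.total == 0:
                continue
            mirna_reads = mirna_expression.get((rec.mirna_name, tissue), 0.0)
            fpkm = mrna_fpkm.get((rec.utr_id, tissue), 0.0)
            if is_coexpressed(mirna_reads, fpkm, config):
                usable.append((tissue, mirna_reads, counts))
        if len(usable) < 2:
            continue
        targeted_is_var = rec.status == "created"

        def targeted_proportion(counts: AllelicCounts) -> float:
            p_ref = counts.ref_proportion
            return 1.0 - p_ref if targeted_is_var else p_ref

        concordant = True
        min_p = 1.0
        for (t1, m1, c1), (t2, m2, c2) in combinations(usable, 2):
            p1, p2 = targeted_proportion(c1), targeted_proportion(c2)
            if m1 == m2 or (m1 - m2) * (p1 - p2) >= 0:
                concordant = False
                break
            min_p = min(min_p, fisher_allelic_proportion_test(c1, c2))
        if concordant and min_p < config.allelic_fisher_alpha:
            flags.append(
                InverseExpressionFlag(
                    snp_id=rec.snp.label, mirna_name=rec.mirna_name,
                    utr_id=rec.utr_id, status=rec.status,
                    tissues=tuple(t for t, _, _ in usable), min_fisher_p=min_p,
                )
            )
    return flags


# ---------------------------------------------------------------------------
# Report writers / readers
# ---------------------------------------------------------------------------

def read_allelic_counts_tsv(path: str | Path) -> dict[tuple[str, str], AllelicCounts]:
    out = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        snp_id, tissue, ref_reads, var_reads = line.split("\t")
        out[(snp_id, tissue)] = AllelicCounts(snp_id, tissue, int(ref_reads), int(var_reads))
    return out


def write_allelic_counts_tsv(path: str | Path,
                             counts: Mapping[tuple[str, str], AllelicCounts]) -> None:
    lines = ["snp\ttissue\tref_reads\tvar_reads"]
    for (snp_id, tissue), c in sorted(counts.items()):
        lines.append(f"{snp_id}\t{tissue}\t{c.ref_reads}\t{c.var_reads}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_tsv(path: str | Path) -> dict[tuple[str, str], float]:
    """Read a (feature, tissue, value) TSV with a header row."""
    out = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        feature, tissue, value = line.split("\t")[:3]
        out[(feature, tissue)] = float(value)
    return out


def write_expression_tsv(path: str | Path, values: Mapping[tuple[str, str], float],
                         feature_col: str = "feature") -> None:
    lines = [f"{feature_col}\ttissue\tvalue"]
    for (feature, tissue), value in sorted(values.items()):
        lines.append(f"{feature}\t{tissue}\t{value:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ase_report(path: str | Path,
                     counts: Mapping[tuple[str, str], AllelicCounts],
                     alpha: float = 0.001) -> None:
    """Run the exact binomial ASE test on every (snp, tissue) cell."""
    lines = ["snp\ttissue\tref_reads\tvar_reads\tp_value\tsignificant"]
    for (snp_id, tissue), c in sorted(counts.items()):
        if c.total == 0:
            continue
        p = binomial_ase_test(c.ref_reads, c.var_reads)
        lines.append(
            f"{snp_id}\t{tissue}\t{c.ref_reads}\t{c.var_reads}\t{p:.6g}"
            f"\t{str(p < alpha).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_inverse_flags(path: str | Path,
                        flags: Sequence[InverseExpressionFlag]) -> None:
    lines = ["snp\tmirna\tgene\tstatus\ttissues\tmin_fisher_p"]
    for f in flags:
        lines.append(
            f"{f.snp_id}\t{f.mirna_name}\t{f.utr_id}\t{f.status}"
            f"\t{','.join(f.tissues)}\t{f.min_fisher_p:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
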