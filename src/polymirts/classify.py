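"""Classification of reference/variant site differences (poly-miRTS).

Sites are matched between alleles by exact key (mirna, start, end, type,
predictor); substitution SNPs preserve coordinates so no gapped matching is
needed.  A site present only in the variant is *created*; present only in
the reference it is *disrupted* — unless its span overlaps unknown variant
sequence, in which case it is *unknown* (truncated alleles must not inflate
the disrupted tally).  A site present in both with a per-predictor score
difference > delta is *perturbed*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from polymirts.core_io import SNPRecord
from polymirts.target_prediction import TargetSite

STATUSES = ("created", "disrupted", "perturbed", "unknown")
PREDICTORS = ("seed_context", "accessibility", "compensatory")


@dataclass(frozen=True)
class PolyMiRTS:
    """One (SNP, miRNA, predictor) classification record."""

    snp: SNPRecord
    mirna_name: str
    utr_id: str
    predictor: str
    status: str
    site_span: tuple[int, int]
    site_type: str
    ref_score: float | None = None
    var_score: float | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "created" and self.ref_score is not None:
            raise ValueError("created site cannot carry a reference score")
        if self.status == "disrupted" and self.var_score is not None:
            raise ValueError("disrupted site cannot carry a variant score")


@dataclass(frozen=True)
class ConsensusSummary:
    """Counts of distinct (mirna, span) sites per Venn region of the three
    predictor sets."""

    seed_context_only: int = 0
    accessibility_only: int = 0
    compensatory_only: int = 0
    seed_context_accessibility: int = 0
    seed_context_compensatory: int = 0
    accessibility_compensatory: int = 0
    all_three: int = 0

    @property
    def total(self) -> int:
        return (self.seed_context_only + self.accessibility_only
                + self.compensatory_only + self.seed_context_accessibility
                + self.seed_context_compensatory + self.accessibility_compensatory
                + self.all_three)


def classify_polymirts(
    ref_sites: Sequence[TargetSite],
    var_sites: Sequence[TargetSite],
    snp: SNPRecord,
    variant_known_mask: Iterable[int] = (),
    perturbation_delta: float = 2.0,
) -> list[PolyMiRTS]:
    """Compare per-predictor site sets between the two alleles of one SNP.

    ``variant_known_mask`` holds the sequence offsets of the variant allele
    whose base is unknown.  Records are emitted for created, disrupted,
    perturbed and unknown differences; identical or sub-threshold sites
    produce no record.
    """
    utr_ids = {s.utr_id for s in ref_sites} | {s.utr_id for s in var_sites}
    if len(utr_ids) > 1:
        raise ValueError(f"site lists span multiple UTRs: {sorted(utr_ids)}")
    utr_id = utr_ids.pop() if utr_ids else ""
    mask = frozenset(variant_known_mask)

    ref_by_key = {s.key: s for s in ref_sites}
    var_by_key = {s.key: s for s in var_sites}
    records = []
    for key, site in ref_by_key.items():
        var = var_by_key.get(key)
        if var is None:
            overlaps_unknown = any(site.start <= off < site.end for off in mask)
            status = "unknown" if overlaps_unknown else "disrupted"
            records.append(
                PolyMiRTS(snp=snp, mirna_name=site.mirna_name, utr_id=utr_id,
                          predictor=site.predictor, status=status,
                          site_span=site.span, site_type=site.site_type,
                          ref_score=site.score, var_score=None)
            )
        elif abs(var.score - site.score) > perturbation_delta:
            records.append(
                PolyMiRTS(snp=snp, mirna_name=site.mirna_name, utr_id=utr_id,
                          predictor=site.predictor, status="perturbed",
                          site_span=site.span, site_type=site.site_type,
                          ref_score=site.score, var_score=var.score)
            )
    for key, site in var_by_key.items():
        if key not in ref_by_key:
            records.append(
                PolyMiRTS(snp=snp, mirna_name=site.mirna_name, utr_id=utr_id,
                          predictor=site.predictor, status="created",
                          site_span=site.span, site_type=site.site_type,
                          var_score=site.score)
            )
    records.sort(key=lambda r: (r.site_span, r.mirna_name, r.predictor, r.status))
    return records


def summarize_consensus(
    seed_context_sites: Iterable[TargetSite],
    accessibility_sites: Iterable[TargetSite],
    compensatory_sites: Iterable[TargetSite],
) -> ConsensusSummary:
    """Partition distinct (mirna, span) sites into the 7 Venn regions."""
    a = {(s.mirna_name, s.span) for s in seed_context_sites}
    b = {(s.mirna_name, s.span) for s in accessibility_sites}
    c = {(s.mirna_name, s.span) for s in compensatory_sites}
    return ConsensusSummary(
        seed_context_only=len(a - b - c),
        accessibility_only=len(b - a - c),
        compensatory_only=len(c - a - b),
        seed_context_accessibility=len((a & b) - c),
        seed_context_compensatory=len((a & c) - b),
        accessibility_compensatory=len((b & c) - a),
        all_three=len(a & b & c),
    )


def tally_created_disrupted(
    records: Iterable[PolyMiRTS],
) -> dict[tuple[str, str], dict[str, int]]:
    """Per-(gene, predictor) created/disrupted/perturbed/unknown counts.

    ``unknown`` records are excluded from the created and disrupted tallies
    and reported under their own key.
    """
    out: dict[tuple[str, str], dict[str, int]] = {}
    for rec in records:
        key = (rec.utr_id, rec.predictor)
        counts = out.setdefault(key, Counter())
        counts[rec.status] += 1
    return {k: {status: c.get(status, 0) for status in STATUSES}
            for k, c in out.items()}


def write_polymirts_table(path: str | Path, records: Sequence[PolyMiRTS]) -> None:
    lines = ["snp_id\tgene\tmirna\tpredictor\tstatus\tsite_start\tsite_end"
             "\tsite_type\tref_score\tvar_score"]
    for r in records:
        ref = "" if r.ref_score is None else f"{r.ref_score:.6g}"
        var = "" if r.var_score is None else f"{r.var_score:.6g}"
        lines.append(
            f"{r.snp.label}\t{r.utr_id}\t{r.mirna_name}\t{r.predictor}\t{r.status}"
            f"\t{r.site_span[0]}\t{r.site_span[1]}\t{r.site_type}\t{ref}\t{var}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_consensus_table(path: str | Path,
                          summaries: dict[str, ConsensusSummary]) -> None:
    lines = ["gene\tseed_context_only\taccessibility_only\tcompensatory_only"
             "\tseed_context+accessibility\tseed_context+compensatory"
             "\taccessibility+compensatory\tall_three\ttotal"]
    for gene, s in sorted(summaries.items()):
        lines.append(
            f"{gene}\t{s.seed_context_only}\t{s.accessibility_only}"
            f"\t{s.compensatory_only}\t{s.seed_context_accessibility}"
            f"\t{s.seed_context_compensatory}\t{s.accessibility_compensatory}"
            f"\t{s.all_three}\t{s.total}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
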