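"""End-to-end orchestration: SNP filters -> mappability -> site prediction
-> poly-miRTS classification -> expression tests, with a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

from polymirts import __version__, classify, coexpression, mappability, variant_filters
from polymirts.config import PipelineConfig
from polymirts.core_io import (
    SNPRecord,
    UTRRecord,
    apply_variant,
    extract_utr_sequences,
    read_fasta,
    read_mirna_fasta,
    read_utr_annotation,
    read_vcf,
    write_vcf,
)
from polymirts.target_prediction import (
    TargetSite,
    find_compensatory_sites,
    predict_accessible_sites,
    predict_seed_context_sites,
    write_site_table,
)

log = logging.getLogger("polymirts")

PREDICTORS = ("seed_context", "accessibility", "compensatory")


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def predict_sites(sequence: str, mirnas, utr_id: str, config: PipelineConfig,
                  predictors: Sequence[str] = PREDICTORS) -> list[TargetSite]:
    sites: list[TargetSite] = []
    for mirna in mirnas:
        if "seed_context" in predictors:
            sites.extend(predict_seed_context_sites(
                sequence, mirna, utr_id, scale=config.score_scale))
        if "accessibility" in predictors:
            sites.extend(predict_accessible_sites(
                sequence, mirna, utr_id, folding_window=config.folding_window))
        if "compensatory" in predictors:
            sites.extend(find_compensatory_sites(sequence, mirna, utr_id))
    return sites


def utr_for_snp(utrs: Sequence[UTRRecord], snp: SNPRecord) -> UTRRecord | None:
    for utr in utrs:
        if utr.contig == snp.contig and utr.start <= snp.position0 < utr.end:
            return utr
    return None


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run every stage described by the config file; returns the output dir.

    Config keys beyond the :class:`PipelineConfig` thresholds (all paths
    relative to the config file's directory):

    - ``genome``, ``utr_annotation``, ``mirnas``, ``snps`` (required)
    - ``known_snps``, ``depth``, ``mirna_counts``, ``mrna_fpkm``,
      ``allelic_counts``, ``predictors``, ``out_dir`` (optional)
    """
    t_start = time.monotonic()
    config_path = Path(config_path)
    config = PipelineConfig.from_file(config_path)
    base = config_path.parent

    def _input(key: str, required: bool = True) -> Path | None:
        value = config.extra.get(key)
        if value is None:
            if required:
                raise StageError("config", f"missing required input key {key!r}")
            return None
        path = (base / value).resolve() if not Path(value).is_absolute() else Path(value)
        if not path.exists():
            raise StageError("config", f"input {key} not found: {path}")
        return path

    out = Path(out_dir or config.extra.get("out_dir") or (base / "out"))
    out.mkdir(parents=True, exist_ok=True)
    predictors = tuple(config.extra.get("predictors", PREDICTORS))
    manifest: dict = {
        "tool_version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "counts": {},
    }

    def stage(name):
        log.info("stage %s (t=%.1fs)", name, time.monotonic() - t_start)

    # --- load inputs -------------------------------------------------------
    stage("load")
    paths = {k: _input(k) for k in ("genome", "utr_annotation", "mirnas", "snps")}
    for key in ("known_snps", "depth", "mirna_counts", "mrna_fpkm", "allelic_counts"):
        paths[key] = _input(key, required=False)
    manifest["inputs"] = {
        k: {"path": str(p), "sha256": _checksum(p)}
        for k, p in paths.items() if p is not None
    }
    try:
        genome = read_fasta(paths["genome"])
        annotation = read_utr_annotation(paths["utr_annotation"])
        utrs = extract_utr_sequences(genome, annotation)
        mirnas = read_mirna_fasta(paths["mirnas"])
        snps = read_vcf(paths["snps"])
    except (ValueError, KeyError, OSError) as exc:
        raise StageError("load", str(exc)) from exc
    manifest["counts"]["utrs"] = len(utrs)
    manifest["counts"]["mirnas"] = len(mirnas)
    manifest["counts"]["snps_input"] = len(snps)

    # --- merge with known SNPs --------------------------------------------
    if paths["known_snps"] is not None:
        stage("merge_known")
        known = read_vcf(paths["known_snps"])
        snps = variant_filters.merge_with_known(snps, known)
        manifest["counts"]["snps_known"] = len(known)
        manifest["counts"]["snps_merged"] = len(snps)

    # --- quality / depth / UTR filters ------------------------------------
    stage("filter_snps")
    retained = variant_filters.filter_candidate_snps(snps, utrs, config)
    manifest["counts"]["snps_after_quality_filter"] = len(retained)

    # --- coverage report ---------------------------------------------------
    if paths["depth"] is not None:
        stage("coverage")
        depth_track = variant_filters.read_depth_bedgraph(
            paths["depth"], {c: len(s) for c, s in genome.items()})
        variant_filters.write_coverage_report(
            out / "coverage.tsv", depth_track, utrs,
            threshold=config.coverage_fraction_threshold)
        covered = sum(
            1 for u in utrs
            if variant_filters.utr_coverage_fraction(
                depth_track, u, config.coverage_fraction_threshold)[1]
        )
        manifest["counts"]["utrs_covered"] = covered

    # --- mappability filter ------------------------------------------------
    stage("mappability")
    track = mappability.compute_mappability(
        genome, config.read_length, config.mismatches,
        both_strands=config.both_strands)
    retained, rejected = mappability.filter_by_mappability(retained, track, config)
    manifest["counts"]["snps_after_mappability_filter"] = len(retained)
    manifest["counts"]["snps_rejected_mappability"] = len(rejected)
    write_vcf(out / "snp_filter.vcf", retained,
              contig_lengths={c: len(s) for c, s in genome.items()})

    # --- site prediction and classification -------------------------------
    stage("predict_classify")
    all_sites: list[TargetSite] = []
    ref_site_cache: dict[str, list[TargetSite]] = {}
    records: list[classify.PolyMiRTS] = []
    for utr in utrs:
        ref_site_cache[utr.transcript_id] = predict_sites(
            utr.sequence, mirnas, utr.transcript_id, config, predictors)
        all_sites.extend(ref_site_cache[utr.transcript_id])
    for snp in retained:
        utr = utr_for_snp(utrs, snp)
        if utr is None:
            continue
        try:
            variant = apply_variant(utr, snp)
        except ValueError as exc:
            raise StageError("predict_classify", str(exc)) from exc
        var_sites = predict_sites(variant.sequence, mirnas,
                                  utr.transcript_id, config, predictors)
        records.extend(
            classify.classify_polymirts(
                ref_site_cache[utr.transcript_id], var_sites, snp,
                variant_known_mask=variant.known_mask,
                perturbation_delta=config.perturbation_delta)
        )
    write_site_table(out / "sites.tsv", all_sites)
    classify.write_polymirts_table(out / "polymirts.tsv", records)
    by_status = {"created": 0, "disrupted": 0, "perturbed": 0, "unknown": 0}
    for rec in records:
        by_status[rec.status] += 1
    manifest["counts"]["polymirts"] = by_status

    # --- per-gene predictor consensus (reference sites) --------------------
    stage("consensus")
    summaries = {}
    for utr in utrs:
        sites = ref_site_cache[utr.transcript_id]
        summaries[utr.transcript_id] = classify.summarize_consensus(
            [s for s in sites if s.predictor == "seed_context"],
            [s for s in sites if s.predictor == "accessibility"],
            [s for s in sites if s.predictor == "compensatory"],
        )
    classify.write_consensus_table(out / "consensus.tsv", summaries)

    # --- allele-specific expression ----------------------------------------
    stage("ase")
    if paths["allelic_counts"] is not None:
        allelic = coexpression.read_allelic_counts_tsv(paths["allelic_counts"])
    else:
        allelic = {
            (snp.label, sample): coexpression.AllelicCounts(snp.label, sample, r, a)
            for snp in retained
            for sample, (r, a) in snp.allele_counts.items()
        }
    coexpression.write_ase_report(out / "ase_tests.tsv", allelic,
                                  alpha=config.ase_alpha)
    manifest["counts"]["ase_tests"] = sum(1 for c in allelic.values() if c.total > 0)

    # --- inverse-expression flags ------------------------------------------
    if paths["mirna_counts"] is not None and paths["mrna_fpkm"] is not None:
        stage("inverse_expression")
        mirna_counts = coexpression.read_expression_tsv(paths["mirna_counts"])
        mrna_fpkm = coexpression.read_expression_tsv(paths["mrna_fpkm"])
        flags = coexpression.flag_inverse_expression(
            records, allelic, mirna_counts, mrna_fpkm, config)
        coexpression.write_inverse_flags(out / "inverse_flags.tsv", flags)
        manifest["counts"]["inverse_flags"] = len(flags)

    manifest["runtime_seconds"] = round(time.monotonic() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    stage("done")
    return out
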