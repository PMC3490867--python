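"""miRNA target site prediction on 3'-UTR sequences.

Three complementary predictors are provided:

* ``seed_context`` — canonical seed-match sites (8mer, 7mer-m8, 7mer-A1,
  6mer) scored with a three-term local-context surrogate,
* ``accessibility`` — seed-match sites kept only when the seed-pairing
  nucleotides are in an open loop of the MFE structure, ranked by a
  binomial over-representation score,
* ``compensatory`` — non-canonical sites with a single seed defect
  rescued by consecutive Watson-Crick pairing to miRNA nt 13-17.

Scores are not comparable across predictors.  Note the deliberate seed
asymmetry: canonical site detection anchors on nt 2-7 / 2-8 matches while
accessibility inspects the seven nucleotides pairing miRNA nt 2-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import binom

from polymirts import _fold
from polymirts.core_io import MatureMiRNA, reverse_complement

CANONICAL_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: site-type contribution to the context score, strongest site first
SITE_TYPE_TERM = {"8mer": 1.0, "7mer-m8": 0.6, "7mer-A1": 0.4, "6mer": 0.2}

#: flank width (each side) for the local AU-content term
AU_FLANK = 30
#: bonus when the site start lies within this distance band of a UTR end
POSITION_BAND = (15, 500)
POSITION_BONUS = 0.5

_RNA_TO_DNA = str.maketrans("U", "T")

#: Watson-Crick partner of an RNA base on the DNA (target) strand
_WC_DNA = {"A": "T", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class TargetSite:
    """One predicted miRNA binding site on a sense-orientation UTR."""

    mirna_name: str
    utr_id: str
    start: int
    end: int
    site_type: str
    predictor: str
    score: float = 0.0
    accessible: bool | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad site span [{self.start}, {self.end})")
        if self.site_type in CANONICAL_TYPES and self.end - self.start not in (6, 7, 8):
            raise ValueError(f"canonical site span must be 6-8 nt, got {self.end - self.start}")
        if (self.site_type == "compensatory") != (self.predictor == "compensatory"):
            raise ValueError("site_type 'compensatory' goes with predictor 'compensatory'")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def key(self) -> tuple[str, int, int, str, str]:
        return (self.mirna_name, self.start, self.end, self.site_type, self.predictor)


def seed_match_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """DNA patterns (5'->3' on the target strand) for the canonical types."""
    core6 = reverse_complement(mirna.seed6.translate(_RNA_TO_DNA))
    core7 = reverse_complement(mirna.seed7.translate(_RNA_TO_DNA))
    return {
        "8mer": core7 + "A",
        "7mer-m8": core7,
        "7mer-A1": core6 + "A",
        "6mer": core6,
    }


def find_seed_sites(utr_sequence: str, mirna: MatureMiRNA,
                    utr_id: str = "", predictor: str = "seed_context") -> list[TargetSite]:
    """Find every canonical seed-match site, each reported once, maximally.

    An 8mer occurrence is reported as 8mer only, not additionally as its
    nested 7mers/6mer.  Spans cover the matched nucleotides including the
    A1 position where applicable.  N never matches.
    """
    seq = utr_sequence.upper()
    n = len(seq)
    patterns = seed_match_patterns(mirna)
    core6 = patterns["6mer"]
    m8_base = patterns["7mer-m8"][0]  # target base pairing miRNA nt 8
    sites = []
    for i in range(n - 5):
        if seq[i:i + 6] != core6:
            continue
        has_m8 = i > 0 and seq[i - 1] == m8_base
        has_a1 = i + 6 < n and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, end = "8mer", i - 1, i + 7
        elif has_m8:
            site_type, start, end = "7mer-m8", i - 1, i + 6
        elif has_a1:
            site_type, start, end = "7mer-A1", i, i + 7
        else:
            site_type, start, end = "6mer", i, i + 6
        if "N" in seq[start:end]:
            continue
        sites.append(
            TargetSite(mirna_name=mirna.name, utr_id=utr_id, start=start,
                       end=end, site_type=site_type, predictor=predictor)
        )
    return sites


def context_score(site: TargetSite, utr_sequence: str, mirna: MatureMiRNA,
                  scale: float = 10.0) -> float:
    """Three-term local-context score, in score units (``scale`` x raw sum).

    type term (8mer > 7mer-m8 > 7mer-A1 > 6mer) + AU term (fraction of A/T
    in the 30-nt flanks on each side, clipped at the UTR ends) + position
    term (bonus when the site starts within 15-500 nt of either UTR end).
    Higher means stronger predicted repression.
    """
    if site.site_type not in SITE_TYPE_TERM:
        raise ValueError(f"unsupported site type {site.site_type!r} for context score")
    seq = utr_sequence.upper()
    type_term = SITE_TYPE_TERM[site.site_type]
    flank = seq[max(0, site.start - AU_FLANK):site.start] + seq[site.end:site.end + AU_FLANK]
    au_term = sum(1 for c in flank if c in "AT") / len(flank) if flank else 0.0
    lo, hi = POSITION_BAND
    dist = min(site.start, len(seq) - 1 - site.start)
    position_term = POSITION_BONUS if lo <= dist <= hi else 0.0
    return scale * (type_term + au_term + position_term)


def _seed_pairing_region(site: TargetSite, utr_length: int) -> list[int]:
    """UTR offsets pairing miRNA nt 2-8 (up to 7 positions, clipped)."""
    if site.site_type in ("8mer", "7mer-m8"):
        start = site.start  # span starts at the m8-pairing base
    elif site.site_type in ("7mer-A1", "6mer"):
        start = site.start - 1  # nt 8 pairs one base 5' of the core
    else:
        raise ValueError(f"unsupported site type {site.site_type!r}")
    return [p for p in range(start, start + 7) if 0 <= p < utr_length]


def assess_accessibility(site: TargetSite, utr_sequence: str,
                         folding_window: int = 150) -> bool:
    """True when >=4 of the 7 seed-pairing nucleotides are in an open loop.

    The MFE structure is computed on a window of ``folding_window`` nt
    centered on the site, clipped at the UTR ends.
    """
    n = len(utr_sequence)
    center = (site.start + site.end) // 2
    half = folding_window // 2
    win_start = max(0, center - half)
    win_end = min(n, win_start + folding_window)
    win_start = max(0, win_end - folding_window)
    try:
        open_in_window = _fold.unpaired_positions(utr_sequence[win_start:win_end])
    except _fold.FoldError as exc:
        raise _fold.FoldError(
            f"folding failed on window [{win_start}, {win_end})"
        ) from exc
    region = _seed_pairing_region(site, n)
    unpaired = sum(
        1 for p in region
        if win_start <= p < win_end and (p - win_start) in open_in_window
    )
    return unpaired >= 4


def rank_overrepresentation(accessible_site_count: int, utr_sequence: str,
                            mirna: MatureMiRNA) -> float:
    """Upper-tail binomial probability of the observed seed-match count.

    The null match probability per position is the product of mononucleotide
    frequencies of the UTR over the 7-mer seed-complementary pattern; the
    number of trials is the number of possible 7-mer start positions.
    Smaller values mean more over-represented; count 0 returns 1.0.
    """
    if accessible_site_count < 0:
        raise ValueError("site count must be non-negative")
    if accessible_site_count == 0:
        return 1.0
    seq = utr_sequence.upper()
    pattern = seed_match_patterns(mirna)["7mer-m8"]
    n_positions = len(seq) - len(pattern) + 1
    if n_positions <= 0:
        return 1.0
    total = len(seq)
    freq = {b: seq.count(b) / total for b in "ACGT"}
    p_match = 1.0
    for base in pattern:
        p_match *= freq.get(base, 0.0)
    return float(min(1.0, binom.sf(accessible_site_count - 1, n_positions, p_match)))


def predict_accessible_sites(utr_sequence: str, mirna: MatureMiRNA,
                             utr_id: str = "", folding_window: int = 150) -> list[TargetSite]:
    """Seed sites that pass the open-loop accessibility criterion.

    Each retained site carries the over-representation score of the
    accessible-site count as its score (shared across the sites of one
    miRNA/UTR pair, as the ranking is per pair).
    """
    seeds = find_seed_sites(utr_sequence, mirna, utr_id=utr_id, predictor="accessibility")
    accessible = [
        s for s in seeds if assess_accessibility(s, utr_sequence, folding_window)
    ]
    score = rank_overrepresentation(len(accessible), utr_sequence, mirna)
    return [
        TargetSite(mirna_name=s.mirna_name, utr_id=s.utr_id, start=s.start,
                   end=s.end, site_type=s.site_type, predictor="accessibility",
                   score=score, accessible=True)
        for s in accessible
    ]


def find_compensatory_sites(utr_sequence: str, mirna: MatureMiRNA,
                            utr_id: str = "") -> list[TargetSite]:
    """Non-canonical sites: one seed defect rescued by 3' pairing.

    A candidate pairs miRNA nt 2-8 with exactly one defect — a mismatch
    (G:U wobble included) or a single-nucleotide bulge on the target — and
    shows >=4 consecutive Watson-Crick pairs between miRNA nt 13-17 and the
    UTR 5' of the seed region, separated from it by a 1-6 nt unpaired gap.
    Perfect-seed (canonical) sites are never reported here; a defect at the
    nt-8 position alone would leave a perfect nt 2-7 match, so those are
    excluded too.
    """
    seq = utr_sequence.upper()
    n = len(seq)
    # perfect target-strand pattern for nt 2-8, 5'->3': [c(nt8) .. c(nt2)]
    pattern7 = seed_match_patterns(mirna)["7mer-m8"]
    sites = []
    for i in range(n - 6):
        for span, defects in _seed_defects(seq, i, pattern7):
            if defects != 1:
                continue
            score3 = _three_prime_pairing(seq, i, mirna)
            if score3 == 0:
                continue
            end = i + span
            if "N" in seq[i:end]:
                continue
            wc_pairs = (span - 1) if span == 8 else sum(
                1 for a, b in zip(seq[i:i + 7], pattern7) if a == b
            )
            sites.append(
                TargetSite(mirna_name=mirna.name, utr_id=utr_id, start=i,
                           end=end, site_type="compensatory",
                           predictor="compensatory", score=float(wc_pairs + score3))
            )
    # repetitive seeds can make a defective window coincide with a canonical
    # span; canonical sites are never reported by this predictor
    canonical_spans = {s.span for s in find_seed_sites(seq, mirna)}
    return [s for s in sites if s.span not in canonical_spans]


def _seed_defects(seq: str, i: int, pattern7: str) -> Iterable[tuple[int, int]]:
    """Yield (window span, defect count) for seed alignments starting at i.

    Span 7: positional comparison with the perfect pattern (mismatches and
    wobbles both count as one defect).  A sole defect at the nt-8 position
    (pattern offset 0) is suppressed — that window is a canonical nt 2-7
    match.  Span 8: one internal bulged target base whose removal restores
    the perfect pattern.
    """
    n = len(seq)
    if i + 7 <= n:
        window = seq[i:i + 7]
        mismatch_at = [j for j in range(7) if window[j] != pattern7[j]]
        if mismatch_at and mismatch_at != [0]:
            yield 7, len(mismatch_at)
    if i + 8 <= n:
        window = seq[i:i + 8]
        bulges = sum(
            1 for d in range(1, 7)
            if window[:d] + window[d + 1:] == pattern7
        )
        if bulges:
            yield 8, 1


def _three_prime_pairing(seq: str, seed_start: int, mirna: MatureMiRNA) -> int:
    """Longest qualifying 3'-region pairing block length (0 if none).

    Checks for >=4 consecutive Watson-Crick pairs between miRNA nt 13-17
    and the UTR upstream (5') of the seed region, at an unpaired gap of
    1-6 nt between the block and the seed-region start.
    """
    if len(mirna.sequence) < 17:
        return 0
    region = mirna.sequence[12:17]  # nt 13-17
    # runs of length 5 and 4 within nt 13-17, as target-strand DNA blocks
    blocks = [region, region[:4], region[1:]]
    best = 0
    seen = set()
    for block in blocks:
        if block in seen:
            continue
        seen.add(block)
        target = reverse_complement(block.translate(_RNA_TO_DNA))
        for gap in range(1, 7):
            start = seed_start - gap - len(block)
            if start < 0:
                continue
            if seq[start:start + len(block)] == target:
                best = max(best, len(block))
    return best


def check_conservation(site: TargetSite, ortholog_utr_sequence: str,
                       mirna: MatureMiRNA) -> bool:
    """Presence-based conservation: the ortholog UTR holds >=1 canonical
    site of the same miRNA family (same seed7); no positional alignment."""
    if not ortholog_utr_sequence:
        raise ValueError("ortholog UTR sequence is empty")
    return bool(find_seed_sites(ortholog_utr_sequence, mirna))


def predict_seed_context_sites(utr_sequence: str, mirna: MatureMiRNA,
                               utr_id: str = "", scale: float = 10.0) -> list[TargetSite]:
    """Canonical sites with their context scores attached."""
    out = []
    for s in find_seed_sites(utr_sequence, mirna, utr_id=utr_id, predictor="seed_context"):
        score = context_score(s, utr_sequence, mirna, scale=scale)
        out.append(
            TargetSite(mirna_name=s.mirna_name, utr_id=s.utr_id, start=s.start,
                       end=s.end, site_type=s.site_type,
                       predictor="seed_context", score=score)
        )
    return out


def predict_all(utr_sequence: str, mirnas: Sequence[MatureMiRNA], utr_id: str = "",
                folding_window: int = 150, scale: float = 10.0) -> list[TargetSite]:
    """Run all three predictors for every miRNA on one UTR sequence."""
    sites: list[TargetSite] = []
    for mirna in mirnas:
        sites.extend(predict_seed_context_sites(utr_sequence, mirna, utr_id, scale))
        sites.extend(predict_accessible_sites(utr_sequence, mirna, utr_id, folding_window))
        sites.extend(find_compensatory_sites(utr_sequence, mirna, utr_id))
    return sites


def write_site_table(path: str | Path, sites: Sequence[TargetSite]) -> None:
    """Emit the site table as TSV."""
    lines = ["utr_id\tmirna\tstart\tend\ttype\tpredictor\tscore\taccessible"]
    for s in sites:
        acc = "" if s.accessible is None else str(s.accessible).lower()
        lines.append(
            f"{s.utr_id}\t{s.mirna_name}\t{s.start}\t{s.end}\t{s.site_type}"
            f"\t{s.predictor}\t{s.score:.6g}\t{acc}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
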