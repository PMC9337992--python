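"""Inverted-repeat Alu pair detection and retained-intron intersection.

Two intronic Alu SINE copies in opposite orientation (an IR-Alu pair) can
base-pair into double-stranded RNA when co-transcribed, the trigger of the
viral-mimicry interferon response this pipeline characterizes.  This
module finds such pairs among RepeatMasker annotations with a greedy
nearest-downstream-neighbor scan, classifies how each pair intersects a
retained intron (first member only, second only, both, or neither — the
first member being the genomically upstream one), and summarizes the
fraction of retained introns carrying IR-Alus and the fraction whose pair
is bidirectionally transcribed (both members inside the transcribed span
of the intron's transcript, hence read in both sense and antisense).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .models import Interval, RepeatFeature, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = ["AluPair", "PairIntronCall", "find_alu_pairs",
           "classify_pair_intron", "iralu_summary", "compare_conditions"]


@dataclass(frozen=True)
class AluPair:
    """Two opposite-strand Alu elements; ``first`` is genomically upstream."""

    first: RepeatFeature
    second: RepeatFeature

    def __post_init__(self):
        if self.first.chrom != self.second.chrom:
            raise ValueError("pair members on different chromosomes")
        if self.first.strand == self.second.strand:
            raise ValueError("pair members must be inverted (opposite strands)")
        if self.first.start > self.second.start:
            raise ValueError("first member must be genomically upstream")

    @property
    def gap(self) -> int:
        """bp between the members (0 when overlapping/adjacent)."""
        return max(0, self.second.start - self.first.end)

    @property
    def span(self) -> Interval:
        return Interval(self.first.start, max(self.first.end, self.second.end))


@dataclass
class PairIntronCall:
    pair: AluPair
    intron: Interval
    category: str                    # first_only / second_only / both / none
    bidirectional_in_transcript: bool = False


# ----------------------------------------------------------- pairing

def find_alu_pairs(repeats: list[RepeatFeature], max_gap: int = 5000,
                   min_len: int = 100, all_pairs: bool = False) -> list[AluPair]:
    """Pair Alu elements in inverted orientation.

    Only Alu-family features of length >= ``min_len`` are considered.  In
    the default greedy mode, features are scanned left to right per
    chromosome and each unpaired Alu is matched to its nearest downstream
    opposite-strand unpaired Alu within ``max_gap`` bp (gap measured
    end-to-start); every Alu belongs to at most one pair.  With
    ``all_pairs`` every inverted combination within ``max_gap`` is
    reported.
    """
    alus = sorted((r for r in repeats if r.is_alu and len(r.interval) >= min_len),
                  key=lambda r: (r.chrom, r.start, r.end))
    pairs: list[AluPair] = []
    if all_pairs:
        for i, a in enumerate(alus):
            for b in alus[i + 1:]:
                if b.chrom != a.chrom or b.start - a.end > max_gap:
                    break
                if b.strand != a.strand:
                    pairs.append(AluPair(first=a, second=b))
        return pairs
    used = [False] * len(alus)
    for i, a in enumerate(alus):
        if used[i]:
            continue
        for j in range(i + 1, len(alus)):
            b = alus[j]
            if b.chrom != a.chrom or b.start - a.end > max_gap:
                break
            if used[j] or b.strand == a.strand:
                continue
            pairs.append(AluPair(first=a, second=b))
            used[i] = used[j] = True
            break
    return pairs


# ------------------------------------------------------ classification

def classify_pair_intron(pair: AluPair, intron: Interval,
                         intron_chrom: str | None = None) -> PairIntronCall:
    """Which members of the pair the intron intersects (>=1 bp, half-open)."""
    if intron_chrom is not None and intron_chrom != pair.first.chrom:
        logger.warning("pair on %s tested against intron on %s",
                       pair.first.chrom, intron_chrom)
        return PairIntronCall(pair=pair, intron=intron, category="none")
    hit_first = pair.first.interval.overlaps(intron)
    hit_second = pair.second.interval.overlaps(intron)
    if hit_first and hit_second:
        category = "both"
    elif hit_first:
        category = "first_only"
    elif hit_second:
        category = "second_only"
    else:
        category = "none"
    return PairIntronCall(pair=pair, intron=intron, category=category)


# ----------------------------------------------------------- summaries

def iralu_summary(retained_introns: list[dict], repeats: list[RepeatFeature],
                  transcripts: list[TranscriptModel] | None = None,
                  max_gap: int = 5000, min_len: int = 100) -> dict:
    """Intersect IR-Alu pairs with retained introns and summarize.

    ``retained_introns`` entries need chrom/start/end and optionally
    transcript_id (used for the bidirectional-transcription test: both
    pair members inside the transcribed span of the intron's transcript,
    and — by pair construction — on opposite genomic strands, hence
    transcribed in both sense and antisense orientation).
    """
    pairs = find_alu_pairs(repeats, max_gap=max_gap, min_len=min_len)
    tx_by_id = {t.transcript_id: t for t in (transcripts or [])}
    category_counts = {"first_only": 0, "second_only": 0, "both": 0, "none": 0}
    n_intersecting = 0
    n_bidirectional = 0
    n_no_transcript = 0
    per_intron = []
    for intron in retained_introns:
        iv = Interval(int(intron["start"]), int(intron["end"]))
        chrom = intron["chrom"]
        calls = [classify_pair_intron(p, iv, intron_chrom=chrom)
                 for p in pairs if p.first.chrom == chrom]
        hit_calls = [c for c in calls if c.category != "none"]
        for c in calls:
            category_counts[c.category] += 1
        intersects = bool(hit_calls)
        if intersects:
            n_intersecting += 1
        bidirectional = False
        tx = tx_by_id.get(intron.get("transcript_id"))
        if tx is None:
            if intron.get("transcript_id") is not None or transcripts:
                n_no_transcript += 1
                logger.warning("intron %s has no parent transcript; excluded "
                               "from bidirectional accounting",
                               intron.get("event_id", iv))
        else:
            span = tx.span
            for c in hit_calls:
                if span.contains(c.pair.first.interval) and \
                        span.contains(c.pair.second.interval):
                    c.bidirectional_in_transcript = True
                    bidirectional = True
            if bidirectional:
                n_bidirectional += 1
        per_intron.append({"intron": intron, "intersects": intersects,
                           "bidirectional": bidirectional,
                           "categories": [c.category for c in hit_calls]})
    n = len(retained_introns)
    n_with_tx = n - n_no_transcript
    return {
        "n_introns": n,
        "n_pairs": len(pairs),
        "n_introns_with_iralu": n_intersecting,
        "fraction_with_iralu": n_intersecting / n if n else 0.0,
        "category_counts": category_counts,
        "n_introns_bidirectional": n_bidirectional,
        "fraction_bidirectional": (n_bidirectional / n_with_tx
                                   if n_with_tx else 0.0),
        "n_introns_without_transcript": n_no_transcript,
        "parameters": {"max_gap": max_gap, "min_len": min_len},
        "per_intron": per_intron,
    }


def compare_conditions(report_a: dict, report_b: dict) -> dict:
    """Side-by-side IR-Alu burden of two conditions from the same genome."""
    if report_a.get("parameters") != report_b.get("parameters"):
        raise ValueError("reports were produced with different parameters")
    a_n = report_a["n_introns_with_iralu"]
    b_n = report_b["n_introns_with_iralu"]
    if b_n == 0:
        ratio: float | str = "inf" if a_n > 0 else 1.0
    else:
        ratio = a_n / b_n
    return {
        "a": {k: report_a[k] for k in
              ("n_introns", "n_introns_with_iralu", "fraction_with_iralu",
               "n_pairs", "category_counts")},
        "b": {k: report_b[k] for k in
              ("n_introns", "n_introns_with_iralu", "fraction_with_iralu",
               "n_pairs", "category_counts")},
        "iralu_intron_ratio": ratio,
    }
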