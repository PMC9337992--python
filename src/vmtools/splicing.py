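"""PSI quantification, Bayesian differential splicing, and ORF impact.

Percent spliced in (PSI) is estimated from junction-normalized inclusion
and exclusion read counts.  Differential splicing between two conditions
uses independent Beta posteriors on the pooled normalized counts: the
point effect is dpsi = psi_treated - psi_control, and the significance
gate is the minimum |dPSI| supported at 95% posterior confidence (mv95,
the 5th percentile of the sign-aligned posterior dPSI draws).  An event
passes when coverage is adequate in every sample, |dpsi| >= 0.2 and
mv95 >= 0.05.

Events are typed as intron retention (IR), exon skipping (EX) or
alternative 3'/5' splice-site use (A3SS/A5SS, defined in transcript
orientation), and their predicted open-reading-frame impact is classified
as neutral, protective or deleterious from the inclusion/exclusion isoform
coding sequences, using the 55-nt last-junction convention for premature
termination codons (PTCs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Interval, TranscriptModel

__all__ = [
    "SpliceEvent", "PsiEstimate", "DiffSpliceResult", "OrfImpactLabel",
    "compute_psi", "diff_splice", "classify_event_type",
    "classify_orf_impact", "summarize_events", "qpcr_retention_ratio",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
PTC_JUNCTION_RULE_NT = 55  # stop >55 nt before the last junction triggers NMD


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative splicing event: a variable segment in a transcript."""

    event_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    segment: Interval           # the variable (included/excluded) region
    event_type: str | None = None   # EX / IR / A3SS / A5SS / other
    n_inc_junctions: int = 1
    n_exc_junctions: int = 1


@dataclass
class PsiEstimate:
    psi: float                  # NaN when undefined (both norms zero)
    inc_norm: float
    exc_norm: float
    posterior_a: float
    posterior_b: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.psi)


@dataclass
class DiffSpliceResult:
    dpsi_point: float
    mv95: float
    passes: bool
    coverage_ok: bool
    psi_control: float
    psi_treated: float
    metadata: dict = field(default_factory=dict)


@dataclass
class OrfImpactLabel:
    label: str                       # neutral / protective / deleterious
    frame_preserved: bool
    ptc_found: bool                  # PTC in the non-annotated isoform
    ptc_position: int | None = None  # transcript coordinate of the PTC start


# ------------------------------------------------------------------ PSI

def compute_psi(inc_reads: float, exc_reads: float,
                n_inc_junc: int = 1, n_exc_junc: int = 1) -> PsiEstimate:
    """Junction-normalized PSI with a Beta posterior.

    inc_norm = inc_reads / n_inc_junc and exc_norm = exc_reads / n_exc_junc
    put multi-junction events on the per-junction read scale;
    psi = inc_norm / (inc_norm + exc_norm).  The posterior is
    Beta(round(inc_norm) + 1, round(exc_norm) + 1) — a uniform prior
    updated with the rounded normalized counts.
    """
    if n_inc_junc < 1 or n_exc_junc < 1:
        raise ValueError("junction counts must be >= 1")
    if inc_reads < 0 or exc_reads < 0:
        raise ValueError("read counts must be >= 0")
    inc_norm = inc_reads / n_inc_junc
    exc_norm = exc_reads / n_exc_junc
    total = inc_norm + exc_norm
    psi = inc_norm / total if total > 0 else float("nan")
    return PsiEstimate(psi=psi, inc_norm=inc_norm, exc_norm=exc_norm,
                       posterior_a=round(inc_norm) + 1.0,
                       posterior_b=round(exc_norm) + 1.0)


# ---------------------------------------------------- differential PSI

def diff_splice(control: list[tuple[float, float]],
                treated: list[tuple[float, float]],
                n_inc_junc: int = 1, n_exc_junc: int = 1,
                n_draws: int = 10_000, seed: int = 0,
                dpsi_cut: float = 0.2, mv_cut: float = 0.05,
                min_reads: float = 10, min_effect: float = 0.01,
                rng: np.random.Generator | None = None) -> DiffSpliceResult:
    """Bayesian dPSI between conditions with the mv95 significance rule.

    ``control``/``treated`` hold per-sample (inclusion, exclusion) read
    counts.  Counts are junction-normalized and pooled within condition
    before posterior construction.  ``coverage_ok`` requires every sample
    to carry at least ``min_reads`` total event reads.  mv95 below
    ``min_effect`` is reported as 0 (effects under the minimum detectable
    floor are not distinguished from no effect); the floor sits well below
    ``mv_cut`` so it never changes the pass decision.
    """
    if not control or not treated:
        raise ValueError("each condition needs >=1 sample")
    pooled = []
    for cond in (control, treated):
        inc = sum(c[0] for c in cond)
        exc = sum(c[1] for c in cond)
        pooled.append(compute_psi(inc, exc, n_inc_junc, n_exc_junc))
    est_c, est_t = pooled
    coverage_ok = all(c[0] + c[1] >= min_reads for c in control + treated)
    dpsi_point = (est_t.psi - est_c.psi
                  if est_t.defined and est_c.defined else float("nan"))

    if rng is None:
        rng = np.random.default_rng(seed)
    draws_c = rng.beta(est_c.posterior_a, est_c.posterior_b, size=n_draws)
    draws_t = rng.beta(est_t.posterior_a, est_t.posterior_b, size=n_draws)
    delta = draws_t - draws_c
    s = 1.0 if np.median(delta) >= 0 else -1.0
    mv95 = max(0.0, float(np.quantile(s * delta, 0.05)))
    if mv95 < min_effect:
        mv95 = 0.0
    passes = bool(coverage_ok and np.isfinite(dpsi_point)
                  and abs(dpsi_point) >= dpsi_cut and mv95 >= mv_cut)
    return DiffSpliceResult(
        dpsi_point=float(dpsi_point), mv95=mv95, passes=passes,
        coverage_ok=coverage_ok, psi_control=est_c.psi, psi_treated=est_t.psi,
        metadata={"n_draws": n_draws, "dpsi_cut": dpsi_cut, "mv_cut": mv_cut,
                  "min_reads": min_reads, "min_effect_floor": min_effect,
                  "replicates": "pooled within condition",
                  "prior": "Beta(1,1)"})


# ------------------------------------------------------ event typing

def classify_event_type(segment: Interval, transcript: TranscriptModel) -> str:
    """Type an event from its variable segment and the transcript structure.

    IR: the segment is a complete intron between adjacent exons.
    EX: the segment is a whole internal exon.
    A3SS/A5SS: the segment extends one end of an intron (one splice site
    shifts); 3' and 5' are assigned in transcript orientation, so a shift
    at the genomic-left intron boundary is A5SS on the plus strand but
    A3SS on the minus strand.
    """
    for intron in transcript.introns:
        if segment.start == intron.start and segment.end == intron.end:
            return "IR"
    for exon in transcript.exons[1:-1]:
        if segment.start == exon.start and segment.end == exon.end:
            return "EX"
    for intron in transcript.introns:
        if intron.contains(segment):
            at_left = segment.start == intron.start
            at_right = segment.end == intron.end
            if at_left and not at_right:
                return "A5SS" if transcript.strand == "+" else "A3SS"
            if at_right and not at_left:
                return "A3SS" if transcript.strand == "+" else "A5SS"
    warnings.warn(f"unclassifiable event segment {segment} in "
                  f"{transcript.transcript_id}")
    return "other"


# ------------------------------------------------------- ORF impact

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _merge_union(exons: list[Interval], extra: Interval) -> list[Interval]:
    """Union of an exon chain with one segment, merging touching pieces."""
    points = sorted(exons + [extra], key=lambda iv: iv.start)
    merged: list[list[int]] = []
    for iv in points:
        if merged and iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [Interval(a, b) for a, b in merged]


def _subtract(exons: list[Interval], seg: Interval) -> list[Interval]:
    out = []
    for iv in exons:
        if not iv.overlaps(seg):
            out.append(iv)
            continue
        if iv.start < seg.start:
            out.append(Interval(iv.start, seg.start))
        if seg.end < iv.end:
            out.append(Interval(seg.end, iv.end))
    return out


class _Isoform:
    """mRNA of one isoform with transcript->genome coordinate mapping."""

    def __init__(self, exons: list[Interval], strand: str, chrom_seq: str):
        self.exons = sorted(exons, key=lambda iv: iv.start)
        self.strand = strand
        tx_exons = self.exons if strand == "+" else self.exons[::-1]
        parts, positions = [], []
        for iv in tx_exons:
            if strand == "+":
                parts.append(chrom_seq[iv.start:iv.end])
                positions.extend(range(iv.start, iv.end))
            else:
                parts.append(_revcomp(chrom_seq[iv.start:iv.end]))
                positions.extend(range(iv.end - 1, iv.start - 1, -1))
        self.seq = "".join(parts).upper()
        self.genomic_pos = np.array(positions, dtype=int)
        # transcript coordinates just after each exon-exon junction
        lengths = [len(iv) for iv in tx_exons]
        self.junctions = list(np.cumsum(lengths)[:-1])

    def tx_index(self, genomic: int) -> int | None:
        hits = np.nonzero(self.genomic_pos == genomic)[0]
        return int(hits[0]) if hits.size else None

    def first_stop(self, start_idx: int) -> tuple[int, set[int]] | None:
        """First in-frame stop codon from ``start_idx``; returns
        (transcript index of codon start, set of its genomic positions)."""
        for i in range(start_idx, len(self.seq) - 2, 3):
            codon = self.seq[i:i + 3]
            if codon in STOP_CODONS:
                return i, set(self.genomic_pos[i:i + 3].tolist())
        return None


def _has_ptc(iso: _Isoform, start_genomic: int,
             annotated_stop_pos: set[int]) -> tuple[bool, int | None]:
    """Scan an isoform for an NMD-triggering premature stop codon."""
    start_idx = iso.tx_index(start_genomic)
    if start_idx is None:
        # start codon spliced out: ORF destroyed, treat as PTC at origin
        return True, 0
    hit = iso.first_stop(start_idx)
    if hit is None:
        return False, None
    stop_idx, stop_genomic = hit
    if stop_genomic == annotated_stop_pos:
        return False, None
    if not iso.junctions:
        return False, None
    last_junction = iso.junctions[-1]
    stop_end = stop_idx + 3
    if last_junction - stop_end > PTC_JUNCTION_RULE_NT:
        return True, stop_idx
    return False, None


def classify_orf_impact(event: SpliceEvent, transcript: TranscriptModel,
                        chrom_seq: str) -> OrfImpactLabel:
    """Classify an event's predicted impact on the open reading frame.

    The inclusion isoform adds the variable segment to the exon chain, the
    exclusion isoform removes it.  A stop codon upstream of the annotated
    stop and more than 55 nt before the final exon-exon junction counts as
    a PTC.  An event whose inclusion carries a PTC absent from exclusion
    is deleterious when the segment is intronic in the annotation (the
    inclusion introduces a new PTC, e.g. a retained intron with an
    in-frame stop) and protective when the segment is an annotated exon
    (the exclusion removes an existing PTC, e.g. skipping a PTC-bearing
    exon).  An exclusion-only PTC (e.g. a frame-shifting skip of an
    essential exon) is deleterious.  Events entirely outside the CDS are
    neutral.
    """
    if not transcript.has_cds:
        raise ValueError(f"transcript {transcript.transcript_id} has no "
                         "annotated CDS; event left unlabeled")
    seg = event.segment
    cds_span = Interval(transcript.cds_start, transcript.cds_end)
    frame_preserved = len(seg) % 3 == 0
    if not seg.overlaps(cds_span):
        return OrfImpactLabel(label="neutral", frame_preserved=frame_preserved,
                              ptc_found=False)

    incl_exons = _merge_union(transcript.exons, seg)
    excl_exons = _subtract(transcript.exons, seg)
    incl = _Isoform(incl_exons, transcript.strand, chrom_seq)
    excl = _Isoform(excl_exons, transcript.strand, chrom_seq)

    if transcript.strand == "+":
        start_genomic = transcript.cds_start
        annotated_stop = set(range(transcript.cds_end - 3, transcript.cds_end))
    else:
        start_genomic = transcript.cds_end - 1
        annotated_stop = set(range(transcript.cds_start, transcript.cds_start + 3))

    ptc_incl, pos_incl = _has_ptc(incl, start_genomic, annotated_stop)
    ptc_excl, pos_excl = _has_ptc(excl, start_genomic, annotated_stop)

    annotated_is_inclusion = any(e.contains(seg) for e in transcript.exons)

    if ptc_incl and not ptc_excl:
        label = "protective" if annotated_is_inclusion else "deleterious"
        return OrfImpactLabel(label=label, frame_preserved=frame_preserved,
                              ptc_found=True, ptc_position=pos_incl)
    if ptc_excl and not ptc_incl:
        return OrfImpactLabel(label="deleterious", frame_preserved=frame_preserved,
                              ptc_found=True, ptc_position=pos_excl)
    return OrfImpactLabel(label="neutral", frame_preserved=frame_preserved,
                          ptc_found=bool(ptc_incl and ptc_excl),
                          ptc_position=pos_incl)


# ------------------------------------------------------------ summaries

def summarize_events(results: pd.DataFrame) -> dict:
    """Summarize differential-splicing calls.

    ``results`` needs columns event_id, gene_id, event_type, chrom, strand,
    start, end, dpsi_point, passes.  Returns counts of passing events by
    type, the distinct passing gene count, and the passing retained-intron
    intervals (for inverted-repeat Alu analysis).
    """
    passing = results[results["passes"].astype(bool)]
    by_type = passing["event_type"].value_counts().to_dict()
    for t in ("EX", "IR", "A3SS", "A5SS"):
        by_type.setdefault(t, 0)
    retained = passing[passing["event_type"] == "IR"]
    retained_introns = [
        {"event_id": row.event_id, "chrom": row.chrom, "start": int(row.start),
         "end": int(row.end), "strand": row.strand,
         "transcript_id": getattr(row, "transcript_id", None),
         "dpsi": float(row.dpsi_point)}
        for row in retained.itertuples()
    ]
    return {
        "n_events_passing": int(len(passing)),
        "n_genes_passing": int(passing["gene_id"].nunique()),
        "counts_by_type": by_type,
        "retained_introns": retained_introns,
    }


# ---------------------------------------------------------------- qPCR

def qpcr_retention_ratio(ct_intron: float, ct_spliced: float) -> float:
    """Intron-containing / fully-spliced transcript ratio from Ct values.

    ratio = 2^-(Ct_intron - Ct_spliced), assuming 100% amplification
    efficiency (one cycle = one doubling).
    """
    if not (math.isfinite(ct_intron) and math.isfinite(ct_spliced)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(ct_intron - ct_spliced)))
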