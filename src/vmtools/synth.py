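"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: a toy genome
bundle (FASTA + GTF + RepeatMasker .out) with strand-annotated Alu
elements, some arranged as inverted pairs inside designated retained
introns; an epigenetic-probe screen confluence table with planted hits;
Hill-shaped dose-response viability tables; log-scale expression matrices
with a planted gene signature correlated to a sensitivity vector; and
beta-binomial junction-count tables at planted PSI values.  The planted
truth is recorded in a :class:`TruthTable` so every downstream stage can
be tested for recovery without external data.

All generators are driven by a single integer seed through
``numpy.random.default_rng``; identical seeds give byte-identical output
files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .drug_response import hill_viability
from .models import Interval, RepeatFeature, TranscriptModel
from .splicing import SpliceEvent

__all__ = [
    "TruthTable", "GenomeBundle", "PlantedEvent",
    "gen_genome", "gen_dose_response", "gen_expression",
    "gen_junction_counts", "gen_screen", "events_from_genome",
    "gen_cds_locus", "mirror_genome", "DEFAULT_DOSES_UM",
    "STOP_FREE_CODONS",
]

# nine doses log-spaced over the tested 40 nM - 10 uM concentration range
DEFAULT_DOSES_UM = np.logspace(np.log10(0.04), np.log10(10.0), 9)

_BASES = np.array(list("ACGT"))
# codons with no stop among {TAA, TAG, TGA}; used to fill CDS regions
_SAFE_CODONS = [a + b + c
                for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in ("TAA", "TAG", "TGA")]
STOP_FREE_CODONS = list(_SAFE_CODONS)

# Synthetic Alu consensus: a fixed 281-bp pseudo-consensus drawn once from
# a pinned generator.  Only its length, label and strand matter to the
# pairing analysis; the sequence itself is decorative.
_ALU_LEN = 281
_ALU_CONSENSUS = "".join(np.random.default_rng(991).choice(_BASES, size=_ALU_LEN))
_ALU_FAMILIES = ("AluY", "AluSx")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


# ---------------------------------------------------------------- truth

@dataclass
class TruthTable:
    """Ground truth planted by the generators, for recovery tests."""

    planted_signature_genes: list[str] = field(default_factory=list)
    planted_correlation: float = 0.0
    planted_psi: dict[str, tuple[float, float]] = field(default_factory=dict)
    planted_ir_alu_introns: list[str] = field(default_factory=list)
    planted_bidirectional_introns: list[str] = field(default_factory=list)
    designated_retained_introns: list[str] = field(default_factory=list)
    planted_hits: list[str] = field(default_factory=list)
    hill_params: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_psi"] = {k: tuple(v) for k, v in raw.get("planted_psi", {}).items()}
        raw["hill_params"] = {k: tuple(v) for k, v in raw.get("hill_params", {}).items()}
        return cls(**raw)


@dataclass
class GenomeBundle:
    """A toy genome: sequence, transcript models, repeats and truth."""

    sequences: dict[str, str]
    transcripts: list[TranscriptModel]
    repeats: list[RepeatFeature]
    truth: TruthTable
    retained_introns: list[dict] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "repeats": outdir / "repeats.out",
            "truth": outdir / "truth.json",
            "introns": outdir / "retained_introns.bed",
        }
        vio.write_fasta(self.sequences, paths["fasta"])
        vio.write_gtf(self.transcripts, paths["gtf"])
        vio.write_repeatmasker(
            self.repeats, paths["repeats"],
            chrom_lengths={c: len(s) for c, s in self.sequences.items()})
        self.truth.to_json(paths["truth"])
        vio.write_bed6([(d["chrom"], d["start"], d["end"], d["intron_id"], 0.0,
                         d["strand"]) for d in self.retained_introns],
                       paths["introns"])
        return paths


# --------------------------------------------------------------- genome

def gen_genome(seed: int, n_transcripts: int = 20, alu_per_intron: float = 0.5,
               ir_pair_fraction: float = 0.62, chrom: str = "chr1",
               pair_gap_range: tuple[int, int] = (100, 1500),
               bidirectional_fraction: float = 0.8) -> GenomeBundle:
    """Generate a toy genome with IR-Alu pairs planted in retained introns.

    Each transcript carries four exons and three introns; the middle
    intron is the designated retained intron.  A fraction
    ``ir_pair_fraction`` of designated introns receive an inverted Alu
    pair (two opposite-strand copies, listed in the truth table); of
    those, ``bidirectional_fraction`` have both members inside the intron
    (hence co-transcribed in sense and antisense within the transcript),
    while the rest have the second member placed downstream of the
    transcript, so the pair intersects the intron without being
    bidirectionally transcribed.  ``alu_per_intron`` is the expected
    number of decoy repeats (truncated Alu fragments and non-Alu
    elements) dropped into the flanking introns.  The default fractions
    mirror an Alu-dense sensitive condition in which roughly five of
    every eight intersecting pairs are bidirectional; resistant-condition
    bundles are generated with a lower ``ir_pair_fraction``.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    for name, frac in (("alu_per_intron", alu_per_intron),
                       ("ir_pair_fraction", ir_pair_fraction),
                       ("bidirectional_fraction", bidirectional_fraction)):
        if frac < 0 or (name != "alu_per_intron" and frac > 1):
            raise ValueError(f"{name} out of range: {frac}")
    rng = np.random.default_rng(seed)

    chrom_parts: list[str] = []
    pos = 0
    transcripts: list[TranscriptModel] = []
    repeats: list[RepeatFeature] = []
    retained: list[dict] = []
    planted_ir: list[str] = []
    planted_bidir: list[str] = []
    designated: list[str] = []

    n_planted = int(round(ir_pair_fraction * n_transcripts))
    planted_idx = set(rng.choice(n_transcripts, size=n_planted, replace=False).tolist())

    def emit_random(length: int) -> tuple[int, int]:
        start = pos_tracker[0]
        chrom_parts.append("".join(rng.choice(_BASES, size=length)))
        pos_tracker[0] += length
        return start, pos_tracker[0]

    pos_tracker = [pos]
    for t in range(n_transcripts):
        tid = f"TX{t:04d}"
        gid = f"GENE{t:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        emit_random(int(rng.integers(200, 500)))  # intergenic spacer

        exon_lens = rng.choice([90, 120, 150, 180], size=4).tolist()
        planted_here = t in planted_idx
        intron_lens = [int(rng.integers(300, 800)),
                       int(rng.integers(1600, 2600)),
                       int(rng.integers(300, 800))]

        exons: list[Interval] = []
        intron_ivs: list[Interval] = []
        for k in range(4):
            s, e = emit_random(exon_lens[k])
            exons.append(Interval(s, e))
            if k < 3:
                s_i, e_i = emit_random(intron_lens[k])
                intron_ivs.append(Interval(s_i, e_i))

        # plant an inverted Alu pair inside the designated (middle) intron
        mid = intron_ivs[1]
        intron_id = f"{tid}_RI"
        designated.append(intron_id)
        if planted_here:
            bidir_here = rng.random() < bidirectional_fraction
            a_strand = "+" if rng.random() < 0.5 else "-"
            b_strand = "-" if a_strand == "+" else "+"
            fam_a, fam_b = rng.choice(_ALU_FAMILIES, size=2).tolist()
            if bidir_here:
                gap_hi = min(pair_gap_range[1], len(mid) - 2 * _ALU_LEN - 60)
                gap = int(rng.integers(pair_gap_range[0],
                                       max(pair_gap_range[0] + 1, gap_hi)))
                margin = len(mid) - (2 * _ALU_LEN + gap)
                off = int(rng.integers(20, max(21, margin - 20)))
                a = RepeatFeature(chrom, mid.start + off,
                                  mid.start + off + _ALU_LEN, a_strand, fam_a)
                b = RepeatFeature(chrom, a.end + gap, a.end + gap + _ALU_LEN,
                                  b_strand, fam_b)
                planted_bidir.append(intron_id)
            else:
                # pair intersects the intron through its first member only;
                # the second member sits just past the transcript's last exon
                off = int(rng.integers(20, len(mid) - _ALU_LEN - 20))
                a = RepeatFeature(chrom, mid.start + off,
                                  mid.start + off + _ALU_LEN, a_strand, fam_a)
                ext = exons[3].end + int(rng.integers(10, 40))
                b = RepeatFeature(chrom, ext, ext + _ALU_LEN, b_strand, fam_b)
            repeats.extend([a, b])
            planted_ir.append(intron_id)
        # decoys in the flanking introns: truncated Alu fragments (below the
        # pairing length filter, as most genomic Alu copies are) and the odd
        # full-length non-Alu repeat, so family and length filtering are both
        # exercised without perturbing the planted pairs
        for iv in (intron_ivs[0], intron_ivs[2]):
            if rng.random() < alu_per_intron and len(iv) >= _ALU_LEN + 40:
                frag_len = int(rng.integers(60, 96))
                off = int(rng.integers(10, len(iv) - frag_len - 10))
                fam = str(rng.choice(_ALU_FAMILIES))
                d_strand = "+" if rng.random() < 0.5 else "-"
                repeats.append(RepeatFeature(chrom, iv.start + off,
                                             iv.start + off + frag_len,
                                             d_strand, fam))
            elif rng.random() < 0.3 and len(iv) >= _ALU_LEN + 40:
                off = int(rng.integers(10, len(iv) - _ALU_LEN - 10))
                d_strand = "+" if rng.random() < 0.5 else "-"
                repeats.append(RepeatFeature(chrom, iv.start + off,
                                             iv.start + off + _ALU_LEN,
                                             d_strand, "L1MA4"))

        retained.append({"intron_id": intron_id, "event_id": intron_id,
                         "chrom": chrom, "start": mid.start, "end": mid.end,
                         "strand": strand, "transcript_id": tid})
        tx = TranscriptModel(transcript_id=tid, gene_id=gid, chrom=chrom,
                             strand=strand, exons=exons)
        transcripts.append(tx)

    # trailing spacer long enough to hold an external pair member
    emit_random(int(rng.integers(400, 700)))
    sequence = list("".join(chrom_parts))

    # write Alu-derived sequences (consensus with 10% mutation, truncated to
    # the feature length, strand-aware); non-Alu repeats keep random sequence
    for rep in repeats:
        if not rep.is_alu:
            continue
        body = _mutate(_ALU_CONSENSUS[:rep.end - rep.start], 0.10, rng)
        if rep.strand == "-":
            body = _revcomp(body)
        sequence[rep.start:rep.end] = body

    # carve a clean CDS into each transcript: start codon at the 5' end of
    # exon 1 (transcript orientation), stop codon at the 3' end of exon 4,
    # stop-free codons in between
    for tx in transcripts:
        _write_cds(tx, sequence, rng)

    seq_str = "".join(sequence)
    truth = TruthTable(planted_ir_alu_introns=sorted(planted_ir),
                       planted_bidirectional_introns=sorted(planted_bidir),
                       designated_retained_introns=sorted(designated))
    repeats_sorted = sorted(repeats, key=lambda r: (r.chrom, r.start))
    return GenomeBundle(sequences={chrom: seq_str}, transcripts=transcripts,
                        repeats=repeats_sorted, truth=truth,
                        retained_introns=retained)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = str(rng.choice(_BASES[_BASES != out[i]]))
    return "".join(out)


def _write_cds(tx: TranscriptModel, sequence: list[str],
               rng: np.random.Generator) -> None:
    """Overwrite the exonic sequence of ``tx`` with a stop-free ORF."""
    total = sum(len(e) for e in tx.exons)
    n_codons = total // 3
    codons = ["ATG"] + [str(rng.choice(_SAFE_CODONS)) for _ in range(n_codons - 2)] \
        + ["TAA"]
    mrna = "".join(codons)
    # genomic positions of exonic bases in transcript order
    if tx.strand == "+":
        positions = [p for e in tx.exons for p in range(e.start, e.end)]
        for i, base in enumerate(mrna):
            sequence[positions[i]] = base
        cds_start = positions[0]
        cds_end = positions[len(mrna) - 1] + 1
    else:
        positions = [p for e in reversed(tx.exons)
                     for p in range(e.end - 1, e.start - 1, -1)]
        comp = str.maketrans("ACGT", "TGCA")
        for i, base in enumerate(mrna):
            sequence[positions[i]] = base.translate(comp)
        cds_start = positions[len(mrna) - 1]
        cds_end = positions[0] + 1
    tx.cds_start = cds_start
    tx.cds_end = cds_end


# -------------------------------------------------------- dose-response

def gen_dose_response(seed: int, hill: tuple[float, float, float],
                      doses: np.ndarray | None = None, noise_sd: float = 0.05,
                      replicates: int = 4) -> pd.DataFrame:
    """Hill-shaped viability table with additive Gaussian noise.

    viability(d) = e_inf + (1 - e_inf) / (1 + (d/ec50)^slope) + N(0, noise_sd),
    clipped to [0, 1.2] (over-confluent wells can exceed control but never
    go negative).  Default grid: nine doses log-spaced 0.04-10 uM.
    """
    ec50, slope, e_inf = hill
    if doses is None:
        doses = DEFAULT_DOSES_UM
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be ascending")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    clean = hill_viability(doses, ec50, slope, e_inf)
    data = {"dose_uM": doses}
    reps = np.empty((doses.size, replicates))
    for r in range(replicates):
        v = clean + rng.normal(0.0, noise_sd, size=doses.size) if noise_sd > 0 \
            else clean.copy()
        reps[:, r] = np.clip(v, 0.0, 1.2)
        data[f"rep_{r + 1}"] = reps[:, r]
    data["viability"] = reps.mean(axis=1)
    return pd.DataFrame(data)


# ----------------------------------------------------------- expression

def gen_expression(seed: int, n_genes: int, sensitivity: pd.Series,
                   signature_genes: list[str] | None = None,
                   strength: float = 0.8, base_mean: float = 5.0,
                   base_sd: float = 1.0) -> pd.DataFrame:
    """Log-scale expression matrix with a planted correlated signature.

    Signature genes are built as strength * z(sensitivity) +
    sqrt(1 - strength^2) * noise, rescaled to the background mean/sd, so
    their expected Pearson correlation with the sensitivity vector equals
    ``strength`` (exactly 1 when strength = 1, since the noise term then
    vanishes).  Background genes are independent Gaussian noise.
    """
    if len(sensitivity) < 3:
        raise ValueError("need >=3 cell lines for a correlation structure")
    if not (0.0 <= strength <= 1.0):
        raise ValueError("strength must lie in [0,1]")
    signature_genes = list(signature_genes or [])
    if len(signature_genes) > n_genes:
        raise ValueError("more signature genes than total genes")
    rng = np.random.default_rng(seed)
    lines = list(sensitivity.index)
    s = sensitivity.to_numpy(dtype=float)
    z = (s - s.mean()) / s.std(ddof=0) if s.std(ddof=0) > 0 else np.zeros_like(s)

    n_background = n_genes - len(signature_genes)
    bg_names = [f"BG{i:05d}" for i in range(n_background)]
    mat = rng.normal(base_mean, base_sd, size=(n_background, len(lines)))
    rows = [pd.DataFrame(mat, index=bg_names, columns=lines)]
    if signature_genes:
        noise = rng.normal(0.0, 1.0, size=(len(signature_genes), len(lines)))
        sig = strength * z[None, :] + math.sqrt(1.0 - strength ** 2) * noise
        sig = base_mean + base_sd * sig
        rows.append(pd.DataFrame(sig, index=signature_genes, columns=lines))
    expr = pd.concat(rows)
    return expr


# ------------------------------------------------------ junction counts

@dataclass(frozen=True)
class PlantedEvent:
    """A splice event plus the PSI values planted in each condition."""

    event: SpliceEvent
    psi_control: float
    psi_treated: float

    def __post_init__(self):
        for v in (self.psi_control, self.psi_treated):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"planted PSI outside [0,1]: {v}")


def gen_junction_counts(seed: int, events: list[PlantedEvent],
                        coverage: int = 100, replicates: int = 3,
                        dispersion: float = 0.01) -> pd.DataFrame:
    """Beta-binomial junction counts at planted PSI values.

    Per replicate, the realized psi* is drawn from a Beta centered on the
    planted PSI with intra-class correlation ``dispersion`` (psi of 0 or 1
    is kept exact), then inclusion ~ Binomial(coverage, psi*) and
    exclusion = coverage - inclusion.  Samples are named ctrl_i / trt_i.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not (0.0 <= dispersion < 1.0):
        raise ValueError("dispersion must lie in [0,1)")
    rng = np.random.default_rng(seed)
    samples = [f"ctrl_{i + 1}" for i in range(replicates)] + \
              [f"trt_{i + 1}" for i in range(replicates)]
    rows = []
    for pe in events:
        ev = pe.event
        row = {"event_id": ev.event_id, "gene_id": ev.gene_id,
               "transcript_id": ev.transcript_id, "event_type": ev.event_type,
               "chrom": ev.chrom, "strand": ev.strand,
               "start": ev.segment.start, "end": ev.segment.end,
               "n_inc_junc": ev.n_inc_junctions, "n_exc_junc": ev.n_exc_junctions}
        for sample in samples:
            psi = pe.psi_control if sample.startswith("ctrl") else pe.psi_treated
            if psi in (0.0, 1.0) or dispersion == 0.0:
                p_star = psi
            else:
                conc = (1.0 - dispersion) / dispersion
                p_star = rng.beta(psi * conc, (1.0 - psi) * conc)
            inc = int(rng.binomial(coverage, p_star))
            row[f"{sample}_inc"] = inc
            row[f"{sample}_exc"] = coverage - inc
        rows.append(row)
    return pd.DataFrame(rows)


def events_from_genome(bundle: GenomeBundle, retained_fraction: float = 1.0,
                       psi_control: float = 0.05, psi_treated: float = 0.6,
                       seed: int = 0) -> list[PlantedEvent]:
    """Planted intron-retention events over a genome bundle's designated
    retained introns: treatment raises PSI (more retention) for a fraction
    of introns; the rest stay at the control level in both conditions."""
    rng = np.random.default_rng(seed)
    events = []
    n = len(bundle.retained_introns)
    affected = set(rng.choice(n, size=int(round(retained_fraction * n)),
                              replace=False).tolist())
    for i, intron in enumerate(bundle.retained_introns):
        ev = SpliceEvent(event_id=intron["intron_id"],
                         gene_id=intron["transcript_id"].replace("TX", "GENE"),
                         transcript_id=intron["transcript_id"],
                         chrom=intron["chrom"], strand=intron["strand"],
                         segment=Interval(intron["start"], intron["end"]),
                         event_type="IR", n_inc_junctions=2, n_exc_junctions=1)
        psi_t = psi_treated if i in affected else psi_control
        events.append(PlantedEvent(event=ev, psi_control=psi_control,
                                   psi_treated=psi_t))
    return events


# -------------------------------------------------- ORF test constructions

def gen_cds_locus(seed: int = 0, intron1_codons: list[str] | None = None,
                  exon2_codons: list[str] | None = None
                  ) -> tuple[str, TranscriptModel]:
    """A plus-strand 3-exon transcript on a 600-bp chromosome, for
    ORF-impact constructions.

    Layout: e1 [100,160) / i1 [160,280) / e2 [280,340) / i2 [340,460) /
    e3 [460,520); the CDS covers the whole mature transcript (180 nt) and
    is stop-free except for the annotated terminal stop.  Intron and exon
    sequences can be overridden codon-wise (in the reading frame of the
    intron-retained isoform, which intron 1 enters at frame 0) to plant or
    avoid premature stop codons.
    """
    rng = np.random.default_rng(seed)
    chrom = list(rng.choice(_BASES, size=600))
    exons = [Interval(100, 160), Interval(280, 340), Interval(460, 520)]
    tx = TranscriptModel(transcript_id="TOY", gene_id="TOYG", chrom="chrT",
                         strand="+", exons=exons, cds_start=100, cds_end=520)
    n_codons = 180 // 3
    codons = ["ATG"] + [str(rng.choice(_SAFE_CODONS))
                        for _ in range(n_codons - 2)] + ["TAA"]
    mrna = "".join(codons)
    positions = [p for e in exons for p in range(e.start, e.end)]
    for i, base in enumerate(mrna):
        chrom[positions[i]] = base
    i1 = intron1_codons or [str(rng.choice(_SAFE_CODONS)) for _ in range(40)]
    chrom[160:280] = list("".join(i1))
    i2 = [str(rng.choice(_SAFE_CODONS)) for _ in range(40)]
    chrom[340:460] = list("".join(i2))
    if exon2_codons is not None:
        chrom[280:340] = list("".join(exon2_codons))
    return "".join(chrom), tx


def mirror_genome(seq: str, tx: TranscriptModel,
                  segment: Interval) -> tuple[str, TranscriptModel, Interval]:
    """Mirror a chromosome: flip coordinates and strands, reverse-complement
    the sequence.  Event typing and ORF labels must survive this."""
    L = len(seq)
    m_exons = [Interval(L - e.end, L - e.start) for e in tx.exons]
    m_tx = TranscriptModel(transcript_id=tx.transcript_id, gene_id=tx.gene_id,
                           chrom=tx.chrom,
                           strand="-" if tx.strand == "+" else "+",
                           exons=m_exons,
                           cds_start=L - tx.cds_end if tx.cds_end is not None else None,
                           cds_end=L - tx.cds_start if tx.cds_start is not None else None)
    return _revcomp(seq), m_tx, Interval(L - segment.end, L - segment.start)


# --------------------------------------------------------------- screen

def gen_screen(seed: int, n_compounds: int = 36, n_lines: int = 15,
               planted_hits: list[str] | None = None,
               hit_line_fraction: float = 0.5, noise_sd: float = 0.05,
               replicates: int = 4,
               compounds: list[str] | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Screen confluence table with planted hit compounds.

    Returns ``(raw_confluence, dmso_wells, planted_hits)``:
    raw confluence has one row per compound replicate (repeated compound
    index), columns = cell lines; DMSO wells are per-line replicate
    measurements.  Planted hits get normalized confluence drawn from
    U(0.15, 0.45) in ``hit_line_fraction`` of the lines (>=1/3 by
    default construction) and near-control values elsewhere; non-hits sit
    near 1 with Gaussian noise.
    """
    if compounds is None:
        compounds = [f"CPD{i + 1:03d}" for i in range(n_compounds)]
    if len(set(compounds)) != len(compounds):
        raise ValueError("duplicate compound names")
    if planted_hits is None:
        planted_hits = []
    unknown = [h for h in planted_hits if h not in compounds]
    if unknown:
        raise ValueError(f"planted hits not among compounds: {unknown}")
    rng = np.random.default_rng(seed)
    lines = [f"LINE{j + 1:02d}" for j in range(n_lines)]
    dmso_level = 0.6  # absolute confluence fraction of DMSO wells
    n_resp = max(int(np.ceil(n_lines / 3.0)),
                 int(round(hit_line_fraction * n_lines)))

    norm_targets = np.empty((len(compounds), n_lines))
    for i, cpd in enumerate(compounds):
        if cpd in planted_hits:
            resp = rng.choice(n_lines, size=n_resp, replace=False)
            vals = np.clip(rng.normal(1.0, noise_sd, size=n_lines), 0.55, 1.2)
            vals[resp] = rng.uniform(0.15, 0.45, size=n_resp)
        else:
            vals = np.clip(rng.normal(1.0, noise_sd, size=n_lines), 0.55, 1.2) \
                if noise_sd > 0 else np.ones(n_lines)
        norm_targets[i] = vals

    rep_rows = []
    index = []
    for i, cpd in enumerate(compounds):
        for _ in range(replicates):
            jitter = rng.normal(0.0, noise_sd / 4.0, size=n_lines) \
                if noise_sd > 0 else 0.0
            rep_rows.append((norm_targets[i] + jitter) * dmso_level)
            index.append(cpd)
    raw = pd.DataFrame(np.clip(rep_rows, 0.0, None), index=index, columns=lines)
    raw.index.name = "compound"
    dmso = pd.DataFrame(np.full((replicates, n_lines), dmso_level),
                        index=[f"dmso_{r + 1}" for r in range(replicates)],
                        columns=lines)
    return raw, dmso, list(planted_hits)
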