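"""Readers and writers for the formats the pipeline consumes.

FASTA goes through Biopython; GTF and RepeatMasker .out use small dedicated
parsers because the toy annotation bundles here need only the gene_id /
transcript_id attributes and the standard 15-column repeat table.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .models import Interval, RepeatFeature, TranscriptModel


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ------------------------------------------------------------------ GTF

def _gtf_attributes(gene_id: str, transcript_id: str) -> str:
    return f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'


def write_gtf(transcripts: list[TranscriptModel], path: str | Path,
              source: str = "vmtools") -> None:
    """Write transcript models as GTF v2.2 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = _gtf_attributes(tx.gene_id, tx.transcript_id)
            span = tx.span
            fh.write("\t".join([tx.chrom, source, "transcript", str(span.start + 1),
                                str(span.end), ".", tx.strand, ".", attrs]) + "\n")
            for exon in tx.exons:
                fh.write("\t".join([tx.chrom, source, "exon", str(exon.start + 1),
                                    str(exon.end), ".", tx.strand, ".", attrs]) + "\n")
            if tx.has_cds:
                fh.write("\t".join([tx.chrom, source, "CDS", str(tx.cds_start + 1),
                                    str(tx.cds_end), ".", tx.strand, ".", attrs]) + "\n")


def _parse_attr(attr_field: str, key: str) -> str | None:
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse GTF exon/CDS rows into transcript models (0-based half-open)."""
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    cds: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise DataError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            tid = _parse_attr(attrs, "transcript_id")
            gid = _parse_attr(attrs, "gene_id")
            if tid is None or gid is None:
                raise DataError(f"{path}: line {lineno}: missing gene_id/transcript_id")
            iv = Interval(int(start) - 1, int(end))
            meta.setdefault(tid, (gid, chrom, strand))
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
    out = []
    for tid, (gid, chrom, strand) in meta.items():
        cds_ivs = cds.get(tid, [])
        cds_start = min(iv.start for iv in cds_ivs) if cds_ivs else None
        cds_end = max(iv.end for iv in cds_ivs) if cds_ivs else None
        out.append(TranscriptModel(transcript_id=tid, gene_id=gid, chrom=chrom,
                                   strand=strand, exons=exons.get(tid, []),
                                   cds_start=cds_start, cds_end=cds_end))
    return out


# ----------------------------------------------------- RepeatMasker .out

_RMSK_HEADER = (
    "   SW  perc perc perc  query     position in query          matching   repeat       position in repeat\n"
    "score  div. del. ins.  sequence  begin    end     (left)    repeat     class/family begin  end    (left)  ID\n"
    "\n"
)


def write_repeatmasker(repeats: list[RepeatFeature], path: str | Path,
                       chrom_lengths: dict[str, int] | None = None) -> None:
    """Write features in RepeatMasker .out layout (1-based inclusive, C = minus)."""
    chrom_lengths = chrom_lengths or {}
    with open(path, "w") as fh:
        fh.write(_RMSK_HEADER)
        for i, rep in enumerate(repeats, 1):
            clen = chrom_lengths.get(rep.chrom, rep.end)
            left = clen - rep.end
            strand = "+" if rep.strand == "+" else "C"
            rclass = "SINE/Alu" if rep.is_alu else "Unknown"
            row = (f"  225  10.0  0.0  0.0  {rep.chrom}  {rep.start + 1}  {rep.end}  "
                   f"({left})  {strand}  {rep.family}  {rclass}  1  {len(rep.interval)}  (0)  {i}")
            fh.write(row + "\n")


def read_repeatmasker(path: str | Path) -> list[RepeatFeature]:
    """Parse a RepeatMasker .out file.

    Converts 1-based inclusive coordinates to 0-based half-open and maps the
    "C" strand code to "-".  Non-Alu families are retained; downstream code
    filters on :attr:`RepeatFeature.is_alu`.
    """
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            # the two banner lines of the standard header
            if stripped.startswith(("SW", "score")):
                continue
            fields = stripped.split()
            if len(fields) < 11:
                raise DataError(f"{path}: line {lineno}: too few columns for .out row")
            try:
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: bad coordinates") from exc
            strand_code = fields[8]
            if strand_code == "+":
                strand = "+"
            elif strand_code in ("C", "-"):
                strand = "-"
            else:
                raise DataError(f"{path}: line {lineno}: bad strand {strand_code!r}")
            repeats.append(RepeatFeature(chrom=fields[4], start=begin - 1, end=end,
                                         strand=strand, family=fields[9]))
    return repeats


# ------------------------------------------------------------------ GMT

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}: line {lineno}: GMT rows need >=3 fields")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ------------------------------------------------------------------ TSV

def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# ------------------------------------------------------------------ BED

def write_bed6(rows: list[tuple[str, int, int, str, float, str]], path: str | Path) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5]))
    return rows
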