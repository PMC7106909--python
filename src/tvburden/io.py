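"""Readers and writers for the standard formats the pipeline consumes.

Coordinate conventions handled here so the rest of the package works in a
single convention (1-based, closed):

* VCF: 1-based positions (pysam exposes 0-based ``start``; converted back).
* BED coverage: 0-based, half-open intervals with a depth column.
* STAR SJ.out.tab: 1-based first and last intronic base of each junction.
* GTF (GENCODE dialect): 1-based, closed exon coordinates.

All tabular outputs are TSV with a header and a schema-version comment line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .consensus import VariantCall
from .junctions import JunctionRecord, SpliceAnnotation

SCHEMA_COMMENT = "# tvburden-table v1"

# STAR SJ.out.tab motif codes -> canonical motif names
SJ_MOTIF_CODES = {0: "other", 1: "GT-AG", 2: "GT-AG", 3: "GC-AG", 4: "GC-AG", 5: "AT-AC", 6: "AT-AC"}
SJ_MOTIF_TO_CODE = {"other": 0, "GT-AG": 1, "GC-AG": 3, "AT-AC": 5}
SJ_STRAND_CODES = {0: ".", 1: "+", 2: "-"}
SJ_STRAND_TO_CODE = {".": 0, "+": 1, "-": 2}


# ---------------------------------------------------------------------------
# coordinate conversions

def bed_to_closed(start: int, end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based closed interval."""
    return start + 1, end


def closed_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based closed interval -> 0-based half-open BED interval."""
    return start - 1, end


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path, caller: str = "") -> list[VariantCall]:
    """Read a VCF into normalized VariantCalls; multi-allelic records split."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            try:
                for alt in rec.alts or ():
                    calls.append(
                        VariantCall.normalized(
                            rec.chrom, rec.pos, rec.ref, alt, caller=caller
                        )
                    )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record #{i + 1}: {exc}") from exc
    return calls


def write_vcf(path: str | Path, variants: Iterable[VariantCall | tuple]) -> None:
    """Write normalized variants as a minimal, sorted VCF 4.2 file."""
    rows = []
    for v in variants:
        if isinstance(v, VariantCall):
            rows.append((v.chrom, v.pos, v.ref, v.alt, v.caller))
        else:
            chrom, pos, ref, alt = v
            rows.append((chrom, pos, ref, alt, ""))
    rows.sort()
    contigs = sorted({r[0] for r in rows})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=CALLER,Number=1,Type=String,Description="Emitting variant caller">\n'
        )
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, caller in rows:
            info = f"CALLER={caller}" if caller else "."
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# BED coverage

def read_bed_coverage(path: str | Path) -> list[tuple[str, int, int, int]]:
    """BED intervals with a depth column (chrom, start, end, depth)."""
    track = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 BED columns")
            chrom, start, end, depth = fields[:4]
            track.append((chrom, int(start), int(end), int(depth)))
    return track


def write_bed_coverage(path: str | Path, track: Iterable[tuple[str, int, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, depth in track:
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


# ---------------------------------------------------------------------------
# STAR SJ.out.tab

def read_sj_tab(path: str | Path) -> list[JunctionRecord]:
    """Parse STAR SJ.out.tab; annotation flags are left False (fill from GTF)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 SJ.out.tab columns")
            chrom = fields[0]
            donor, acceptor = int(fields[1]), int(fields[2])
            strand = SJ_STRAND_CODES[int(fields[3])]
            motif = SJ_MOTIF_CODES[int(fields[4])]
            reads = int(fields[6])
            records.append(
                JunctionRecord(
                    chrom=chrom,
                    donor_pos=donor,
                    acceptor_pos=acceptor,
                    strand=strand,
                    motif=motif,
                    reads=reads,
                )
            )
    return records


def write_sj_tab(path: str | Path, records: Iterable[JunctionRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom,
                        r.donor_pos,
                        r.acceptor_pos,
                        SJ_STRAND_TO_CODE[r.strand],
                        SJ_MOTIF_TO_CODE[r.motif],
                        int(r.fully_annotated),
                        r.reads,
                        0,
                        50,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF (GENCODE dialect)

def read_gtf_transcripts(path: str | Path) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """Exon structures per transcript: {tid: (chrom, [(start, end), ...])}."""
    transcripts: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "exon":
                continue
            chrom, start, end = fields[0], int(fields[3]), int(fields[4])
            tid = None
            for attr in fields[8].split(";"):
                attr = attr.strip()
                if attr.startswith("transcript_id"):
                    tid = attr.split('"')[1]
                    break
            if tid is None:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            transcripts.setdefault(tid, (chrom, []))[1].append((start, end))
    return {tid: (chrom, sorted(exons)) for tid, (chrom, exons) in transcripts.items()}


def write_gtf(path: str | Path, transcripts: Mapping[str, tuple[str, list[tuple[int, int]]]]) -> None:
    with open(path, "w") as fh:
        for tid, (chrom, exons) in transcripts.items():
            gene = tid.rsplit(".", 1)[0]
            attrs = f'gene_id "{gene}"; transcript_id "{tid}";'
            start = min(e[0] for e in exons)
            end = max(e[1] for e in exons)
            fh.write(f"{chrom}\tsyn\ttranscript\t{start}\t{end}\t.\t+\t.\t{attrs}\n")
            for s, e in sorted(exons):
                fh.write(f"{chrom}\tsyn\texon\t{s}\t{e}\t.\t+\t.\t{attrs}\n")


def splice_annotation_from_gtf(path: str | Path) -> SpliceAnnotation:
    return SpliceAnnotation.from_transcript_exons(read_gtf_transcripts(path))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV tables with schema comment

def write_table(df: pd.DataFrame, path: str | Path, name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_COMMENT} {name}\n")
        df.to_csv(fh, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
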