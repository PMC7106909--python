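"""Tumor-specific splice junction identification.

Junction calls from tumor RNA-seq (STAR SJ.out.tab dialect: 1-based
coordinates of the first and last intronic base) are filtered against a
compendium of junctions ever observed in normal tissue (GTEx, TCGA matched
normals, normal melanocytes).  Membership in the compendium is exact on the
identity key, and a single supporting read in a single normal sample is
enough to eliminate a junction.  Four removal rules apply:

  1. non-canonical splice motif (kept motifs: GT-AG, GC-AG, AT-AC);
  2. observed in any normal sample (compendium membership);
  3. the exact donor-acceptor pair occurs in an annotated transcript
     ("fully annotated");
  4. neither end matches an annotated splice site.

No minimum read support is required on the tumor side.  Strand participates
in the identity key only when both records have a known strand; unknown
strand ('.') matches either.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, replace
from typing import Iterable

CANONICAL_MOTIFS = frozenset({"GT-AG", "GC-AG", "AT-AC"})

JunctionKey = tuple[str, int, int]


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction; donor/acceptor are first/last intronic base (1-based)."""

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str = "."
    motif: str = "GT-AG"
    reads: int = 0
    left_annotated: bool = False
    right_annotated: bool = False
    fully_annotated: bool = False

    def __post_init__(self) -> None:
        if self.donor_pos >= self.acceptor_pos:
            raise ValueError(
                f"donor_pos must be < acceptor_pos at {self.chrom}:"
                f"{self.donor_pos}-{self.acceptor_pos}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.reads < 0:
            raise ValueError("reads must be >= 0")
        if self.fully_annotated and not (self.left_annotated and self.right_annotated):
            raise ValueError("fully_annotated requires both ends annotated")

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.donor_pos, self.acceptor_pos)


class JunctionCompendium:
    """Exact-key index of junctions observed in any normal sample."""

    def __init__(self) -> None:
        self._index: dict[JunctionKey, set[str]] = {}

    def __len__(self) -> int:
        return len(self._index)

    def add(self, chrom: str, donor_pos: int, acceptor_pos: int, strand: str = ".") -> None:
        self._index.setdefault((chrom, donor_pos, acceptor_pos), set()).add(strand)

    def add_record(self, rec: JunctionRecord) -> None:
        self.add(rec.chrom, rec.donor_pos, rec.acceptor_pos, rec.strand)

    def matches(self, rec: JunctionRecord) -> bool:
        """True when the record's identity key is in the compendium.

        Strand disambiguates only when both sides know it.
        """
        strands = self._index.get(rec.key)
        if strands is None:
            return False
        if rec.strand == "." or "." in strands:
            return True
        return rec.strand in strands

    def to_sqlite(self, path: str) -> None:
        """Persist the index as an embedded SQLite database."""
        con = sqlite3.connect(path)
        with con:
            con.execute("DROP TABLE IF EXISTS junctions")
            con.execute(
                "CREATE TABLE junctions (chrom TEXT, donor INTEGER, acceptor INTEGER,"
                " strand TEXT, PRIMARY KEY (chrom, donor, acceptor, strand))"
            )
            con.executemany(
                "INSERT INTO junctions VALUES (?, ?, ?, ?)",
                (
                    (chrom, donor, acceptor, strand)
                    for (chrom, donor, acceptor), strands in self._index.items()
                    for strand in strands
                ),
            )
        con.close()

    @classmethod
    def from_sqlite(cls, path: str) -> "JunctionCompendium":
        comp = cls()
        con = sqlite3.connect(path)
        for chrom, donor, acceptor, strand in con.execute(
            "SELECT chrom, donor, acceptor, strand FROM junctions"
        ):
            comp.add(chrom, donor, acceptor, strand)
        con.close()
        return comp


def build_compendium(
    normal_junction_tables: Iterable[Iterable[JunctionRecord]],
) -> JunctionCompendium:
    """Union of junction identity keys across normal-sample tables.

    A junction with a single supporting read in a single normal sample is
    included: any normal evidence at all later eliminates the junction from
    tumor sets.
    """
    comp = JunctionCompendium()
    for table in normal_junction_tables:
        for rec in table:
            comp.add_record(rec)
    return comp


def tumor_specific_junctions(
    patient_junctions: Iterable[JunctionRecord],
    compendium: JunctionCompendium,
) -> list[JunctionRecord]:
    """Apply the four removal rules; order-stable pure set filter."""
    out = []
    for j in patient_junctions:
        if j.motif not in CANONICAL_MOTIFS:
            continue
        if compendium.matches(j):
            continue
        if j.fully_annotated:
            continue
        if not (j.left_annotated or j.right_annotated):
            continue
        out.append(j)
    return out


def junction_burden(tumor_specific: Iterable[JunctionRecord]) -> int:
    """Count of distinct retained junction identity keys."""
    return len({j.key for j in tumor_specific})


@dataclass
class SpliceAnnotation:
    """Annotated splice sites and donor-acceptor pairs derived from a gene model."""

    donor_sites: set[tuple[str, int]]
    acceptor_sites: set[tuple[str, int]]
    pairs: set[JunctionKey]

    @classmethod
    def from_transcript_exons(
        cls, transcripts: dict[str, tuple[str, list[tuple[int, int]]]]
    ) -> "SpliceAnnotation":
        """Build from {transcript_id: (chrom, [(exon_start, exon_end), ...])},
        with 1-based inclusive exon coordinates sorted by start."""
        donors: set[tuple[str, int]] = set()
        acceptors: set[tuple[str, int]] = set()
        pairs: set[JunctionKey] = set()
        for chrom, exons in transcripts.values():
            exons = sorted(exons)
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                donor, acceptor = e1 + 1, s2 - 1  # first/last intronic base
                if donor > acceptor:
                    continue
                donors.add((chrom, donor))
                acceptors.add((chrom, acceptor))
                pairs.add((chrom, donor, acceptor))
        return cls(donor_sites=donors, acceptor_sites=acceptors, pairs=pairs)

    def annotate(self, rec: JunctionRecord) -> JunctionRecord:
        """Return a copy of ``rec`` with annotation flags filled in."""
        left = (rec.chrom, rec.donor_pos) in self.donor_sites
        right = (rec.chrom, rec.acceptor_pos) in self.acceptor_sites
        full = rec.key in self.pairs
        return replace(
            rec, left_annotated=left, right_annotated=right, fully_annotated=full
        )
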