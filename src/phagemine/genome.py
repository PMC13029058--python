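"""FASTA/GFF3 I/O, ORF detection, and translation for phage contigs.

Coordinates follow the GFF3 convention throughout the package: 1-based,
inclusive, always reported on the forward strand, with a separate strand
field. An ORF span includes its stop codon; the translated protein does not
include the terminal stop. Start codons default to the bacterial set
(ATG/GTG/TTG, code table 11) and alternative starts are rendered as M.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils.feature
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence (uppercase)."""

    id: str
    seq: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"illegal {self.alphabet} characters {sorted(bad)} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneFeature:
    """A gene on a contig: 1-based inclusive span, forward-strand coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str = "cds"
    id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span {self.start}..{self.end} for {self.id!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def overlaps(self, start: int, end: int) -> bool:
        return not (end < self.start or start > self.end)


@dataclass(frozen=True)
class OrfRecord:
    """A complete ORF (start codon through in-frame stop) and its protein."""

    feature: GeneFeature
    aa_seq: str
    aa_length: int


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a multi-record FASTA; sequences are uppercased, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        SequenceRecord(rec.id, str(rec.seq), alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_gff3(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 (type CDS; the kind is kept in the attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id};kind={f.kind}"
            fh.write(
                "\t".join(
                    [f.contig_id, "phagemine", "CDS", str(f.start), str(f.end), ".", f.strand, "0", attrs]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GeneFeature]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    features = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = gffutils.feature.feature_from_line(line)
            features.append(
                GeneFeature(
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    kind=feat.attributes.get("kind", ["cds"])[0],
                    id=feat.attributes.get("ID", [""])[0],
                )
            )
    return features


def translate(nt_seq: str, genetic_code: int = 11) -> str:
    """Translate a coding sequence; stops render as ``*``, N-codons as ``X``."""
    if len(nt_seq) % 3:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    forward = table.forward_table
    stops = set(table.stop_codons)
    out = []
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i : i + 3].upper()
        if codon in stops:
            out.append("*")
        elif codon in forward:
            out.append(forward[codon])
        else:
            out.append("X")
    return "".join(out)


def find_orfs(
    contig: SequenceRecord,
    min_aa_length: int = 1,
    genetic_code: int = 11,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[OrfRecord]:
    """All complete ORFs (start codon ... in-frame stop) on both strands.

    Nested ORFs sharing a stop are all reported; use :func:`longest_orfs`
    to collapse to one ORF per stop. Coordinates are forward-strand and
    include the stop codon. Alternative start codons translate to M.
    """
    if contig.alphabet != "dna":
        raise ValueError("find_orfs requires a dna-alphabet contig")
    if min_aa_length < 1:
        raise ValueError("min_aa_length must be >= 1")
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    stops = set(table.stop_codons)
    starts = set(c.upper() for c in start_codons)
    n = len(contig.seq)
    orfs: list[OrfRecord] = []
    for strand, seq in (("+", contig.seq), ("-", reverse_complement(contig.seq))):
        for frame in range(3):
            open_starts: list[int] = []
            for i in range(frame, n - 2, 3):
                codon = seq[i : i + 3]
                if codon in stops:
                    for s in open_starts:
                        aa_len = (i - s) // 3
                        if aa_len < min_aa_length:
                            continue
                        aa = "M" + (translate(seq[s + 3 : i], genetic_code) if i > s + 3 else "")
                        p1, p2 = s + 1, i + 3  # strand-local 1-based span incl. stop
                        if strand == "+":
                            start, end = p1, p2
                        else:
                            start, end = n - p2 + 1, n - p1 + 1
                        feat = GeneFeature(
                            contig_id=contig.id,
                            start=start,
                            end=end,
                            strand=strand,
                            kind="cds",
                            id=f"orf|{contig.id}|{strand}|{start}-{end}",
                        )
                        orfs.append(OrfRecord(feat, aa, aa_len))
                    open_starts = []
                elif codon in starts:
                    open_starts.append(i)
    orfs.sort(key=lambda o: (o.feature.start, o.feature.end, o.feature.strand))
    return orfs


def longest_orfs(orfs: Iterable[OrfRecord]) -> list[OrfRecord]:
    """Collapse nested ORFs to the longest one per (contig, strand, stop)."""
    best: dict[tuple, OrfRecord] = {}
    for orf in orfs:
        f = orf.feature
        stop = f.end if f.strand == "+" else f.start
        key = (f.contig_id, f.strand, stop)
        if key not in best or orf.aa_length > best[key].aa_length:
            best[key] = orf
    return sorted(best.values(), key=lambda o: (o.feature.contig_id, o.feature.start))


def retranslate(orf: OrfRecord, contig: SequenceRecord, genetic_code: int = 11) -> str:
    """Recover an ORF's protein from its coordinates (consistency check)."""
    f = orf.feature
    nt = contig.seq[f.start - 1 : f.end]
    if f.strand == "-":
        nt = reverse_complement(nt)
    return "M" + translate(nt[3:-3], genetic_code) if len(nt) > 6 else "M"
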