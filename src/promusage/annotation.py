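"""Gene models and isoform-discriminating first-exon regions.

A gene transcribed from several alternative promoters produces transcript
isoforms that differ in their first exon but share downstream exons.  Reads
mapping to the part of a first exon that no other isoform uses are therefore
unambiguous evidence for one promoter.  This module parses gene models from
GTF, and for a multi-isoform gene derives the *unique* portion of each
isoform's first exon — the promoter-proxy regions the counting stage
quantifies.

Coordinates are 1-based inclusive throughout (the GTF convention); the BED
exporter converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "FirstExonSet",
    "parse_gtf",
    "derive_first_exons",
    "write_first_exon_bed",
]

DEFAULT_MIN_UNIQUE_LENGTH = 25
"""Minimum length (bases) of a usable unique first-exon region.

Shorter regions cannot reliably anchor a 150-nt read; configurable per call.
"""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval on one strand (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with *other* (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class TranscriptModel:
    """One transcript isoform: ordered exons in transcription (5'->3') order."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes {chroms}")
        if any(e.strand != self.strand for e in self.exons):
            raise ValueError(f"transcript {self.transcript_id} has mixed exon strands")
        # transcription order: ascending coordinates on +, descending on -
        ordered = sorted(self.exons, key=lambda e: e.start, reverse=(self.strand == "-"))
        if ordered != self.exons:
            raise ValueError(
                f"exons of {self.transcript_id} not in transcription order"
            )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start <= a.end + 1:  # overlap or abutting (no intron)
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or lack an intron: "
                    f"{a.start}-{a.end} vs {b.start}-{b.end}"
                )

    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons[0]

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A gene: one or more transcript isoforms sharing a gene_id."""

    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ValueError(f"transcript gene_ids disagree with {self.gene_id}")


@dataclass
class FirstExonSet:
    """Isoform-discriminating first-exon regions of one gene.

    ``regions`` maps a promoter id (``P1`` is the 5'-most promoter in
    transcription direction) to the pieces of that isoform's first exon that
    overlap no exon of any other isoform.  ``transcript_ids`` records which
    isoforms each promoter drives (isoforms with byte-identical first exons
    collapse onto one promoter).
    """

    gene_id: str
    regions: dict[str, list[GenomicInterval]]
    transcript_ids: dict[str, list[str]]
    min_unique_length: int

    def unique_length(self, promoter_id: str) -> int:
        return sum(len(r) for r in self.regions[promoter_id])

    @property
    def promoter_ids(self) -> list[str]:
        return list(self.regions)


# ---------------------------------------------------------------------------
# GTF parsing

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]*)"')
_TX_ID_RE = re.compile(r'transcript_id\s+"([^"]*)"')


def parse_gtf(path: str) -> list[GeneModel]:
    """Parse gene models from a GTF file (Ensembl dialect).

    Only ``exon`` feature lines contribute exons; transcripts are assembled
    from their exon lines and grouped by gene, both in order of first
    appearance.  Exons are returned in transcription order (ascending
    coordinates on ``+``, descending on ``-``).

    Raises
    ------
    ValueError
        On a malformed line (naming its line number) or a transcript that
        appears in the file but has no exon lines.
    """
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_strand: dict[str, str] = {}
    seen_tx: dict[str, None] = {}  # insertion-ordered set of transcript ids
    gene_order: dict[str, None] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            m_gene = _GENE_ID_RE.search(attrs)
            m_tx = _TX_ID_RE.search(attrs)
            if m_gene is None:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")
            gene_order.setdefault(m_gene.group(1), None)
            if m_tx is None:
                continue  # gene-level line
            tx_id = m_tx.group(1)
            seen_tx.setdefault(tx_id, None)
            tx_gene[tx_id] = m_gene.group(1)
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            tx_exons.setdefault(tx_id, []).append(iv)
            tx_strand[tx_id] = strand

    empty = [t for t in seen_tx if t not in tx_exons]
    if empty:
        raise ValueError(f"{path}: transcripts with zero exons: {', '.join(empty)}")

    genes: dict[str, list[TranscriptModel]] = {g: [] for g in gene_order}
    for tx_id in seen_tx:
        strand = tx_strand[tx_id]
        exons = sorted(tx_exons[tx_id], key=lambda e: e.start, reverse=(strand == "-"))
        tm = TranscriptModel(tx_id, tx_gene[tx_id], strand, exons)
        genes.setdefault(tm.gene_id, []).append(tm)
    return [GeneModel(g, txs) for g, txs in genes.items() if txs]


# ---------------------------------------------------------------------------
# First-exon derivation

def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive (start, end) pairs into disjoint sorted pairs."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(iv: GenomicInterval, blockers: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pieces of *iv* not covered by any merged blocker interval."""
    pieces: list[tuple[int, int]] = []
    cur = iv.start
    for bs, be in blockers:
        if be < cur or bs > iv.end:
            continue
        if bs > cur:
            pieces.append((cur, bs - 1))
        cur = max(cur, be + 1)
        if cur > iv.end:
            break
    if cur <= iv.end:
        pieces.append((cur, iv.end))
    return pieces


def derive_first_exons(
    gene: GeneModel, min_unique_length: int = DEFAULT_MIN_UNIQUE_LENGTH
) -> FirstExonSet:
    """Derive the isoform-discriminating first-exon regions of *gene*.

    For each distinct first exon, subtract every base that any exon of any
    other isoform covers; what remains uniquely identifies that promoter's
    transcripts.  Isoforms sharing an identical first exon collapse to one
    promoter.  Promoters whose unique residue has no piece of at least
    ``min_unique_length`` bases are unobservable by read counting and are
    excluded with a warning; fewer than two usable promoters is an error.

    Promoter ids ``P1..Pk`` follow transcription direction (5'-most first).
    """
    if len(gene.transcripts) < 2:
        raise ValueError(
            f"gene {gene.gene_id}: promoter-usage analysis needs >=2 transcripts"
        )
    strand = gene.transcripts[0].strand

    # group transcripts by identical first exon
    groups: dict[GenomicInterval, list[TranscriptModel]] = {}
    for tx in gene.transcripts:
        groups.setdefault(tx.first_exon, []).append(tx)

    # 5'-most first: ascending TSS on +, descending on -
    def tss(fe: GenomicInterval) -> int:
        return fe.start if strand == "+" else -fe.end

    ordered = sorted(groups, key=tss)

    regions: dict[str, list[GenomicInterval]] = {}
    tx_ids: dict[str, list[str]] = {}
    dropped: list[str] = []
    for fe in ordered:
        members = groups[fe]
        others = [
            (e.start, e.end)
            for tx in gene.transcripts
            if tx not in members
            for e in tx.exons
            if e.chrom == fe.chrom
        ]
        pieces = [
            p for p in _subtract(fe, _merge(others))
            if p[1] - p[0] + 1 >= min_unique_length
        ]
        label = "/".join(t.transcript_id for t in members)
        if not pieces:
            dropped.append(label)
            continue
        pid = f"P{len(regions) + 1}"
        regions[pid] = [GenomicInterval(fe.chrom, s, e, strand) for s, e in pieces]
        tx_ids[pid] = [t.transcript_id for t in members]

    if dropped:
        warnings.warn(
            f"gene {gene.gene_id}: first exon(s) of {', '.join(dropped)} have no "
            f"unique region >= {min_unique_length} b; promoter(s) excluded as "
            "unobservable",
            stacklevel=2,
        )
    if len(regions) < 2:
        raise ValueError(
            f"gene {gene.gene_id}: fewer than 2 usable promoters "
            f"(got {len(regions)})"
        )
    return FirstExonSet(gene.gene_id, regions, tx_ids, min_unique_length)


def write_first_exon_bed(fes: FirstExonSet, path: str) -> None:
    """Write promoter-proxy regions as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for pid, ivs in fes.regions.items():
            for iv in ivs:
                fh.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                    f"{fes.gene_id}|{pid}\t0\t{iv.strand}\n"
                )
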