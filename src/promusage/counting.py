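"""Count reads supporting each promoter's first exon from spliced alignments.

A read supports promoter *i* when its aligned reference bases (CIGAR M/=/X
blocks; N, D, S, I contribute nothing) overlap that promoter's unique
first-exon regions by at least ``min_overlap`` bases.  Because the regions of
different promoters are disjoint, a read can only qualify for two promoters by
bridging both; such reads go to the promoter with the larger overlap, ties are
discarded.  Counts are normalized to RPM (reads per million) against the
whole-file count of mapped units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pysam

from .annotation import FirstExonSet

__all__ = [
    "AlignmentPolicy",
    "FirstExonCounts",
    "RpmVector",
    "count_first_exon_reads",
    "rpm_normalize",
    "write_counts_tsv",
]


@dataclass(frozen=True)
class AlignmentPolicy:
    """Filters and conventions for assigning alignment records to promoters.

    Defaults are conventional: unstranded libraries, per-read counting,
    MAPQ >= 20, at least a 10-base overlap with a unique first-exon region,
    duplicates included.
    """

    min_overlap: int = 10
    min_mapq: int = 20
    strandedness: Literal["unstranded", "forward", "reverse"] = "unstranded"
    count_unit: Literal["read", "fragment"] = "read"
    include_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.strandedness not in ("unstranded", "forward", "reverse"):
            raise ValueError(f"bad strandedness {self.strandedness!r}")
        if self.count_unit not in ("read", "fragment"):
            raise ValueError(f"bad count_unit {self.count_unit!r}")


@dataclass
class FirstExonCounts:
    """Per-sample first-exon counts for one gene.

    ``library_size`` is the number of counted units (reads or fragments) in
    the whole file that are mapped, primary, non-supplementary and pass MAPQ —
    the RPM denominator.  ``ties_discarded`` records units dropped because two
    promoters tied for the larger overlap (or, in fragment mode, mates voted
    for different promoters).
    """

    sample_id: str
    gene_id: str
    counts: dict[str, int]
    library_size: int
    ties_discarded: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RpmVector:
    sample_id: str
    gene_id: str
    rpm: dict[str, float]


def _region_arrays(fes: FirstExonSet) -> dict[str, list[tuple[int, int]]]:
    """Promoter regions as 0-based half-open (start, end) pairs."""
    return {
        pid: [(iv.start - 1, iv.end) for iv in ivs]
        for pid, ivs in fes.regions.items()
    }


def _overlap_len(blocks: list[tuple[int, int]], regions: list[tuple[int, int]]) -> int:
    total = 0
    for bs, be in blocks:
        for rs, re_ in regions:
            total += max(0, min(be, re_) - max(bs, rs))
    return total


def _strand_ok(rec: pysam.AlignedSegment, feature_strand: str, mode: str) -> bool:
    if mode == "unstranded":
        return True
    read_strand = "-" if rec.is_reverse else "+"
    # in a stranded protocol mate 2 reports the opposite strand of its fragment
    if rec.is_paired and rec.is_read2:
        read_strand = "-" if read_strand == "+" else "+"
    if mode == "forward":
        return read_strand == feature_strand
    return read_strand != feature_strand


def count_first_exon_reads(
    path: str,
    fes: FirstExonSet,
    policy: AlignmentPolicy | None = None,
    sample_id: str | None = None,
) -> FirstExonCounts:
    """Count alignment records in *path* (SAM or BAM) against *fes*.

    The file is streamed sequentially; unmapped, secondary and supplementary
    records never count, duplicates only if the policy includes them.  Every
    record passing those filters and MAPQ contributes to ``library_size``;
    assignment to a promoter additionally requires strand compatibility and a
    ``min_overlap``-base overlap with the promoter's regions.

    In fragment mode a read pair counts once: if both mates qualify for
    different promoters the fragment is discarded (tallied in
    ``ties_discarded``).
    """
    policy = policy or AlignmentPolicy()
    regions = _region_arrays(fes)
    chroms = {iv.chrom for ivs in fes.regions.values() for iv in ivs}
    feature_strand = next(iter(fes.regions.values()))[0].strand

    counts = {pid: 0 for pid in regions}
    ties = 0
    library = 0
    n_records = 0
    # fragment mode: qname -> (passed_any, votes per mate)
    frag_votes: dict[str, list[str]] = {}
    frag_seen: set[str] = set()

    with pysam.AlignmentFile(path, check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            n_records += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_duplicate and not policy.include_duplicates:
                continue
            if rec.mapping_quality < policy.min_mapq:
                continue
            if policy.count_unit == "read":
                library += 1
            else:
                if rec.query_name not in frag_seen:
                    frag_seen.add(rec.query_name)
                    library += 1
            if rec.reference_name not in chroms:
                continue
            if not _strand_ok(rec, feature_strand, policy.strandedness):
                continue
            blocks = rec.get_blocks()  # 0-based half-open M/=/X blocks
            best_pid: str | None = None
            best_ov = 0
            tie = False
            for pid, regs in regions.items():
                ov = _overlap_len(blocks, regs)
                if ov > best_ov:
                    best_pid, best_ov, tie = pid, ov, False
                elif ov == best_ov and ov > 0:
                    tie = True
            if best_ov < policy.min_overlap or best_pid is None:
                continue
            if tie:
                ties += 1
                continue
            if policy.count_unit == "read":
                counts[best_pid] += 1
            else:
                frag_votes.setdefault(rec.query_name, []).append(best_pid)

    if policy.count_unit == "fragment":
        for votes in frag_votes.values():
            if len(set(votes)) == 1:
                counts[votes[0]] += 1
            else:
                ties += 1

    if n_records == 0:
        warnings.warn(f"{path}: no alignment records; all counts zero", stacklevel=2)
    return FirstExonCounts(
        sample_id=sample_id or path,
        gene_id=fes.gene_id,
        counts=counts,
        library_size=library,
        ties_discarded=ties,
    )


def rpm_normalize(counts: FirstExonCounts) -> RpmVector:
    """Reads per million: count * 1e6 / library_size."""
    if counts.library_size <= 0:
        raise ValueError(
            f"sample {counts.sample_id}: library_size is 0, RPM undefined"
        )
    return RpmVector(
        sample_id=counts.sample_id,
        gene_id=counts.gene_id,
        rpm={
            pid: c * 1e6 / counts.library_size for pid, c in counts.counts.items()
        },
    )


def write_counts_tsv(counts_list: Iterable[FirstExonCounts], path: str) -> None:
    """Write per-sample counts and RPM as a long-format TSV."""
    with open(path, "w") as fh:
        fh.write("sample_id\tgene_id\tpromoter_id\tcount\tlibrary_size\trpm\n")
        for fc in counts_list:
            rpm = rpm_normalize(fc).rpm if fc.library_size > 0 else {
                pid: float("nan") for pid in fc.counts
            }
            for pid, c in fc.counts.items():
                fh.write(
                    f"{fc.sample_id}\t{fc.gene_id}\t{pid}\t{c}\t"
                    f"{fc.library_size}\t{rpm[pid]:.6f}\n"
                )
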