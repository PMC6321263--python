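"""Synthetic data with machine-readable truth for every pipeline stage.

The read simulator emulates the design this pipeline targets: one gene with
three alternative promoters, each driving an isoform with a distinct first
exon and shared downstream exons, sequenced as 150-nt paired-end reads with
three biological replicates per group.  Reads are emitted as already-aligned,
coordinate-sorted SAM (spliced CIGARs with N across introns), so tests stay
hermetic — no aligner is involved.  Every emitted read carries a truth label:
it supports a promoter iff its aligned bases overlap that isoform's unique
first-exon region by at least one base, judged in transcript coordinates,
independently of the counting module's genomic-interval path.

Note the two truths: the molar isoform mixture, and the expected *read-mass*
first-exon shares — the probability-weighted fraction of counted reads
overlapping each isoform's unique first exon, computed exactly under the
fragment sampling scheme (roughly: molar weighted by unique-first-exon length
over transcript length).  Read counting estimates the latter; with the
default equal exon lengths the two coincide exactly.

Count matrices are negative-binomial with log-normal gene means and a planted
fraction of fold-changes; annotation maps carry one deliberately
over-represented term.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import FirstExonSet, GeneModel, GenomicInterval, TranscriptModel, derive_first_exons
from .counting import FirstExonCounts

__all__ = [
    "SimConfig",
    "SimTruth",
    "CountMatrixSim",
    "AnnotationSim",
    "simulate_gene_model",
    "write_gtf",
    "simulate_alignments",
    "simulate_usage_counts",
    "simulate_count_matrix",
    "simulate_annotation",
]

# group-specific isoform mixtures: an obese-type breed favouring promoter 1
# and a lean-type breed favouring promoter 3, as observed for porcine PPARg
DEFAULT_MIXTURES: dict[str, tuple[float, ...]] = {
    "min": (0.3403, 0.1615, 0.4982),
    "dl": (0.1869, 0.1694, 0.6437),
}


@dataclass
class SimConfig:
    """Design of the simulated three-promoter gene and its sequencing.

    First-exon and shared-exon lengths default equal across isoforms so the
    expected first-exon read shares equal the molar mixture exactly.
    """

    n_isoforms: int = 3
    first_exon_lengths: tuple[int, ...] = (300, 300, 300)
    shared_exon_lengths: tuple[int, ...] = (300, 250, 450)
    intron_length: int = 700
    mixture: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_MIXTURES.items()}
    )
    reads_per_sample: int = 20_000
    samples_per_group: int = 3
    read_length: int = 150
    paired: bool = True
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    strand: str = "+"
    chrom: str = "chrSim"
    gene_id: str = "PPARG_like"
    softclip_max: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.first_exon_lengths) != self.n_isoforms:
            raise ValueError("first_exon_lengths must have one entry per isoform")
        for g, mix in self.mixture.items():
            if len(mix) != self.n_isoforms:
                raise ValueError(f"mixture for group {g!r} has wrong length")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"mixture for group {g!r} does not sum to 1")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be > 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


# ---------------------------------------------------------------------------
# gene model

def simulate_gene_model(cfg: SimConfig) -> GeneModel:
    """One gene, ``n_isoforms`` transcripts with distinct first exons followed
    by shared downstream exons, laid out with fixed intron gaps."""
    cursor = 1001
    fe: list[tuple[int, int]] = []
    for L in cfg.first_exon_lengths:
        fe.append((cursor, cursor + L - 1))
        cursor += L + cfg.intron_length
    shared: list[tuple[int, int]] = []
    for L in cfg.shared_exon_lengths:
        shared.append((cursor, cursor + L - 1))
        cursor += L + cfg.intron_length

    for (s1, e1), (s2, e2) in zip(fe, fe[1:]):
        if s2 <= e1:
            raise ValueError("first exons overlap in layout")

    glen = cursor + 1000
    if cfg.strand == "-":
        reflect = lambda p: (glen - p[1] + 1, glen - p[0] + 1)  # noqa: E731
        fe = [reflect(p) for p in fe]
        shared = [reflect(p) for p in shared]

    transcripts = []
    for i, (fs, fe_end) in enumerate(fe):
        coords = [(fs, fe_end)] + shared
        # transcription order: ascending on +, descending on -
        coords = sorted(coords, reverse=(cfg.strand == "-"))
        exons = [GenomicInterval(cfg.chrom, s, e, cfg.strand) for s, e in coords]
        transcripts.append(
            TranscriptModel(f"{cfg.gene_id}-{i + 1}", cfg.gene_id, cfg.strand, exons)
        )
    return GeneModel(cfg.gene_id, transcripts)


def write_gtf(model: GeneModel, path: str, source: str = "promusage_sim") -> None:
    """Serialize a gene model as GTF exon lines (Ensembl attribute dialect)."""
    with open(path, "w") as fh:
        for tx in model.transcripts:
            for e in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def genome_length(model: GeneModel, margin: int = 1000) -> int:
    return max(e.end for tx in model.transcripts for e in tx.exons) + margin


# ---------------------------------------------------------------------------
# coordinate projection helpers

class _TxMap:
    """Transcript-coordinate arithmetic for one isoform."""

    def __init__(self, tx: TranscriptModel):
        self.tx = tx
        self.exon_lengths = [len(e) for e in tx.exons]
        self.cum = np.cumsum([0] + self.exon_lengths)  # cum[k] = bases before exon k
        self.length = int(self.cum[-1])

    def to_genome_blocks(self, a: int, b: int) -> list[tuple[int, int]]:
        """Genomic blocks (1-based inclusive, ascending) of transcript [a, b]."""
        blocks = []
        for k, e in enumerate(self.tx.exons):
            lo = max(a, int(self.cum[k]) + 1)
            hi = min(b, int(self.cum[k + 1]))
            if lo > hi:
                continue
            off_lo, off_hi = lo - (int(self.cum[k]) + 1), hi - (int(self.cum[k]) + 1)
            if e.strand == "+":
                blocks.append((e.start + off_lo, e.start + off_hi))
            else:
                blocks.append((e.end - off_hi, e.end - off_lo))
        return sorted(blocks)

    def from_genome(self, iv: GenomicInterval) -> list[tuple[int, int]]:
        """Transcript-coordinate segments covered by genomic interval *iv*."""
        segs = []
        for k, e in enumerate(self.tx.exons):
            lo, hi = max(iv.start, e.start), min(iv.end, e.end)
            if lo > hi or iv.chrom != e.chrom:
                continue
            if e.strand == "+":
                a = int(self.cum[k]) + 1 + (lo - e.start)
                b = int(self.cum[k]) + 1 + (hi - e.start)
            else:
                a = int(self.cum[k]) + 1 + (e.end - hi)
                b = int(self.cum[k]) + 1 + (e.end - lo)
            segs.append((a, b))
        return sorted(segs)


def _cigar(blocks: list[tuple[int, int]], clip5: int = 0, clip3: int = 0) -> str:
    parts = []
    if clip5:
        parts.append(f"{clip5}S")
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1] - 1
            parts.append(f"{gap}N")
        parts.append(f"{e - s + 1}M")
    if clip3:
        parts.append(f"{clip3}S")
    return "".join(parts)


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class SimTruth:
    """Ground truth emitted alongside one sample's alignments."""

    sample_id: str
    molar_proportions: dict[str, float]  # promoter_id -> molar isoform fraction
    read_mass_shares: dict[str, float]  # expected first-exon read share
    reads: pd.DataFrame  # qname, mate, isoform, promoter_id ('' if none)
    promoter_of_isoform: dict[str, str]  # transcript_id -> promoter_id

    @property
    def truth_counts(self) -> dict[str, int]:
        """Reads overlapping each promoter's unique first-exon region >=1 b."""
        labelled = self.reads[self.reads["promoter_id"] != ""]
        out = {p: 0 for p in self.molar_proportions}
        out.update(labelled["promoter_id"].value_counts().to_dict())
        return out


def _qualifying_starts(segs: list[tuple[int, int]], r: int, lo: int, hi: int) -> int:
    """Number of start positions s in [lo, hi] whose read [s, s+r-1] overlaps
    any unique segment by >=1 base."""
    merged: list[tuple[int, int]] = []
    for a, b in sorted((a - r + 1, b) for a, b in segs):
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return sum(max(0, min(b, hi) - max(a, lo) + 1) for a, b in merged)


def _expected_read_mass_shares(
    mixture: np.ndarray,
    unique_segs: list[list[tuple[int, int]]],
    lengths: np.ndarray,
    cfg: SimConfig,
) -> np.ndarray:
    """Exact expected share of first-exon-overlapping reads per isoform under
    the fragment sampling scheme (uniform start, discretized truncated-normal
    fragment length; both mates of a pair counted as reads)."""
    from scipy.stats import norm

    r = cfg.read_length
    w = np.zeros(len(unique_segs))
    for i, segs in enumerate(unique_segs):
        L = int(lengths[i])
        if cfg.paired:
            ks = np.arange(r, L + 1)
            upper = norm.cdf(ks + 0.5, cfg.fragment_length_mean, cfg.fragment_length_sd)
            lower = norm.cdf(ks - 0.5, cfg.fragment_length_mean, cfg.fragment_length_sd)
            pf = upper - lower
            pf[0] = upper[0]  # rounding below r clips up to r
            pf /= pf.sum()  # fragments longer than the transcript are resampled
        else:
            ks, pf = np.array([r]), np.array([1.0])
        exp_reads = 0.0
        for k, p in zip(ks, pf):
            if p == 0.0:
                continue
            v = L - int(k) + 1  # valid fragment starts
            a1 = _qualifying_starts(segs, r, 1, v)  # mate 1 starts at s
            exp_reads += p * a1 / v
            if cfg.paired:  # mate 2 starts at s + k - r
                a2 = _qualifying_starts(segs, r, int(k) - r + 1, L - r + 1)
                exp_reads += p * a2 / v
        w[i] = mixture[i] * exp_reads
    return w / w.sum()


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # one stream per emitted file, keyed by (seed, sample_id)
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode()) & 0x7FFFFFFF])


def simulate_alignments(
    model: GeneModel,
    mixture: Sequence[float],
    n_reads: int,
    cfg: SimConfig,
    sam_path: str,
    sample_id: str = "s1",
    seed: int | None = None,
) -> SimTruth:
    """Simulate *n_reads* fragments from an isoform *mixture* into SAM.

    Each fragment picks an isoform from the mixture, a fragment length (for
    paired data, truncated normal; single-end, the read length) and a uniform
    start over valid transcript positions, then is projected to the genome as
    spliced alignments.  Records are coordinate-sorted and deterministic for
    a given (seed, sample_id).
    """
    if abs(sum(mixture) - 1.0) > 1e-9:
        raise ValueError("mixture must sum to 1")
    if len(mixture) != len(model.transcripts):
        raise ValueError("mixture length != number of isoforms")
    rng = _sample_rng(cfg.seed if seed is None else seed, sample_id)

    fes = derive_first_exons(model, min_unique_length=1)
    promoter_of = {
        tid: pid for pid, tids in fes.transcript_ids.items() for tid in tids
    }
    maps = [_TxMap(tx) for tx in model.transcripts]
    # unique first-exon regions of each isoform, in its transcript coordinates
    unique_segs: list[list[tuple[int, int]]] = []
    for tx, tm in zip(model.transcripts, maps):
        pid = promoter_of[tx.transcript_id]
        segs = [s for iv in fes.regions[pid] for s in tm.from_genome(iv)]
        unique_segs.append(sorted(segs))

    r = cfg.read_length
    iso_idx = rng.choice(len(maps), size=n_reads, p=np.asarray(mixture, float))
    lengths = np.array([tm.length for tm in maps])
    if cfg.paired:
        frag = np.rint(
            rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, n_reads)
        ).astype(int)
        frag = np.maximum(frag, r)
        for _ in range(50):  # resample fragments longer than their transcript
            bad = frag > lengths[iso_idx]
            if not bad.any():
                break
            frag[bad] = np.maximum(
                np.rint(
                    rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, bad.sum())
                ).astype(int),
                r,
            )
        else:
            raise ValueError("fragment length exceeds transcript length; check config")
    else:
        frag = np.full(n_reads, r)
        if (frag > lengths[iso_idx]).any():
            raise ValueError("read length exceeds transcript length")
    starts = 1 + np.floor(
        rng.random(n_reads) * (lengths[iso_idx] - frag + 1)
    ).astype(int)

    if cfg.softclip_max > 0:
        clips = rng.integers(0, cfg.softclip_max + 1, size=(n_reads, 2, 2))
    else:
        clips = np.zeros((n_reads, 2, 2), dtype=int)

    minus = model.transcripts[0].strand == "-"
    flags_paired = (83, 163) if minus else (99, 147)
    flag_single = 16 if minus else 0
    seq = "A" * r

    records = []  # (pos0, qname, flag, cigar, pnext0, tlen, iso, label)
    truth_rows = []
    for j in range(n_reads):
        tm = maps[iso_idx[j]]
        tid = model.transcripts[iso_idx[j]].transcript_id
        s, f = int(starts[j]), int(frag[j])
        mates = [(s, s + r - 1)]
        if cfg.paired:
            mates.append((s + f - r, s + f - 1))
        qname = f"{sample_id}.{j}"
        mate_recs = []
        for mi, (a, b) in enumerate(mates):
            c5, c3 = int(clips[j, mi, 0]), int(clips[j, mi, 1])
            aa, bb = a + c5, b - c3
            if bb - aa + 1 < 1:  # fully clipped; keep at least 1 aligned base
                c5, c3, aa, bb = 0, 0, a, b
            blocks = tm.to_genome_blocks(aa, bb)
            # clip sides swap on the genome for reverse-strand transcripts
            g5, g3 = (c3, c5) if minus else (c5, c3)
            cigar = _cigar(blocks, g5, g3)
            segs = unique_segs[iso_idx[j]]
            ov = sum(max(0, min(bb, e) - max(aa, s0) + 1) for s0, e in segs)
            label = promoter_of[tid] if ov >= 1 else ""
            mate_recs.append((blocks[0][0] - 1, blocks[-1][1], cigar, label))
            truth_rows.append(
                {
                    "qname": qname,
                    "mate": mi + 1,
                    "isoform": tid,
                    "promoter_id": label,
                }
            )
        if cfg.paired:
            span_lo = min(mr[0] for mr in mate_recs)
            span_hi = max(mr[1] for mr in mate_recs)
            tlen = span_hi - span_lo
            for mi, (pos0, _end, cigar, _lab) in enumerate(mate_recs):
                other = mate_recs[1 - mi][0]
                sign = 1 if pos0 == span_lo and other != pos0 else (-1 if pos0 != span_lo else 1)
                records.append(
                    (pos0, qname, flags_paired[mi], cigar, other, sign * tlen)
                )
        else:
            pos0, _end, cigar, _lab = mate_recs[0]
            records.append((pos0, qname, flag_single, cigar, -1, 0))

    records.sort(key=lambda t: (t[0], t[1], t[2]))

    glen = genome_length(model)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": model.transcripts[0].chrom, "LN": glen}],
        }
    )
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for pos0, qname, flag, cigar, pnext0, tlen in records:
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = cigar
            if pnext0 >= 0:
                a.next_reference_id = 0
                a.next_reference_start = pnext0
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.template_length = tlen
            a.query_sequence = seq
            out.write(a)

    shares = _expected_read_mass_shares(
        np.asarray(mixture, float), unique_segs, lengths, cfg
    )
    pids = [promoter_of[tx.transcript_id] for tx in model.transcripts]
    return SimTruth(
        sample_id=sample_id,
        molar_proportions={p: float(m) for p, m in zip(pids, mixture)},
        read_mass_shares={p: float(s0) for p, s0 in zip(pids, shares)},
        reads=pd.DataFrame(truth_rows),
        promoter_of_isoform=promoter_of,
    )


def simulate_usage_counts(
    shares: Sequence[float],
    n_reads: int,
    rng: np.random.Generator,
    sample_id: str = "s1",
    gene_id: str = "gene",
    promoter_ids: Sequence[str] | None = None,
) -> FirstExonCounts:
    """Multinomial first-exon counts — the counts-level limit of the read
    simulator (exact conditional distribution of first-exon counts given the
    total), for fast calibration studies."""
    shares = np.asarray(shares, float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("shares must sum to 1")
    pids = list(promoter_ids) if promoter_ids else [f"P{i+1}" for i in range(len(shares))]
    draw = rng.multinomial(n_reads, shares)
    return FirstExonCounts(
        sample_id=sample_id,
        gene_id=gene_id,
        counts={p: int(c) for p, c in zip(pids, draw)},
        library_size=n_reads,
    )


# ---------------------------------------------------------------------------
# count matrices

@dataclass
class CountMatrixSim:
    counts: pd.DataFrame  # genes x samples
    lengths: pd.Series  # gene -> bases
    truth: pd.DataFrame  # gene_id index: log2_fc, is_de
    sample_groups: dict[str, str]


def simulate_count_matrix(
    n_genes: int = 2000,
    samples_per_group: int = 3,
    frac_de: float = 0.1,
    effect_log2fc: float = 2.0,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    group_ids: tuple[str, str] = ("A", "B"),
    base_mean_meanlog: float = math.log(150.0),
    base_mean_sdlog: float = 1.0,
    length_range: tuple[int, int] = (500, 5000),
    depth_sdlog: float = 0.1,
) -> CountMatrixSim:
    """Negative-binomial gene x sample counts with a planted DE fraction.

    Gene base means are log-normal; for the planted fraction, group-B means
    are multiplied by 2**(+/- effect_log2fc) with random sign.  Samples get
    mild log-normal depth variation.  ``nb_dispersion`` is the NB dispersion
    alpha (variance = mu + alpha*mu**2); alpha = 0 is the Poisson limit.
    """
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must be in [0, 1]")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"{g}{k + 1}" for g in group_ids for k in range(samples_per_group)]
    groups = dict(zip(samples, (g for g in group_ids for _ in range(samples_per_group))))

    mu = rng.lognormal(base_mean_meanlog, base_mean_sdlog, n_genes)
    is_de = rng.random(n_genes) < frac_de
    sign = rng.choice([-1.0, 1.0], n_genes)
    lfc = np.where(is_de, sign * effect_log2fc, 0.0)
    depth = rng.lognormal(0.0, depth_sdlog, len(samples))

    mat = np.empty((n_genes, len(samples)))
    for j, s in enumerate(samples):
        fc = np.where(groups[s] == group_ids[1], 2.0 ** lfc, 1.0)
        mu_j = mu * fc * depth[j]
        if nb_dispersion > 0:
            r = 1.0 / nb_dispersion
            mat[:, j] = rng.negative_binomial(r, r / (r + mu_j))
        else:
            mat[:, j] = rng.poisson(mu_j)
    counts = pd.DataFrame(mat.astype(int), index=genes, columns=samples)
    lengths = pd.Series(
        rng.integers(length_range[0], length_range[1] + 1, n_genes),
        index=genes,
        name="length",
    )
    truth = pd.DataFrame({"log2_fc": lfc, "is_de": is_de}, index=genes)
    return CountMatrixSim(counts=counts, lengths=lengths, truth=truth, sample_groups=groups)


# ---------------------------------------------------------------------------
# annotation maps

@dataclass
class AnnotationSim:
    terms: dict[str, frozenset[str]]
    background: frozenset[str]
    gene_set: set[str]
    planted_term_id: str


def simulate_annotation(
    n_genes: int = 2000,
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (20, 60),
    gene_set_size: int = 100,
    planted_fraction: float = 0.3,
    seed: int = 0,
) -> AnnotationSim:
    """Random term -> gene annotation with one over-represented term.

    The query gene set draws ``planted_fraction`` of its members from the
    planted term and the rest uniformly from the background.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    term_ids = [f"T{i + 1:03d}" for i in range(n_terms)]
    gene_set_size = min(gene_set_size, n_genes)
    hi = min(term_size_range[1], n_genes)
    lo = min(term_size_range[0], hi)
    sizes = rng.integers(lo, hi + 1, n_terms)
    terms = {
        t: frozenset(rng.choice(genes, size=int(sz), replace=False))
        for t, sz in zip(term_ids, sizes)
    }
    planted = term_ids[int(rng.integers(0, n_terms))]
    n_planted = min(int(round(planted_fraction * gene_set_size)), len(terms[planted]))
    from_term = rng.choice(sorted(terms[planted]), size=n_planted, replace=False)
    rest_pool = np.array(sorted(set(genes) - set(from_term)))
    rest = rng.choice(rest_pool, size=gene_set_size - n_planted, replace=False)
    return AnnotationSim(
        terms=terms,
        background=frozenset(genes),
        gene_set=set(from_term) | set(rest),
        planted_term_id=planted,
    )
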