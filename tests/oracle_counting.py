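"""Independent brute-force oracle for first-exon read counting.

Parses SAM text directly (no pysam) and expands every CIGAR to a per-base
reference position set, intersecting it with per-promoter base sets — a
completely separate code path from promusage.counting, used to validate it.
Also provides a generator of random small SAM files with CIGARs over
{M, I, D, N, S} and a mix of flag bits.
"""

from __future__ import annotations

import re

import numpy as np

from promusage.annotation import FirstExonSet

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def promoter_base_sets(fes: FirstExonSet) -> dict[str, set[int]]:
    """0-based reference positions of each promoter's regions."""
    return {
        pid: {p for iv in ivs for p in range(iv.start - 1, iv.end)}
        for pid, ivs in fes.regions.items()
    }


def oracle_count(
    sam_path: str,
    fes: FirstExonSet,
    min_overlap: int = 10,
    min_mapq: int = 20,
    include_duplicates: bool = True,
) -> tuple[dict[str, int], int]:
    """Per-base expansion counting (read units, unstranded).

    Returns (counts per promoter, library size).
    """
    base_sets = promoter_base_sets(fes)
    counts = {pid: 0 for pid in base_sets}
    library = 0
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & (0x4 | 0x100 | 0x800):
                continue
            if (flag & 0x400) and not include_duplicates:
                continue
            if int(f[4]) < min_mapq:
                continue
            library += 1
            pos = int(f[3]) - 1
            ref_pos: set[int] = set()
            for length, op in _CIGAR_RE.findall(f[5]):
                L = int(length)
                if op in "M=X":
                    ref_pos.update(range(pos, pos + L))
                    pos += L
                elif op in "DN":
                    pos += L
                # I, S, H, P consume no reference bases
            best_pid, best_ov, tie = None, 0, False
            for pid, bs in base_sets.items():
                ov = len(ref_pos & bs)
                if ov > best_ov:
                    best_pid, best_ov, tie = pid, ov, False
                elif ov == best_ov and ov > 0:
                    tie = True
            if best_pid is not None and best_ov >= min_overlap and not tie:
                counts[best_pid] += 1
    return counts, library


def write_random_sam(
    path: str,
    rng: np.random.Generator,
    n_records: int = 200,
    chrom: str = "chrSim",
    chrom_len: int = 20000,
    pos_range: tuple[int, int] = (900, 7600),
) -> None:
    """Random small SAM with CIGARs over {M, I, D, N, S} and varied flags."""
    lines = [f"@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{chrom_len}"]
    flags = [0, 16, 4, 256, 1024, 2048]
    flag_p = [0.4, 0.3, 0.05, 0.1, 0.1, 0.05]
    for i in range(n_records):
        flag = int(rng.choice(flags, p=flag_p))
        mapq = int(rng.integers(0, 61))
        if flag & 0x4:
            lines.append(f"u{i}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*")
            continue
        parts = []
        qlen = 0
        if rng.random() < 0.3:
            s = int(rng.integers(1, 11))
            parts.append(f"{s}S")
            qlen += s
        n_blocks = int(rng.integers(1, 4))
        for b in range(n_blocks):
            if b:
                op = rng.choice(["I", "D", "N"])
                L = int(rng.integers(50, 1501)) if op == "N" else int(rng.integers(1, 6))
                parts.append(f"{L}{op}")
                if op == "I":
                    qlen += L
            m = int(rng.integers(5, 81))
            parts.append(f"{m}M")
            qlen += m
        if rng.random() < 0.3:
            s = int(rng.integers(1, 11))
            parts.append(f"{s}S")
            qlen += s
        pos = int(rng.integers(pos_range[0], pos_range[1]))
        cigar = "".join(parts)
        lines.append(
            f"r{i}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{'A' * qlen}\t*"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
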