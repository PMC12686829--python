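"""Genomic interval arithmetic (BED semantics: 0-based, half-open).

Also defines the synthetic autosome table used by the simulator: 22
chromosome lengths proportional to the human autosomes, rescaled so that
their total equals the autosomal callable genome size used for burden
normalization (2,745,186,691 bp).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Autosomal callable genome size used to normalize callable fractions.
AUTOSOMAL_GENOME_SIZE = 2_745_186_691

_HUMAN_AUTOSOMES = [
    248956422, 242193529, 198295559, 190214555, 181538259, 170805979,
    159345973, 145138636, 138394717, 133797422, 135086622, 133275309,
    114364328, 107043718, 101991189, 90338345, 83257441, 80373285,
    58617616, 64444167, 46709983, 50818468,
]


def _scaled_lengths() -> dict[str, int]:
    total = sum(_HUMAN_AUTOSOMES)
    scaled = [int(l * AUTOSOMAL_GENOME_SIZE / total) for l in _HUMAN_AUTOSOMES]
    scaled[0] += AUTOSOMAL_GENOME_SIZE - sum(scaled)
    return {f"chr{i + 1}": l for i, l in enumerate(scaled)}


#: Synthetic autosome lengths (chr1..chr22), summing exactly to the
#: autosomal callable genome size.
CHROM_LENGTHS = _scaled_lengths()
CHROM_ORDER = list(CHROM_LENGTHS)


def merge_intervals(intervals) -> list[tuple[str, int, int]]:
    """Sort and merge possibly-overlapping (chrom, start, end) intervals."""
    by_chrom: dict[str, list] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    out = []
    for chrom in sorted(by_chrom, key=lambda c: (CHROM_ORDER.index(c) if c in CHROM_LENGTHS else len(CHROM_ORDER), c)):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def total_length(intervals) -> int:
    return sum(e - s for _, s, e in merge_intervals(intervals)) if intervals else 0


def intersect(a, b) -> list[tuple[str, int, int]]:
    """Intersection of two interval sets (merged beforehand)."""
    a = merge_intervals(a) if a else []
    b = merge_intervals(b) if b else []
    by_chrom_b: dict[str, list] = {}
    for chrom, s, e in b:
        by_chrom_b.setdefault(chrom, []).append((s, e))
    out = []
    for chrom, s, e in a:
        for bs, be in by_chrom_b.get(chrom, []):
            lo, hi = max(s, bs), min(e, be)
            if lo < hi:
                out.append((chrom, lo, hi))
    return out


def union(a, b) -> list[tuple[str, int, int]]:
    return merge_intervals(list(a) + list(b))


def in_regions(chroms, positions, intervals) -> np.ndarray:
    """Vectorized membership test of 1-based positions in merged intervals."""
    merged = merge_intervals(intervals) if intervals else []
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, s, e in merged:
        starts.setdefault(chrom, []).append(s)
        ends.setdefault(chrom, []).append(e)
    starts = {c: np.asarray(v) for c, v in starts.items()}
    ends = {c: np.asarray(v) for c, v in ends.items()}

    chroms = np.asarray(chroms)
    pos0 = np.asarray(positions, dtype=np.int64) - 1  # to 0-based
    result = np.zeros(len(pos0), dtype=bool)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        if chrom not in starts:
            continue
        idx = np.searchsorted(starts[chrom], pos0[mask], side="right") - 1
        ok = idx >= 0
        ok[ok] = pos0[mask][ok] < ends[chrom][idx[ok]]
        result[mask] = ok
    return result


def read_bed(path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
    )
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in merge_intervals(intervals):
            fh.write(f"{chrom}\t{s}\t{e}\n")
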