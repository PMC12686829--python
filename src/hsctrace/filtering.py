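"""Somatic variant filtering against a pseudo-bulk germline reference.

Without a matched germline sample, two clonally unrelated colonies are
merged into a pseudo-bulk reference: any variant with alt-read evidence in
the pseudo-bulk is treated as germline and removed.  The remaining calls are
filtered on depth (>= 5 in sample and pseudo-bulk), site quality (>= 100),
mapping quality (>= 55), genotype quality (99 for heterozygous, 10 for
homozygous calls) and VAF (>= 0.15, removing in-vitro subclonal artifacts).
Per-sample somatic sensitivity ``p`` is the callable-region overlap of the
sample with the pseudo-bulk, normalized to the autosomal callable genome
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import AUTOSOMAL_GENOME_SIZE, intersect, merge_intervals
from .variant_table import VariantTable


@dataclass
class FilterThresholds:
    min_depth: int = 5
    min_site_quality: float = 100.0
    min_mapping_quality: float = 55.0
    min_gq_het: int = 99
    min_gq_hom: int = 10
    min_vaf: float = 0.15

    def __post_init__(self):
        if min(self.min_depth, self.min_site_quality, self.min_mapping_quality,
               self.min_gq_het, self.min_gq_hom, self.min_vaf) < 0:
            raise ValueError("thresholds must be nonnegative")
        if not 0 <= self.min_vaf <= 1:
            raise ValueError("min_vaf must be in [0, 1]")


@dataclass
class PseudoBulk:
    """Summed evidence of two clonally unrelated colonies."""

    members: tuple[str, str]
    depth: np.ndarray
    alt_count: np.ndarray
    gq: np.ndarray  # conservative: the minimum of the member genotype qualities


@dataclass
class SomaticCatalog:
    """High-quality somatic catalog: passing variants per colony."""

    variants: pd.DataFrame  # sample, chrom, pos, ref, alt, vaf, depth, alt_count
    pseudobulk_members: tuple[str, str]
    callable_fraction: dict[str, float] = field(default_factory=dict)
    filter_counts: dict[str, int] = field(default_factory=dict)

    def per_sample(self, sample: str) -> pd.DataFrame:
        return self.variants[self.variants["sample"] == sample]

    def burden(self, sample: str) -> int:
        return int((self.variants["sample"] == sample).sum())

    @property
    def samples(self) -> list[str]:
        return sorted(self.variants["sample"].unique())

    def write(self, path) -> None:
        self.variants.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, members=("", "")) -> "SomaticCatalog":
        return cls(variants=pd.read_csv(path, sep="\t"), pseudobulk_members=tuple(members))


def build_pseudobulk(table: VariantTable, members) -> PseudoBulk:
    members = tuple(members)
    if len(members) != 2 or members[0] == members[1]:
        raise ValueError("pseudo-bulk needs two distinct member samples")
    idx = [table.sample_index(m) for m in members]
    return PseudoBulk(
        members=members,
        depth=table.depth[:, idx].sum(axis=1),
        alt_count=table.alt_count[:, idx].sum(axis=1),
        gq=table.gq[:, idx].min(axis=1),
    )


def filter_somatic(
    table: VariantTable,
    pseudobulk: PseudoBulk,
    thresholds: FilterThresholds | None = None,
) -> SomaticCatalog:
    """Apply the filter ladder; pseudo-bulk members are excluded from output.

    A variant passes for a sample iff depth >= min_depth in the sample and
    the pseudo-bulk, site/mapping quality meet thresholds, genotype quality
    meets the het/hom rule in both, VAF >= min_vaf in the sample, and the
    pseudo-bulk has zero alt reads.
    """
    th = thresholds or FilterThresholds()
    for m in pseudobulk.members:
        table.sample_index(m)

    keep_samples = [s for s in table.samples if s not in pseudobulk.members]
    counts = {
        "input": 0, "depth": 0, "site_quality": 0, "mapping_quality": 0,
        "genotype_quality": 0, "vaf": 0, "pseudobulk_evidence": 0, "pass": 0,
    }
    site_q = table.sites["qual"].to_numpy(dtype=float)
    site_mq = table.sites["mq"].to_numpy(dtype=float)
    vaf = table.vaf()

    rows = []
    for s in keep_samples:
        j = table.sample_index(s)
        has_call = table.alt_count[:, j] > 0
        counts["input"] += int(has_call.sum())
        # het/hom genotype-quality rule based on the sample's VAF
        is_hom = vaf[:, j] > 0.9
        gq_min = np.where(is_hom, th.min_gq_hom, th.min_gq_het)

        ok = has_call.copy()
        stages = [
            ("depth", (table.depth[:, j] >= th.min_depth)
                      & (pseudobulk.depth >= th.min_depth)),
            ("site_quality", site_q >= th.min_site_quality),
            ("mapping_quality", site_mq >= th.min_mapping_quality),
            ("genotype_quality", (table.gq[:, j] >= gq_min)
                                 & (pseudobulk.gq >= th.min_gq_hom)
                                 & ((pseudobulk.alt_count == 0)
                                    | (pseudobulk.gq >= th.min_gq_het))),
            ("vaf", vaf[:, j] >= th.min_vaf),
            ("pseudobulk_evidence", pseudobulk.alt_count == 0),
        ]
        for name, mask in stages:
            fail = ok & ~mask
            counts[name] += int(fail.sum())
            ok &= mask
        counts["pass"] += int(ok.sum())
        for i in np.flatnonzero(ok):
            rows.append((
                s,
                table.sites["chrom"].iat[i], int(table.sites["pos"].iat[i]),
                table.sites["ref"].iat[i], table.sites["alt"].iat[i],
                float(vaf[i, j]), int(table.depth[i, j]),
                int(table.alt_count[i, j]),
            ))
    variants = pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "vaf", "depth", "alt_count"],
    )
    return SomaticCatalog(
        variants=variants,
        pseudobulk_members=pseudobulk.members,
        filter_counts=counts,
    )


def callable_fraction(
    sample_regions,
    pseudobulk_regions,
    genome_size: int = AUTOSOMAL_GENOME_SIZE,
) -> float:
    """Somatic variant sensitivity p: overlap of sample and pseudo-bulk
    callable regions over the autosomal callable genome size."""
    overlap = intersect(merge_intervals(sample_regions),
                        merge_intervals(pseudobulk_regions))
    length = sum(e - s for _, s, e in overlap)
    if length == 0:
        raise ValueError("sample and pseudo-bulk callable regions do not overlap")
    return min(length / genome_size, 1.0)
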