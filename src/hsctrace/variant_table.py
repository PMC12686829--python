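"""Multi-sample variant table: the in-memory form of a multi-sample VCF.

Sites are a DataFrame (chrom, pos, ref, alt, qual, mq); per-sample depth,
alt-read count and genotype quality live in aligned integer matrices.
Multi-allelic sites are decomposed into one row per alternate allele on
read.  Reading goes through cyvcf2; writing emits plain-text VCFv4.2 with
contig headers so the output round-trips through standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import CHROM_LENGTHS, CHROM_ORDER


@dataclass
class VariantTable:
    samples: list[str]
    sites: pd.DataFrame  # columns: chrom, pos, ref, alt, qual, mq
    depth: np.ndarray    # (n_sites, n_samples) int
    alt_count: np.ndarray
    gq: np.ndarray

    def __post_init__(self):
        n = len(self.sites)
        for name in ("depth", "alt_count", "gq"):
            m = getattr(self, name)
            if m.shape != (n, len(self.samples)):
                raise ValueError(f"{name} matrix shape {m.shape} inconsistent")
        if (self.alt_count > self.depth).any():
            raise ValueError("alt count exceeds depth")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def vaf(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.alt_count / self.depth
        return np.nan_to_num(v, nan=0.0)

    # -- I/O ---------------------------------------------------------------

    def write_vcf(self, path, contigs: dict[str, int] | None = None) -> None:
        contigs = contigs or CHROM_LENGTHS
        lines = [
            "##fileformat=VCFv4.2",
            "##source=hsctrace",
        ]
        for chrom in contigs:
            lines.append(f"##contig=<ID={chrom},length={contigs[chrom]}>")
        lines += [
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.samples),
        ]
        cols = self.sites
        for i in range(self.n_sites):
            fields = [
                str(cols["chrom"].iat[i]),
                str(int(cols["pos"].iat[i])),
                ".",
                cols["ref"].iat[i],
                cols["alt"].iat[i],
                f"{float(cols['qual'].iat[i]):g}",
                "PASS",
                f"MQ={float(cols['mq'].iat[i]):g}",
                "GT:DP:AD:GQ",
            ]
            for j in range(len(self.samples)):
                dp = int(self.depth[i, j])
                ac = int(self.alt_count[i, j])
                gt = "0/1" if ac > 0 else "0/0"
                fields.append(f"{gt}:{dp}:{dp - ac},{ac}:{int(self.gq[i, j])}")
            lines.append("\t".join(fields))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_vcf(cls, path) -> "VariantTable":
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        rows, depths, alts, gqs = [], [], [], []
        for v in vcf:
            dp = _fmt_vector(v, "DP", len(samples))
            ad = v.format("AD")
            gq = _fmt_vector(v, "GQ", len(samples))
            mq = v.INFO.get("MQ")
            for ai, alt_allele in enumerate(v.ALT):
                rows.append(
                    (v.CHROM, v.POS, v.REF, alt_allele,
                     v.QUAL if v.QUAL is not None else 0.0,
                     float(mq) if mq is not None else 0.0)
                )
                depths.append(dp)
                if ad is not None:
                    a = np.clip(ad[:, ai + 1], 0, None)
                else:
                    a = np.zeros(len(samples), dtype=int)
                alts.append(a)
                gqs.append(gq)
        sites = pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "qual", "mq"]
        )
        return cls(
            samples=samples,
            sites=sites,
            depth=np.asarray(depths, dtype=np.int64),
            alt_count=np.asarray(alts, dtype=np.int64),
            gq=np.asarray(gqs, dtype=np.int64),
        )


def _fmt_vector(variant, key, n) -> np.ndarray:
    arr = variant.format(key)
    if arr is None:
        return np.zeros(n, dtype=np.int64)
    arr = np.asarray(arr).reshape(n, -1)[:, 0]
    return np.clip(np.nan_to_num(arr, nan=0).astype(np.int64), 0, None)


def sort_key(sites: pd.DataFrame) -> pd.DataFrame:
    """Genome-order sort (chr1..chr22 then lexical) for deterministic output."""
    order = {c: i for i, c in enumerate(CHROM_ORDER)}
    key = sites["chrom"].map(lambda c: order.get(c, len(order)))
    return sites.assign(_k=key).sort_values(["_k", "pos", "alt"]).drop(columns="_k")
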