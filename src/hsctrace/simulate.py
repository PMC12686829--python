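"""Synthetic single-HSPC-colony datasets with matching ground truth.

The generator emulates the structure of a colony-based lineage-tracing
study: ~10 clonally expanded HSPC colonies per recipient, a driver clone
whose colonies coalesce on a single clonal branch, very polyclonal wildtype
lineages that diverge during an early embryonic burst, linear postnatal
mutation accumulation (~16 substitutions/year) on top of a fetal burden,
an age-dependent SBS1/SBS5/SBS18/HSPC signature mixture, ~15x sequencing
coverage with per-sample callable regions, plus injected germline variants
and low-VAF in-vitro artifacts so the downstream filters are exercised.

Three stages, each deterministic given the seed:

1. :func:`simulate_phylogeny` — topology and node times (years since
   conception);
2. :func:`simulate_mutations`  — per-branch mutation draws (Poisson counts,
   signature-mixture contexts, unique synthetic genome positions);
3. :func:`simulate_observation` — the multi-sample variant table and
   per-sample callable BEDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .regions import (
    AUTOSOMAL_GENOME_SIZE,
    CHROM_LENGTHS,
    CHROM_ORDER,
    in_regions,
    merge_intervals,
    write_bed,
)
from .signature_profiles import (
    DEFAULT_SCHEDULE,
    default_catalog,
    schedule_weights,
    validate_schedule,
)
from .spectra import parse_context
from .trees import Node, Tree
from .variant_table import VariantTable

GESTATION_YEARS = 0.75


@dataclass
class SimulationParams:
    """Study conditions for one simulated recipient.

    ``driver_time`` is years since conception (values below 0.75 place the
    driver acquisition before birth); ``clone_size`` colonies descend from
    the driver clone.  ``birth_load_mean`` substitutions accumulate over
    gestation, then ``postnatal_rate`` per year.  Wildtype lineages diverge
    while fewer than ``embryonic_split_burden`` substitutions have
    accumulated.  ``dropout_rate`` is the probability that a carried
    heterozygous variant yields no alt reads in a colony (negligible for
    bulk-sequenced colony expansions, hence 0 by default; raise it to mimic
    amplification-based protocols).
    """

    n_colonies: int = 10
    hsc_age: float = 40.0
    driver_time: Optional[float] = None
    clone_size: int = 0
    postnatal_rate: float = 16.0
    birth_load_mean: float = 84.0
    embryonic_split_burden: float = 10.0
    signature_mixture_schedule: tuple = DEFAULT_SCHEDULE
    coverage_mean: float = 15.0
    dropout_rate: float = 0.0
    callable_fraction_range: tuple[float, float] = (0.80, 0.95)
    germline_count: int = 150
    artifact_rate: float = 40.0
    artifact_vaf: float = 0.05
    lowqual_count: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_colonies < 2:
            raise ValueError("need at least two colonies")
        if self.driver_time is not None:
            if not (2 <= self.clone_size <= self.n_colonies):
                raise ValueError("clone_size must be in [2, n_colonies] when a driver is simulated")
            if not (0 < self.driver_time < self.hsc_age + GESTATION_YEARS):
                raise ValueError("driver_time must fall inside the lifespan")
        elif self.clone_size:
            raise ValueError("clone_size without driver_time")
        if self.postnatal_rate < 0 or self.birth_load_mean < 0:
            raise ValueError("rates must be nonnegative")
        if not (0 <= self.dropout_rate <= 1):
            raise ValueError("dropout_rate must be a probability")
        lo, hi = self.callable_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("callable_fraction_range must be within (0, 1]")
        validate_schedule(self.signature_mixture_schedule)

    @property
    def total_time(self) -> float:
        return self.hsc_age + GESTATION_YEARS

    @property
    def prenatal_rate(self) -> float:
        return self.birth_load_mean / GESTATION_YEARS


@dataclass
class TruthBundle:
    """Ground truth for parameter-recovery tests."""

    tree: Tree                       # node.time = years since conception
    params: SimulationParams
    driver_branch: Optional[str] = None
    driver_time_true: Optional[float] = None
    clone_tips: list = field(default_factory=list)
    mutations: Optional[pd.DataFrame] = None   # one row per true mutation
    per_sample_callable: Optional[dict] = None
    callable_fraction: Optional[dict] = None

    def branch_mutations(self) -> dict[str, pd.DataFrame]:
        if self.mutations is None:
            raise ValueError("mutations not simulated yet")
        return dict(tuple(self.mutations.groupby("branch", sort=False)))

    def carriers(self) -> dict[str, frozenset]:
        """Mutation id -> set of carrier colonies (tips below its branch)."""
        clades = {
            n.name: self.tree.clade_tips(n) for n in self.tree.preorder()
        }
        return {
            row.id: clades[row.branch] for row in self.mutations.itertuples()
        }


# ---------------------------------------------------------------------------
# stage 1: topology + node times


def simulate_phylogeny(params: SimulationParams) -> TruthBundle:
    rng = np.random.default_rng([params.seed, 11])
    total = params.total_time
    has_driver = params.driver_time is not None
    n_wild = params.n_colonies - (params.clone_size if has_driver else 0)
    n_founders = n_wild + (1 if has_driver else 0)

    t_emb = (
        params.embryonic_split_burden / params.prenatal_rate
        if params.prenatal_rate > 0
        else 0.0
    )
    t_emb = min(t_emb, GESTATION_YEARS)

    root = Node()
    root.time = 0.0
    founders: list[Node]
    if n_founders == 1:
        founders = [root]
    else:
        times = np.concatenate(
            [[0.0], np.sort(rng.uniform(0.0, t_emb, n_founders - 2))]
        )
        active = [root]
        for t in times:
            node = active.pop(int(rng.integers(len(active))))
            node.time = t
            for _ in range(2):
                active.append(node.add_child(Node()))
        founders = active

    if has_driver:
        # the stem lineage must originate before the driver is acquired
        eligible = [
            f for f in founders
            if (f.parent.time if f.parent else 0.0) < params.driver_time
        ]
        if not eligible:
            raise ValueError("driver_time precedes every embryonic divergence")
        stem = eligible[int(rng.integers(len(eligible)))]
        founders.remove(stem)
        _grow_clade(
            stem, params.clone_size, params.driver_time, total, "MUT", rng
        )
        driver_branch_node = stem
    else:
        driver_branch_node = None

    for i, f in enumerate(founders):
        f.name = f"WT{i + 1:02d}"
        f.time = total

    tree = Tree(root)
    k = 0
    for node in tree.preorder():
        if node.name is None:
            node.name = f"n{k}"
            k += 1
    clone_tips = sorted(
        t.name for t in tree.tips() if t.name.startswith("MUT")
    )
    return TruthBundle(
        tree=tree,
        params=params,
        driver_branch=driver_branch_node.name if driver_branch_node else None,
        driver_time_true=params.driver_time,
        clone_tips=clone_tips,
    )


def _grow_clade(stem: Node, size: int, t_split: float, total: float,
                prefix: str, rng) -> None:
    """Coalesce ``size`` tips below ``stem``, whose split is at ``t_split``."""
    times = np.concatenate(
        [[t_split], np.sort(rng.uniform(t_split, total, size - 2))]
    ) if size >= 2 else np.array([])
    active = [stem]
    for t in times:
        node = active.pop(int(rng.integers(len(active))))
        node.time = t
        for _ in range(2):
            active.append(node.add_child(Node()))
    for i, tip in enumerate(active):
        tip.name = f"{prefix}{i + 1:02d}"
        tip.time = total


# ---------------------------------------------------------------------------
# stage 2: mutations


def simulate_mutations(
    truth: TruthBundle, params: SimulationParams, catalog: pd.DataFrame = None
) -> TruthBundle:
    rng = np.random.default_rng([params.seed, 23])
    catalog = default_catalog() if catalog is None else catalog
    schedule = params.signature_mixture_schedule
    sig_names = list(catalog.columns)
    profiles = {s: catalog[s].to_numpy() for s in sig_names}
    chrom_p = np.array([CHROM_LENGTHS[c] for c in CHROM_ORDER], dtype=float)
    chrom_p /= chrom_p.sum()

    taken: set[tuple[str, int]] = set()
    records = []
    mid = 0
    for node in truth.tree.preorder():
        t0 = node.parent.time if node.parent is not None else 0.0
        t1 = node.time
        segs = []
        pre = (max(t0, 0.0), min(t1, GESTATION_YEARS))
        if pre[1] > pre[0] and params.prenatal_rate > 0:
            segs.append((pre, params.prenatal_rate))
        post = (max(t0, GESTATION_YEARS), t1)
        if post[1] > post[0] and params.postnatal_rate > 0:
            segs.append((post, params.postnatal_rate))
        muts = []
        for (a, b), rate in segs:
            n = rng.poisson((b - a) * rate)
            for age in np.sort(rng.uniform(a, b, n)):
                weights = schedule_weights(schedule, age)
                names = list(weights)
                sig = names[
                    int(rng.choice(len(names), p=np.array([weights[s] for s in names])))
                ]
                chan_idx = int(rng.choice(96, p=profiles[sig]))
                context = catalog.index[chan_idx]
                five, ref, alt, three = parse_context(context)
                while True:
                    chrom = CHROM_ORDER[int(rng.choice(22, p=chrom_p))]
                    pos = int(rng.integers(2, CHROM_LENGTHS[chrom]))
                    if (chrom, pos) not in taken:
                        taken.add((chrom, pos))
                        break
                mid += 1
                muts.append(
                    dict(id=f"m{mid:06d}", branch=node.name, chrom=chrom,
                         pos=pos, ref=ref, alt=alt, context=context,
                         signature=sig, age=float(age))
                )
        node.mutations = [m["id"] for m in muts]
        node.length = float(len(muts))
        records.extend(muts)

    truth.mutations = pd.DataFrame(
        records,
        columns=["id", "branch", "chrom", "pos", "ref", "alt",
                 "context", "signature", "age"],
    )
    return truth


# ---------------------------------------------------------------------------
# stage 3: observation


@dataclass
class Observation:
    table: VariantTable
    callable_regions: dict[str, list]        # sample -> merged intervals
    callable_fraction: dict[str, float]      # realized fraction per sample
    truth_map: pd.DataFrame                  # chrom,pos,alt -> class, branch

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.write_vcf(out / "colonies.vcf")
        for sample, regions in self.callable_regions.items():
            write_bed(regions, out / f"{sample}.callable.bed")
        self.truth_map.to_csv(out / "truth_variants.tsv", sep="\t", index=False)


def _draw_callable(rng, fraction: float, window: int = 1_000_000) -> list:
    regions = []
    for chrom in CHROM_ORDER:
        length = CHROM_LENGTHS[chrom]
        n_win = length // window + (1 if length % window else 0)
        keep = rng.random(n_win) < fraction
        for w in np.flatnonzero(keep):
            regions.append((chrom, int(w * window), int(min((w + 1) * window, length))))
    return merge_intervals(regions) if regions else []


def simulate_observation(
    truth: TruthBundle, params: SimulationParams
) -> Observation:
    if truth.mutations is None:
        raise ValueError("run simulate_mutations first")
    rng = np.random.default_rng([params.seed, 37])
    samples = sorted(truth.tree.tip_names())
    n_samples = len(samples)
    sample_idx = {s: j for j, s in enumerate(samples)}

    callable_regions, callable_fraction = {}, {}
    lo, hi = params.callable_fraction_range
    for s in samples:
        f = rng.uniform(lo, hi)
        regions = _draw_callable(rng, f)
        callable_regions[s] = regions
        callable_fraction[s] = sum(e - b for _, b, e in regions) / AUTOSOMAL_GENOME_SIZE

    clades = {n.name: truth.tree.clade_tips(n) for n in truth.tree.preorder()}

    taken = set(zip(truth.mutations["chrom"], truth.mutations["pos"]))
    bases = np.array(list("ACGT"))

    def draw_site(rng):
        while True:
            chrom = CHROM_ORDER[int(rng.integers(22))]
            pos = int(rng.integers(2, CHROM_LENGTHS[chrom]))
            if (chrom, pos) not in taken:
                taken.add((chrom, pos))
                ref, alt = rng.choice(4, size=2, replace=False)
                return chrom, pos, bases[ref], bases[alt]

    rows = []  # chrom,pos,ref,alt,cls,branch,carriers(frozenset),vaf_p
    for r in truth.mutations.itertuples():
        rows.append((r.chrom, r.pos, r.ref, r.alt, "somatic", r.branch,
                     clades[r.branch], 0.5))
    for _ in range(params.germline_count):
        chrom, pos, ref, alt = draw_site(rng)
        rows.append((chrom, pos, ref, alt, "germline", "", frozenset(samples), 0.5))
    for s in samples:
        for _ in range(rng.poisson(params.artifact_rate)):
            chrom, pos, ref, alt = draw_site(rng)
            rows.append((chrom, pos, ref, alt, "artifact", "",
                         frozenset([s]), params.artifact_vaf))
    lowqual_mode = []
    for k in range(params.lowqual_count):
        chrom, pos, ref, alt = draw_site(rng)
        s = samples[int(rng.integers(n_samples))]
        rows.append((chrom, pos, ref, alt, "lowqual", "", frozenset([s]), 0.5))
        lowqual_mode.append(("mq", "qual", "gq")[k % 3])

    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "cls", "branch", "carriers", "vaf_p"],
    )
    order = {c: i for i, c in enumerate(CHROM_ORDER)}
    df = df.assign(_k=df["chrom"].map(order)).sort_values(
        ["_k", "pos"], kind="mergesort"
    ).drop(columns="_k").reset_index(drop=True)

    n = len(df)
    qual = np.round(rng.uniform(200.0, 1500.0, n), 1)
    mq = np.full(n, 60.0)
    gq_site = np.full(n, 99)
    lq_pos = np.flatnonzero((df["cls"] == "lowqual").to_numpy())
    modes = iter(lowqual_mode)
    lq_gq_rows = []
    for i in lq_pos:
        mode = next(modes)
        if mode == "mq":
            mq[i] = 30.0
        elif mode == "qual":
            qual[i] = 50.0
        else:
            lq_gq_rows.append(i)

    depth = np.zeros((n, n_samples), dtype=np.int64)
    alt_count = np.zeros((n, n_samples), dtype=np.int64)
    gq = np.tile(gq_site[:, None], (1, n_samples))
    chroms = df["chrom"].to_numpy()
    positions = df["pos"].to_numpy()
    carrier_mat = np.zeros((n, n_samples), dtype=bool)
    for i, carriers in enumerate(df["carriers"]):
        for s in carriers:
            carrier_mat[i, sample_idx[s]] = True
    vaf_p = df["vaf_p"].to_numpy(dtype=float)

    for j, s in enumerate(samples):
        inside = in_regions(chroms, positions, callable_regions[s])
        d = np.where(inside, rng.poisson(params.coverage_mean, n), rng.poisson(1.0, n))
        a = np.zeros(n, dtype=np.int64)
        carried = carrier_mat[:, j]
        a[carried] = rng.binomial(d[carried], vaf_p[carried])
        if params.dropout_rate > 0:
            drop = carried & (rng.random(n) < params.dropout_rate)
            a[drop] = 0
        depth[:, j] = d
        alt_count[:, j] = a
    for i in lq_gq_rows:
        gq[i, :] = 30

    sites = df[["chrom", "pos", "ref", "alt"]].copy()
    sites["qual"] = qual
    sites["mq"] = mq
    table = VariantTable(
        samples=samples, sites=sites, depth=depth, alt_count=alt_count, gq=gq
    )
    truth.per_sample_callable = callable_regions
    truth.callable_fraction = callable_fraction
    truth_map = df[["chrom", "pos", "ref", "alt", "cls", "branch"]].copy()
    truth_map["carriers"] = df["carriers"].map(lambda c: ",".join(sorted(c)))
    return Observation(
        table=table,
        callable_regions=callable_regions,
        callable_fraction=callable_fraction,
        truth_map=truth_map,
    )


# ---------------------------------------------------------------------------
# convenience


def simulate_dataset(params: SimulationParams):
    """Run all three stages; returns (truth, observation)."""
    truth = simulate_phylogeny(params)
    truth = simulate_mutations(truth, params)
    obs = simulate_observation(truth, params)
    return truth, obs


def write_truth(truth: TruthBundle, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "truth_tree_mutations.nwk", "w") as fh:
        fh.write(truth.tree.to_newick(lengths="length") + "\n")
    with open(out / "truth_tree_time.nwk", "w") as fh:
        fh.write(truth.tree.to_newick(lengths="time") + "\n")
    if truth.mutations is not None:
        truth.mutations.to_csv(out / "truth_mutations.tsv", sep="\t", index=False)
    params = asdict(truth.params)
    params["signature_mixture_schedule"] = [
        [a, "inf" if b == float("inf") else b, w]
        for a, b, w in params["signature_mixture_schedule"]
    ]
    meta = dict(
        params=params,
        driver_branch=truth.driver_branch,
        driver_time_true=truth.driver_time_true,
        clone_tips=truth.clone_tips,
    )
    with open(out / "truth_params.json", "w") as fh:
        json.dump(meta, fh, indent=2)
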