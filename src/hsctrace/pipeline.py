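"""Stage orchestration: simulate -> filter -> fetal-estimate -> burden ->
tree -> timescale -> signatures, driven by one flat config.

Each stage reads its predecessors' outputs from disk under the working
directory, so any stage can be rerun in isolation; the run report
aggregates the machine-readable summaries of every enabled stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burden import (
    AgeBurdenModel,
    BurdenObservation,
    compare_burdens,
    corrected_burden,
    fit_age_model,
)
from .fetal import estimate_filtered_fetal_mutations
from .filtering import (
    FilterThresholds,
    SomaticCatalog,
    build_pseudobulk,
    callable_fraction,
    filter_somatic,
)
from .phylogeny import build_tree, genotype_matrix, map_and_reassign
from .regions import read_bed, union
from .signature_profiles import AgeSpectrumModel, default_catalog
from .signatures import (
    class_spectra,
    cumulative_age_similarity,
    driver_signature_probability,
    partition_branch_classes,
    refit_contributions,
)
from .simulate import SimulationParams, simulate_dataset, write_truth
from .timescale import TimeScaleConfig, convert_to_time, time_driver_acquisition
from .trees import Tree
from .variant_table import VariantTable

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    workdir: str = "hsctrace_run"
    stages: tuple[str, ...] = (
        "simulate", "filter", "fetal_estimate", "burden",
        "tree", "timescale", "signatures",
    )
    seed: int = 7
    # simulate
    n_colonies: int = 10
    hsc_age: float = 40.0
    driver_time: float | None = 3.0
    clone_size: int = 5
    dropout_rate: float = 0.0
    # filter
    vcf: str | None = None                  # defaults to the simulate output
    callable_dir: str | None = None
    pseudobulk: tuple[str, str] | None = None   # default: first two wildtype
    clone_prefix: str = "MUT"
    # fetal / burden
    fetal_trees: tuple[str, ...] = ()       # default: simulator truth tree
    fetal_iterations: int = 1000
    healthy_tsv: str | None = None          # sample, donor, age, burden, p
    baseline_slope: float = 16.0
    baseline_intercept: float = 84.0
    # tree / timescale
    n_boot: int = 100
    missing_cutoff: float = 0.1
    birth_load: float = 84.0
    birth_load_ci: tuple[float, float] = (52.0, 121.0)
    gestation_years: float = 0.75
    target_age: float | None = None         # defaults to hsc_age
    # signatures
    contexts_tsv: str | None = None         # chrom, pos, context
    driver_context: str | None = None
    n_boots_refit: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "pseudobulk", "fetal_trees", "birth_load_ci"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _paths(cfg: RunConfig) -> dict[str, Path]:
    base = Path(cfg.workdir)
    return {s: base / s for s in (
        "simulate", "filter", "fetal_estimate", "burden",
        "tree", "timescale", "signatures",
    )}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run report."""
    dirs = _paths(config)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }
    for stage in config.stages:
        runner = _STAGES.get(stage)
        if runner is None:
            raise ValueError(f"unknown stage {stage!r}")
        dirs[stage].mkdir(parents=True, exist_ok=True)
        report["stages"][stage] = runner(config, dirs)
    out = Path(config.workdir) / "report.json"
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, dirs) -> dict:
    params = SimulationParams(
        n_colonies=cfg.n_colonies, hsc_age=cfg.hsc_age,
        driver_time=cfg.driver_time,
        clone_size=cfg.clone_size if cfg.driver_time is not None else 0,
        dropout_rate=cfg.dropout_rate, seed=cfg.seed,
    )
    truth, obs = simulate_dataset(params)
    obs.write(dirs["simulate"])
    write_truth(truth, dirs["simulate"])
    return dict(
        n_colonies=params.n_colonies,
        n_true_mutations=len(truth.mutations),
        n_vcf_records=obs.table.n_sites,
        driver_branch=truth.driver_branch,
        clone_tips=truth.clone_tips,
    )


def _load_table(cfg: RunConfig, dirs) -> VariantTable:
    vcf = cfg.vcf or dirs["simulate"] / "colonies.vcf"
    return VariantTable.from_vcf(vcf)


def _pseudobulk_members(cfg: RunConfig, samples) -> tuple[str, str]:
    if cfg.pseudobulk:
        return tuple(cfg.pseudobulk)
    wt = sorted(s for s in samples if not s.startswith(cfg.clone_prefix))
    if len(wt) < 2:
        raise ValueError("cannot choose pseudo-bulk: fewer than two wildtype colonies")
    return (wt[0], wt[1])


def _stage_filter(cfg: RunConfig, dirs) -> dict:
    table = _load_table(cfg, dirs)
    members = _pseudobulk_members(cfg, table.samples)
    pb = build_pseudobulk(table, members)
    catalog = filter_somatic(table, pb, FilterThresholds())
    bed_dir = Path(cfg.callable_dir or dirs["simulate"])
    pb_regions = union(
        read_bed(bed_dir / f"{members[0]}.callable.bed"),
        read_bed(bed_dir / f"{members[1]}.callable.bed"),
    )
    for s in catalog.samples:
        catalog.callable_fraction[s] = callable_fraction(
            read_bed(bed_dir / f"{s}.callable.bed"), pb_regions
        )
    catalog.write(dirs["filter"] / "catalog.tsv")
    summary = dict(
        pseudobulk=list(members),
        filter_counts=catalog.filter_counts,
        burdens={s: catalog.burden(s) for s in catalog.samples},
        callable_fraction=catalog.callable_fraction,
    )
    with open(dirs["filter"] / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return summary


def _load_catalog(cfg: RunConfig, dirs) -> SomaticCatalog:
    catalog = SomaticCatalog.read(dirs["filter"] / "catalog.tsv")
    with open(dirs["filter"] / "summary.json") as fh:
        summary = json.load(fh)
    catalog.pseudobulk_members = tuple(summary["pseudobulk"])
    catalog.callable_fraction = summary["callable_fraction"]
    return catalog


def _stage_fetal(cfg: RunConfig, dirs) -> dict:
    paths = list(cfg.fetal_trees) or [
        dirs["simulate"] / "truth_tree_mutations.nwk"
    ]
    trees = [Tree.from_newick(str(p)) for p in paths]
    estimate, medians = estimate_filtered_fetal_mutations(
        trees, n_iter=cfg.fetal_iterations, seed=cfg.seed, round_result=True
    )
    out = dict(estimate=estimate, per_tree_medians=medians,
               n_iterations=cfg.fetal_iterations)
    with open(dirs["fetal_estimate"] / "fetal.json", "w") as fh:
        json.dump(out, fh, indent=2, default=_jsonable)
    return out


def _fetal_add(dirs) -> float:
    path = dirs["fetal_estimate"] / "fetal.json"
    if path.exists():
        with open(path) as fh:
            return float(json.load(fh)["estimate"])
    return 0.0


def _stage_burden(cfg: RunConfig, dirs) -> dict:
    catalog = _load_catalog(cfg, dirs)
    if cfg.healthy_tsv:
        df = pd.read_csv(cfg.healthy_tsv, sep="\t")
        model = fit_age_model([
            BurdenObservation(r.sample, str(r.donor), r.age, int(r.burden), r.p)
            for r in df.itertuples()
        ])
    else:
        model = AgeBurdenModel(
            slope=cfg.baseline_slope, intercept=cfg.baseline_intercept,
            birth_load_ci=tuple(cfg.birth_load_ci),
        )
    fetal = _fetal_add(dirs)
    age = cfg.hsc_age
    ratios, groups = {}, {}
    for s in catalog.samples:
        obs = BurdenObservation(
            s, s, age, catalog.burden(s), catalog.callable_fraction[s],
            genotype="mutant" if s.startswith(cfg.clone_prefix) else "wildtype",
        )
        ratios[s] = corrected_burden(obs, fetal, model)
        groups.setdefault(obs.genotype, []).append(ratios[s])
    tests = compare_burdens(groups) if len(groups) > 1 else pd.DataFrame()
    pd.Series(ratios, name="oe_ratio").rename_axis("sample").to_csv(
        dirs["burden"] / "ratios.tsv", sep="\t"
    )
    out = dict(
        model=dict(slope=model.slope, intercept=model.intercept,
                   birth_load_ci=list(model.birth_load_ci)),
        fetal_add=fetal,
        oe_ratios={k: round(v, 3) for k, v in ratios.items()},
        wilcoxon=tests.to_dict("records"),
    )
    with open(dirs["burden"] / "burden.json", "w") as fh:
        json.dump(out, fh, indent=2, default=_jsonable)
    return out


def _stage_tree(cfg: RunConfig, dirs) -> dict:
    table = _load_table(cfg, dirs)
    catalog = _load_catalog(cfg, dirs)
    matrix = genotype_matrix(catalog, table)
    tree = build_tree(matrix, n_boot=cfg.n_boot, seed=cfg.seed)
    assignment = map_and_reassign(tree, matrix, cfg.missing_cutoff)
    with open(dirs["tree"] / "tree.nwk", "w") as fh:
        fh.write(tree.to_newick() + "\n")
    assignment.to_csv(dirs["tree"] / "assignment.tsv", sep="\t", index=False)
    support = pd.DataFrame(
        [
            (n.name, n.support, "timing_eligible" in n.flags,
             ",".join(sorted(tree.clade_tips(n))))
            for n in tree.internal_nodes(include_root=False)
        ],
        columns=["branch", "support", "timing_eligible", "clade"],
    )
    support.to_csv(dirs["tree"] / "support.tsv", sep="\t", index=False)
    return dict(
        n_variants=matrix.n_variants,
        n_internal_splits=len(support),
        supports=support.set_index("branch")["support"].round(3).to_dict(),
        branch_lengths={n.name: int(n.length) for n in tree.preorder()},
    )


def _load_tree(dirs) -> tuple[Tree, pd.DataFrame]:
    tree = Tree.from_newick(str(dirs["tree"] / "tree.nwk"))
    assignment = pd.read_csv(dirs["tree"] / "assignment.tsv", sep="\t")
    support = pd.read_csv(dirs["tree"] / "support.tsv", sep="\t")
    for r in support.itertuples():
        node = tree.find(r.branch)
        node.support = r.support
        if r.timing_eligible:
            node.flags.add("timing_eligible")
    counts = assignment.groupby("branch").size()
    for node in tree.preorder():
        node.length = float(counts.get(node.name, 0))
    return tree, assignment


def _clone_tips(cfg: RunConfig, samples) -> list[str]:
    return sorted(s for s in samples if s.startswith(cfg.clone_prefix))


def _stage_timescale(cfg: RunConfig, dirs) -> dict:
    tree, _ = _load_tree(dirs)
    catalog = _load_catalog(cfg, dirs)
    tcfg = TimeScaleConfig(
        target_age=cfg.target_age or cfg.hsc_age,
        gestation_years=cfg.gestation_years,
        birth_load=cfg.birth_load,
        birth_load_ci=tuple(cfg.birth_load_ci),
    )
    fetal = _fetal_add(dirs)
    p = catalog.callable_fraction
    timetree = convert_to_time(tree, p, fetal, tcfg)
    with open(dirs["timescale"] / "timetree.nwk", "w") as fh:
        fh.write(timetree.tree.to_newick(lengths="time") + "\n")
    out = dict(
        tip_times={k: round(v, 3) for k, v in timetree.tip_times().items()},
        flags=sorted(timetree.flags),
    )
    clone = _clone_tips(cfg, tree.tip_names())
    if len(clone) >= 2:
        timing = time_driver_acquisition(tree, p, fetal, clone, tcfg)
        out["driver_timing"] = timing.report()
    with open(dirs["timescale"] / "timing.json", "w") as fh:
        json.dump(out, fh, indent=2, default=_jsonable)
    return out


def _stage_signatures(cfg: RunConfig, dirs) -> dict:
    tree, assignment = _load_tree(dirs)
    ctx_path = cfg.contexts_tsv or dirs["simulate"] / "truth_mutations.tsv"
    contexts = pd.read_csv(ctx_path, sep="\t")[["chrom", "pos", "context"]]
    merged = assignment.merge(contexts, on=["chrom", "pos"], how="left").dropna(
        subset=["context"]
    )
    by_branch = {
        b: list(g["context"]) for b, g in merged.groupby("branch")
    }
    clone = _clone_tips(cfg, tree.tip_names())
    classes = partition_branch_classes(tree, clone)
    spectra = class_spectra(tree, by_branch, classes)
    catalog = default_catalog()
    refit = refit_contributions(
        spectra, catalog, n_boots=cfg.n_boots_refit, seed=cfg.seed
    )
    model = AgeSpectrumModel(birth_load=cfg.birth_load,
                             rate=cfg.baseline_slope, catalog=catalog)
    sim = cumulative_age_similarity(tree, by_branch, model)
    sim.to_csv(dirs["signatures"] / "age_similarity.tsv", sep="\t", index=False)
    refit.relative.to_csv(dirs["signatures"] / "contributions.tsv", sep="\t")
    out = dict(
        class_totals={c: float(spectra[c].sum()) for c in spectra.columns},
        relative_contributions=refit.relative.round(4).to_dict(),
        flags=refit.flags,
    )
    driver_ctx = cfg.driver_context
    if driver_ctx is None and clone:
        mrca = tree.mrca(clone)
        muts = by_branch.get(mrca.name, [])
        driver_ctx = muts[0] if muts else None
    if driver_ctx and refit.absolute["clonal"].sum() > 0:
        probs = driver_signature_probability(
            refit.absolute["clonal"], driver_ctx, catalog
        )
        out["driver_context"] = driver_ctx
        out["driver_signature_probability"] = probs.round(4).to_dict()
    with open(dirs["signatures"] / "signatures.json", "w") as fh:
        json.dump(out, fh, indent=2, default=_jsonable)
    return out


_STAGES = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "fetal_estimate": _stage_fetal,
    "burden": _stage_burden,
    "tree": _stage_tree,
    "timescale": _stage_timescale,
    "signatures": _stage_signatures,
}
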