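"""Conversion of mutation-scaled trees to time and driver timing.

Five steps turn a mutation-count phylogeny into an ultrametric tree in
years from conception: (1) the estimated fetal mutations removed by
germline filtering are added back to the root branch; (2) branch lengths
are corrected for somatic sensitivity — a terminal branch by its tip's
callable fraction p, a shared branch by 1 - prod(1 - p_i) over the tips
below it; (3) every root-to-tip path is cut at the mutation load at birth;
(4) the prenatal part is scaled to the 0.75-year gestation and each
postnatal part to the hematopoietic stem cell age using an iteratively
reweighted means scheme whose fixed point keeps the ratio of a shared
branch to the mean of its immediate descendant branches while making all
tips equidistant; (5) the scaled parts are merged back into one tree.

Splits are timed as years from birth; the uncertainty interval of a
driver-clone timing comes from redoing the conversion at the lower and
upper bounds of the 95% CI of the birth mutation load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .burden import DEFAULT_BIRTH_LOAD_CI
from .trees import Node, Tree

GESTATION_YEARS = 0.75


@dataclass
class TimeScaleConfig:
    target_age: float
    gestation_years: float = GESTATION_YEARS
    birth_load: float = 84.0
    birth_load_ci: tuple[float, float] = DEFAULT_BIRTH_LOAD_CI
    irm_tolerance: float = 1e-9
    irm_max_iter: int = 10000

    def __post_init__(self):
        if self.gestation_years <= 0 or self.target_age <= 0:
            raise ValueError("gestation_years and target_age must be positive")
        if self.birth_load_ci[0] > self.birth_load_ci[1]:
            raise ValueError("birth_load_ci must be ordered")


# ---------------------------------------------------------------------------
# step 2: coverage correction


def coverage_correct(tree: Tree, p: dict[str, float]) -> Tree:
    """Scale branch lengths by per-sample somatic sensitivity.

    Terminal branches divide by the tip's p; shared branches (the root
    branch included) divide by 1 - prod(1 - p_i) over descendant tips.
    Never shortens a branch since all p <= 1.
    """
    out = tree.copy()
    for tip in out.tips():
        if tip.name not in p:
            raise ValueError(f"no callable fraction for tip {tip.name!r}")
        if not 0 < p[tip.name] <= 1:
            raise ValueError(f"p for {tip.name!r} must be in (0, 1]")
    for node in out.preorder():
        if node.is_leaf:
            node.length /= p[node.name]
        else:
            miss = np.prod([1.0 - p[t] for t in out.clade_tips(node)])
            node.length /= (1.0 - miss) if miss < 1.0 else 1.0
    return out


# ---------------------------------------------------------------------------
# step 3: birth split


@dataclass
class BirthSplit:
    prenatal: Tree | None            # cut points appear as tips named cut*
    postnatal_parts: list[Tree]      # each rooted at a cut, root edge = remainder
    cut_points: list[tuple[str, float]]   # (branch name, distance into branch)
    entirely_prenatal_tips: list[str] = field(default_factory=list)


def split_at_birth(tree: Tree, birth_load: float) -> BirthSplit:
    """Cut every root-to-tip path at cumulative corrected distance
    ``birth_load``; branches straddling the cut are divided."""
    if birth_load < 0:
        raise ValueError("birth_load must be nonnegative")
    cuts: list[tuple[str, float]] = []
    parts: list[Tree] = []
    short_tips: list[str] = []

    def postnatal_subtree(node: Node, root_length: float) -> Tree:
        sub = Tree(node).copy()
        sub.root.length = root_length
        return sub

    if birth_load == 0:
        whole = tree.copy()
        cuts.append((tree.root.name, 0.0))
        parts.append(whole)
        return BirthSplit(None, parts, cuts)

    n_cut = 0

    def rec(node: Node, d0: float, pre_parent: Node | None) -> None:
        nonlocal n_cut
        d1 = d0 + node.length
        if d1 < birth_load or (d1 == birth_load and not node.children):
            rep = Node(node.name, node.length)
            if pre_parent is None:
                pre_root.append(rep)
            else:
                pre_parent.add_child(rep)
            if not node.children:
                short_tips.append(node.name)
            for child in node.children:
                rec(child, d1, rep)
        elif d1 == birth_load:
            rep = Node(node.name, node.length)
            (pre_root.append(rep) if pre_parent is None else pre_parent.add_child(rep))
            cuts.append((node.name, node.length))
            for child in node.children:
                parts.append(postnatal_subtree(child, child.length))
        else:
            pre_len = birth_load - d0
            cut_name = f"cut{n_cut}"
            n_cut += 1
            rep = Node(cut_name, pre_len)
            (pre_root.append(rep) if pre_parent is None else pre_parent.add_child(rep))
            cuts.append((node.name, pre_len))
            parts.append(postnatal_subtree(node, d1 - birth_load))

    pre_root: list[Node] = []
    rec(tree.root, 0.0, None)
    prenatal = Tree(pre_root[0]) if pre_root else None
    return BirthSplit(prenatal, parts, cuts, short_tips)


# ---------------------------------------------------------------------------
# step 4: scaling


def scale_ultrametric(
    part: Tree,
    target_span: float,
    tolerance: float = 1e-9,
    max_iter: int = 10000,
) -> dict[str, float]:
    """Node times (years from the top of the part's root branch) under the
    iteratively reweighted means fixed point.

    Every tip sits at ``target_span``; each internal node keeps the
    mutation-scale ratio of its branch to the mean of its child branches.
    Returns ``{node name: time}``.
    """
    if target_span <= 0:
        raise ValueError("target_span must be positive")
    nodes = list(part.preorder())
    if not nodes:
        raise ValueError("empty tree part")
    times: dict[int, float] = {}
    # initialize proportionally to mutation distance, per-path normalized
    for nd in nodes:
        if nd.is_leaf:
            times[id(nd)] = target_span
        else:
            d = part.distance_to_root(nd)
            tip_d = [part.distance_to_root(t) for t in part._subtree_tips(nd)]
            mean_d = float(np.mean(tip_d))
            times[id(nd)] = target_span * d / mean_d if mean_d > 0 else 0.0

    internals = [nd for nd in nodes if nd.children]
    ratios = {}
    for nd in internals:
        mean_child = float(np.mean([c.length for c in nd.children]))
        ratios[id(nd)] = (nd.length / mean_child) if mean_child > 0 else None

    for it in range(max_iter):
        delta = 0.0
        for nd in internals:
            t_parent = times[id(nd.parent)] if nd.parent is not None else 0.0
            mean_c = float(np.mean([times[id(c)] for c in nd.children]))
            r = ratios[id(nd)]
            if r is None:
                new = mean_c if nd.length > 0 else t_parent
            else:
                new = (t_parent + r * mean_c) / (1.0 + r)
            new = min(max(new, t_parent), min(times[id(c)] for c in nd.children))
            delta = max(delta, abs(new - times[id(nd)]))
            times[id(nd)] = new
        if delta < tolerance:
            break
    else:
        raise RuntimeError(
            f"iteratively reweighted means did not converge in {max_iter} "
            f"iterations (last change {delta:g})"
        )
    return {nd.name: times[id(nd)] for nd in nodes}


# ---------------------------------------------------------------------------
# step 5: merge / full conversion


@dataclass
class TimeTree:
    """Ultrametric tree with node times in years from conception."""

    tree: Tree
    config: TimeScaleConfig
    flags: set = field(default_factory=set)

    @property
    def birth_time(self) -> float:
        return self.config.gestation_years

    def split_time_from_birth(self, node_name: str) -> float:
        return self.tree.find(node_name).time - self.config.gestation_years

    def tip_times(self) -> dict[str, float]:
        return {t.name: t.time for t in self.tree.tips()}


def convert_to_time(
    tree: Tree,
    p: dict[str, float],
    fetal_add: float,
    cfg: TimeScaleConfig,
) -> TimeTree:
    """Run the five-step conversion; returns a time tree whose node names
    match the input tree."""
    work = tree.copy()
    work.root.length += fetal_add
    corrected = coverage_correct(work, p)
    split = split_at_birth(corrected, cfg.birth_load)

    times: dict[str, float] = {}
    flags = set()
    if split.prenatal is not None:
        L = cfg.birth_load
        for nd in split.prenatal.preorder():
            d = split.prenatal.distance_to_root(nd)
            times[nd.name] = cfg.gestation_years * min(d / L, 1.0)
    if split.entirely_prenatal_tips:
        flags.add("entirely_prenatal_paths")
    for part in split.postnatal_parts:
        part_times = scale_ultrametric(
            part, cfg.target_age, cfg.irm_tolerance, cfg.irm_max_iter
        )
        for name, t in part_times.items():
            times[name] = cfg.gestation_years + t

    out = corrected
    for nd in out.preorder():
        nd.time = times.get(nd.name)
        if nd.time is None:  # cut point fell exactly on this node
            nd.time = cfg.gestation_years
    return TimeTree(tree=out, config=cfg, flags=flags)


# ---------------------------------------------------------------------------
# driver timing


@dataclass
class DriverTiming:
    estimate: float                 # years from birth to the clone MRCA split
    interval: tuple[float, float]   # from the birth-load 95% CI bounds
    prenatal: bool
    since_conception: float
    clone_tips: list

    def report(self) -> dict:
        return dict(
            estimate_years_from_birth=float(round(self.estimate, 1)),
            interval_years_from_birth=[float(round(v, 1)) for v in self.interval],
            prenatal=bool(self.prenatal),
            clone_tips=list(self.clone_tips),
        )


def time_driver_acquisition(
    tree: Tree,
    p: dict[str, float],
    fetal_add: float,
    clone_tips,
    cfg: TimeScaleConfig,
    require_support: bool = True,
) -> DriverTiming:
    """Latest driver-acquisition time: the clone's MRCA split in years from
    birth, with the uncertainty interval from the birth-load CI bounds.

    The clone tips must form a clade; with ``require_support`` the clade
    must have been reproduced in every bootstrap replicate.
    """
    clone_tips = sorted(clone_tips)
    mrca = tree.mrca(clone_tips)
    if tree.clade_tips(mrca) != frozenset(clone_tips):
        raise ValueError("clone tips do not form a clade in the tree")
    if require_support and mrca.support is not None and mrca.support < 1.0:
        raise ValueError(
            f"clone clade support {mrca.support:.2f} < 1.0; not timing-eligible"
        )

    def split_time(birth_load: float) -> float:
        tt = convert_to_time(tree, p, fetal_add, replace(cfg, birth_load=birth_load))
        return tt.tree.find(mrca.name).time - cfg.gestation_years

    estimate = split_time(cfg.birth_load)
    lo, hi = sorted(
        split_time(b) for b in cfg.birth_load_ci
    )
    return DriverTiming(
        estimate=estimate,
        interval=(lo, hi),
        prenatal=estimate < 0,
        since_conception=estimate + cfg.gestation_years,
        clone_tips=clone_tips,
    )
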