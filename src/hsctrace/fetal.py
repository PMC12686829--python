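"""Estimate true somatic mutations lost to pseudo-bulk germline filtering.

Filtering against a pseudo-bulk of two random colonies removes any early
embryonic mutation shared between the colony of interest and either
pseudo-bulk member.  The size of that loss is estimated by resampling tip
triples from reference phylogenies (mutation-count branch lengths): one
"sample of interest" and two "pseudo-bulk" tips are drawn, and the shared
variants are the summed lengths of the unique edges connecting each
MRCA(pseudo-bulk tip, interest tip) to the root.  The per-tree statistic is
the median over iterations; the final estimate is the mean over trees.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np

from .trees import Tree


def shared_variants_for_triple(tree: Tree, interest: str, pseudobulk) -> float:
    """Shared-variant count for one (interest, two pseudo-bulk tips) triple.

    Edges above each MRCA(pseudo-bulk tip, interest) up to and including the
    root branch are collected; overlapping edges count once.
    """
    edges: dict[int, float] = {}
    for pb in pseudobulk:
        mrca = tree.mrca([pb, interest])
        for node in tree.ancestors(mrca, include_self=True):
            edges[id(node)] = node.length
    return float(sum(edges.values()))


def _triples(tip_names, rng=None):
    if rng is None:  # exhaustive: all unordered pseudo-bulk pairs x interest
        for interest in tip_names:
            rest = [t for t in tip_names if t != interest]
            for pair in itertools.combinations(rest, 2):
                yield interest, pair
    else:
        while True:
            picks = rng.choice(len(tip_names), size=3, replace=False)
            yield tip_names[picks[0]], (tip_names[picks[1]], tip_names[picks[2]])


def tree_median_shared(
    tree: Tree, n_iter: int = 1000, rng=None, exhaustive: bool = False
) -> float:
    """Median shared-variant count over resampled (or all) tip triples."""
    tips = tree.tip_names()
    if len(tips) < 3:
        raise ValueError("tree needs at least 3 tips")
    if exhaustive:
        values = [
            shared_variants_for_triple(tree, i, pair)
            for i, pair in _triples(tips, None)
        ]
    else:
        rng = np.random.default_rng(rng)
        gen = _triples(tips, rng)
        values = [
            shared_variants_for_triple(tree, *next(gen)) for _ in range(n_iter)
        ]
    return float(np.median(values))


def estimate_filtered_fetal_mutations(
    trees,
    n_iter: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    round_result: bool = False,
):
    """Mean over trees of the per-tree median shared-variant count.

    Trees with fewer than 3 tips are skipped with a warning.  With
    ``round_result`` the estimate is rounded half-up to a whole mutation
    count, the form in which it is added to a root branch.
    Returns ``(estimate, per_tree_medians)``.
    """
    rng = np.random.default_rng(seed)
    medians = []
    for tree in trees:
        if len(tree.tips()) < 3:
            warnings.warn("skipping reference tree with fewer than 3 tips")
            continue
        medians.append(
            tree_median_shared(tree, n_iter=n_iter, rng=rng, exhaustive=exhaustive)
        )
    if not medians:
        raise ValueError("no reference tree with >= 3 tips")
    estimate = float(np.mean(medians))
    if round_result:
        estimate = math.floor(estimate + 0.5)
    return estimate, medians
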