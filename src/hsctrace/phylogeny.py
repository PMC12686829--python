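"""Colony phylogeny reconstruction and mutation-to-branch mapping.

Colonies are clonal, so their somatic genotypes are near-perfect clade
markers and a greedy perfect-phylogeny construction suffices: candidate
splits (sets of colonies sharing variants) are ranked by supporting variant
count and accepted when compatible (nested or disjoint) with the splits
already accepted, treating low-coverage entries as wildcards.  Colonies
without any accepted grouping attach at the root — the expected, very
polyclonal base of a blood phylogeny.  Split robustness is assessed by
bootstrap-resampling variants; only splits present in all replicates are
marked eligible for timing.

An externally reconstructed tree (Newick plus a mutation-to-branch TSV) can
be imported instead; mapping and reassignment then run unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import FilterThresholds, SomaticCatalog
from .trees import Node, Tree
from .variant_table import VariantTable

PRESENT, ABSENT, MISSING = 1, 0, -1


@dataclass
class GenotypeMatrix:
    """Variants x samples states with per-entry read evidence retained.

    States: present (passed the somatic filter in that sample), missing
    (depth below the callable threshold), absent (adequate depth, no call).
    """

    samples: list[str]
    variants: pd.DataFrame          # chrom, pos, ref, alt
    state: np.ndarray               # (n_var, n_samples) in {1, 0, -1}
    depth: np.ndarray
    alt_count: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[tuple]:
        return list(
            zip(self.variants["chrom"], self.variants["pos"],
                self.variants["ref"], self.variants["alt"])
        )


def genotype_matrix(
    catalog: SomaticCatalog,
    table: VariantTable,
    thresholds: FilterThresholds | None = None,
) -> GenotypeMatrix:
    """Build the genotype matrix over all catalog variants and colonies."""
    th = thresholds or FilterThresholds()
    samples = [s for s in table.samples if s not in catalog.pseudobulk_members]
    keys = catalog.variants[["chrom", "pos", "ref", "alt"]].drop_duplicates()
    site_index = {
        (c, p, r, a): i
        for i, (c, p, r, a) in enumerate(
            zip(table.sites["chrom"], table.sites["pos"],
                table.sites["ref"], table.sites["alt"])
        )
    }
    rows = [site_index[k] for k in keys.itertuples(index=False, name=None)]
    cols = [table.sample_index(s) for s in samples]
    depth = table.depth[np.ix_(rows, cols)]
    alt = table.alt_count[np.ix_(rows, cols)]
    state = np.where(depth < th.min_depth, MISSING, ABSENT)
    passing = set(
        zip(catalog.variants["sample"], catalog.variants["chrom"],
            catalog.variants["pos"], catalog.variants["ref"],
            catalog.variants["alt"])
    )
    keylist = list(keys.itertuples(index=False, name=None))
    for i, k in enumerate(keylist):
        for j, s in enumerate(samples):
            if (s, *k) in passing:
                state[i, j] = PRESENT
    keep = (state == PRESENT).any(axis=1)
    return GenotypeMatrix(
        samples=samples,
        variants=keys.reset_index(drop=True)[keep.tolist()].reset_index(drop=True)
        if not keep.all() else keys.reset_index(drop=True),
        state=state[keep],
        depth=depth[keep],
        alt_count=alt[keep],
    )


# ---------------------------------------------------------------------------
# greedy split selection on bitmask patterns


def _patterns(matrix: GenotypeMatrix):
    """Collapse variants into distinct (present-mask, missing-mask) patterns."""
    n = len(matrix.samples)
    weights = 2 ** np.arange(n, dtype=object)
    p_masks = ((matrix.state == PRESENT) @ weights).astype(object)
    m_masks = ((matrix.state == MISSING) @ weights).astype(object)
    counts: dict[tuple[int, int], int] = {}
    index: dict[tuple[int, int], list[int]] = {}
    for i, (p, m) in enumerate(zip(p_masks, m_masks)):
        key = (int(p), int(m))
        counts[key] = counts.get(key, 0) + 1
        index.setdefault(key, []).append(i)
    return counts, index


def _compatible(s: int, t: int) -> bool:
    inter = s & t
    return inter == 0 or inter == s or inter == t


def _mask_labels(mask: int, samples) -> tuple:
    return tuple(sorted(samples[j] for j in range(len(samples)) if mask >> j & 1))


def _greedy_accept(pattern_counts: dict, n_samples: int, samples,
                   min_carriers: int = 2):
    """Greedy split acceptance; returns (accepted masks, support, tie flag)."""
    full = (1 << n_samples) - 1
    remaining = dict(pattern_counts)
    accepted: list[int] = []
    support: dict[int, int] = {}
    tie_flagged = False
    while True:
        cands = {
            p for (p, m) in remaining
            if min_carriers <= bin(p).count("1") <= n_samples - 1
        }
        if not cands:
            break
        scores = {}
        for s in cands:
            tot = 0
            for (p, m), c in remaining.items():
                if bin(p).count("1") >= min_carriers and (p & ~s) == 0 and (s & ~(p | m)) == 0:
                    tot += c
            scores[s] = tot
        best_score = max(scores.values())
        if best_score == 0:
            break
        top = [s for s, sc in scores.items() if sc == best_score]
        if len(top) > 1:
            if any(not _compatible(a, b) for a in top for b in top if a != b):
                tie_flagged = True
            top.sort(key=lambda s: _mask_labels(s, samples))
        chosen = top[0]
        if all(_compatible(chosen, a) for a in accepted):
            accepted.append(chosen)
            support[chosen] = best_score
        remaining = {
            (p, m): c for (p, m), c in remaining.items()
            if not (bin(p).count("1") >= min_carriers
                    and (p & ~chosen) == 0 and (chosen & ~(p | m)) == 0)
        }
    return accepted, support, tie_flagged


def build_tree(
    matrix: GenotypeMatrix, n_boot: int = 100, seed: int | None = None
) -> Tree:
    """Greedy perfect-phylogeny reconstruction with bootstrap supports.

    Branch lengths are supporting-variant counts; tips with no accepted
    grouping attach at the root.  ``node.support`` on internal splits is
    the fraction of bootstrap replicates (variants resampled with
    replacement) reproducing the split; splits with support 1.0 carry the
    ``timing_eligible`` flag.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least two samples")
    samples = matrix.samples
    n = len(samples)
    counts, index = _patterns(matrix)
    accepted, support_counts, tie = _greedy_accept(counts, n, samples)

    # bootstrap: multinomial resampling of pattern multiplicities
    rng = np.random.default_rng(seed)
    keys = list(counts)
    probs = np.array([counts[k] for k in keys], dtype=float)
    total = probs.sum()
    boot_hits = {s: 0 for s in accepted}
    if total > 0 and n_boot > 0:
        probs /= total
        for _ in range(n_boot):
            draw = rng.multinomial(int(total), probs)
            resampled = {k: int(c) for k, c in zip(keys, draw) if c > 0}
            acc_b, _, _ = _greedy_accept(resampled, n, samples)
            acc_set = set(acc_b)
            for s in accepted:
                if s in acc_set:
                    boot_hits[s] += 1

    # assemble topology: nested splits, largest first
    full = (1 << n) - 1
    root = Node(name="root")
    nodes = {full: root}
    for mask in sorted(accepted, key=lambda m: -bin(m).count("1")):
        parent_mask = min(
            (pm for pm in nodes if pm & mask == mask and pm != mask),
            key=lambda pm: bin(pm).count("1"),
        )
        node = Node()
        node.support = boot_hits[mask] / n_boot if n_boot else None
        if node.support == 1.0:
            node.flags.add("timing_eligible")
        nodes[parent_mask].add_child(node)
        nodes[mask] = node
    for j, s in enumerate(samples):
        tipmask = 1 << j
        parent_mask = min(
            (pm for pm in nodes if pm & tipmask),
            key=lambda pm: bin(pm).count("1"),
        )
        nodes[parent_mask].add_child(Node(name=s))

    tree = Tree(root)
    if tie:
        root.flags.add("tie_broken")
    k = 0
    for node in tree.preorder():
        if node.name is None:
            node.name = f"n{k}"
            k += 1

    # initial mutation assignment: supporters to their split, privates to
    # tips, all-sample variants to the root branch; leftovers to the root
    # flagged (map_and_reassign refines all of this).
    node_by_mask = nodes
    assigned = np.full(matrix.n_variants, -1, dtype=int)
    order = list(tree.preorder())
    node_pos = {id(nd): i for i, nd in enumerate(order)}
    tip_mask = {s: 1 << j for j, s in enumerate(samples)}

    def assign(i, node):
        node.mutations.append(i)
        assigned[i] = node_pos[id(node)]

    consumed_masks = sorted(accepted, key=lambda m: bin(m).count("1"))
    for (p, m), idxs in index.items():
        npop = bin(p).count("1")
        if npop == n:
            target = root
        elif npop == 1:
            target = tree.find(samples[p.bit_length() - 1])
        else:
            target = None
            for s in consumed_masks:
                if (p & ~s) == 0 and (s & ~(p | m)) == 0:
                    target = node_by_mask[s]
                    break
            if target is None:
                target = root
        for i in idxs:
            assign(i, target)
    for node in tree.preorder():
        node.length = float(len(node.mutations))
    return tree


# ---------------------------------------------------------------------------
# mapping and reassignment


def map_and_reassign(
    tree: Tree, matrix: GenotypeMatrix, missing_cutoff: float = 0.1
) -> pd.DataFrame:
    """Refine the mutation-to-branch assignment on a reconstructed tree.

    End-branch cleanup: a variant on a terminal branch with alt reads in two
    or more samples is removed from the terminal branch and re-evaluated as
    shared.  Each shared variant goes to the deepest branch whose clade
    contains all its carriers; it may stay there while at most
    ``missing_cutoff`` of that clade's colonies lack the call; otherwise it
    is reassigned to the best-fitting descendant branch (maximal carrier
    coverage, minimal confirmed non-carriers, ties to the deeper branch).
    Variants fitting no branch land on the root branch, flagged.

    Returns the assignment table (variant, branch, flag) and updates the
    tree's per-branch mutation lists and lengths in place.
    """
    samples = matrix.samples
    sidx = {s: j for j, s in enumerate(samples)}
    order = list(tree.preorder())
    clades = {id(nd): tree.clade_tips(nd) for nd in order}
    depth_of = {id(tree.root): 0}
    for nd in order:
        for c in nd.children:
            depth_of[id(c)] = depth_of[id(nd)] + 1

    for nd in order:
        nd.mutations = []

    keys = matrix.variant_keys()
    rows = []
    for i in range(matrix.n_variants):
        st_row = matrix.state[i]
        carriers = frozenset(s for s in samples if st_row[sidx[s]] == PRESENT)
        evidence = frozenset(
            s for s in samples if matrix.alt_count[i, sidx[s]] > 0
        )
        flag = ""
        if len(carriers) == 1 and len(evidence) < 2:
            target = tree.find(next(iter(carriers)))
        elif len(carriers) == 1:
            # end-branch cleanup: alt reads in >= 2 samples, so the variant
            # is shared; place it over the samples with read evidence
            flag = "end_branch_rescued"
            target = tree.mrca(evidence)
        else:
            # deepest branch whose clade contains all carriers; low-coverage
            # entries and subthreshold alt evidence are wildcards — only a
            # confirmed reference call (adequate depth, zero alt reads)
            # counts against the clade
            node = tree.mrca(carriers)
            clade = clades[id(node)]
            confirmed_absent = sum(
                1 for s in clade
                if st_row[sidx[s]] == ABSENT and matrix.alt_count[i, sidx[s]] == 0
            )
            if confirmed_absent / len(clade) <= missing_cutoff:
                target = node
            else:
                target, flag = _best_fitting(
                    tree, node, carriers, st_row, matrix.alt_count[i],
                    sidx, clades, depth_of
                )
        target.mutations.append(i)
        rows.append((*keys[i], target.name, flag))

    for nd in order:
        nd.length = float(len(nd.mutations))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "branch", "flag"]
    )


def _best_fitting(tree, top, carriers, st_row, alt_row, sidx, clades, depth_of):
    """Best-fitting branch below ``top`` for a variant's carrier set."""
    best, best_key = None, None
    stack = list(top.children)
    while stack:
        nd = stack.pop()
        clade = clades[id(nd)]
        cov = len(carriers & clade)
        if cov:
            noncarr = sum(
                1 for s in clade
                if s not in carriers and st_row[sidx[s]] == ABSENT
                and alt_row[sidx[s]] == 0
            )
            key = (cov, -noncarr, depth_of[id(nd)])
            if best_key is None or key > best_key:
                best, best_key = nd, key
        stack.extend(nd.children)
    if best is None:
        return tree.root, "root_fallback"
    flag = "" if clades[id(best)] >= carriers else "imperfect_fit"
    return best, flag


def assignments_table(tree: Tree, matrix: GenotypeMatrix) -> pd.DataFrame:
    keys = matrix.variant_keys()
    rows = []
    for nd in tree.preorder():
        for i in nd.mutations:
            rows.append((*keys[i], nd.name))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "branch"])
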