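import numpy as np
import pandas as pd
import pytest

from hsctrace.phylogeny import (
    ABSENT,
    MISSING,
    PRESENT,
    GenotypeMatrix,
    build_tree,
    map_and_reassign,
)


def make_matrix(samples, rows):
    """rows: list of (state vector, alt vector) or state vector only."""
    states, alts = [], []
    for r in rows:
        st, alt = r if isinstance(r, tuple) else (r, None)
        states.append(st)
        alts.append(
            alt if alt is not None else [1 if s == PRESENT else 0 for s in st]
        )
    state = np.array(states)
    alt = np.array(alts)
    depth = np.where(state == MISSING, 0, 15)
    variants = pd.DataFrame(
        dict(chrom="chr1", pos=np.arange(1, len(rows) + 1),
             ref="C", alt="T")
    )
    return GenotypeMatrix(samples=samples, variants=variants, state=state,
                          depth=depth, alt_count=alt)


def test_no_shared_variants_gives_star_tree():
    samples = ["a", "b", "c", "d"]
    rows = [[PRESENT if j == i % 4 else ABSENT for j in range(4)]
            for i in range(12)]
    tree = build_tree(make_matrix(samples, rows), n_boot=10, seed=0)
    assert all(c.is_leaf for c in tree.root.children)
    assert sorted(tree.tip_names()) == samples


def test_clean_clade_recovered_with_full_support():
    samples = list("abcdef")
    clade = [PRESENT, PRESENT, PRESENT, ABSENT, ABSENT, ABSENT]
    rows = [clade] * 40
    for i in range(6):  # private variants
        rows += [[PRESENT if j == i else ABSENT for j in range(6)]] * 5
    tree = build_tree(make_matrix(samples, rows), n_boot=50, seed=1)
    internal = tree.internal_nodes(include_root=False)
    assert len(internal) == 1
    node = internal[0]
    assert tree.clade_tips(node) == frozenset("abc")
    assert node.length == 40
    assert node.support == 1.0
    assert "timing_eligible" in node.flags


def test_clade_recovery_under_dropout():
    """A 3-colony clade marked by 40 variants survives 10% per-entry
    dropout (confirmed reference miscalls) in >= 95% of replicate
    datasets."""
    samples = list("abcdef")
    rng = np.random.default_rng(42)
    recovered = 0
    n_rep = 200
    for _ in range(n_rep):
        rows = []
        for _ in range(40):
            st = [PRESENT, PRESENT, PRESENT, ABSENT, ABSENT, ABSENT]
            alt = [8, 8, 8, 0, 0, 0]
            for j in range(3):
                if rng.random() < 0.1:
                    st[j], alt[j] = ABSENT, 0
            rows.append((st, alt))
        for i in range(6):
            rows += [[PRESENT if j == i else ABSENT for j in range(6)]] * 3
        tree = build_tree(make_matrix(samples, rows), n_boot=0)
        clades = {
            tree.clade_tips(n) for n in tree.internal_nodes(include_root=False)
        }
        recovered += frozenset("abc") in clades
    assert recovered >= 0.95 * n_rep


def big_clade_matrix():
    """12 colonies; clade of 10 (a..j) with a nested sub-clade of 7 (a..g)."""
    samples = list("abcdefghijkl")
    ten = [PRESENT] * 10 + [ABSENT] * 2
    seven = [PRESENT] * 7 + [ABSENT] * 5
    rows = [list(ten)] * 30 + [list(seven)] * 20
    for i in range(12):
        rows += [[PRESENT if j == i else ABSENT for j in range(12)]] * 3
    return samples, rows


def test_variant_missing_in_one_of_ten_stays_on_clade():
    samples, rows = big_clade_matrix()
    probe = [PRESENT] * 9 + [MISSING] + [ABSENT] * 2
    rows = rows + [probe]
    m = make_matrix(samples, rows)
    tree = build_tree(m, n_boot=0)
    asg = map_and_reassign(tree, m)
    clade_ten = tree.mrca(list("abcdefghij"))
    assert asg.iloc[-1]["branch"] == clade_ten.name


def test_variant_absent_with_data_in_three_is_reassigned():
    samples, rows = big_clade_matrix()
    # present in the 7-subclade, confirmed absent (alt 0) in h, i, j
    probe = ([PRESENT] * 7 + [ABSENT] * 5, [8] * 7 + [0] * 5)
    rows = rows + [probe]
    m = make_matrix(samples, rows)
    tree = build_tree(m, n_boot=0)
    asg = map_and_reassign(tree, m)
    sub_seven = tree.mrca(list("abcdefg"))
    assert asg.iloc[-1]["branch"] == sub_seven.name


def test_end_branch_variant_with_shared_evidence_is_rescued():
    samples, rows = big_clade_matrix()
    # passes filters only in 'a' but has alt reads in b and c
    probe = ([PRESENT] + [ABSENT] * 11, [9, 2, 2] + [0] * 9)
    rows = rows + [probe]
    m = make_matrix(samples, rows)
    tree = build_tree(m, n_boot=0)
    asg = map_and_reassign(tree, m)
    assert asg.iloc[-1]["flag"] == "end_branch_rescued"
    assert asg.iloc[-1]["branch"] == tree.mrca(["a", "b", "c"]).name


def test_mutation_conservation(driver_analysis):
    params, truth, obs, catalog, matrix, tree, assignment = driver_analysis
    assert len(assignment) == matrix.n_variants
    total = sum(len(n.mutations) for n in tree.preorder())
    assert total == matrix.n_variants
    assert all(n.length == len(n.mutations) for n in tree.preorder())


def test_no_noise_recovery_matches_truth(clean_dataset):
    """Clean data: reconstruction reproduces the truth clone clade and the
    clone's per-branch mutation counts for the analyzed colonies."""
    from conftest import analyze

    params, truth, obs = clean_dataset
    catalog, matrix, tree, assignment = analyze(truth, obs, n_boot=30)
    clone = truth.clone_tips
    mrca = tree.mrca(clone)
    assert tree.clade_tips(mrca) == frozenset(clone)
    assert mrca.support == 1.0

    truth_mrca = truth.tree.find(truth.driver_branch)
    # per-branch counts inside the clone match the truth exactly
    def counts_by_clade(t, node):
        return {
            t.clade_tips(n): len(n.mutations)
            for n in t.preorder()
            if t.clade_tips(n) <= frozenset(clone)
        }

    assert counts_by_clade(tree, mrca) == counts_by_clade(truth.tree, truth_mrca)
    # clone stem length matches the truth stem
    assert mrca.length == truth_mrca.length


def test_same_driver_colonies_form_one_clade(driver_analysis):
    """Colonies carrying the same driver always share a clonal origin when
    the clone-shared burden exceeds the embryonic one."""
    params, truth, obs, catalog, matrix, tree, assignment = driver_analysis
    mrca = tree.mrca(truth.clone_tips)
    assert tree.clade_tips(mrca) == frozenset(truth.clone_tips)
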