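import numpy as np
import pandas as pd
import pytest

from hsctrace.signature_profiles import AgeSpectrumModel, default_catalog
from hsctrace.signatures import (
    class_spectra,
    cumulative_age_similarity,
    driver_signature_probability,
    extract_signatures,
    match_reference,
    partition_branch_classes,
    refit_contributions,
)
from hsctrace.spectra import CHANNELS, cosine, spectrum_frame
from hsctrace.trees import Tree


@pytest.fixture(scope="module")
def catalog():
    return default_catalog()


def near_orthogonal_profiles():
    a = np.zeros(96)
    a[:16] = 1.0
    b = np.zeros(96)
    b[48:72] = 1.0
    return a / a.sum(), b / b.sum()


def test_catalog_profiles_distinct_and_normalized(catalog):
    assert np.allclose(catalog.sum(axis=0), 1.0)
    cols = list(catalog.columns)
    for i, x in enumerate(cols):
        for y in cols[i + 1:]:
            assert cosine(catalog[x], catalog[y]) < 0.8


def test_nmf_rank1_recovers_single_profile(catalog):
    prof = catalog["SBS18"].to_numpy()
    X = spectrum_frame({f"s{i}": prof * n for i, n in enumerate([100, 300, 50, 200])})
    res = extract_signatures(X, rank=1, n_runs=5, seed=0)
    assert cosine(res.signatures["sig1"], prof) >= 0.999
    assert all(v >= 0.999 for v in res.per_sample_cosine.values())


def test_nmf_rank2_recovers_known_mixture():
    a, b = near_orthogonal_profiles()
    rng = np.random.default_rng(1)
    cols = {}
    for i, w in enumerate([0.1, 0.35, 0.6, 0.85, 0.95, 0.25]):
        mix = w * a + (1 - w) * b
        cols[f"s{i}"] = rng.multinomial(3000, mix).astype(float)
    res = extract_signatures(spectrum_frame(cols), rank=2, n_runs=20, seed=2)
    sims = np.array(
        [[cosine(res.signatures[c], p) for p in (a, b)]
         for c in res.signatures.columns]
    )
    assert sims.max(axis=0).min() >= 0.98  # each truth profile recovered


def test_nmf_rank_validation():
    a, _ = near_orthogonal_profiles()
    X = spectrum_frame({"s": a * 100})
    with pytest.raises(ValueError):
        extract_signatures(X, rank=2, n_runs=2, seed=0)


def test_nmf_deterministic_given_seed(catalog):
    a, b = near_orthogonal_profiles()
    X = spectrum_frame({"x": 200 * a + 50 * b, "y": 50 * a + 300 * b})
    r1 = extract_signatures(X, rank=2, n_runs=10, seed=5)
    r2 = extract_signatures(X, rank=2, n_runs=10, seed=5)
    assert np.allclose(r1.signatures.to_numpy(), r2.signatures.to_numpy())


def test_match_reference_identity_and_threshold(catalog):
    extracted = catalog[["SBS1"]].rename(columns={"SBS1": "sig1"})
    final, report = match_reference(extracted, catalog)
    assert report.iloc[0]["replaced"]
    assert report.iloc[0]["cosine"] == pytest.approx(1.0)
    assert "SBS1" in final.columns

    rng = np.random.default_rng(3)
    noise = rng.dirichlet(np.ones(96) * 0.05)
    denovo = spectrum_frame({"sig1": noise})
    final2, report2 = match_reference(denovo, catalog)
    if report2.iloc[0]["cosine"] < 0.85:
        assert not report2.iloc[0]["replaced"]
        assert "sig1" in final2.columns


def test_match_reference_collision_flagged(catalog):
    e = catalog[["SBS1", "SBS1"]]
    e.columns = ["sig1", "sig2"]
    final, report = match_reference(e, catalog)
    assert report["collapsed"].any()
    assert list(final.columns).count("SBS1") == 1


def test_refit_pure_column(catalog):
    spectra = spectrum_frame({"c": 100 * catalog["SBS5"].to_numpy()})
    res = refit_contributions(spectra, catalog, n_boots=30, seed=0)
    assert res.absolute.loc["SBS5", "c"] == pytest.approx(100, rel=0.05)
    others = res.relative["c"].drop("SBS5")
    assert (others < 0.05).all()


def test_refit_recovers_even_mixture():
    a, b = near_orthogonal_profiles()
    sigs = spectrum_frame({"A": a, "B": b})
    rng = np.random.default_rng(4)
    y = rng.multinomial(1000, 0.5 * a + 0.5 * b).astype(float)
    res = refit_contributions(spectrum_frame({"c": y}), sigs, n_boots=100, seed=5)
    assert res.relative.loc["A", "c"] == pytest.approx(0.5, abs=0.05)
    assert res.relative.loc["B", "c"] == pytest.approx(0.5, abs=0.05)


def test_refit_relative_normalization_and_flags(catalog):
    spectra = spectrum_frame({
        "ok": 500 * catalog["SBS5"].to_numpy(),
        "tiny": 20 * catalog["SBS1"].to_numpy(),
        "empty": np.zeros(96),
    })
    res = refit_contributions(spectra, catalog, n_boots=20, seed=6)
    assert res.relative["ok"].sum() == pytest.approx(1.0, abs=1e-6)
    assert res.flags.get("tiny") == "low_confidence"
    assert res.flags.get("empty") == "empty"
    assert res.absolute["empty"].sum() == 0


def fixture_tree():
    # 8 tips: clone (m1,m2,m3), wildtype (w1..w4), excluded unique-driver u1
    return Tree.from_newick(
        "(((m1:5,(m2:4,m3:6)s1:7)clonal_stem:30,(w1:8,w2:9)wt1:3)top:2,"
        "w3:12,(w4:10,u1:11)mix:1)root:4;"
    )


def test_partition_branch_classes_enumerated():
    tree = fixture_tree()
    classes = partition_branch_classes(
        tree, ["m1", "m2", "m3"], excluded_tips=["u1"]
    )
    assert set(classes.clonal) == {"root", "top", "clonal_stem"}
    assert set(classes.subclonal) == {"m1", "s1", "m2", "m3"}
    assert set(classes.wildtype) == {"wt1", "w1", "w2", "w3", "w4"}
    # u1's terminal branch and the mixed branch join no class
    everything = set(classes.clonal + classes.subclonal + classes.wildtype)
    assert "u1" not in everything and "mix" not in everything


def test_partition_wildtype_only():
    tree = Tree.from_newick("((a:1,b:2)x:3,c:4)root:0;")
    classes = partition_branch_classes(tree, [])
    assert classes.clonal == [] and classes.subclonal == []
    assert set(classes.wildtype) == {"root", "x", "a", "b", "c"}


def test_partition_rejects_non_clade_clone():
    tree = Tree.from_newick("((a:1,b:2)x:3,c:4)root:0;")
    with pytest.raises(ValueError):
        partition_branch_classes(tree, ["a", "c"])


def test_class_spectra_conserve_mutations():
    tree = fixture_tree()
    classes = partition_branch_classes(
        tree, ["m1", "m2", "m3"], excluded_tips=["u1"]
    )
    by_branch = {
        n.name: ["A[C>T]G"] * int(n.length) for n in tree.preorder()
    }
    spectra = class_spectra(tree, by_branch, classes)
    in_scope = set(classes.clonal + classes.subclonal + classes.wildtype)
    expected = sum(int(n.length) for n in tree.preorder() if n.name in in_scope)
    assert spectra.to_numpy().sum() == expected


def test_cumulative_age_similarity_argmax_near_truth():
    """With distinguishable prenatal/postnatal profiles the argmax age
    tracks the simulated sampling age (the age contrast is strongest early
    in life, where the fetal fraction still changes quickly)."""
    a, b = near_orthogonal_profiles()
    model = AgeSpectrumModel(
        birth_load=84.0, rate=16.0, prenatal_profile=a, postnatal_profile=b
    )
    rng = np.random.default_rng(7)
    pred = model.predicted(10)
    counts = rng.multinomial(2000, pred / pred.sum())
    contexts = [c for c, k in zip(CHANNELS, counts) for _ in range(k)]
    tree = Tree.from_newick("(tip:1)root:0;")
    sim = cumulative_age_similarity(tree, {"tip": contexts}, model)
    tip_rows = sim[(sim["branch"] == "tip") & (sim["age"] >= 0)]
    best_age = tip_rows.loc[tip_rows["cosine"].idxmax(), "age"]
    assert abs(best_age - 10) <= 5
    assert tip_rows["cosine"].max() >= 0.98


def test_cumulative_similarity_plateau_at_true_age(catalog):
    """Under the default clock-like mixture the cosine at the true sampling
    age sits on the curve's plateau (>= 0.95)."""
    model = AgeSpectrumModel(catalog=catalog)
    rng = np.random.default_rng(8)
    pred = model.predicted(40)
    counts = rng.multinomial(2000, pred / pred.sum())
    contexts = [c for c, k in zip(CHANNELS, counts) for _ in range(k)]
    tree = Tree.from_newick("(tip:1)root:0;")
    sim = cumulative_age_similarity(tree, {"tip": contexts}, model)
    at_40 = sim[(sim["branch"] == "tip") & (sim["age"] == 40)]["cosine"].iloc[0]
    assert at_40 >= 0.95


def test_cumulative_low_count_flagged(catalog):
    model = AgeSpectrumModel(catalog=catalog)
    tree = Tree.from_newick("(tip:1)root:0;")
    sim = cumulative_age_similarity(tree, {"tip": ["A[C>T]G"] * 10}, model)
    flags = sim[sim["branch"] == "tip"]["flag"]
    assert (flags[sim["age"] >= 0] == "low_confidence").all()


def test_driver_probability_worked_example():
    sigs = spectrum_frame({
        "A": np.full(96, 0.9 / 95).tolist(),
        "B": np.full(96, 0.99 / 95).tolist(),
    })
    ch = "A[C>T]G"
    sigs.loc[ch, "A"] = 0.10
    sigs.loc[ch, "B"] = 0.01
    sigs /= sigs.sum(axis=0)
    # contributions 30/70, channel weights 0.10/0.01 -> 0.8108 / 0.1892
    probs = driver_signature_probability({"A": 30.0, "B": 70.0}, ch, sigs)
    assert probs["A"] == pytest.approx(0.8108, abs=2e-4)
    assert probs["B"] == pytest.approx(0.1892, abs=2e-4)
    assert probs.sum() == pytest.approx(1.0)


def test_driver_probability_invariances(catalog):
    ch = "T[C>T]G"
    p1 = driver_signature_probability(
        {"SBS1": 40.0, "SBS5": 60.0}, ch, catalog
    )
    p2 = driver_signature_probability(
        {"SBS1": 4.0, "SBS5": 6.0}, ch, catalog
    )
    assert np.allclose(p1, p2)
    single = driver_signature_probability({"SBS1": 10.0}, ch, catalog)
    assert single["SBS1"] == pytest.approx(1.0)


def test_driver_probability_unexplained_context_errors():
    sigs = spectrum_frame({"A": np.eye(96)[0]})
    with pytest.raises(ValueError):
        driver_signature_probability({"A": 10.0}, CHANNELS[5], sigs)


def test_refit_on_simulated_branch_classes(driver_analysis, catalog):
    """The strict refit recovers the simulator's postnatal signature mixture
    from the merged wildtype-branch spectrum."""
    params, truth, obs, catalog_f, matrix, tree, assignment = driver_analysis
    merged = assignment.merge(
        truth.mutations[["chrom", "pos", "context"]], on=["chrom", "pos"],
        how="left",
    ).dropna(subset=["context"])
    by_branch = {b: list(g["context"]) for b, g in merged.groupby("branch")}
    classes = partition_branch_classes(tree, truth.clone_tips)
    spectra = class_spectra(tree, by_branch, classes)
    res = refit_contributions(spectra, catalog, n_boots=50, seed=8)
    # wildtype branches are almost entirely postnatal at age 20
    rel = res.relative["wildtype"]
    expected = {"SBS1": 0.15, "SBS5": 0.45, "SBS18": 0.10, "HSPC": 0.30}
    for sig, w in expected.items():
        assert rel[sig] == pytest.approx(w, abs=0.08)
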