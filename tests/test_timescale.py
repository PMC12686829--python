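import numpy as np
import pytest

from hsctrace.timescale import (
    TimeScaleConfig,
    convert_to_time,
    coverage_correct,
    scale_ultrametric,
    split_at_birth,
    time_driver_acquisition,
)
from hsctrace.trees import Tree


def lengths(tree):
    return {n.name: n.length for n in tree.preorder()}


def test_coverage_correction_closed_forms():
    tree = Tree.from_newick("((t1:10,t2:30)A:49)root:0;")
    out = coverage_correct(tree, {"t1": 0.8, "t2": 0.9})
    l = lengths(out)
    assert l["t1"] == pytest.approx(10 / 0.8)  # = 12.5
    assert l["A"] == pytest.approx(49 / (1 - 0.1 * 0.2))  # = 50
    ident = coverage_correct(tree, {"t1": 1.0, "t2": 1.0})
    assert lengths(ident) == lengths(tree)


def test_coverage_correction_never_shortens():
    tree = Tree.from_newick("((a:5,b:7)x:11,(c:3,d:9)y:2)root:6;")
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = {t: float(rng.uniform(0.05, 1.0)) for t in "abcd"}
        out = coverage_correct(tree, p)
        assert all(
            lengths(out)[k] >= v - 1e-12 for k, v in lengths(tree).items()
        )


def test_coverage_correction_rejects_zero_p():
    tree = Tree.from_newick("(a:1,b:1)root:0;")
    with pytest.raises(ValueError):
        coverage_correct(tree, {"a": 0.0, "b": 1.0})


def test_split_at_birth_degenerate_and_straddle():
    tree = Tree.from_newick("(t1:20,t2:20)root:80;")
    zero = split_at_birth(tree, 0.0)
    assert zero.prenatal is None and len(zero.postnatal_parts) == 1

    sp = split_at_birth(tree, 60.0)
    assert sp.prenatal.root.length == pytest.approx(60.0)
    assert len(sp.postnatal_parts) == 1
    assert sp.postnatal_parts[0].root.length == pytest.approx(20.0)


def test_split_node_before_cut_is_prenatal():
    # split node at cumulative 55 with birth load 60 lies prenatal
    tree = Tree.from_newick("((t1:100,t2:100)A:55)root:0;")
    sp = split_at_birth(tree, 60.0)
    prenatal_names = {n.name for n in sp.prenatal.preorder()}
    assert "A" in prenatal_names
    assert len(sp.postnatal_parts) == 2  # one per child of A


def test_scale_ultrametric_private_branches_only():
    part = Tree.from_newick("(t1:13,t2:37)root:0;")
    times = scale_ultrametric(part, 10.0)
    assert times["t1"] == pytest.approx(10.0)
    assert times["t2"] == pytest.approx(10.0)
    assert times["root"] == pytest.approx(0.0)


def test_scale_ultrametric_ratio_fixed_point():
    # root -> shared 10 -> tips 20 and 40, target 30:
    # shared branch 7.5 y, terminal branches 22.5 y (7.5/22.5 = 10/30)
    part = Tree.from_newick("((t1:20,t2:40)A:10)root:0;")
    times = scale_ultrametric(part, 30.0)
    assert times["A"] == pytest.approx(7.5)
    assert times["t1"] == pytest.approx(30.0)
    ratio = times["A"] / np.mean([30 - times["A"], 30 - times["A"]])
    assert ratio == pytest.approx(10 / np.mean([20, 40]))


def test_scale_ultrametric_scale_invariance():
    a = Tree.from_newick("(((a:6,b:9)x:4,c:14)y:3)root:2;")
    b = Tree.from_newick("(((a:60,b:90)x:40,c:140)y:30)root:20;")
    ta = scale_ultrametric(a, 12.0)
    tb = scale_ultrametric(b, 12.0)
    for k in ta:
        assert ta[k] == pytest.approx(tb[k])


def test_convert_identity_composition_is_linear():
    # fetal 0, p = 1, birth load 0: a single linear scaling of the input
    tree = Tree.from_newick("((a:10,b:10)x:5,c:15)root:0;")
    cfg = TimeScaleConfig(target_age=30.0, birth_load=0.0)
    tt = convert_to_time(tree, {t: 1.0 for t in "abc"}, 0.0, cfg)
    t = {n.name: n.time for n in tt.tree.preorder()}
    # tips ultrametric at gestation + target
    assert t["a"] == pytest.approx(0.75 + 30.0)
    # node x sits at 5/15 of the postnatal span past the (degenerate) birth point
    assert t["x"] - 0.75 == pytest.approx(30.0 * 5 / 15)


def test_convert_gestation_anchor_and_ultrametricity(driver_analysis):
    params, truth, obs, catalog, matrix, tree, assignment = driver_analysis
    cfg = TimeScaleConfig(target_age=params.hsc_age)
    tt = convert_to_time(tree, catalog.callable_fraction, 6.0, cfg)
    for name, t in tt.tip_times().items():
        assert t == pytest.approx(cfg.gestation_years + params.hsc_age, abs=1e-6)
    assert tt.birth_time == pytest.approx(0.75)
    # nodes rootward of the birth cut are timed within gestation
    corrected = coverage_correct(tree, catalog.callable_fraction)
    for n in corrected.preorder():
        d = corrected.distance_to_root(n)
        t = tt.tree.find(n.name).time
        if d <= cfg.birth_load:
            assert t <= cfg.gestation_years + 1e-9


def test_merge_conservation():
    tree = Tree.from_newick("((a:100,b:120)x:60,c:150)root:10;")
    sp = split_at_birth(tree, 84.0)
    full = {t.name: tree.distance_to_root(t) for t in tree.tips()}
    post = {}
    for part in sp.postnatal_parts:
        for t in part.tips():
            post[t.name] = part.distance_to_root(t)
    for name in full:
        assert post[name] + 84.0 == pytest.approx(full[name])


def test_driver_timing_monotone_in_birth_load(driver_analysis):
    params, truth, obs, catalog, matrix, tree, assignment = driver_analysis
    clone = truth.clone_tips
    estimates = []
    for bl in (52.0, 84.0, 121.0):
        cfg = TimeScaleConfig(target_age=params.hsc_age, birth_load=bl)
        t = time_driver_acquisition(
            tree, catalog.callable_fraction, 6.0, clone, cfg
        )
        estimates.append(t.estimate)
    assert estimates[0] >= estimates[1] >= estimates[2]


def test_driver_timing_interval_ordered_and_contains_estimate(driver_analysis):
    params, truth, obs, catalog, matrix, tree, assignment = driver_analysis
    cfg = TimeScaleConfig(target_age=params.hsc_age)
    t = time_driver_acquisition(
        tree, catalog.callable_fraction, 6.0, truth.clone_tips, cfg
    )
    assert t.interval[0] <= t.estimate <= t.interval[1]


def test_driver_timing_requires_supported_clade(driver_analysis):
    params, truth, obs, catalog, matrix, tree, assignment = driver_analysis
    cfg = TimeScaleConfig(target_age=params.hsc_age)
    with pytest.raises(ValueError):
        # a mixed set of colonies is not a clade
        time_driver_acquisition(
            tree, catalog.callable_fraction, 6.0,
            [truth.clone_tips[0], "WT03"], cfg,
        )


def test_clean_driver_time_recovered_within_half_year(clean_dataset):
    from conftest import analyze

    params, truth, obs = clean_dataset
    catalog, matrix, tree, assignment = analyze(truth, obs, n_boot=30)
    cfg = TimeScaleConfig(
        target_age=params.hsc_age, birth_load=params.birth_load_mean
    )
    fetal = 0.0  # no embryonic sharing in the clean fixture
    t = time_driver_acquisition(
        tree, catalog.callable_fraction, fetal, truth.clone_tips, cfg
    )
    truth_from_birth = params.driver_time - 0.75
    assert abs(t.estimate - truth_from_birth) <= 0.5
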