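import numpy as np
import pandas as pd
import pytest

from hsctrace.filtering import (
    FilterThresholds,
    build_pseudobulk,
    callable_fraction,
    filter_somatic,
)
from hsctrace.regions import AUTOSOMAL_GENOME_SIZE
from hsctrace.variant_table import VariantTable


def make_table(rows, samples):
    """rows: list of (chrom,pos,ref,alt,qual,mq, per-sample (dp,alt,gq))."""
    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4], r[5]) for r in rows],
        columns=["chrom", "pos", "ref", "alt", "qual", "mq"],
    )
    depth = np.array([[t[0] for t in r[6]] for r in rows])
    alt = np.array([[t[1] for t in r[6]] for r in rows])
    gq = np.array([[t[2] for t in r[6]] for r in rows])
    return VariantTable(samples=samples, sites=sites, depth=depth,
                        alt_count=alt, gq=gq)


@pytest.fixture
def toy_table():
    # samples: S (interest), P1, P2 (pseudo-bulk)
    rows = [
        # clean somatic, VAF 0.5
        ("chr1", 100, "C", "T", 500, 60, [(20, 10, 99), (18, 0, 99), (22, 0, 99)]),
        # VAF 0.10 -> fails VAF
        ("chr1", 200, "C", "A", 500, 60, [(20, 2, 99), (18, 0, 99), (22, 0, 99)]),
        # depth 4 -> fails depth
        ("chr1", 300, "T", "C", 500, 60, [(4, 2, 99), (18, 0, 99), (22, 0, 99)]),
        # pseudo-bulk alt 1 -> germline evidence
        ("chr1", 400, "T", "G", 500, 60, [(20, 10, 99), (18, 1, 99), (22, 0, 99)]),
        # clean somatic
        ("chr2", 100, "C", "G", 500, 60, [(15, 7, 99), (18, 0, 99), (22, 0, 99)]),
    ]
    return make_table(rows, ["S", "P1", "P2"])


def test_pseudobulk_sums_member_evidence(toy_table):
    pb = build_pseudobulk(toy_table, ("P1", "P2"))
    assert pb.depth[0] == 40
    assert pb.alt_count[3] == 1
    assert pb.gq[0] == 99


def test_pseudobulk_member_validation(toy_table):
    with pytest.raises(ValueError):
        build_pseudobulk(toy_table, ("P1", "P1"))
    with pytest.raises(KeyError):
        build_pseudobulk(toy_table, ("P1", "nope"))


def test_filter_ladder_hand_evaluated(toy_table):
    pb = build_pseudobulk(toy_table, ("P1", "P2"))
    catalog = filter_somatic(toy_table, pb)
    passed = set(zip(catalog.variants["chrom"], catalog.variants["pos"]))
    assert passed == {("chr1", 100), ("chr2", 100)}
    assert catalog.filter_counts["pass"] == 2
    assert catalog.samples == ["S"]  # pseudo-bulk members excluded


def test_vacuous_thresholds_pass_everything(toy_table):
    pb = build_pseudobulk(toy_table, ("P1", "P2"))
    th = FilterThresholds(min_depth=0, min_site_quality=0,
                          min_mapping_quality=0, min_gq_het=0, min_gq_hom=0,
                          min_vaf=0.0)
    # neutralize the germline rule by zeroing pseudo-bulk alt evidence
    pb.alt_count = np.zeros_like(pb.alt_count)
    catalog = filter_somatic(toy_table, pb, th)
    # every record with an alt call in S passes (all 5 toy records)
    assert catalog.filter_counts["pass"] == 5


def test_germline_excluded_in_every_sample():
    rows = [
        ("chr1", 50, "A", "G", 500, 60,
         [(20, 10, 99), (20, 9, 99), (20, 11, 99), (20, 10, 99)]),
    ]
    table = make_table(rows, ["S1", "S2", "P1", "P2"])
    pb = build_pseudobulk(table, ("P1", "P2"))
    catalog = filter_somatic(table, pb)
    assert len(catalog.variants) == 0


@pytest.mark.parametrize(
    "field,stricter",
    [("min_depth", 10), ("min_site_quality", 600), ("min_vaf", 0.4),
     ("min_mapping_quality", 70)],
)
def test_filter_monotone_in_thresholds(driver_analysis, field, stricter):
    params, truth, obs, catalog, *_ = driver_analysis
    pb = build_pseudobulk(obs.table, catalog.pseudobulk_members)
    base = filter_somatic(obs.table, pb).filter_counts["pass"]
    tight = filter_somatic(
        obs.table, pb, FilterThresholds(**{field: stricter})
    ).filter_counts["pass"]
    assert tight <= base


def test_no_noise_catalog_equals_truth_carriers(clean_dataset):
    """Oracle equivalence: with clean observation conditions the catalog is
    exactly the truth carrier sets of the non-pseudo-bulk colonies."""
    params, truth, obs = clean_dataset
    members = ("WT01", "WT02")
    pb = build_pseudobulk(obs.table, members)
    catalog = filter_somatic(obs.table, pb)
    carriers = truth.carriers()
    expected = set()
    for r in truth.mutations.itertuples():
        for s in carriers[r.id]:
            if s not in members:
                expected.add((s, r.chrom, r.pos))
    observed = set(zip(catalog.variants["sample"], catalog.variants["chrom"],
                       catalog.variants["pos"]))
    assert observed == expected


def test_callable_fraction_interval_arithmetic():
    p = callable_fraction([("chr1", 0, 1_000_000)],
                          [("chr1", 500_000, 1_500_000)])
    assert p == pytest.approx(500_000 / AUTOSOMAL_GENOME_SIZE)


def test_callable_fraction_full_genome_is_one():
    from hsctrace.regions import CHROM_LENGTHS

    full = [(c, 0, l) for c, l in CHROM_LENGTHS.items()]
    assert callable_fraction(full, full) == pytest.approx(1.0)


def test_callable_fraction_disjoint_errors():
    with pytest.raises(ValueError):
        callable_fraction([("chr1", 0, 100)], [("chr1", 200, 300)])
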