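"""Site/genotype hard filters and diallelic SNP extraction."""

import math

import numpy as np
import pytest

from oakscan.variants import (
    Genotype,
    SiteRecord,
    extract_diallelic_snps,
    filter_genotypes,
    filter_sites,
    site_passes,
    ts_tv_ratio,
)

from conftest import make_locus


def passing_record(**overrides):
    info = {
        "AC": (3.0,),
        "BaseQRankSum": 0.0,
        "DP": 20.0,
        "Dels": 0.0,
        "FS": 1.0,
        "HaplotypeScore": 2.0,
        "MQ": 40.0,
        "MQRankSum": 0.0,
        "ReadPosRankSum": 0.0,
        "SB": 0.0,
    }
    qual = overrides.pop("QUAL", 50.0)
    info.update(overrides)
    return SiteRecord(
        contig="c1",
        pos=10,
        ref="A",
        alts=("G",),
        qual=qual,
        info=info,
        genotypes=[Genotype((0, 1), 20, 60)],
    )


# one violation per bound side: 17 distinct single-metric failures
VIOLATIONS = [
    {"QUAL": 10.0},
    {"QUAL": 100000.0},
    {"AC": (0.0,)},
    {"AC": (48.0,)},
    {"BaseQRankSum": -3.5},
    {"BaseQRankSum": 7.0},
    {"DP": 4.0},
    {"Dels": 0.1},
    {"FS": 90.0},
    {"HaplotypeScore": 25.0},
    {"MQ": 19.9},
    {"MQRankSum": -25.0},
    {"MQRankSum": 10.0},
    {"ReadPosRankSum": -3.5},
    {"ReadPosRankSum": 9.0},
    {"SB": 3.0},
    {"SB": 100.0},
]


def test_each_single_bound_violation_is_caught():
    for overrides in VIOLATIONS:
        rec = passing_record(**overrides)
        assert not site_passes(rec, n_individuals=24), overrides
    assert site_passes(passing_record(), n_individuals=24)


def test_site_filter_counts_on_mixed_batch():
    """83 of 100 records survive when exactly 17 violate one bound each."""
    records = [passing_record(**v) for v in VIOLATIONS]
    records += [passing_record() for _ in range(83)]
    surviving = filter_sites(records, n_individuals=24)
    assert len(surviving) == 83


def test_absent_info_metrics_pass():
    rec = passing_record()
    del rec.info["BaseQRankSum"], rec.info["MQRankSum"], rec.info["ReadPosRankSum"]
    assert site_passes(rec, n_individuals=24)


def test_ac_bound_scales_with_sample_size():
    rec = passing_record(AC=(48.0,))
    assert not site_passes(rec, n_individuals=24)
    assert site_passes(rec, n_individuals=30)  # 48 < 60


@pytest.mark.parametrize(
    "dp,gq,expect_called",
    [(150, 99, False), (30, 20, True), (100, 19, False), (100, 20, True)],
)
def test_genotype_filter_boundaries(dp, gq, expect_called):
    rec = passing_record()
    rec.genotypes = [Genotype((0, 1), dp, gq)]
    out = filter_genotypes(rec)
    assert out.genotypes[0].called is expect_called


def test_filters_are_idempotent(small_dataset):
    records = small_dataset.records
    once = filter_sites(records, len(small_dataset.samples))
    twice = filter_sites(once, len(small_dataset.samples))
    assert once == twice
    g_once = [filter_genotypes(r) for r in once]
    g_twice = [filter_genotypes(r) for r in g_once]
    assert g_once == g_twice


def _site(ref, alts, calls):
    return SiteRecord(
        contig="c1",
        pos=5,
        ref=ref,
        alts=alts,
        qual=50.0,
        genotypes=[Genotype(c, 20, 60) for c in calls],
    )


def test_diallelic_extraction_rules():
    samples = ("a", "b")
    # plain ref/alt site
    snps = extract_diallelic_snps([_site("A", ("G",), [(0, 0), (0, 1)])], samples)
    assert len(snps) == 1 and (snps[0].ref, snps[0].var) == ("A", "G")
    # triallelic record whose third allele survives in no called genotype
    snps = extract_diallelic_snps([_site("A", ("G", "T"), [(0, 0), (0, 1)])], samples)
    assert len(snps) == 1 and snps[0].var == "G"
    # reference not represented among surviving genotypes -> excluded
    snps = extract_diallelic_snps([_site("A", ("G",), [(1, 1), (1, 1)])], samples)
    assert snps == []
    # only reference represented -> not diallelic
    snps = extract_diallelic_snps([_site("A", ("G",), [(0, 0), (0, 0)])], samples)
    assert snps == []
    # uncalled genotypes do not contribute represented alleles
    snps = extract_diallelic_snps(
        [_site("A", ("G", "T"), [(0, 1), None, (0, 0)])], samples + ("c",)
    )
    assert len(snps) == 1 and snps[0].var == "G"


def test_extraction_is_order_invariant(small_dataset):
    records = [r for r in small_dataset.records][:200]
    samples = small_dataset.samples
    fwd = extract_diallelic_snps(records, samples)
    rev = extract_diallelic_snps(list(reversed(records)), samples)
    key = lambda s: (s.contig, s.pos)
    assert sorted((key(s) for s in fwd)) == sorted((key(s) for s in rev))


def test_snp_locus_invariants_enforced():
    with pytest.raises(ValueError):
        make_locus([0, 1], ref="AA", var="G")
    with pytest.raises(ValueError):
        make_locus([0, 0], ref="A", var="A")
    # all-hom-var vector cannot represent the reference allele
    with pytest.raises(ValueError):
        make_locus([2, 2])


def test_ts_tv_ratio_counts():
    loci = [
        make_locus([0, 1], "A", "G"),
        make_locus([0, 1], "C", "T"),
        make_locus([0, 1], "A", "C"),
        make_locus([0, 1], "G", "T"),
    ]
    assert ts_tv_ratio(loci) == 1.0
    assert ts_tv_ratio([loci[0], loci[0], make_locus([0, 1], "A", "T")]) == 2.0
    assert math.isinf(ts_tv_ratio([loci[0]]))
    with pytest.raises(ValueError):
        ts_tv_ratio([])


def test_ts_tv_converges_to_kappa_expectation(dense_dataset):
    """Emitted ts:tv ratio matches kappa/2 within 3 SE at ~10^4 sites."""
    import oakscan as ok

    snps = ok.filtered_snps(dense_dataset.records, dense_dataset.samples)
    assert len(snps) > 8000
    ts = sum(1 for s in snps if s.is_transition)
    n = len(snps)
    kappa = dense_dataset.config.kappa
    p_expected = kappa / (kappa + 2.0)
    se = math.sqrt(p_expected * (1 - p_expected) / n)
    assert abs(ts / n - p_expected) < 3 * se
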