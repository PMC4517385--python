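"""PBL dN/dS estimator: degeneracy, K2P components, haplotypes, summaries."""

import math

import numpy as np
import pytest

import oakscan as ok
from oakscan._codons import AMBIG, encode
from oakscan.genes import GeneModel
from oakscan.molevol import (
    CalibrationError,
    build_haplotypes,
    calibrate_tails,
    codon_degeneracy,
    compare_to_outgroup,
    count_substitutions,
    k2p_components,
    pbl_rates,
    summarize_gene,
    synonymous_site_count,
)

from _oracles import pbl_oracle
from conftest import make_locus


@pytest.mark.parametrize(
    "codon,pos,expect",
    [("GGA", 3, 4), ("ATG", 3, 0), ("GAT", 3, 2), ("CTA", 1, 2), ("AAA", 1, 0)],
)
def test_codon_degeneracy_classes(codon, pos, expect):
    assert codon_degeneracy(codon, pos) == expect


def test_degeneracy_rejects_stops_and_bad_input():
    with pytest.raises(ValueError):
        codon_degeneracy("TAA", 3)
    with pytest.raises(ValueError):
        codon_degeneracy("GAN", 1)
    with pytest.raises(ValueError):
        codon_degeneracy("GAT", 4)


def test_k2p_closed_form_values():
    assert k2p_components(0.0, 0.0) == (0.0, 0.0)
    A, B = k2p_components(0.1, 0.05)
    assert A == pytest.approx(0.117501, abs=1e-6)
    assert B == pytest.approx(0.052680, abs=1e-6)
    A, B = k2p_components(0.45, 0.1)  # 1-2P-Q = 0: undefined
    assert math.isnan(A) and math.isnan(B)


def test_count_substitutions_single_codon():
    c = count_substitutions("GAT", "GAC")
    # positions 1,2 are 0-fold, position 3 is 2-fold in both codons
    assert c.L == {0: 2.0, 2: 1.0, 4: 0.0}
    assert c.ts[2] == 1.0 and c.n_diff == 1
    assert c.P(2) == 1.0


def test_ambiguous_or_stop_columns_are_excluded():
    c = count_substitutions("AATGGA", "NATGGA")
    assert c.n_codons == 1 and c.n_diff == 0
    assert sum(c.L.values()) == 3.0
    c = count_substitutions("TAAGGA", "TACGGA")  # first column contains a stop
    assert c.n_codons == 1 and c.n_diff == 0


def test_count_substitutions_is_symmetric(dense_dataset):
    rng = np.random.default_rng(0)
    bases = "ACGT"
    s1 = "".join(rng.choice(list(bases), 300))
    s2 = "".join(rng.choice(list(bases), 300))
    a, b = count_substitutions(s1, s2), count_substitutions(s2, s1)
    assert a.L == b.L and a.ts == b.ts and a.tv == b.tv


def _random_pair(rng, n_codons=300, n_subs=25):
    sense = [c for c in ok.simulate._SENSE_CODONS]
    idx = rng.integers(0, len(sense), n_codons)
    s1 = "".join(sense[i] for i in idx)
    s2 = list(s1)
    pos = rng.choice(len(s2), size=n_subs, replace=False)
    for p in pos:
        s2[p] = rng.choice([b for b in "ACGT" if b != s2[p]])
    return s1, "".join(s2)


def test_pbl_matches_independent_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(30):
        s1, s2 = _random_pair(rng)
        est = pbl_rates(count_substitutions(s1, s2))
        if not est.valid:
            continue
        dn, ds = pbl_oracle(s1, s2)
        assert est.dn == pytest.approx(dn, abs=1e-10)
        assert est.ds == pytest.approx(ds, abs=1e-10)
        checked += 1
    assert checked >= 25


def test_monotonicity_of_rates():
    """An extra nonsynonymous (synonymous) difference never lowers dN (dS)."""
    # ATG AAA GGA x20: AAA pos1 is 0-fold, GGA pos3 is 4-fold
    s1 = ("ATG" + "AAA" + "GGA") * 20
    s2 = list(s1)
    prev_dn = prev_ds = 0.0
    for k in range(8):
        s2[9 * k + 3] = "G"  # AAA -> GAA, nonsynonymous transition
        est = pbl_rates(count_substitutions(s1, "".join(s2)))
        assert est.dn >= prev_dn
        prev_dn = est.dn
    for k in range(8):
        s2[9 * k + 8] = "G"  # GGA -> GGG, synonymous transition
        est = pbl_rates(count_substitutions(s1, "".join(s2)))
        assert est.ds >= prev_ds
        prev_ds = est.ds


def test_sentinel_rules():
    s1 = ("ATG" + "AAA" + "GGA") * 30
    only_nonsyn = list(s1)
    for k in range(8):
        only_nonsyn[9 * k + 3] = "G"
    est = pbl_rates(count_substitutions(s1, "".join(only_nonsyn)))
    assert est.qualifying and est.ds == 0.0 and est.ratio == 10.0
    only_syn = list(s1)
    for k in range(8):
        only_syn[9 * k + 8] = "G"
    est = pbl_rates(count_substitutions(s1, "".join(only_syn)))
    assert est.qualifying and est.dn == 0.0 and est.ratio == 0.0


def test_six_substitution_qualifying_rule():
    s1 = ("ATG" + "AAA" + "GGA") * 30
    s2 = list(s1)
    for k in range(5):
        s2[9 * k + 3] = "G"
    assert not pbl_rates(count_substitutions(s1, "".join(s2))).qualifying
    s2[9 * 5 + 3] = "G"
    assert pbl_rates(count_substitutions(s1, "".join(s2))).qualifying


# --- haplotype construction -------------------------------------------------

CONTIG = "T" * 10 + "ATGGATAAAGGACCTTAA" + "C" * 10  # 18 nt CDS at 10..28


def _model(**kw):
    defaults = dict(gene_id="g", contig="c", strand="+", cds=((10, 28),))
    defaults.update(kw)
    return GeneModel(**defaults)


def test_haplotypes_of_hom_ref_individual_equal_cds():
    m = _model()
    a, b = build_haplotypes(m, [], 0, CONTIG)
    assert (a == encode("ATGGATAAAGGACCTTAA")).all()
    assert (a == b).all()


def test_het_uncalled_and_homvar_placement():
    m = _model()
    # locus at contig pos 13 (CDS position 3, first base of GAT)
    het = make_locus([1, 2, -1], ref="G", var="A", contig="c", pos=14)
    a, b = build_haplotypes(m, [het], 0, CONTIG)
    assert a[3] == encode("G")[0] and b[3] == encode("A")[0]
    a, b = build_haplotypes(m, [het], 1, CONTIG)
    assert a[3] == b[3] == encode("A")[0]
    a, b = build_haplotypes(m, [het], 2, CONTIG)
    assert a[3] == b[3] == AMBIG


def test_partial_cds_padded_to_codon_boundary():
    m = _model(cds=((10, 17),), has_start=False, has_stop=False)  # 7 nt
    a, b = build_haplotypes(m, [], 0, CONTIG)
    assert len(a) == 9 and len(b) == 9
    assert (a[-2:] == AMBIG).all()


def test_phase_offset_pads_leading_partial_codon():
    m = _model(cds=((11, 28),), has_start=False, phase=2)  # 17 nt, 2 lead-in
    a, _ = build_haplotypes(m, [], 0, CONTIG)
    assert len(a) % 3 == 0
    assert (a[:1] == AMBIG).all()


def test_inconsistent_snp_reference_raises():
    m = _model()
    bad = make_locus([1], ref="C", var="A", contig="c", pos=14)
    with pytest.raises(ValueError):
        build_haplotypes(m, [bad], 0, CONTIG)


def test_outgroup_comparison_counts_het_site_in_two_of_four_pairings():
    m = _model()
    het = make_locus([1, 0], ref="G", var="A", contig="c", pos=14)
    ind = build_haplotypes(m, [het], 0, CONTIG)
    outg = build_haplotypes(m, [het], 1, CONTIG)
    est = compare_to_outgroup(ind, outg, min_substitutions=0)
    assert est.n_diff == 2
    # phase swap leaves the estimate unchanged
    est_swapped = compare_to_outgroup((ind[1], ind[0]), outg, min_substitutions=0)
    assert est_swapped.dn == est.dn and est_swapped.ds == est.ds


def test_homozygous_pair_equals_single_comparison():
    m = _model()
    hom = make_locus([2, 0], ref="G", var="A", contig="c", pos=14)
    ind = build_haplotypes(m, [hom], 0, CONTIG)
    outg = build_haplotypes(m, [hom], 1, CONTIG)
    four = compare_to_outgroup(ind, outg, min_substitutions=0)
    single = pbl_rates(count_substitutions(ind[0], outg[0]), min_substitutions=0)
    assert four.dn == pytest.approx(single.dn)
    assert four.ds == pytest.approx(single.ds)


# --- summaries and calibration ----------------------------------------------

def test_geometric_mean_summaries():
    assert summarize_gene([0.5, 2.0]) == pytest.approx(1.0)
    assert summarize_gene([0.7]) == pytest.approx(0.7)
    assert summarize_gene([0.2] * 22) == pytest.approx(0.2)
    # zeros are floored, high sentinel enters as-is
    assert summarize_gene([0.0, 4.0]) == pytest.approx(math.sqrt(2.0 ** -10 * 4.0))
    with pytest.raises(ValueError):
        summarize_gene([])


def test_tail_calibration_recovers_parameters_and_threshold():
    rng = np.random.default_rng(1)
    mu, sigma = -2.2, 1.0
    ratios = 2.0 ** rng.normal(mu, sigma, 10000)
    cal = calibrate_tails(ratios)
    assert cal.mu == pytest.approx(mu, abs=0.05)
    assert cal.sigma == pytest.approx(sigma, abs=0.05)
    z95 = 1.6449
    assert cal.threshold(0.05) == pytest.approx(
        2.0 ** (cal.mu + cal.sigma * z95), rel=1e-4
    )
    assert cal.threshold(0.05) < cal.threshold(0.01)
    assert 0 < cal.upper_tail_prob(1.0) < cal.upper_tail_prob(0.5)


def test_degenerate_calibration_fails():
    with pytest.raises(CalibrationError):
        calibrate_tails([0.25] * 100)
    with pytest.raises(CalibrationError):
        calibrate_tails([0.5] * 10)  # too few values


def test_synonymous_site_count():
    # GGA: pos3 4-fold (pos1 is 0-fold: TGA is a stop); GAT: pos3 2-fold
    assert synonymous_site_count("GGA") == pytest.approx(1.0)
    assert synonymous_site_count("ATG") == pytest.approx(0.0)
    assert synonymous_site_count("GAT") == pytest.approx(1.0 / 3.0)
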