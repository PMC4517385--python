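"""Run decomposition, quintuple counting and candidate-locus VCF formation."""

import numpy as np
import pytest

from oakscan.alleles import (
    Alignment,
    AlignmentRun,
    DELETE,
    INSERT,
    MISMATCH,
    count_and_threshold,
    decompose_alignment,
    prefilter_alignments,
    quintuples_to_vcf,
    read_sam,
)
from oakscan.formats import write_sam
from oakscan.simulate import simulate_alignments

REF = "ACGTACGTACGTACGTACGTACGTACGTACGT"  # 32 nt


def aln(seq, pos=0, cigar=None, flag=0, mapq=60):
    cigar = cigar or [("M", len(seq))]
    return Alignment("r1", flag, "c", pos, mapq, cigar, seq)


def test_prefilter_mapq_and_flag_mask():
    good = aln(REF[:10])
    assert prefilter_alignments([good]) == [good]
    assert prefilter_alignments([aln(REF[:10], mapq=19)]) == []
    assert prefilter_alignments([aln(REF[:10], flag=0x100)]) == []
    assert prefilter_alignments([aln(REF[:10], flag=0x400)]) == []
    kept = prefilter_alignments([aln(REF[:10], flag=0x63, mapq=42)])
    assert len(kept) == 1  # 0x63 & 0x704 == 0


def test_perfect_match_decomposes_to_nothing():
    assert decompose_alignment(aln(REF[:12]), REF) == []


def test_adjacent_mismatches_coalesce():
    seq = list(REF[:12])
    seq[4], seq[5] = "G", "T"  # ref 'AC' -> 'GT'
    runs = decompose_alignment(aln("".join(seq)), REF)
    assert runs == [AlignmentRun(MISMATCH, "c", 4, "AC", "GT")]


def test_separated_mismatches_stay_separate():
    seq = list(REF[:12])
    seq[2] = "T" if REF[2] != "T" else "A"
    seq[7] = "C" if REF[7] != "C" else "A"
    runs = decompose_alignment(aln("".join(seq)), REF)
    assert len(runs) == 2


def test_insertion_run_has_empty_reference():
    # 2-nt insertion between ref positions 19 and 20 (0-based)
    seq = REF[10:20] + "CC" + REF[20:26]
    a = aln(seq, pos=10, cigar=[("M", 10), ("I", 2), ("M", 6)])
    runs = decompose_alignment(a, REF)
    assert runs == [AlignmentRun(INSERT, "c", 20, "", "CC")]


def test_deletion_run_has_empty_read():
    seq = REF[4:10] + REF[12:18]
    a = aln(seq, pos=4, cigar=[("M", 6), ("D", 2), ("M", 6)])
    runs = decompose_alignment(a, REF)
    assert runs == [AlignmentRun(DELETE, "c", 10, REF[10:12], "")]


def test_soft_clips_are_excluded_from_runs():
    seq = "NNN" + REF[6:14]
    a = aln(seq, pos=6, cigar=[("S", 3), ("M", 8)])
    assert decompose_alignment(a, REF) == []


def test_cigar_sequence_length_mismatch_rejected():
    with pytest.raises(ValueError):
        decompose_alignment(aln(REF[:10], cigar=[("M", 12)]), REF)


def _rebuild(read_runs, pos, ref, read_len):
    """Reconstruct (seq, cigar) from reference plus runs for the round trip."""
    seq = []
    cigar = []
    rpos = pos
    consumed = 0
    for run in sorted(read_runs, key=lambda r: r.pos):
        gap = run.pos - rpos
        if gap:
            seq.append(ref[rpos : rpos + gap])
            cigar.append(("M", gap))
            consumed += gap
        if run.run_type == MISMATCH:
            seq.append(run.read)
            cigar.append(("M", len(run.read)))
            rpos = run.pos + len(run.ref)
            consumed += len(run.read)
        elif run.run_type == INSERT:
            seq.append(run.read)
            cigar.append(("I", len(run.read)))
            rpos = run.pos
            consumed += len(run.read)
        else:
            cigar.append(("D", len(run.ref)))
            rpos = run.pos + len(run.ref)
    tail = read_len - consumed
    if tail > 0:
        seq.append(ref[rpos : rpos + tail])
        cigar.append(("M", tail))
    return "".join(seq), cigar


def test_decomposition_round_trip():
    rng = np.random.default_rng(12)
    ref = "".join(rng.choice(list("ACGT"), 200))
    cases = [
        [AlignmentRun(MISMATCH, "c", 30, ref[30], "A" if ref[30] != "A" else "C")],
        [AlignmentRun(INSERT, "c", 45, "", "TTG")],
        [AlignmentRun(DELETE, "c", 60, ref[60:63], "")],
        [
            AlignmentRun(
                MISMATCH, "c", 25, ref[25:27],
                "".join("A" if b != "A" else "C" for b in ref[25:27]),
            ),
            AlignmentRun(DELETE, "c", 40, ref[40:42], ""),
        ],
    ]
    for runs in cases:
        runs = [r for r in runs if r.ref != r.read]
        seq, cigar = _rebuild(runs, 20, ref, 50)
        again = decompose_alignment(Alignment("r", 0, "c", 20, 60, cigar, seq), ref)
        assert again == sorted(runs, key=lambda r: r.pos)


def test_count_threshold_and_iupac_exclusion():
    mm = AlignmentRun(MISMATCH, "c", 4, "A", "G")
    ambig = AlignmentRun(MISMATCH, "c", 8, "AC", "GN")
    runs = [mm] * 5 + [AlignmentRun(MISMATCH, "c", 6, "G", "T")] * 4 + [ambig] * 9
    kept = count_and_threshold(runs)
    assert len(kept) == 1
    assert kept[0].run == mm and kept[0].count == 5


def test_counting_is_order_independent():
    rng = np.random.default_rng(13)
    runs = [AlignmentRun(MISMATCH, "c", int(p), "A", "G") for p in rng.integers(0, 5, 40)]
    a = count_and_threshold(runs)
    b = count_and_threshold(list(reversed(runs)))
    assert a == b


def test_vcf_conversion_basic_events():
    contig = {"c": REF}
    # mismatch at 0-based 99 -> POS=100 in the spec's 1-based terms;
    # here use 0-based 9 -> POS 10
    mm = quintuples_to_vcf(
        count_and_threshold([AlignmentRun(MISMATCH, "c", 9, REF[9], "A")] * 5), contig
    )
    assert mm == [("c", 10, REF[9], ("A",))]
    ins = quintuples_to_vcf(
        count_and_threshold([AlignmentRun(INSERT, "c", 10, "", "CC")] * 5), contig
    )
    assert ins == [("c", 10, REF[9], (REF[9] + "CC",))]


def test_overlapping_chain_merges_with_rewritten_alleles():
    """A deletion at 1-based 98-99 grown upstream meets a mismatch at 100:
    one record whose REF spans 97-100 and carries both rewritten alleles."""
    ref = "".join(np.random.default_rng(14).choice(list("ACGT"), 120))
    contig = {"c": ref}
    dele = AlignmentRun(DELETE, "c", 97, ref[97:99], "")  # 0-based 97..99
    alt_base = "A" if ref[99] != "A" else "G"
    mism = AlignmentRun(MISMATCH, "c", 99, ref[99], alt_base)
    records = quintuples_to_vcf(count_and_threshold([dele] * 5 + [mism] * 6), contig)
    assert len(records) == 1
    c, pos, span_ref, alts = records[0]
    assert pos == 97 and span_ref == ref[96:100]
    expected = {ref[96] + ref[99], ref[96:99] + alt_base}
    assert set(alts) == expected


def test_merged_records_do_not_overlap():
    rng = np.random.default_rng(15)
    ref = "".join(rng.choice(list("ACGT"), 400))
    runs = []
    for p in rng.integers(1, 390, 25):
        p = int(p)
        runs.extend([AlignmentRun(MISMATCH, "c", p, ref[p], "A" if ref[p] != "A" else "C")] * 5)
        runs.extend([AlignmentRun(DELETE, "c", p + 1, ref[p + 1 : p + 3], "")] * 5)
    records = quintuples_to_vcf(count_and_threshold(runs), {"c": ref})
    spans = sorted((pos - 1, pos - 1 + len(r)) for _, pos, r, _ in records)
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        assert s1 >= e0


def test_sam_fixture_respects_count_threshold(tmp_path):
    """Planted events supported 7x survive discovery; 4x are dropped; the
    decoy reads (low MAPQ / secondary) are removed by the prefilter."""
    rng = np.random.default_rng(16)
    ref = "".join(rng.choice(list("ACGT"), 300))
    ev7 = AlignmentRun(MISMATCH, "c1", 100, ref[100], "A" if ref[100] != "A" else "T")
    ev4 = AlignmentRun(MISMATCH, "c1", 200, ref[200], "G" if ref[200] != "G" else "T")
    reads = simulate_alignments("c1", ref, [ev7], depth=7, rng=rng)
    reads += simulate_alignments("c1", ref, [ev4], depth=4, rng=rng)
    path = tmp_path / "reads.sam"
    write_sam(
        path,
        {"c1": len(ref)},
        [
            (a.qname, a.flag, a.contig, a.pos + 1, a.mapq,
             "".join(f"{n}{op}" for op, n in a.cigar), a.seq)
            for a in reads
        ],
    )
    parsed = read_sam(str(path))
    assert len(parsed) == len(reads)
    kept = prefilter_alignments(parsed)
    assert len(kept) == len(parsed) - 4  # two decoys per event
    runs = []
    for a in kept:
        runs.extend(decompose_alignment(a, ref))
    quintuples = count_and_threshold(runs)
    assert [q.run for q in quintuples] == [ev7]
    assert quintuples[0].count == 7
    with pytest.raises(ValueError):
        simulate_alignments("c1", ref, [ev7], depth=0)
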