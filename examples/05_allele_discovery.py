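"""Tentative allele discovery from read alignments.

Plants a mismatch supported by 7 reads and another by only 4, decomposes
the alignments into runs, counts quintuples and shows that only events
seen at least 5 times become candidate VCF loci.
"""

import numpy as np

from oakscan.alleles import (
    AlignmentRun,
    MISMATCH,
    count_and_threshold,
    decompose_alignment,
    prefilter_alignments,
    quintuples_to_vcf,
)
from oakscan.simulate import simulate_alignments

rng = np.random.default_rng(3)
ref = "".join(rng.choice(list("ACGT"), 400))
strong = AlignmentRun(MISMATCH, "ctg1", 120, ref[120], "A" if ref[120] != "A" else "T")
weak = AlignmentRun(MISMATCH, "ctg1", 250, ref[250], "G" if ref[250] != "G" else "C")

reads = simulate_alignments("ctg1", ref, [strong], depth=7, rng=rng)
reads += simulate_alignments("ctg1", ref, [weak], depth=4, rng=rng)
print(f"simulated reads (incl. low-MAPQ/secondary decoys): {len(reads)}")

kept = prefilter_alignments(reads)
print(f"pass MAPQ >= 20 and FLAG & 0x704 == 0           : {len(kept)}")

runs = [r for a in kept for r in decompose_alignment(a, ref)]
quintuples = count_and_threshold(runs)
for q in quintuples:
    print(f"retained quintuple at {q.run.pos}: {q.run.ref}->{q.run.read} "
          f"seen {q.count}x")

for contig, pos, refseq, alts in quintuples_to_vcf(quintuples, {"ctg1": ref}):
    print(f"candidate locus {contig}:{pos} REF={refseq} ALT={','.join(alts)}")

# Only the 7x event survives the >= 5 threshold; the 4x event and the
# decoy alignments are filtered before counting.
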