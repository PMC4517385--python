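"""Reciprocal-best-hit orthologs from bidirectional protein hit tables.

Two small hit tables (A->B and B->A) are reduced per query and per
subject to hits within 99% of the top bitscore, then turned into a
bipartite graph in which only vertices with one outgoing arc survive.
"""

import pandas as pd

from oakscan.orthologs import reciprocal_unique_pairs, two_stage_99pct_filter

cols = ["query", "subject", "bitscore"]
ab = pd.DataFrame(
    [
        ("oak1", "AT1G01010.1", 310.0),
        ("oak1", "AT1G01010.2", 308.5),   # isoform of the same locus
        ("oak2", "AT2G02020.1", 150.0),
        ("oak2", "AT3G03030.1", 149.5),   # ambiguous: two near-top hits
        ("oak3", "AT4G04040.1", 95.0),
    ],
    columns=cols,
)
ba = pd.DataFrame(
    [
        ("AT1G01010.1", "oak1", 305.0),
        ("AT2G02020.1", "oak2", 148.0),
        ("AT4G04040.1", "oak5", 90.0),    # points elsewhere: not reciprocal
    ],
    columns=cols,
)

pairs = reciprocal_unique_pairs(
    two_stage_99pct_filter(ab), two_stage_99pct_filter(ba)
)
for a, b in pairs:
    print(f"ortholog pair: {a} <-> {b}")
print(f"{len(pairs)} one-to-one pair(s)")

# oak1/AT1G01010 survives (isoforms collapse to one vertex); oak2 is
# dropped for having two outgoing arcs after the 99% reduction; oak3 is
# not reciprocated.
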