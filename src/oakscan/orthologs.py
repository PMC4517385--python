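"""Reciprocal-best-hit ortholog calling over precomputed protein hit tables.

Directed hit tables (query, subject, bitscore) from alignments in both
directions are reduced in two stages — per query, then per subject, each
keeping only hits within 99% of the relevant top bitscore — and turned
into a bipartite digraph.  Vertices with out-degree other than one are
removed; reciprocal arcs among the survivors are the putative one-to-one
ortholog pairs.  Splice-variant suffixes are collapsed before graph
construction so isoforms of one locus count as one vertex.
"""

from __future__ import annotations

import re
from typing import Sequence

import pandas as pd

__all__ = [
    "two_stage_99pct_filter",
    "reciprocal_unique_pairs",
    "collapse_splice_variants",
    "read_hit_table",
]

# TAIR-style isoform suffix, e.g. AT1G01010.2 -> AT1G01010
DEFAULT_VARIANT_REGEX = r"\.\d+$"


def read_hit_table(path: str) -> pd.DataFrame:
    """Read a (query, subject, bitscore) TSV, tolerating extra columns in
    aligner tabular output (query/subject first, bitscore last)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        df.columns = ["query", "subject", "bitscore"]
    else:  # blast -outfmt 6: qseqid sseqid ... bitscore
        df = df.iloc[:, [0, 1, df.shape[1] - 1]]
        df.columns = ["query", "subject", "bitscore"]
    df["bitscore"] = df["bitscore"].astype(float)
    return df


def _collapse_duplicates(hits: pd.DataFrame) -> pd.DataFrame:
    return (
        hits.groupby(["query", "subject"], as_index=False)["bitscore"].max()
    )


def two_stage_99pct_filter(hits: pd.DataFrame, fraction: float = 0.99) -> pd.DataFrame:
    """Keep hits within ``fraction`` of the top bitscore, per query then
    per subject (subject-stage tops computed on the query-stage
    survivors).  The boundary is inclusive (>=)."""
    if hits.empty:
        raise ValueError("empty hit table")
    hits = _collapse_duplicates(hits)
    top_q = hits.groupby("query")["bitscore"].transform("max")
    hits = hits[hits["bitscore"] >= fraction * top_q]
    top_s = hits.groupby("subject")["bitscore"].transform("max")
    hits = hits[hits["bitscore"] >= fraction * top_s]
    return hits.reset_index(drop=True)


def collapse_splice_variants(
    hits: pd.DataFrame, variant_regex: str | None = DEFAULT_VARIANT_REGEX
) -> pd.DataFrame:
    """Strip isoform suffixes from both id columns and re-collapse."""
    if variant_regex is None:
        return _collapse_duplicates(hits)
    pat = re.compile(variant_regex)
    out = hits.copy()
    out["query"] = out["query"].map(lambda s: pat.sub("", s))
    out["subject"] = out["subject"].map(lambda s: pat.sub("", s))
    return _collapse_duplicates(out)


def reciprocal_unique_pairs(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    variant_regex: str | None = DEFAULT_VARIANT_REGEX,
) -> list[tuple[str, str]]:
    """One-to-one ortholog pairs from filtered A->B and B->A hit tables.

    Both tables should already be reduced by
    :func:`two_stage_99pct_filter`.  After splice-variant collapsing and
    parallel-arc merging, only vertices with exactly one outgoing arc
    survive; pairs (a, b) with a->b and b->a are returned sorted by the
    A-side id.
    """
    ab = collapse_splice_variants(hits_ab, variant_regex)
    ba = collapse_splice_variants(hits_ba, variant_regex)
    out_a = ab.groupby("query")["subject"].agg(["nunique", "first"])
    out_b = ba.groupby("query")["subject"].agg(["nunique", "first"])
    arc_a = {q: row["first"] for q, row in out_a[out_a["nunique"] == 1].iterrows()}
    arc_b = {q: row["first"] for q, row in out_b[out_b["nunique"] == 1].iterrows()}
    pairs = [
        (a, b) for a, b in arc_a.items() if arc_b.get(b) == a
    ]
    return sorted(pairs)


def pairs_to_frame(pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(pairs, columns=["id_a", "id_b"])
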