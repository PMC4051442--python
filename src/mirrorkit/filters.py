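"""Context filters: expression-restricted backgrounds and score quantile cuts.

Enrichment probabilities depend strongly on the background size N.  When an
experiment comes from a particular tissue or cell line, genes that are not
expressed there cannot be regulated there, so both the candidate edges and
the background are restricted to the expressed gene set before testing.
Two further cuts narrow the search: keeping only the top-expressed fraction
of genes, and keeping only the top fraction of each database's edges by its
native confidence score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .exceptions import EmptyBackgroundError, MDBFormatError
from .mdb import MDBTable

#: Score-fraction cuts offered by the tool.
ALLOWED_SCORE_FRACTIONS = (0.10, 0.25, 0.50, 1.00)


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-context (tissue / cell line) expression levels.

    A gene counts as expressed when its value exceeds ``presence_cutoff``
    (default 0: any positive signal).
    """

    context_id: str
    values: Mapping[str, float]
    presence_cutoff: float = 0.0

    @property
    def expressed(self) -> frozenset:
        return frozenset(
            g for g, v in self.values.items() if v > self.presence_cutoff
        )


def load_expression(path, presence_cutoff: float = 0.0) -> dict:
    """Read profiles from TSV (gene_id, context_id, value) -> {context: profile}."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "context_id": str})
    for col in ("gene_id", "context_id", "value"):
        if col not in df.columns:
            raise MDBFormatError(f"expression table {path}: missing column {col!r}")
    profiles = {}
    for ctx, sub in df.groupby("context_id", sort=True):
        profiles[str(ctx)] = ExpressionProfile(
            context_id=str(ctx),
            values=dict(zip(sub["gene_id"], sub["value"].astype(float))),
            presence_cutoff=presence_cutoff,
        )
    return profiles


def restrict_to_gene_set(mdb: MDBTable, genes: frozenset) -> MDBTable:
    """Drop edges whose gene is outside ``genes``; backgrounds recompute."""
    kept = mdb.edges[mdb.edges["gene"].isin(genes)]
    if len(kept) == 0:
        raise EmptyBackgroundError(
            f"MDB {mdb.mdb_id!r}: no gene left after restriction"
        )
    return MDBTable.from_edges(mdb.mdb_id, kept)


def restrict_to_context(mdb: MDBTable, profile: ExpressionProfile) -> MDBTable:
    """Keep only edges to genes expressed in the context.

    The returned table recomputes its distinct-gene count, so every
    downstream background N reflects the genes that actually express in
    the tissue or cell line.
    """
    if not profile.values:
        raise EmptyBackgroundError(f"profile {profile.context_id!r} is empty")
    return restrict_to_gene_set(mdb, profile.expressed)


def top_expressed(profile: ExpressionProfile, fraction: float = 0.30) -> frozenset:
    """The highest-expressed genes: count = ceil(fraction * n_genes).

    Ties at the cut are admitted in id-lexicographic order up to the count,
    keeping the selection deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    genes = sorted(profile.values, key=lambda g: (-profile.values[g], g))
    count = math.ceil(fraction * len(genes))
    return frozenset(genes[:count])


def filter_by_score_fraction(mdb: MDBTable, fraction: float) -> MDBTable:
    """Keep the top-scoring fraction of edges by the MDB's native score.

    Databases without scores pass through unchanged with a warning — not
    every predictor publishes a confidence value.  Edge count kept is
    ceil(fraction * n_edges); ties break deterministically by (miRNA, gene).
    """
    if not any(math.isclose(fraction, f) for f in ALLOWED_SCORE_FRACTIONS):
        raise ValueError(
            f"fraction must be one of {ALLOWED_SCORE_FRACTIONS}, got {fraction}"
        )
    if math.isclose(fraction, 1.0):
        return mdb
    if not mdb.has_scores:
        warnings.warn(
            f"MDB {mdb.mdb_id!r} has no native scores; score-fraction filter skipped"
        )
        return mdb
    count = math.ceil(fraction * mdb.n_edges)
    ranked = mdb.edges.sort_values(
        ["score", "mirna", "gene"],
        ascending=[False, True, True],
        kind="mergesort",
        na_position="last",
    )
    return MDBTable.from_edges(mdb.mdb_id, ranked.head(count))
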