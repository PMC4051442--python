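"""Hypergeometric multi-database enrichment and miRIS scoring.

The core statistic: given a query set (regulated genes, or profiled miRNAs),
each candidate molecule on the opposite side of the bipartite prediction
graph is tested per database with an exact upper-tail hypergeometric
probability — the chance of drawing at least the observed number of query
hits among the candidate's predicted partners, from that database's own
background.  Candidates are then required to be significant (after
Benjamini-Hochberg FDR, applied within each database) in a minimum number
of databases and to cover a minimum number of query members.

Survivors are ranked by miRIS, an equal-weight combination of (i) the
fraction of the selected databases supporting the candidate and (ii) the
fraction of the analyzed input it hits.  With the default requirement of
two supporting databases out of ten selected, miRIS always exceeds 0.1.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mdb import MDBTable, QuerySet


class Direction(str, enum.Enum):
    """Which side of the bipartite graph the query lives on."""

    GENE2MIR = "gene2mir"  # genes in, explaining miRNAs out
    MIR2GENE = "mir2gene"  # miRNAs in, jointly targeted genes out


@dataclass(frozen=True)
class EnrichmentParams:
    """Search thresholds; defaults mirror the tool's standard protocol."""

    p_threshold: float = 0.05
    min_mdbs: int = 2
    min_hits: int = 2
    min_miris: float = 0.0
    selected_mdbs: frozenset | None = None
    fdr_enabled: bool = True

    def __post_init__(self):
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.min_mdbs < 1 or self.min_hits < 1:
            raise ValueError("min_mdbs and min_hits must be >= 1")
        if not (0.0 <= self.min_miris <= 1.0):
            raise ValueError("min_miris must be in [0, 1]")


@dataclass(frozen=True)
class MdbCandidateStat:
    """One candidate's test in one database.

    k query hits among the candidate's K partners; n query members present
    in this database; N the database background (genes for Gene2miR, miRNAs
    for miR2Gene).
    """

    mdb_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float | None = None
    hits: frozenset = frozenset()
    n_sites_total: int | None = None


@dataclass(frozen=True)
class EnrichmentResult:
    candidate_id: str
    direction: Direction
    per_mdb: tuple
    supporting_mdbs: tuple
    hit_union: frozenset
    best_p: float
    miris: float
    validated: bool | None = None


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n).

    Population of N molecules of which K are the candidate's partners; n
    drawn (the query members present in the database); k observed hits.
    No normal approximation is used.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}"
        )
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_fdr(p_values: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def miris(n_support: int, n_selected: int, n_hits: int, input_size: int) -> float:
    """miRror Internal Score: mean of MDB-support and input-hit fractions.

    score = (n_support/n_selected + n_hits/input_size) / 2, in (0, 1].
    """
    if not (1 <= n_support <= n_selected):
        raise ValueError("need 1 <= n_support <= n_selected")
    if not (1 <= n_hits <= input_size):
        raise ValueError("need 1 <= n_hits <= input_size")
    return 0.5 * (n_support / n_selected) + 0.5 * (n_hits / input_size)


def _per_mdb_stats(
    query_ids: frozenset, mdb: MDBTable, direction: Direction
) -> dict:
    """Test every candidate with >= 1 query hit in one database."""
    if direction == Direction.GENE2MIR:
        background = mdb.n_genes
        present = query_ids & mdb.genes
        partners_of = mdb.targets_of      # candidate miRNA -> gene partners
        neighbors_of = mdb.regulators_of  # query gene -> candidate miRNAs
    else:
        background = mdb.n_mirnas
        present = query_ids & mdb.mirnas
        partners_of = mdb.regulators_of
        neighbors_of = mdb.targets_of
    if not present:
        return {}
    n = len(present)
    hits_by_candidate: dict = {}
    for member in present:
        for cand in neighbors_of.get(member, ()):
            hits_by_candidate.setdefault(cand, set()).add(member)
    site_counts = mdb.site_counts
    stats: dict = {}
    for cand in sorted(hits_by_candidate):
        hits = frozenset(hits_by_candidate[cand])
        K = len(partners_of[cand])
        p = hypergeom_tail(len(hits), n, K, background)
        sites = None
        if site_counts:
            pair = (
                (lambda h: (cand, h))
                if direction == Direction.GENE2MIR
                else (lambda h: (h, cand))
            )
            counted = [site_counts[pair(h)] for h in hits if pair(h) in site_counts]
            sites = sum(counted) if counted else None
        stats[cand] = MdbCandidateStat(
            mdb_id=mdb.mdb_id,
            k=len(hits),
            n=n,
            K=K,
            N=background,
            p_value=p,
            hits=hits,
            n_sites_total=sites,
        )
    # FDR across this database's tested candidates
    order = sorted(stats)
    qvals = bh_fdr([stats[c].p_value for c in order])
    for cand, q in zip(order, qvals):
        stats[cand] = replace(stats[cand], q_value=float(q))
    return stats


def enrich_direction(
    query: QuerySet,
    mdbs: Sequence[MDBTable],
    params: EnrichmentParams = EnrichmentParams(),
    direction: Direction = Direction.GENE2MIR,
) -> list:
    """Run per-database exact enrichment and aggregate across databases.

    Each selected database is tested independently against its own
    background, FDR-corrected within the database; a candidate's supporting
    databases are those whose (adjusted) value passes the threshold.
    Candidates failing the minimum-support or minimum-hit requirements are
    dropped; survivors carry miRIS and are ranked by it.
    """
    direction = Direction(direction)
    if params.selected_mdbs is not None:
        mdbs = [m for m in mdbs if m.mdb_id in params.selected_mdbs]
    if not mdbs:
        raise ValueError("no selected MDB available")
    n_selected = len(mdbs)
    query_ids = frozenset(query.ids)
    input_size = query.analyzed

    per_mdb: dict = {}
    any_overlap = False
    for mdb in mdbs:
        stats = _per_mdb_stats(query_ids, mdb, direction)
        if stats:
            any_overlap = True
        for cand, st in stats.items():
            per_mdb.setdefault(cand, []).append(st)
    if not any_overlap:
        warnings.warn("query shares no member with any selected MDB")
        return []

    results = []
    for cand in sorted(per_mdb):
        stats = per_mdb[cand]
        supporting = [
            st
            for st in stats
            if (st.q_value if params.fdr_enabled else st.p_value)
            <= params.p_threshold
        ]
        if len(supporting) < params.min_mdbs:
            continue
        hit_union = frozenset().union(*(st.hits for st in supporting))
        if len(hit_union) < params.min_hits:
            continue
        best_p = min(st.p_value for st in supporting)
        score = miris(len(supporting), n_selected, len(hit_union), input_size)
        results.append(
            EnrichmentResult(
                candidate_id=cand,
                direction=direction,
                per_mdb=tuple(stats),
                supporting_mdbs=tuple(st.mdb_id for st in supporting),
                hit_union=hit_union,
                best_p=best_p,
                miris=score,
            )
        )
    return rank_and_filter(results, params)


def rank_and_filter(
    results: Sequence[EnrichmentResult], params: EnrichmentParams
) -> list:
    """Drop sub-threshold miRIS and sort: miRIS desc, best_p asc, id asc."""
    kept = [r for r in results if r.miris >= params.min_miris]
    return sorted(kept, key=lambda r: (-r.miris, r.best_p, r.candidate_id))


def annotate_validated(
    results: Sequence[EnrichmentResult],
    validated_pairs: set,
    direction: Direction,
) -> list:
    """Flag candidates with an experimentally validated (miRNA, gene) hit."""
    out = []
    for r in results:
        if direction == Direction.GENE2MIR:
            flag = any((r.candidate_id, g) in validated_pairs for g in r.hit_union)
        else:
            flag = any((m, r.candidate_id) in validated_pairs for m in r.hit_union)
        out.append(replace(r, validated=flag))
    return out
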