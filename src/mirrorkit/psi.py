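"""Iterative greedy refinement of miRNA/gene sets by the Edge-Value ratio.

A set of miRNAs M and a set of genes G induce a bipartite subgraph in each
prediction database; its Edge-Value (EV) ratio is the number of realized
miRNA-gene edges divided by the maximum possible |M|*|G|.  EV = 1 means a
complete biclique — every miRNA in M is predicted to hit every gene in G.

The refinement greedily removes members whose removal increases EV (weakly
connected molecules: likely contaminants, or molecules not under miRNA
control) and then adds outside candidates whose addition increases EV,
under a stability constraint that bounds how much of the original input may
change per iteration.  The procedure runs independently per database; the
final report keeps only molecules supported by a minimum number of
per-database outputs.

Four modes: full cycles return the input's own molecule type after
alternating inference of the opposite side (miR2miR, Gene2Gene); partial
modes stop after half a cycle on the opposite type (Gene2miR, miR2Gene).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .enrich import Direction, EnrichmentParams, enrich_direction
from .exceptions import EmptyQueryError
from .mdb import MDBTable, QuerySet

_EV_TOL = 1e-12  # strict-improvement margin; ties are rejected to terminate


class PsiMode(str, enum.Enum):
    GENE2GENE = "gene2gene"
    MIR2MIR = "mir2mir"
    GENE2MIR = "gene2mir"
    MIR2GENE = "mir2gene"


FULL_MODES = (PsiMode.GENE2GENE, PsiMode.MIR2MIR)


@dataclass(frozen=True)
class PsiParams:
    """Iteration controls; enrichment params are embedded for the half-steps."""

    mode: PsiMode = PsiMode.MIR2MIR
    n_iterations: int = 2
    stability: float = 0.90
    min_mdbs: int = 2
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    candidate_cap: int = 200

    def __post_init__(self):
        object.__setattr__(self, "mode", PsiMode(self.mode))
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.75 <= self.stability <= 1.0):
            raise ValueError("stability must be in [0.75, 1.0]")
        if self.min_mdbs < 1:
            raise ValueError("min_mdbs must be >= 1")


@dataclass(frozen=True)
class MoveRecord:
    iteration: int
    action: str  # "remove" | "add"
    molecule: str
    ev_before: float
    ev_after: float


@dataclass(frozen=True)
class PsiState:
    """The bipartite working subgraph after refinement in one database."""

    M: frozenset
    G: frozenset
    ev: float
    iteration: int = 0
    log: tuple = ()


@dataclass(frozen=True)
class PsiResult:
    mode: PsiMode
    input_ids: tuple
    output_ids: tuple
    retained: tuple
    removed: tuple
    added: tuple
    support: Mapping[str, int]
    per_mdb: Mapping[str, PsiState]


def ev_ratio(M, G, edges) -> float:
    """Edge-Value ratio: realized edges over the complete-biclique count.

    ``edges`` is a set of (mirna, gene) pairs or an :class:`MDBTable`.
    """
    M, G = frozenset(M), frozenset(G)
    if not M or not G:
        raise ValueError("M and G must be non-empty")
    if isinstance(edges, MDBTable):
        edges = edges.edge_set
    realized = sum(1 for m in M for g in G if (m, g) in edges)
    return realized / (len(M) * len(G))


def _max_moves(anchor_size: int, stability: float) -> int:
    """Members that may leave (or enter) per iteration under the stability floor."""
    return anchor_size - int(math.ceil(stability * anchor_size - 1e-9))


def greedy_refine(
    mdb: MDBTable,
    M,
    G,
    params: PsiParams,
    side: str = "M",
    anchor=None,
    iteration: int = 0,
) -> PsiState:
    """One refinement pass on the mutable side: removals first, then additions.

    Every accepted move must strictly increase EV; candidates are scanned in
    deterministic id order and the best-improving move wins (first id on a
    delta tie).  Removals of anchored members stop at the stability floor
    (at least ``stability * |anchor|`` of the anchor retained); additions are
    capped symmetrically at ``(1 - stability) * |anchor|`` per pass.
    Terminates because EV strictly increases and is bounded by 1.
    """
    if side not in ("M", "G"):
        raise ValueError("side must be 'M' or 'G'")
    M, G = frozenset(M), frozenset(G)
    mutable = set(M if side == "M" else G)
    fixed = frozenset(G if side == "M" else M)
    if not mutable or not fixed:
        raise ValueError("both sides must be non-empty")
    adj = mdb.targets_of if side == "M" else mdb.regulators_of
    opp_adj = mdb.regulators_of if side == "M" else mdb.targets_of
    anchor = frozenset(anchor) if anchor is not None else frozenset(mutable)
    floor = int(math.ceil(params.stability * len(anchor) - 1e-9))
    max_adds = _max_moves(len(anchor), params.stability)

    deg = {x: len(adj.get(x, frozenset()) & fixed) for x in sorted(mutable)}
    E = sum(deg.values())
    nf = len(fixed)
    ev = E / (len(mutable) * nf)
    log: list = []

    # --- removal phase ---
    while len(mutable) > 1:
        retained = len(anchor & mutable)
        best = None
        for x in sorted(mutable):
            if x in anchor and retained - 1 < floor:
                continue
            new_ev = (E - deg[x]) / ((len(mutable) - 1) * nf)
            if new_ev > ev + _EV_TOL and (best is None or new_ev > best[1] + _EV_TOL):
                best = (x, new_ev)
        if best is None:
            break
        x, new_ev = best
        log.append(MoveRecord(iteration, "remove", x, ev, new_ev))
        mutable.discard(x)
        E -= deg.pop(x)
        ev = new_ev

    # --- addition phase ---
    pool = set()
    for f in fixed:
        pool.update(opp_adj.get(f, frozenset()))
    pool -= mutable
    adds_done = 0
    while adds_done < max_adds and pool:
        best = None
        for x in sorted(pool):
            d = len(adj.get(x, frozenset()) & fixed)
            new_ev = (E + d) / ((len(mutable) + 1) * nf)
            if new_ev > ev + _EV_TOL and (best is None or new_ev > best[1] + _EV_TOL):
                best = (x, new_ev, d)
        if best is None:
            break
        x, new_ev, d = best
        log.append(MoveRecord(iteration, "add", x, ev, new_ev))
        mutable.add(x)
        deg[x] = d
        E += d
        pool.discard(x)
        ev = new_ev
        adds_done += 1

    new_M = frozenset(mutable) if side == "M" else M
    new_G = frozenset(mutable) if side == "G" else G
    return PsiState(M=new_M, G=new_G, ev=ev, iteration=iteration, log=tuple(log))


def _infer_opposite(
    ids: frozenset, mdb: MDBTable, params: PsiParams, direction: Direction
) -> frozenset:
    """Half-step: enrich the current set against one database, keep top candidates."""
    enr = replace(params.enrichment, min_mdbs=1, selected_mdbs=None)
    query = QuerySet(ids=tuple(sorted(ids)), n_input=len(ids))
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        results = enrich_direction(query, [mdb], enr, direction)
    return frozenset(r.candidate_id for r in results[: params.candidate_cap])


def _refine_in_mdb(ids: frozenset, mdb: MDBTable, params: PsiParams) -> PsiState | None:
    """Run the mode's cycle(s) for one database; None if the query misses it."""
    mode = params.mode
    mirna_input = mode in (PsiMode.MIR2MIR, PsiMode.MIR2GENE)
    present = ids & (mdb.mirnas if mirna_input else mdb.genes)
    if not present:
        return None

    if mode in FULL_MODES:
        infer_dir = Direction.MIR2GENE if mode == PsiMode.MIR2MIR else Direction.GENE2MIR
        side = "M" if mode == PsiMode.MIR2MIR else "G"
        current = present
        state = None
        log: list = []
        for it in range(1, params.n_iterations + 1):
            opposite = _infer_opposite(current, mdb, params, infer_dir)
            if not opposite:
                break
            if side == "M":
                st = greedy_refine(
                    mdb, current, opposite, params, side="M",
                    anchor=present, iteration=it,
                )
                new = st.M
            else:
                st = greedy_refine(
                    mdb, opposite, current, params, side="G",
                    anchor=present, iteration=it,
                )
                new = st.G
            log.extend(st.log)
            state = replace(st, log=tuple(log))
            if new == current:  # converged
                break
            current = new
        if state is None:
            state = PsiState(
                M=current if side == "M" else frozenset(),
                G=current if side == "G" else frozenset(),
                ev=0.0,
            )
        return state

    # partial modes: one half-cycle ending on the opposite molecule type
    infer_dir = Direction.MIR2GENE if mode == PsiMode.MIR2GENE else Direction.GENE2MIR
    opposite = _infer_opposite(present, mdb, params, infer_dir)
    if not opposite:
        return None
    if mode == PsiMode.GENE2MIR:  # genes fixed, refine the inferred miRNA side
        return greedy_refine(mdb, opposite, present, params, side="M", iteration=1)
    return greedy_refine(mdb, present, opposite, params, side="G", iteration=1)


def _output_side(state: PsiState, mode: PsiMode) -> frozenset:
    if mode in (PsiMode.MIR2MIR, PsiMode.GENE2MIR):
        return state.M
    return state.G


def psi_iterate(
    query: QuerySet, mdbs: Sequence[MDBTable], params: PsiParams
) -> PsiResult:
    """Refine the query independently per database, then take the consensus.

    A molecule is reported iff it appears in at least ``min_mdbs``
    per-database final states (capped at the number of databases actually
    overlapping the query).  The result records the input/output diff:
    retained = input ∩ output, removed = input \\ output, added = output \\ input.
    """
    input_ids = frozenset(query.ids)
    if not input_ids:
        raise EmptyQueryError("query is empty after mapping")
    per_mdb: dict = {}
    for mdb in mdbs:
        state = _refine_in_mdb(input_ids, mdb, params)
        if state is not None:
            per_mdb[mdb.mdb_id] = state
    support: dict = {}
    for state in per_mdb.values():
        for mol in _output_side(state, params.mode):
            support[mol] = support.get(mol, 0) + 1
    needed = min(params.min_mdbs, len(per_mdb)) if per_mdb else params.min_mdbs
    output = frozenset(m for m, s in support.items() if s >= needed)
    return PsiResult(
        mode=params.mode,
        input_ids=tuple(sorted(input_ids)),
        output_ids=tuple(sorted(output)),
        retained=tuple(sorted(input_ids & output)),
        removed=tuple(sorted(input_ids - output)),
        added=tuple(sorted(output - input_ids)),
        support=dict(sorted(support.items())),
        per_mdb=per_mdb,
    )
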