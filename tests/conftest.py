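import itertools

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirrorkit.mdb import MDBTable

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Independent oracles (brute force; deliberately naive)
# ---------------------------------------------------------------------------

def enumeration_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by enumerating every possible draw of n from N."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total if total else 1.0


def stepup_fdr(p_values) -> list:
    """Hand-written Benjamini-Hochberg step-up, independent of statsmodels."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q


def exhaustive_ev_optimum(edges, mutable0, fixed, pool, stability):
    """Best EV over all stability-feasible mutable sets (removals + additions)."""
    import itertools as it
    import math

    mutable0 = sorted(mutable0)
    pool = sorted(set(pool) - set(mutable0))
    floor = int(math.ceil(stability * len(mutable0) - 1e-9))
    max_adds = len(mutable0) - floor
    fixed = sorted(fixed)
    best = -1.0
    for keep_n in range(floor, len(mutable0) + 1):
        for kept in it.combinations(mutable0, keep_n):
            for add_n in range(0, max_adds + 1):
                for added in it.combinations(pool, add_n):
                    M = set(kept) | set(added)
                    if not M:
                        continue
                    realized = sum(
                        1 for m in M for g in fixed if (m, g) in edges
                    )
                    best = max(best, realized / (len(M) * len(fixed)))
    return best


# ---------------------------------------------------------------------------
# Shared fixtures
# ---------------------------------------------------------------------------

def make_mdb(mdb_id, pairs, scores=None, sites=None) -> MDBTable:
    df = pd.DataFrame(pairs, columns=["mirna", "gene"])
    if scores is not None:
        df["score"] = scores
    if sites is not None:
        df["n_sites"] = sites
    return MDBTable.from_edges(mdb_id, df)


@pytest.fixture
def toy_mdb():
    """10 genes; miRNA mA targets g1..g4; mB and mC cover the remainder."""
    pairs = (
        [("mA", f"g{i}") for i in range(1, 5)]
        + [("mB", f"g{i}") for i in range(5, 7)]
        + [("mC", f"g{i}") for i in range(4, 11)]
    )
    return make_mdb("toy", pairs)
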