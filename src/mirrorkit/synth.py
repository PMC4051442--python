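"""Seeded synthetic MDBs with planted combinatorial regulation.

Real prediction databases are large, licensed and noisy; for self-contained
verification the generator emulates their structure instead: a universe of
genes and miRNAs, several databases whose edges are independent background
noise, and one planted module — a dense miRNA-by-gene block standing in for
a coordinated regulatory program — whose edges replicate across databases
with a configurable agreement level.  The planted truth is serialized next
to the fixtures so recovery tests can score themselves.

Identifiers mimic the central RefSeq-like namespace (``NM_000123`` genes,
``mir-0007`` miRNAs).  Sequences are 22-nt mature miRNAs whose canonical
seeds (positions 2-8) realize a chosen number of seed families.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .filters import ExpressionProfile
from .mdb import MDBTable, write_mdb_table

_RNA = np.array(list("ACGU"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults give a desk-scale but non-trivial study.

    200 genes x 50 miRNAs keeps every run sub-second while leaving room for
    a 5x20 planted module to dominate its background (edge density 0.02,
    roughly the sparsity regime of conservative predictors).
    """

    n_genes: int = 200
    n_mirnas: int = 50
    n_mdbs: int = 4
    p_background: float = 0.02
    planted_mirnas: int = 5
    planted_genes: int = 20
    p_signal: float = 0.9
    mdb_agreement: float = 1.0
    n_seed_families: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        probs = (self.p_background, self.p_signal, self.mdb_agreement)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.p_signal <= self.p_background:
            raise ConfigError("p_signal must exceed p_background")
        if self.planted_mirnas > self.n_mirnas or self.planted_genes > self.n_genes:
            raise ConfigError("planted module larger than the universe")
        if self.n_seed_families > self.n_mirnas:
            raise ConfigError("more seed families than miRNAs")


@dataclass(frozen=True)
class SyntheticTruth:
    """What was planted: the answer key for recovery tests."""

    planted_mirnas: tuple
    planted_genes: tuple
    per_mdb_edges: dict  # mdb_id -> list of [mirna, gene]
    families: dict  # mirna_id -> family index (when sequences were generated)
    config: SyntheticConfig

    def to_json(self) -> str:
        payload = {
            "planted_mirnas": list(self.planted_mirnas),
            "planted_genes": list(self.planted_genes),
            "per_mdb_edges": self.per_mdb_edges,
            "families": self.families,
            "config": asdict(self.config),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def gene_ids(n: int) -> list:
    return [f"NM_{i:06d}" for i in range(1, n + 1)]


def mirna_ids(n: int) -> list:
    return [f"mir-{i:04d}" for i in range(1, n + 1)]


def generate_mdbs(
    config: SyntheticConfig, outdir=None
) -> tuple[list, SyntheticTruth]:
    """Draw the MDB tables; optionally write TSVs plus a truth JSON.

    Background edges are i.i.d. Bernoulli(p_background) per database; each
    planted-module cell appears with probability p_signal * mdb_agreement
    per database, independently, on top of the background.  Deterministic
    under ``rng_seed``.
    """
    genes = gene_ids(config.n_genes)
    mirnas = mirna_ids(config.n_mirnas)
    planted_m = mirnas[: config.planted_mirnas]
    planted_g = genes[: config.planted_genes]
    rng = np.random.default_rng([config.rng_seed, 101])

    tables: list = []
    per_mdb_edges: dict = {}
    for idx in range(1, config.n_mdbs + 1):
        mdb_id = f"mdb{idx:02d}"
        mask = rng.random((config.n_mirnas, config.n_genes)) < config.p_background
        signal = (
            rng.random((config.planted_mirnas, config.planted_genes))
            < config.p_signal * config.mdb_agreement
        )
        mask[: config.planted_mirnas, : config.planted_genes] |= signal
        mi, gi = np.nonzero(mask)
        if mi.size == 0:  # degenerate config: keep the table loadable
            mi, gi = np.array([0]), np.array([0])
        df = pd.DataFrame(
            {
                "mirna": np.asarray(mirnas)[mi],
                "gene": np.asarray(genes)[gi],
                "score": np.round(rng.uniform(0.0, 1.0, size=mi.size), 6),
                "n_sites": rng.integers(1, 4, size=mi.size),
            }
        )
        table = MDBTable.from_edges(mdb_id, df)
        tables.append(table)
        per_mdb_edges[mdb_id] = [
            [m, g] for m, g in zip(table.edges["mirna"], table.edges["gene"])
        ]

    families = _family_assignment(config)
    truth = SyntheticTruth(
        planted_mirnas=tuple(planted_m),
        planted_genes=tuple(planted_g),
        per_mdb_edges=per_mdb_edges,
        families=families,
        config=config,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for table in tables:
            write_mdb_table(table, outdir / f"{table.mdb_id}.tsv")
        (outdir / "truth.json").write_text(truth.to_json())
    return tables, truth


def _family_assignment(config: SyntheticConfig) -> dict:
    """Round-robin miRNA -> family index (families sized as evenly as possible)."""
    return {
        m: i % config.n_seed_families
        for i, m in enumerate(mirna_ids(config.n_mirnas))
    }


def generate_sequences(config: SyntheticConfig, path=None) -> list:
    """Mature 22-nt miRNA sequences realizing exactly n_seed_families seeds.

    Positions 2-8 carry one of ``n_seed_families`` distinct 7-mers; the
    flanks are random RNA.  Returns ``(mirna_id, sequence)`` pairs and
    optionally writes FASTA.
    """
    rng = np.random.default_rng([config.rng_seed, 202])
    seeds: list = []
    seen: set = set()
    while len(seeds) < config.n_seed_families:
        cand = "".join(rng.choice(_RNA, size=7))
        if cand not in seen:
            seen.add(cand)
            seeds.append(cand)
    assignment = _family_assignment(config)
    records: list = []
    for m in mirna_ids(config.n_mirnas):
        seed = seeds[assignment[m]]
        head = "".join(rng.choice(_RNA, size=1))
        tail = "".join(rng.choice(_RNA, size=14))
        records.append((m, head + seed + tail))
    if path is not None:
        with open(path, "w") as fh:
            for mid, seq in records:
                fh.write(f">{mid}\n{seq}\n")
    return records


def generate_expression(
    config: SyntheticConfig,
    contexts: int = 1,
    expressed_fraction: float = 1.0,
    path=None,
) -> dict:
    """Per-context expression profiles with a designated expressed subset.

    Expressed genes draw log-normal positive levels; the rest are 0.  The
    expressed subset differs across contexts (seeded), covering
    ``expressed_fraction`` of the gene universe each.
    """
    if contexts < 1:
        raise ConfigError("contexts must be >= 1")
    if not (0.0 < expressed_fraction <= 1.0):
        raise ConfigError("expressed_fraction must be in (0, 1]")
    genes = gene_ids(config.n_genes)
    n_expr = math.ceil(expressed_fraction * config.n_genes)
    rng = np.random.default_rng([config.rng_seed, 303])
    profiles: dict = {}
    rows: list = []
    for c in range(1, contexts + 1):
        ctx = f"ctx{c:02d}"
        chosen = set(rng.choice(genes, size=n_expr, replace=False))
        values = {}
        for g in genes:
            values[g] = float(np.round(rng.lognormal(1.0, 1.0), 4)) if g in chosen else 0.0
            rows.append((g, ctx, values[g]))
        profiles[ctx] = ExpressionProfile(context_id=ctx, values=values)
    if path is not None:
        pd.DataFrame(rows, columns=["gene_id", "context_id", "value"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )
    return profiles
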