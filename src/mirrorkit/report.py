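"""Run orchestration and the TSV output surfaces.

Three surfaces per enrichment run: a run summary (parameters as chosen plus
the number of molecules actually analyzed, which can differ from the raw
input through mapping and de-duplication), the ranked main table (sorted by
miRIS, colored in the web original by the minimal per-MDB p-value, here a
plain column), and one zoomed support table per candidate listing each
database's counts, p/q values and reported binding sites.  PSI runs add a
diff listing: retained / removed / added relative to the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import filters as flt
from .enrich import (
    Direction,
    EnrichmentParams,
    EnrichmentResult,
    annotate_validated,
    enrich_direction,
)
from .exceptions import MDBFormatError
from .mdb import (
    MDBTable,
    QuerySet,
    build_seed_families,
    compact_mdb_to_families,
    load_identifier_maps,
    load_mdb_table,
    normalize_query,
)
from .psi import PsiParams, PsiResult, psi_iterate

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Everything a run needs; serialized verbatim into the summary table."""

    query_path: str
    query_type: str  # "genes" | "mirnas"
    mdb_paths: tuple
    mapping_path: str | None = None
    fasta_path: str | None = None
    use_families: bool = False
    expression_path: str | None = None
    tissue: str | None = None
    top_expressed_fraction: float | None = None
    score_fraction: float | None = None
    validated_path: str | None = None
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    psi: PsiParams | None = None
    out_dir: str = "."
    seed: int = 0


def read_query_file(path) -> list:
    """Plain-text query: one id per line, '#' comments, blanks ignored."""
    lines = Path(path).read_text().splitlines()
    out = []
    for line in lines:
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def load_validated_pairs(path) -> set:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("mirna", "gene"):
        if col not in df.columns:
            raise MDBFormatError(f"validated-pair table {path}: missing {col!r}")
    return set(zip(df["mirna"].str.strip(), df["gene"].str.strip()))


def _prepare_inputs(config: RunConfig) -> tuple:
    """Shared loading path: query normalization, MDBs, families, filters."""
    raw_ids = read_query_file(config.query_path)
    maps = load_identifier_maps(config.mapping_path) if config.mapping_path else ()
    query = normalize_query(raw_ids, maps)

    mdbs = [load_mdb_table(p) for p in config.mdb_paths]

    fam = None
    if config.fasta_path and config.use_families:
        fam = build_seed_families(config.fasta_path)
        mdbs = [compact_mdb_to_families(m, fam) for m in mdbs]
        if config.query_type == "mirnas":
            mapped = sorted({fam.family_of(i) or i for i in query.ids})
            query = QuerySet(
                ids=tuple(mapped),
                unmapped=query.unmapped,
                n_input=query.n_input,
                n_duplicates=query.n_input - len(query.unmapped) - len(mapped),
            )

    if config.expression_path and config.tissue:
        profiles = flt.load_expression(config.expression_path)
        profile = profiles[config.tissue]
        gene_set = profile.expressed
        if config.top_expressed_fraction:
            gene_set = flt.top_expressed(profile, config.top_expressed_fraction)
        mdbs = [flt.restrict_to_gene_set(m, gene_set) for m in mdbs]
    if config.score_fraction:
        mdbs = [flt.filter_by_score_fraction(m, config.score_fraction) for m in mdbs]
    return query, mdbs, fam


def _summary_rows(config: RunConfig, query: QuerySet, extra=()) -> pd.DataFrame:
    rows = [("query_type", config.query_type)]
    rows += [(f"param.{k}", v) for k, v in asdict(config.enrichment).items()]
    if config.psi is not None:
        rows += [
            ("psi.mode", config.psi.mode.value),
            ("psi.n_iterations", config.psi.n_iterations),
            ("psi.stability", config.psi.stability),
            ("psi.min_mdbs", config.psi.min_mdbs),
        ]
    rows += [
        ("n_input", query.n_input),
        ("n_analyzed", query.analyzed),
        ("n_duplicates", query.n_duplicates),
        ("n_unmapped", len(query.unmapped)),
        ("seed", config.seed),
    ]
    rows += list(extra)
    return pd.DataFrame(rows, columns=["key", "value"])


def _results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "candidate": r.candidate_id,
                "miris": r.miris,
                "best_p": r.best_p,
                "n_supporting_mdbs": len(r.supporting_mdbs),
                "supporting_mdbs": ";".join(r.supporting_mdbs),
                "n_hits": len(r.hit_union),
                "hits": ";".join(sorted(r.hit_union)),
                "validated": "" if r.validated is None else str(r.validated).lower(),
            }
            for r in results
        ],
        columns=[
            "candidate", "miris", "best_p", "n_supporting_mdbs",
            "supporting_mdbs", "n_hits", "hits", "validated",
        ],
    )


def _write_support_tables(results, out_dir: Path) -> None:
    support_dir = out_dir / "support"
    support_dir.mkdir(exist_ok=True)
    for r in results:
        frame = pd.DataFrame(
            [
                {
                    "mdb_id": st.mdb_id,
                    "k": st.k,
                    "n": st.n,
                    "K": st.K,
                    "N": st.N,
                    "p_value": st.p_value,
                    "q_value": st.q_value,
                    "supporting": str(st.mdb_id in r.supporting_mdbs).lower(),
                    "n_sites_total": st.n_sites_total,
                    "hits": ";".join(sorted(st.hits)),
                }
                for st in sorted(r.per_mdb, key=lambda s: s.mdb_id)
            ]
        )
        safe = r.candidate_id.replace("/", "_")
        frame.to_csv(
            support_dir / f"{safe}.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT,
        )


def run_mirror(config: RunConfig) -> list:
    """Full enrichment run: load, filter, enrich, write the three surfaces."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    query, mdbs, _ = _prepare_inputs(config)
    direction = (
        Direction.GENE2MIR if config.query_type == "genes" else Direction.MIR2GENE
    )
    results = enrich_direction(query, mdbs, config.enrichment, direction)
    if config.validated_path:
        pairs = load_validated_pairs(config.validated_path)
        results = annotate_validated(results, pairs, direction)

    _summary_rows(
        config, query, extra=[("n_mdbs", len(mdbs)), ("n_results", len(results))]
    ).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    _results_frame(results).to_csv(
        out_dir / "results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    _write_support_tables(results, out_dir)
    return results


def run_psi(config: RunConfig) -> PsiResult:
    """PSI refinement run: per-MDB greedy refinement, consensus, diff lists."""
    if config.psi is None:
        raise ValueError("RunConfig.psi is required for a PSI run")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    query, mdbs, _ = _prepare_inputs(config)
    result = psi_iterate(query, mdbs, config.psi)

    # score: enrichment miRIS where the output side is an enrichment target
    # (partial modes); otherwise the cross-MDB consensus fraction.
    n_mdbs = max(len(result.per_mdb), 1)
    miris_by_mol: dict = {}
    if config.psi.mode.value in ("gene2mir", "mir2gene"):
        direction = (
            Direction.GENE2MIR
            if config.psi.mode.value == "gene2mir"
            else Direction.MIR2GENE
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            enr = enrich_direction(query, mdbs, config.enrichment, direction)
        miris_by_mol = {r.candidate_id: r.miris for r in enr}

    rows = []
    for mol in result.output_ids:
        support = result.support.get(mol, 0)
        rows.append(
            {
                "molecule": mol,
                "n_supporting_mdbs": support,
                "consensus": support / n_mdbs,
                "miris": miris_by_mol.get(mol, support / n_mdbs),
                "status": "retained" if mol in result.retained else "added",
            }
        )
    frame = pd.DataFrame(
        rows, columns=["molecule", "n_supporting_mdbs", "consensus", "miris", "status"]
    )
    if len(frame):
        frame = frame.sort_values(
            ["miris", "molecule"], ascending=[False, True], kind="mergesort"
        )

    _summary_rows(
        config, query,
        extra=[
            ("n_mdbs", len(mdbs)),
            ("n_output", len(result.output_ids)),
            ("n_retained", len(result.retained)),
            ("n_removed", len(result.removed)),
            ("n_added", len(result.added)),
        ],
    ).to_csv(out_dir / "psi_summary.tsv", sep="\t", index=False)
    frame.to_csv(
        out_dir / "psi_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    diff_rows = (
        [("retained", m) for m in result.retained]
        + [("removed", m) for m in result.removed]
        + [("added", m) for m in result.added]
    )
    pd.DataFrame(diff_rows, columns=["section", "molecule"]).to_csv(
        out_dir / "diff.tsv", sep="\t", index=False
    )
    return result
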