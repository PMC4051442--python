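"""Loading, validation and indexing of miRNA-target prediction databases (MDBs).

An MDB is a bipartite edge table: predicted miRNA -> gene pairs, optionally
carrying the database's native confidence score and the number of predicted
binding sites on the transcript.  All databases are normalized to one TSV
dialect (columns ``mirna``, ``gene``, optional ``score``, ``n_sites``;
``#`` starts a comment line) so that downstream statistics are reproducible
bit for bit.

The module also handles the two identifier problems that plague miRNA
target resources:

* gene identifiers are unified into one central (RefSeq-like) namespace via
  static many-to-one mapping tables, with a verbatim audit list of whatever
  could not be mapped;
* mature miRNAs are compacted into *seed families* — groups sharing the
  canonical seed, nucleotides 2-8 of the mature sequence — which collapses
  the many synonymous miRNA names the databases use for one sequence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import EmptyInputError, EmptyQueryError, MDBFormatError

REQUIRED_COLUMNS = ("mirna", "gene")
OPTIONAL_COLUMNS = ("score", "n_sites")

#: 1-based inclusive positions of the canonical seed on the mature miRNA.
SEED_START, SEED_END = 2, 8


# ---------------------------------------------------------------------------
# MDB tables
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class MDBTable:
    """One prediction database as a deduplicated bipartite edge table.

    ``edges`` is a DataFrame in canonical order (sorted by miRNA then gene)
    with exactly one row per (mirna, gene) pair.  Duplicate input rows are
    collapsed keeping the maximum score and the maximum site count — max is
    order-independent, so the collapse is deterministic regardless of row
    order in the source file.
    """

    mdb_id: str
    edges: pd.DataFrame

    @classmethod
    def from_edges(cls, mdb_id: str, edges: pd.DataFrame) -> "MDBTable":
        df = edges.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise MDBFormatError(
                f"MDB {mdb_id!r}: missing required column(s) {missing}"
            )
        if len(df) == 0:
            raise EmptyInputError(f"MDB {mdb_id!r}: table has no edges")
        df["mirna"] = df["mirna"].astype(str).str.strip()
        df["gene"] = df["gene"].astype(str).str.strip()
        if (df["mirna"] == "").any() or (df["gene"] == "").any():
            raise MDBFormatError(f"MDB {mdb_id!r}: empty mirna/gene identifier")
        if "score" in df.columns:
            df["score"] = pd.to_numeric(df["score"], errors="coerce")
        if "n_sites" in df.columns:
            df["n_sites"] = pd.to_numeric(df["n_sites"], errors="coerce").astype("Int64")
            bad = df["n_sites"].dropna() < 1
            if bad.any():
                raise MDBFormatError(f"MDB {mdb_id!r}: n_sites must be >= 1")
        agg = {c: "max" for c in OPTIONAL_COLUMNS if c in df.columns}
        if agg:
            df = df.groupby(["mirna", "gene"], as_index=False).agg(agg)
        else:
            df = df.drop_duplicates(["mirna", "gene"])
        keep = ["mirna", "gene"] + [c for c in OPTIONAL_COLUMNS if c in df.columns]
        df = (
            df[keep]
            .sort_values(["mirna", "gene"], kind="mergesort")
            .reset_index(drop=True)
        )
        return cls(mdb_id=mdb_id, edges=df)

    # -- background counts -------------------------------------------------

    @cached_property
    def genes(self) -> frozenset:
        return frozenset(self.edges["gene"])

    @cached_property
    def mirnas(self) -> frozenset:
        return frozenset(self.edges["mirna"])

    @property
    def n_genes(self) -> int:
        """Distinct genes in the table: the enrichment background for Gene2miR."""
        return len(self.genes)

    @property
    def n_mirnas(self) -> int:
        """Distinct miRNAs in the table: the enrichment background for miR2Gene."""
        return len(self.mirnas)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def edge_set(self) -> frozenset:
        return frozenset(zip(self.edges["mirna"], self.edges["gene"]))

    @cached_property
    def targets_of(self) -> Mapping[str, frozenset]:
        """miRNA -> set of predicted target genes."""
        grouped = self.edges.groupby("mirna")["gene"].agg(frozenset)
        return dict(grouped)

    @cached_property
    def regulators_of(self) -> Mapping[str, frozenset]:
        """gene -> set of miRNAs predicted to target it."""
        grouped = self.edges.groupby("gene")["mirna"].agg(frozenset)
        return dict(grouped)

    @cached_property
    def site_counts(self) -> Mapping[tuple, int]:
        """(mirna, gene) -> reported binding-site count, where present."""
        if "n_sites" not in self.edges.columns:
            return {}
        sub = self.edges.dropna(subset=["n_sites"])
        return {
            (m, g): int(s)
            for m, g, s in zip(sub["mirna"], sub["gene"], sub["n_sites"])
        }

    @property
    def has_scores(self) -> bool:
        return "score" in self.edges.columns and self.edges["score"].notna().any()


def load_mdb_table(path, mdb_id: str | None = None) -> MDBTable:
    """Read one MDB from a headered TSV (columns mirna, gene[, score, n_sites]).

    Comment lines start with ``#``.  Duplicate (mirna, gene) rows are collapsed
    (max score / max n_sites).  Raises :class:`MDBFormatError` on a missing
    required column and :class:`EmptyInputError` on a row-less table.
    """
    path = Path(path)
    if mdb_id is None:
        mdb_id = path.stem
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"MDB {mdb_id!r}: file {path} is empty") from None
    return MDBTable.from_edges(mdb_id, df)


def write_mdb_table(mdb: MDBTable, path) -> None:
    """Write the canonical, sorted edge table as TSV (stable formatting)."""
    mdb.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Identifier unification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentifierMap:
    """A static many-to-one mapping from one namespace into the central one.

    Ambiguous sources (one id mapping to several central ids) are rejected at
    construction and land on the unmapped audit list during normalization —
    a deterministic snapshot beats a live conversion service here.
    """

    source_namespace: str
    target_namespace: str
    pairs: Mapping[str, str]
    ambiguous: frozenset = frozenset()
    central_ids: frozenset = frozenset()

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple],
        source_namespace: str = "",
        target_namespace: str = "central",
    ) -> "IdentifierMap":
        mapping: dict = {}
        ambiguous: set = set()
        central: set = set()
        for source, central_id in pairs:
            source, central_id = str(source).strip(), str(central_id).strip()
            central.add(central_id)
            if source in ambiguous:
                continue
            if source in mapping and mapping[source] != central_id:
                ambiguous.add(source)
                del mapping[source]
            else:
                mapping[source] = central_id
        if ambiguous:
            warnings.warn(
                f"identifier map {source_namespace or '<anon>'}: "
                f"{len(ambiguous)} ambiguous source id(s) rejected"
            )
        return cls(
            source_namespace, target_namespace, mapping,
            frozenset(ambiguous), frozenset(central),
        )


def load_identifier_maps(path) -> list:
    """Read mapping tables from TSV with columns source_id, central_id[, namespace]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("source_id", "central_id"):
        if col not in df.columns:
            raise MDBFormatError(f"mapping table {path}: missing column {col!r}")
    if "namespace" not in df.columns:
        df["namespace"] = "default"
    maps = []
    for ns, sub in df.groupby("namespace", sort=True):
        maps.append(
            IdentifierMap.from_pairs(
                zip(sub["source_id"], sub["central_id"]), source_namespace=str(ns)
            )
        )
    return maps


@dataclass(frozen=True)
class QuerySet:
    """A normalized input list with its mapping audit trail.

    ``ids`` are unique central-namespace identifiers; ``analyzed`` (their
    count) is the effective input size used by every downstream statistic,
    and may differ from the raw input length through de-duplication and
    unmapped entries.
    """

    ids: tuple
    unmapped: tuple = ()
    n_input: int = 0
    n_duplicates: int = 0

    @property
    def analyzed(self) -> int:
        return len(self.ids)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "QuerySet":
        """Wrap an already-central id collection (dedup, sorted)."""
        raw = [str(i) for i in ids]
        if not raw:
            raise EmptyQueryError("query is empty")
        unique = tuple(sorted(set(raw)))
        return cls(ids=unique, n_input=len(raw), n_duplicates=len(raw) - len(unique))


def normalize_query(ids: Sequence[str], maps: Sequence[IdentifierMap] = ()) -> QuerySet:
    """Map raw identifiers into the central namespace, with an audit trail.

    Every raw occurrence lands in exactly one bucket, so
    ``n_input == analyzed + n_duplicates + len(unmapped)`` always holds.
    With no maps supplied, ids are assumed central and pass through; with
    maps, an id must be a known source (translated) or a known central id
    (kept verbatim) — anything else is preserved on the unmapped list.
    """
    raw = [str(i).strip() for i in ids if str(i).strip()]
    if not raw:
        raise EmptyQueryError("query is empty")
    central_ids: set = set()
    for m in maps:
        central_ids.update(m.central_ids or m.pairs.values())

    def translate(identifier: str):
        for m in maps:
            if identifier in m.pairs:
                return m.pairs[identifier]
        if not maps or identifier in central_ids:
            return identifier
        return None

    normalized: list = []
    seen: set = set()
    seen_raw: set = set()
    unmapped: list = []
    n_duplicates = 0
    for identifier in raw:
        if identifier in seen_raw:
            n_duplicates += 1
            continue
        seen_raw.add(identifier)
        central = translate(identifier)
        if central is None:
            unmapped.append(identifier)
        elif central in seen:
            n_duplicates += 1
        else:
            seen.add(central)
            normalized.append(central)
    if not normalized:
        raise EmptyQueryError(
            f"no query identifier could be mapped ({len(unmapped)} unmapped)"
        )
    if unmapped:
        warnings.warn(f"{len(unmapped)} query identifier(s) left unmapped")
    return QuerySet(
        ids=tuple(sorted(normalized)),
        unmapped=tuple(unmapped),
        n_input=len(raw),
        n_duplicates=n_duplicates,
    )


# ---------------------------------------------------------------------------
# Seed families
# ---------------------------------------------------------------------------

def canonical_seed(sequence: str) -> str | None:
    """The 7-nt canonical seed: 1-based positions 2-8 of the mature sequence.

    Case-insensitive; DNA input is normalized to RNA (T -> U).  Returns None
    for sequences shorter than 8 nt.
    """
    seq = str(sequence).upper().replace("T", "U")
    if len(seq) < SEED_END:
        return None
    return seq[SEED_START - 1 : SEED_END]


@dataclass(frozen=True)
class SeedFamilyIndex:
    """Grouping of mature miRNAs by identical canonical seed.

    ``families`` maps the 7-character seed string to its member ids; every
    miRNA with an accepted sequence belongs to exactly one family.
    """

    families: Mapping[str, frozenset]
    mirna_to_family: Mapping[str, str]
    rejected: tuple = ()

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_to_family)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def compact_ratio(self) -> float:
        return self.n_mirnas / self.n_families if self.n_families else 1.0

    def family_of(self, mirna_id: str) -> str | None:
        return self.mirna_to_family.get(mirna_id)


def build_seed_families(sequences) -> SeedFamilyIndex:
    """Group mature miRNAs into seed families.

    ``sequences`` may be a FASTA path or an iterable of ``(id, sequence)``
    pairs / SeqRecords.  Sequences shorter than 8 nt are rejected per record
    with a warning, never fatally.
    """
    records = _iter_sequences(sequences)
    families: dict = {}
    mirna_to_family: dict = {}
    rejected: list = []
    for mirna_id, seq in records:
        seed = canonical_seed(seq)
        if seed is None:
            rejected.append(mirna_id)
            continue
        families.setdefault(seed, set()).add(mirna_id)
        mirna_to_family[mirna_id] = seed
    if rejected:
        warnings.warn(
            f"{len(rejected)} sequence(s) shorter than 8 nt rejected from "
            "seed-family construction"
        )
    return SeedFamilyIndex(
        families={k: frozenset(v) for k, v in families.items()},
        mirna_to_family=mirna_to_family,
        rejected=tuple(rejected),
    )


def _iter_sequences(sequences):
    if isinstance(sequences, (str, Path)):
        from Bio import SeqIO

        for rec in SeqIO.parse(str(sequences), "fasta"):
            yield rec.id, str(rec.seq)
        return
    for item in sequences:
        if hasattr(item, "seq"):  # SeqRecord
            yield item.id, str(item.seq)
        else:
            yield item[0], str(item[1])


def compact_mdb_to_families(mdb: MDBTable, fam: SeedFamilyIndex) -> MDBTable:
    """Re-key an MDB's miRNAs onto their seed families.

    miRNAs without a known sequence keep their own id as a singleton family,
    so no edge information is lost.  (family, gene) duplicates collapse with
    the usual max rules; the gene set is unchanged.  Idempotent: family ids
    are either seeds (no longer present as miRNA ids with sequences) or the
    original ids themselves.
    """
    df = mdb.edges.copy()
    df["mirna"] = [fam.family_of(m) or m for m in df["mirna"]]
    return MDBTable.from_edges(mdb.mdb_id, df)


@dataclass(frozen=True)
class MDBStats:
    mdb_id: str
    n_genes: int
    n_mirnas: int
    n_families: int
    compact_ratio: float


def mdb_stats(mdb: MDBTable, fam: SeedFamilyIndex | None = None) -> MDBStats:
    """Per-MDB summary: distinct genes, miRNAs, seed families and their ratio.

    The compact ratio (miRNAs / families, reported to 2 decimals) measures
    how much identifier redundancy family compaction removes.  miRNAs absent
    from the sequence index count as their own singleton family.
    """
    if fam is None:
        n_families = mdb.n_mirnas
    else:
        n_families = len({fam.family_of(m) or m for m in mdb.mirnas})
    ratio = mdb.n_mirnas / n_families if n_families else 1.0
    return MDBStats(
        mdb_id=mdb.mdb_id,
        n_genes=mdb.n_genes,
        n_mirnas=mdb.n_mirnas,
        n_families=n_families,
        compact_ratio=round(ratio, 2),
    )
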