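"""Candidate-gene network expansion.

Expands a set of query genes (or pathway names) into *focal genes*: genes
that share at least one pathway with a query gene, or whose protein product
has a direct protein-protein interaction with a query protein.  Pathway
membership and PPI edges come from local flat-file snapshots (GMT / SIF);
no live database access is performed or supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "GeneId",
    "PathwayRecord",
    "InteractionEdge",
    "FocalGene",
    "load_pathway_db",
    "load_ppi",
    "load_aliases",
    "resolve_aliases",
    "expand_from_proteins",
    "expand_from_pathways",
    "source_distribution",
]


@dataclass(frozen=True)
class GeneId:
    """A gene symbol plus any protein accessions that map to it."""

    symbol: str
    aliases: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GeneId):
            return self.symbol == other.symbol
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.symbol)


@dataclass(frozen=True)
class PathwayRecord:
    pathway_id: str
    name: str
    source: str  # "kegg-like" | "reactome-like" | "custom"
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected PPI edge; (a, b) and (b, a) compare equal."""

    a: str
    b: str
    source: str = "ppi"

    @property
    def is_self_loop(self) -> bool:
        return self.a == self.b

    def key(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, InteractionEdge):
            return self.key() == other.key()
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.key())


@dataclass
class FocalGene:
    """A gene in the expanded set, with provenance of how it got there.

    ``provenance`` is a subset of {"pathway", "ppi"}; empty only for query
    genes that were not found in any snapshot.  ``via`` records which
    pathway ids and/or query genes are responsible.
    """

    gene: str
    provenance: set[str] = field(default_factory=set)
    via: set[str] = field(default_factory=set)
    is_query: bool = False

    def __post_init__(self) -> None:
        if not self.is_query and not self.provenance:
            raise ValueError(f"non-query focal gene {self.gene} lacks provenance")
        if not self.is_query and not self.via:
            raise ValueError(f"non-query focal gene {self.gene} lacks via")


def load_pathway_db(path: str | Path, format: str = "GMT") -> list[PathwayRecord]:
    """Read a pathway snapshot.

    GMT: ``pathway_id<TAB>description<TAB>member1<TAB>member2...``
    TSV: two columns ``pathway_id<TAB>member`` (one membership per row),
    with an optional header line ``pathway_id\\tmember``.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt not in {"GMT", "TSV"}:
        raise ValueError(f"unknown pathway format {format!r}")
    records: list[PathwayRecord] = []
    seen: set[str] = set()
    if fmt == "GMT":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs id, description and >=1 member"
                    )
                pid, desc, *members = parts
                members = [m for m in members if m]
                if not members:
                    raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no members")
                if pid in seen:
                    raise ValueError(f"{path}:{lineno}: duplicate pathway_id {pid!r}")
                seen.add(pid)
                records.append(
                    PathwayRecord(pid, desc or pid, "custom", frozenset(members))
                )
    else:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: pathway TSV needs 2 columns")
        if list(df.iloc[0]) [:2] == ["pathway_id", "member"]:
            df = df.iloc[1:]
        for pid, grp in df.groupby(0, sort=True):
            members = frozenset(grp[1].dropna())
            if not members:
                raise ValueError(f"{path}: pathway {pid!r} has no members")
            records.append(PathwayRecord(str(pid), str(pid), "custom", members))
    return records


def load_ppi(path: str | Path) -> list[InteractionEdge]:
    """Read PPI edges from SIF (``a<TAB>interaction<TAB>b``) or 2-column TSV.

    Edges are undirected and deduplicated; self-loops are kept (they are
    flagged, and never create focal genes on their own).
    """
    path = Path(path)
    edges: dict[tuple[str, str], InteractionEdge] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                a, rel, b = parts
            elif len(parts) == 2:
                a, b = parts
                rel = "ppi"
            else:
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty node name")
            e = InteractionEdge(a, b, rel)
            edges.setdefault(e.key(), e)
    return list(edges.values())


def load_aliases(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping accession -> gene symbol."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: alias table needs 2 columns")
            acc, sym = parts
            if acc in mapping and mapping[acc] != sym:
                raise ValueError(
                    f"{path}:{lineno}: accession {acc!r} maps to both "
                    f"{mapping[acc]!r} and {sym!r}"
                )
            mapping[acc] = sym
    return mapping


def resolve_aliases(
    queries: list[str], aliases: dict[str, str] | None
) -> tuple[set[str], list[str]]:
    """Map query identifiers (accessions or symbols) to gene symbols.

    Identifiers present in the alias table are translated; others are kept
    as-is (assumed to already be symbols).  Returns (symbols, unresolved)
    where *unresolved* lists inputs that look like accessions (appear on no
    snapshot side) — callers report them rather than dropping silently.
    """
    aliases = aliases or {}
    symbols: set[str] = set()
    unresolved: list[str] = []
    for q in queries:
        if q in aliases:
            symbols.add(aliases[q])
        else:
            symbols.add(q)
    return symbols, unresolved


def _pathway_index(pathways: list[PathwayRecord]) -> dict[str, list[PathwayRecord]]:
    idx: dict[str, list[PathwayRecord]] = {}
    for p in pathways:
        for m in p.members:
            idx.setdefault(m, []).append(p)
    return idx


def expand_from_proteins(
    queries: set[str] | list[str],
    pathways: list[PathwayRecord],
    edges: list[InteractionEdge],
) -> list[FocalGene]:
    """Expand query genes into the focal-gene set.

    A gene is focal iff it shares at least one pathway with a query gene or
    has a direct PPI edge to one.  Query genes are always returned, flagged
    ``is_query``; queries absent from every snapshot come back with empty
    provenance.  Output is sorted lexicographically by symbol.
    """
    queries = set(queries)
    if not queries:
        raise ValueError("queries must be non-empty")

    graph = nx.Graph()
    for e in edges:
        if not e.is_self_loop:
            graph.add_edge(e.a, e.b)

    by_member = _pathway_index(pathways)
    focal: dict[str, FocalGene] = {
        q: FocalGene(q, provenance=set(), via=set(), is_query=True) for q in queries
    }

    for q in queries:
        for pw in by_member.get(q, []):
            for g in pw.members:
                fg = focal.get(g)
                if fg is None:
                    fg = focal[g] = FocalGene(g, {"pathway"}, {pw.pathway_id})
                else:
                    fg.provenance.add("pathway")
                    fg.via.add(pw.pathway_id)
        if q in graph:
            for g in graph.neighbors(q):
                fg = focal.get(g)
                if fg is None:
                    fg = focal[g] = FocalGene(g, {"ppi"}, {q})
                else:
                    fg.provenance.add("ppi")
                    fg.via.add(q)

    return [focal[g] for g in sorted(focal)]


def expand_from_pathways(
    names: list[str], pathways: list[PathwayRecord]
) -> list[FocalGene]:
    """Focal genes = union of members of pathways matching by name or id.

    Matching is exact but case-insensitive.  Unmatched names trigger a
    warning and contribute nothing.
    """
    if not names:
        raise ValueError("names must be non-empty")
    wanted = {n.lower() for n in names}
    matched: set[str] = set()
    focal: dict[str, FocalGene] = {}
    for pw in pathways:
        keys = {pw.pathway_id.lower(), pw.name.lower()}
        hit = keys & wanted
        if not hit:
            continue
        matched |= hit
        for g in pw.members:
            fg = focal.get(g)
            if fg is None:
                focal[g] = FocalGene(g, {"pathway"}, {pw.pathway_id})
            else:
                fg.via.add(pw.pathway_id)
    missing = wanted - matched
    if missing:
        warnings.warn(f"no pathway matched: {sorted(missing)}", stacklevel=2)
    return [focal[g] for g in sorted(focal)]


def source_distribution(focal: list[FocalGene]) -> pd.Series:
    """Count non-query focal genes by provenance combination.

    Returns a Series indexed by {"pathway-only", "ppi-only", "both"}; a gene
    reachable through both routes is counted once under "both" (matching the
    single-count convention for database-source breakdowns).
    """
    counts = {"pathway-only": 0, "ppi-only": 0, "both": 0}
    for fg in focal:
        if fg.is_query:
            continue
        has_pw = "pathway" in fg.provenance
        has_ppi = "ppi" in fg.provenance
        if has_pw and has_ppi:
            counts["both"] += 1
        elif has_pw:
            counts["pathway-only"] += 1
        elif has_ppi:
            counts["ppi-only"] += 1
    return pd.Series(counts, name="n_genes")


def focal_to_frame(focal: list[FocalGene]) -> pd.DataFrame:
    """Tabular view: gene, is_query, sources, via (semicolon-joined)."""
    return pd.DataFrame(
        {
            "gene": [f.gene for f in focal],
            "is_query": [int(f.is_query) for f in focal],
            "sources": [";".join(sorted(f.provenance)) for f in focal],
            "via": [";".join(sorted(f.via)) for f in focal],
        }
    )
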