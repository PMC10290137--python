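"""Parsing, ortholog mapping and merging of PPI edge tables.

Two tab-separated input dialects are supported: a BioGRID-tab-like table
(named symbol and organism columns) and a MITAB-2.5-like table (15 fields,
``uniprotkb:`` prefixed identifiers, ``taxid:NNNN(name)`` organism fields).
Records from any species are mapped into human identifier space through an
ortholog table and merged into one deduplicated undirected edge set with
per-edge source provenance. Inter-species records (different taxa on the
two sides) are retained and flagged.

Identifier handling is deliberately minimal: one canonical identifier per
endpoint, no alias resolution beyond the ortholog map. Self-loops are
dropped at merge time because the downstream topology statistics assume a
simple graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from epinet.errors import FormatError

__all__ = [
    "PPIRecord",
    "RejectedLine",
    "ParseResult",
    "OrthologMap",
    "MergedPPIDatabase",
    "read_biogrid_tab",
    "read_mitab",
    "read_orthologs",
    "map_to_human",
    "merge",
]

logger = logging.getLogger(__name__)

HUMAN_TAXON = 9606


@dataclass(frozen=True)
class PPIRecord:
    """One raw interaction record as parsed from an input file."""

    id_a: str
    id_b: str
    taxon_a: int
    taxon_b: int
    source: str  # "biogrid_like" | "mitab_like"
    raw_line_no: int

    @property
    def inter_species(self) -> bool:
        return self.taxon_a != self.taxon_b


class RejectedLine(NamedTuple):
    line_no: int
    reason: str
    text: str


class ParseResult(NamedTuple):
    records: list[PPIRecord]
    rejects: list[RejectedLine]


_BIOGRID_COLS = {
    "id_a": "Official Symbol Interactor A",
    "id_b": "Official Symbol Interactor B",
    "taxon_a": "Organism Interactor A",
    "taxon_b": "Organism Interactor B",
}


def read_biogrid_tab(path: str | Path) -> ParseResult:
    """Parse a BioGRID-tab-like file.

    Malformed data lines (wrong field count, empty IDs, non-integer taxa)
    are collected into the rejects report rather than raised; a header
    missing a mandatory column is a :class:`FormatError`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        return ParseResult([], [])
    header = [h.lstrip("#") for h in lines[0].split("\t")]
    idx = {}
    for key, col in _BIOGRID_COLS.items():
        if col not in header:
            raise FormatError(f"missing mandatory column '{col}' in {path.name}")
        idx[key] = header.index(col)
    records: list[PPIRecord] = []
    rejects: list[RejectedLine] = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            rejects.append(RejectedLine(line_no, "wrong field count", line))
            continue
        id_a, id_b = fields[idx["id_a"]].strip(), fields[idx["id_b"]].strip()
        if not id_a or not id_b:
            rejects.append(RejectedLine(line_no, "empty interactor ID", line))
            continue
        try:
            taxon_a = int(fields[idx["taxon_a"]])
            taxon_b = int(fields[idx["taxon_b"]])
        except ValueError:
            rejects.append(RejectedLine(line_no, "non-integer taxon", line))
            continue
        if taxon_a <= 0 or taxon_b <= 0:
            rejects.append(RejectedLine(line_no, "non-positive taxon", line))
            continue
        records.append(PPIRecord(id_a, id_b, taxon_a, taxon_b, "biogrid_like", line_no))
    return ParseResult(records, rejects)


def _strip_prefix(raw: str) -> str:
    return raw.split(":", 1)[1] if ":" in raw else raw


def _parse_taxid(raw: str) -> int:
    # "taxid:9606(Homo sapiens)" -> 9606
    if not raw.startswith("taxid:"):
        raise ValueError(f"not a taxid field: {raw!r}")
    body = raw[len("taxid:"):]
    body = body.split("(", 1)[0]
    return int(body)


def read_mitab(path: str | Path) -> ParseResult:
    """Parse a MITAB-2.5-like file (15 tab-separated fields, no header).

    Identifier prefixes (``uniprotkb:``) are stripped; organism fields are
    parsed from ``taxid:NNNN(...)``. Inter-species lines are retained (the
    record's ``inter_species`` flag distinguishes them).
    """
    path = Path(path)
    records: list[PPIRecord] = []
    rejects: list[RejectedLine] = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            rejects.append(RejectedLine(line_no, "fewer than 11 MITAB fields", line))
            continue
        id_a = _strip_prefix(fields[0].strip())
        id_b = _strip_prefix(fields[1].strip())
        if not id_a or not id_b or id_a == "-" or id_b == "-":
            rejects.append(RejectedLine(line_no, "empty interactor ID", line))
            continue
        try:
            taxon_a = _parse_taxid(fields[9].strip())
            taxon_b = _parse_taxid(fields[10].strip())
        except ValueError:
            rejects.append(RejectedLine(line_no, "unparseable taxid field", line))
            continue
        if taxon_a <= 0 or taxon_b <= 0:
            rejects.append(RejectedLine(line_no, "non-positive taxon", line))
            continue
        records.append(PPIRecord(id_a, id_b, taxon_a, taxon_b, "mitab_like", line_no))
    return ParseResult(records, rejects)


@dataclass
class OrthologMap:
    """(source_id, source_taxon) -> human identifier.

    Human identifiers map to themselves implicitly; the table only needs to
    cover foreign records.
    """

    mapping: dict[tuple[str, int], str] = field(default_factory=dict)
    provenance: str = ""

    def to_human(self, protein_id: str, taxon: int) -> str | None:
        if taxon == HUMAN_TAXON:
            return protein_id
        return self.mapping.get((protein_id, taxon))


def read_orthologs(path: str | Path) -> OrthologMap:
    """Read an ortholog TSV with columns source_id, source_taxid, human_id."""
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "human_id": str})
    for col in ("source_id", "source_taxid", "human_id"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column '{col}' in ortholog table")
    mapping = {
        (row.source_id, int(row.source_taxid)): row.human_id
        for row in df.itertuples()
    }
    return OrthologMap(mapping, provenance=str(path))


def map_to_human(
    records: Iterable[PPIRecord], orthologs: OrthologMap
) -> tuple[list[PPIRecord], list[PPIRecord]]:
    """Replace foreign endpoints by their human orthologs.

    Records with any endpoint lacking an ortholog are dropped into the
    unmapped report (second return value); they are never raised. Human
    records pass through unchanged; ``|mapped| + |unmapped| = |input|``.
    """
    mapped: list[PPIRecord] = []
    unmapped: list[PPIRecord] = []
    for rec in records:
        h_a = orthologs.to_human(rec.id_a, rec.taxon_a)
        h_b = orthologs.to_human(rec.id_b, rec.taxon_b)
        if h_a is None or h_b is None:
            unmapped.append(rec)
            continue
        mapped.append(
            PPIRecord(h_a, h_b, HUMAN_TAXON, HUMAN_TAXON, rec.source, rec.raw_line_no)
        )
    return mapped, unmapped


class MergedPPIDatabase:
    """Deduplicated undirected edge set over human IDs with provenance."""

    def __init__(self, edges: dict[tuple[str, str], set[str]] | None = None):
        self._edges: dict[tuple[str, str], set[str]] = edges or {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, id_a: str, id_b: str, source: str) -> None:
        if id_a == id_b:
            return  # self-loops have no meaning in the simple-graph analyses
        self._edges.setdefault(self._key(id_a, id_b), set()).add(source)

    @property
    def edges(self) -> dict[tuple[str, str], set[str]]:
        return self._edges

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._edges:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._edges

    def neighbors(self, protein_id: str) -> set[str]:
        out = set()
        for a, b in self._edges:
            if a == protein_id:
                out.add(b)
            elif b == protein_id:
                out.add(a)
        return out

    def get_interactors(self, query_ids: set[str]) -> set[str]:
        """Union of the neighbors of the query set, minus the queries.

        Unknown query IDs contribute nothing (logged, not raised)."""
        known = self.nodes
        for q in query_ids:
            if q not in known:
                logger.warning("query ID %s not present in the PPI database", q)
        partners: set[str] = set()
        for a, b in self._edges:
            if a in query_ids:
                partners.add(b)
            if b in query_ids:
                partners.add(a)
        return partners - set(query_ids)

    # --- serialization ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = ["id_a\tid_b\tprovenance"]
        for (a, b), sources in sorted(self._edges.items()):
            lines.append(f"{a}\t{b}\t{'|'.join(sorted(sources))}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MergedPPIDatabase":
        db = cls()
        lines = Path(path).read_text().splitlines()
        if not lines:
            return db
        header = lines[0].split("\t")
        if header[:3] != ["id_a", "id_b", "provenance"]:
            raise FormatError("merged PPI table must have columns id_a, id_b, provenance")
        for line in lines[1:]:
            if not line.strip():
                continue
            a, b, prov = line.split("\t")[:3]
            for source in prov.split("|"):
                db.add(a, b, source)
        return db


def merge(*record_lists: Iterable[PPIRecord]) -> MergedPPIDatabase:
    """Merge human-mapped records into one deduplicated database.

    Unordered-pair deduplication across sources; self-loops dropped;
    provenance is the union of contributing sources. Order-independent and
    idempotent.
    """
    db = MergedPPIDatabase()
    for records in record_lists:
        for rec in records:
            db.add(rec.id_a, rec.id_b, rec.source)
    return db
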