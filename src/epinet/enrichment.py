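"""Gene-set over-representation analysis with optional set hierarchy.

Each gene set in a GMT collection is tested for over-representation in a
query list by a one-sided Fisher's exact test on the 2x2 table
(in-set & in-query, in-set & not, in-query & not, neither), all counts
taken inside an explicit background universe. P-values are adjusted across
sets by Benjamini-Hochberg. Reactome-style ratios are reported alongside:
``entities_ratio`` (set size / background size) and ``found_ratio``
(overlap / query size).

When a parent->child set hierarchy is supplied, results can be rolled up
into a tree: every hierarchy node carries its own enrichment (or is marked
``empty`` when no query member maps to it — the "borderless node"
semantic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epinet.errors import ConfigError, FormatError, StructuralError

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "read_hierarchy",
    "enrich",
    "hierarchy_rollup",
]


@dataclass
class GeneSetCollection:
    """Named member-ID sets, optional descriptions and hierarchy edges."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    hierarchy: list[tuple[str, str]] = field(default_factory=list)  # (parent, child)
    rejected: list[str] = field(default_factory=list)  # names of empty sets

    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, members; tab-separated).

    Duplicate members within a set are collapsed; sets with no (non-blank)
    members are recorded in ``rejected`` rather than kept; a line with
    fewer than 3 fields raises a :class:`FormatError` naming the line.
    """
    coll = GeneSetCollection()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {line_no}: expected >= 3 tab-separated fields")
        name, desc = fields[0], fields[1]
        members = frozenset(m for m in fields[2:] if m.strip())
        if not members:
            coll.rejected.append(name)
            continue
        coll.sets[name] = members
        coll.descriptions[name] = desc
    return coll


def read_hierarchy(path: str | Path) -> list[tuple[str, str]]:
    """Read parent-child hierarchy edges from a two-column TSV."""
    edges = []
    lines = Path(path).read_text().splitlines()
    for line_no, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"hierarchy line {line_no}: expected parent<TAB>child")
        if line_no == 1 and fields[0] == "parent":
            continue
        edges.append((fields[0], fields[1]))
    return edges


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str] | None = None,
) -> pd.DataFrame:
    """Over-representation of the query in every set of the collection.

    ``background`` defaults to the union of all set members plus the
    query. Query members outside the background are dropped with a
    warning; each set is intersected with the background before testing.
    Results are sorted by FDR, then p-value, then set name.
    """
    if background is None:
        background = collection.universe() | set(query)
    if not background:
        raise ConfigError("background universe is empty")
    stray = set(query) - set(background)
    if stray:
        warnings.warn(
            f"{len(stray)} query IDs outside the background were dropped"
        )
    query_bg = set(query) & set(background)

    rows = []
    n_bg = len(background)
    n_query = len(query_bg)
    for name in sorted(collection.sets):
        members = collection.sets[name] & background
        overlap = members & query_bg
        k = len(overlap)
        table = [
            [k, len(members) - k],
            [n_query - k, n_bg - len(members) - (n_query - k)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(members),
                "query_size": n_query,
                "background_size": n_bg,
                "entities_ratio": len(members) / n_bg,
                "found_ratio": k / n_query if n_query else 0.0,
                "p_value": float(p),
                "overlap_ids": "|".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["fdr", "p_value", "set_name"]).reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    cols = ["set_name", "overlap", "set_size", "query_size", "background_size",
            "entities_ratio", "found_ratio", "p_value", "fdr", "overlap_ids"]
    return df[cols]


def hierarchy_rollup(results: pd.DataFrame, collection: GeneSetCollection) -> list[dict]:
    """Arrange per-set results as a parent->child tree.

    Every hierarchy node is annotated with its own enrichment numbers, or
    marked ``empty`` (zero overlap or never tested) — the semantic of a
    borderless node in a pathway-map figure. With no hierarchy edges the
    result is a flat one-level tree over all tested sets. A cyclic
    hierarchy raises a :class:`StructuralError`.
    """
    by_name = {r["set_name"]: r for r in results.to_dict("records")}
    children: dict[str, list[str]] = {}
    indegree: dict[str, int] = {}
    node_names: set[str] = set(by_name)
    for parent, child in collection.hierarchy:
        children.setdefault(parent, []).append(child)
        indegree[child] = indegree.get(child, 0) + 1
        node_names.update((parent, child))

    # cycle check: Kahn's algorithm over the hierarchy edges
    if collection.hierarchy:
        pending = dict(indegree)
        queue = [n for n in sorted(node_names) if pending.get(n, 0) == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for c in children.get(node, []):
                pending[c] -= 1
                if pending[c] == 0:
                    queue.append(c)
        if seen != len(node_names):
            raise StructuralError("hierarchy contains a cycle")

    def build(name: str) -> dict:
        rec = by_name.get(name)
        node = {
            "name": name,
            "empty": rec is None or rec["overlap"] == 0,
            "overlap": int(rec["overlap"]) if rec else 0,
            "p_value": float(rec["p_value"]) if rec else None,
            "fdr": float(rec["fdr"]) if rec else None,
            "children": [build(c) for c in sorted(children.get(name, []))],
        }
        return node

    roots = sorted(n for n in node_names if indegree.get(n, 0) == 0)
    return [build(r) for r in roots]


def count_rollup_nodes(tree: list[dict]) -> int:
    """Number of nodes in a rollup tree (traversal helper)."""
    total = 0
    stack = list(tree)
    while stack:
        node = stack.pop()
        total += 1
        stack.extend(node["children"])
    return total
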