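"""Gene Ontology level-collapse annotation.

Direct GO annotations of a gene are sparse and heterogeneous in depth.  To
turn them into a compact per-gene scheme, each gene's terms are first
expanded upward through the ``is_a`` hierarchy (ancestor closure, root
included); then, at each hierarchical level, the candidate terms are
collapsed by keeping only the one most frequent across the whole gene
corpus being processed (ties to the lexicographically smallest GO id).
The result assigns every gene at most one term per level, which can be
joined onto a region table (up to five levels) after a nearest-TSS search.

The level of a term is the length of the shortest ``is_a`` path to its
namespace root (root = level 0); a longest-path variant is available via
``method="longest"`` since GO depth is sometimes defined that way.  Only
``is_a`` edges are used — the go-basic release is acyclic over those.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import networkx as nx
import pandas as pd

from .regions import RegionTable

__all__ = [
    "GoDag",
    "GeneAnnotation",
    "parse_obo",
    "term_levels",
    "expand_annotations",
    "collapse_scheme",
    "annotate_table_go",
    "load_gene_annotations",
]

MAX_GO_LEVELS = 5

_NAMESPACE_CATEGORY = {
    "molecular_function": "Function",
    "biological_process": "Process",
    "cellular_component": "Component",
}


@dataclass
class GoDag:
    """GO term hierarchy restricted to ``is_a`` edges.

    ``terms`` maps id -> (name, namespace); ``parents`` maps child id ->
    set of parent ids; ``roots`` maps namespace -> root term id.
    """

    terms: dict[str, tuple[str, str]]
    parents: dict[str, set[str]]
    roots: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            if child not in self.terms:
                raise ValueError(f"edge child {child} is not a known term")
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"edge parent {p} is not a known term")
        g = nx.DiGraph((c, p) for c, ps in self.parents.items() for p in ps)
        g.add_nodes_from(self.terms)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"is_a cycle detected involving term {cycle[0][0]}")
        if not self.roots:
            for tid, (_, ns) in sorted(self.terms.items()):
                if not self.parents.get(tid):
                    self.roots.setdefault(ns, tid)

    def children(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                out[p].add(child)
        return out

    def ancestors(self, term: str) -> set[str]:
        """All ``is_a`` ancestors of ``term`` (term itself excluded)."""
        seen: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents.get(t, ()))
        return seen

    def name_of(self, term: str) -> str:
        return self.terms[term][0]


GeneAnnotation = Mapping[str, set[str]]  # gene -> directly annotated term ids


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2 file (go-basic style) into a :class:`GoDag`.

    Only the id / name / namespace / is_a / is_obsolete tags are used;
    obsolete terms are skipped; relationship edges other than ``is_a`` are
    ignored.  A cycle among is_a edges raises, naming one member.
    """
    import obonet

    graph = obonet.read_obo(str(path))  # skips obsolete terms by default
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", ""))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    # drop edges pointing at terms pruned as obsolete
    parents = {c: {p for p in ps if p in terms} for c, ps in parents.items() if c in terms}
    return GoDag(terms=terms, parents=parents)


def term_levels(dag: GoDag, method: Literal["shortest", "longest"] = "shortest") -> dict[str, int]:
    """Hierarchical level of every term (root = 0).

    ``shortest`` (default): length of the shortest is_a path to the
    namespace root.  ``longest``: length of the longest such path.  A term
    that cannot reach any root raises.
    """
    children = dag.children()
    levels: dict[str, int] = {}
    if method == "shortest":
        for root in dag.roots.values():
            queue = deque([(root, 0)])
            while queue:
                term, lvl = queue.popleft()
                if term in levels and levels[term] <= lvl:
                    continue
                levels[term] = lvl
                for ch in children[term]:
                    queue.append((ch, lvl + 1))
    else:
        g = nx.DiGraph((c, p) for c, ps in dag.parents.items() for p in ps)
        g.add_nodes_from(dag.terms)
        for term in nx.topological_sort(g.reverse()):  # roots first
            ps = dag.parents.get(term)
            if not ps:
                levels[term] = 0
            else:
                reachable = [levels[p] for p in ps if p in levels]
                if reachable:
                    levels[term] = max(reachable) + 1
    unreachable = set(dag.terms) - set(levels)
    if unreachable:
        raise ValueError(f"term(s) unreachable from any root: {sorted(unreachable)[:3]}")
    return levels


def expand_annotations(ann: GeneAnnotation, dag: GoDag) -> dict[str, set[str]]:
    """Ancestor closure of each gene's direct annotations (roots included)."""
    cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in cache:
            cache[term] = {term} | dag.ancestors(term)
        return cache[term]

    out: dict[str, set[str]] = {}
    for gene, terms in ann.items():
        expanded: set[str] = set()
        for t in terms:
            if t not in dag.terms:
                raise KeyError(f"gene {gene} annotated to unknown term {t}")
            expanded |= closure(t)
        out[gene] = expanded
    return out


def collapse_scheme(
    expanded: Mapping[str, set[str]],
    dag: GoDag,
    max_level: int = MAX_GO_LEVELS,
    level_method: Literal["shortest", "longest"] = "shortest",
) -> dict[str, dict[int, str]]:
    """Collapse expanded annotations to one term per gene per level.

    The corpus frequency ``f(t)`` is the number of genes whose expanded
    set contains ``t``.  For each gene and level 1..max_level, the
    candidate terms are its expanded terms at that level and the one with
    the highest corpus frequency wins (ties to the smallest GO id).  A
    level with no candidates gets no assignment.  The result is
    independent of gene input order.
    """
    if not expanded:
        raise ValueError("expanded annotation set is empty")
    levels = term_levels(dag, method=level_method)
    freq: Counter[str] = Counter()
    for terms in expanded.values():
        freq.update(terms)
    scheme: dict[str, dict[int, str]] = {}
    for gene in sorted(expanded):
        by_level: dict[int, str] = {}
        for lvl in range(1, max_level + 1):
            candidates = [t for t in expanded[gene] if levels[t] == lvl]
            if candidates:
                by_level[lvl] = max(candidates, key=lambda t: (freq[t], _neg_lex(t)))
        scheme[gene] = by_level
    return scheme


def _neg_lex(term: str):
    """Sort key making the lexicographically smallest id win a max()."""
    return tuple(-ord(c) for c in term)


def annotate_table_go(
    table: RegionTable,
    gene_column: str,
    scheme: Mapping[str, Mapping[int, str]],
    dag: GoDag,
    levels: int = 3,
) -> RegionTable:
    """Join the simplified GO scheme onto a region table.

    Adds text columns ``go_level_1 .. go_level_<levels>`` holding term
    *names* looked up via ``gene_column`` (typically the accession from a
    nearest-TSS annotation).  Genes absent from the scheme get missing
    values.  At most five levels may be requested.
    """
    if not (1 <= levels <= MAX_GO_LEVELS):
        raise ValueError(f"levels must be between 1 and {MAX_GO_LEVELS}")
    if not table.has_column(gene_column):
        raise KeyError(f"no column named {gene_column!r}")
    genes = table.df[gene_column]
    for lvl in range(1, levels + 1):
        vals = []
        for g in genes:
            entry = scheme.get(g) if isinstance(g, str) else None
            term = entry.get(lvl) if entry else None
            vals.append(dag.name_of(term) if term else None)
        table.df[f"go_level_{lvl}"] = pd.array(vals, dtype=object)
    return table


def load_gene_annotations(
    gene2go_path: str | Path,
    gene2refseq_path: str | Path,
    dag: GoDag,
    namespace: str = "molecular_function",
) -> dict[str, set[str]]:
    """Join NCBI gene2go and gene2refseq tables into refseq -> GO term sets.

    Both files are tab-separated with ``#``-prefixed header/comment lines.
    gene2go supplies GeneID -> GO id (filtered to the requested namespace
    via its Category column); gene2refseq supplies GeneID -> RNA accession
    (version suffix stripped).  Terms absent from the DAG are dropped.
    """
    category = _NAMESPACE_CATEGORY.get(namespace)
    if category is None:
        raise ValueError(f"unknown namespace {namespace!r}")
    go_by_gene: dict[str, set[str]] = {}
    with open(gene2go_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene_id, go_id, cat = parts[1], parts[2], parts[7]
            if cat == category and go_id in dag.terms:
                go_by_gene.setdefault(gene_id, set()).add(go_id)
    ann: dict[str, set[str]] = {}
    with open(gene2refseq_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene_id, rna_acc = parts[1], parts[3]
            if rna_acc == "-" or gene_id not in go_by_gene:
                continue
            acc = rna_acc.split(".")[0]
            ann.setdefault(acc, set()).update(go_by_gene[gene_id])
    return ann
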