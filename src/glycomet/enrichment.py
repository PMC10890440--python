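"""Pathway over-representation analysis with a topology-based impact score.

Hits (e.g. members of a differentially connected module) are tested against
a known-metabolite background with a one-sided Fisher's exact
(hypergeometric) test per pathway. Each pathway additionally carries an
impact score: node importances are relative betweenness centralities of
the pathway's compound graph (normalized to sum to 1, uniform when every
centrality is 0), and the impact is the share of total importance carried
by the hit compounds.

Pathway definitions are plain text: a GMT file for membership and a
three-column TSV (pathway_id, node_a, node_b) for the undirected edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataError


@dataclass
class PathwayGraph:
    pathway_id: str
    name: str
    nodes: frozenset[str]
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        self.nodes = frozenset(_fold(n) for n in self.nodes)
        if not self.nodes:
            raise DataError(f"pathway {self.pathway_id}: empty node set")
        folded = []
        for a, b in self.edges:
            a, b = _fold(a), _fold(b)
            if a == b:
                raise DataError(f"pathway {self.pathway_id}: self-loop at {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise DataError(
                    f"pathway {self.pathway_id}: edge ({a}, {b}) references unknown node")
            folded.append((a, b))
        self.edges = tuple(folded)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(self.edges)
        return g


def _fold(s: str) -> str:
    return str(s).strip().casefold()


def load_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file: id <tab> description <tab> member ids... Duplicate
    members within a set are dropped (set semantics)."""
    out: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        pid, name, members = parts[0], parts[1], parts[2:]
        seen: list[str] = []
        for m in members:
            fm = _fold(m)
            if fm and fm not in seen:
                seen.append(fm)
        out[pid] = (name, seen)
    return out


def load_edges(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Parse the per-pathway edge list TSV (pathway_id, node_a, node_b)."""
    out: dict[str, list[tuple[str, str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 3:
            raise DataError(f"malformed edge line: {line[:60]!r}")
        out.setdefault(parts[0], []).append((parts[1], parts[2]))
    return out


def load_pathway_db(gmt_path: str | Path, edges_path: str | Path | None = None,
                    ) -> dict[str, PathwayGraph]:
    gmt = load_gmt(gmt_path)
    if not gmt:
        raise DataError("empty pathway database")
    edges = load_edges(edges_path) if edges_path else {}
    return {
        pid: PathwayGraph(pid, name, frozenset(members), tuple(edges.get(pid, ())))
        for pid, (name, members) in gmt.items()
    }


# ---------------------------------------------------------------------------


def fisher_enrichment(hits, pathway_nodes, background) -> float:
    """One-sided over-representation p: the hypergeometric probability of
    observing at least the seen overlap, on the 2x2 table restricted to
    background compounds."""
    hits = {_fold(h) for h in hits}
    background = {_fold(b) for b in background}
    if not hits <= background:
        raise DataError(f"hits outside background: {sorted(hits - background)[:5]}")
    pw = {_fold(n) for n in pathway_nodes} & background
    k = len(hits & pw)
    if k == 0:
        return 1.0
    # P(X >= k), X ~ Hypergeom(N=|bg|, K=|pathway in bg|, n=|hits|)
    return float(stats.hypergeom.sf(k - 1, len(background), len(pw), len(hits)))


def betweenness_importance(graph: PathwayGraph) -> dict[str, float]:
    """Relative node importance: betweenness centrality (shortest-path count
    form, per connected component) normalized to sum to 1 over the pathway;
    uniform 1/|nodes| when every centrality is 0."""
    g = graph.graph()
    bc = nx.betweenness_centrality(g, normalized=False)
    total = sum(bc.values())
    n = g.number_of_nodes()
    if total <= 0:
        return {v: 1.0 / n for v in g.nodes}
    return {v: c / total for v, c in bc.items()}


def impact_score(hits, graph: PathwayGraph) -> float:
    """Share of the pathway's total topological importance carried by the
    hit compounds (importances already sum to 1)."""
    imp = betweenness_importance(graph)
    hits = {_fold(h) for h in hits}
    return float(sum(w for v, w in imp.items() if v in hits))


def run_enrichment(
    hits,
    pathway_db: dict[str, PathwayGraph],
    background,
) -> tuple[pd.DataFrame, list[str]]:
    """Score every pathway with >= 1 background member.

    Returns (table sorted by Fisher p, unmatched hits). Compounds are
    matched by exact identifier after case-folding; hits absent from every
    pathway are listed, never silently dropped. An optional BH column is
    provided since pathway p-values are reported raw by default.
    """
    if not pathway_db:
        raise DataError("empty pathway database")
    background = {_fold(b) for b in background}
    if not background:
        raise DataError("empty background")
    hits = [_fold(h) for h in hits]
    bg_hits = [h for h in hits if h in background]
    if len(bg_hits) < len(hits):
        raise DataError(
            f"hits outside background: {sorted(set(hits) - background)[:5]}")

    all_pathway_nodes: set[str] = set()
    rows = []
    for pid, pw in sorted(pathway_db.items()):
        all_pathway_nodes |= pw.nodes
        in_bg = pw.nodes & background
        if not in_bg:
            continue
        overlap = set(bg_hits) & pw.nodes
        rows.append({
            "pathway": pid,
            "name": pw.name,
            "size": len(pw.nodes),
            "n_in_background": len(in_bg),
            "overlap": len(overlap),
            "fisher_p": fisher_enrichment(bg_hits, pw.nodes, background),
            "impact": impact_score(overlap, pw) if overlap else 0.0,
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        from statsmodels.stats.multitest import multipletests

        table["bh_p"] = multipletests(table["fisher_p"], method="fdr_bh")[1]
        table = table.sort_values(
            ["fisher_p", "pathway"], kind="mergesort").reset_index(drop=True)
    unmatched = sorted(set(bg_hits) - all_pathway_nodes)
    return table, unmatched
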