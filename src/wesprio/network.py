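"""Dual-network protein-interaction node scoring and combined gene ranking.

Two PPI networks are built from the same weighted edge list under different
gene memberships (e.g. group 1: collapsing candidates + reference genes with
rare variants; group 2: collapsing candidates + association-derived pathway
genes).  Within each group, edges with confidence score strictly above a
threshold (0.4 = medium confidence) and both endpoints inside the group are
retained; a gene's node count is its number of distinct retained interactors
and its total score the sum of retained edge scores.  The two groups are
then averaged per gene, an absent group contributing zero but still dividing
by two, and genes are ranked by the combined total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class PPIEdge:
    """Undirected confidence-weighted interaction, stored canonically ordered."""

    gene_a: str
    gene_b: str
    combined_score: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a}")
        if not (0.0 <= self.combined_score <= 1.0):
            raise ValueError(f"combined_score must be in [0,1], got {self.combined_score}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class GroupNodeScore:
    gene: str
    n_nodes: int
    total_score: float

    @property
    def mean_score(self) -> float | None:
        return self.total_score / self.n_nodes if self.n_nodes else None


@dataclass(frozen=True)
class CombinedNodeRank:
    gene: str
    group1: GroupNodeScore | None
    group2: GroupNodeScore | None

    @property
    def combined_total(self) -> float:
        t1 = self.group1.total_score if self.group1 else 0.0
        t2 = self.group2.total_score if self.group2 else 0.0
        return (t1 + t2) / 2.0

    @property
    def combined_nodes(self) -> float:
        n1 = self.group1.n_nodes if self.group1 else 0
        n2 = self.group2.n_nodes if self.group2 else 0
        return (n1 + n2) / 2.0

    def row(self) -> dict:
        def g(grp, attr):
            return getattr(grp, attr) if grp else None
        return {
            "gene": self.gene,
            "n_nodes_1": g(self.group1, "n_nodes"),
            "total_1": g(self.group1, "total_score"),
            "mean_1": g(self.group1, "mean_score"),
            "n_nodes_2": g(self.group2, "n_nodes"),
            "total_2": g(self.group2, "total_score"),
            "mean_2": g(self.group2, "mean_score"),
            "combined_total": self.combined_total,
            "combined_nodes": self.combined_nodes,
        }


def _dedupe(edges: Iterable[PPIEdge]) -> dict[tuple[str, str], float]:
    """Canonical undirected storage; a duplicated pair keeps the first score."""
    seen: dict[tuple[str, str], float] = {}
    for e in edges:
        seen.setdefault(e.pair, e.combined_score)
    return seen


def node_scores(
    edges: Iterable[PPIEdge],
    members: Iterable[str],
    threshold: float = 0.4,
) -> dict[str, GroupNodeScore]:
    """Per-member node count and score total in the thresholded induced subgraph.

    Edges are kept iff score strictly exceeds ``threshold`` and both
    endpoints are members.  Members retaining no edge are omitted (they have
    no presence in this group's network).
    """
    members = set(members)
    g = nx.Graph()
    for (a, b), score in _dedupe(edges).items():
        if score > threshold and a in members and b in members:
            g.add_edge(a, b, score=score)
    out = {}
    for gene in g.nodes:
        nbrs = list(g.neighbors(gene))
        total = sum(g.edges[gene, nb]["score"] for nb in nbrs)
        out[gene] = GroupNodeScore(gene=gene, n_nodes=len(nbrs), total_score=total)
    return out


def combine_groups(
    g1: Mapping[str, GroupNodeScore],
    g2: Mapping[str, GroupNodeScore],
) -> list[CombinedNodeRank]:
    """Average the two group scores per gene and rank.

    Ranking is by combined total descending, ties by combined node count
    descending, then gene symbol — a deterministic total order.
    """
    ranks = [
        CombinedNodeRank(gene=gene, group1=g1.get(gene), group2=g2.get(gene))
        for gene in set(g1) | set(g2)
    ]
    ranks.sort(key=lambda r: (-r.combined_total, -r.combined_nodes, r.gene))
    return ranks


def prioritize(
    ranked: Sequence[CombinedNodeRank],
    burden_results: Iterable = (),
    panel_genes: Iterable[str] = (),
    k: int = 10,
) -> pd.DataFrame:
    """Top-k report: combined network scores with burden evidence attached.

    Genes from the reference panel are flagged separately — the route by
    which a reference gene absent from the collapsing candidates can still
    be admitted to the final list.
    """
    burden_p: dict[str, dict[str, float]] = {}
    for r in burden_results:
        burden_p.setdefault(r.gene, {})[r.stratum] = r.p_value
    panel = set(panel_genes)
    rows = []
    for rank, r in enumerate(ranked[:k], start=1):
        row = {
            "rank": rank, "gene": r.gene,
            "combined_total": r.combined_total,
            "combined_nodes": r.combined_nodes,
            "from_reference_panel": r.gene in panel,
        }
        for stratum, p in sorted(burden_p.get(r.gene, {}).items()):
            row[f"burden_p[{stratum}]"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def ranking_table(ranked: Sequence[CombinedNodeRank]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in ranked])
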