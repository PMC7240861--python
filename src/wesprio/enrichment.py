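"""Hypergeometric pathway over-representation with rich factor.

For an input gene list drawn from a background universe of size M, a pathway
with K background members, and an overlap of k genes out of n input genes,
the enrichment p-value is the upper hypergeometric tail P(X >= k).  The
*rich factor* is k / K, the fraction of the pathway hit by the input list.
Multiplicity correction defaults to Benjamini-Hochberg and is recorded in
the output, since over-representation services differ in both background
and correction method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayGeneSet:
    set_id: str
    name: str
    genes: frozenset[str]
    # not persisted by GMT, hence excluded from equality
    source: str = field(default="reactome", compare=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    input_number: int          # overlap count k
    background_number: int     # pathway size within the background, K
    p_value: float
    corrected_p: float
    rich_factor: float         # k / K
    overlap_genes: tuple[str, ...]
    correction_method: str = "bh"

    def row(self) -> dict:
        return {
            "set_id": self.set_id, "name": self.name,
            "input_number": self.input_number,
            "background_number": self.background_number,
            "p_value": self.p_value, "corrected_p": self.corrected_p,
            "rich_factor": self.rich_factor,
            "genes": ",".join(self.overlap_genes),
        }


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh") -> list[float]:
    """Multiplicity correction; output order matches input order.

    ``"bh"`` is Benjamini-Hochberg step-up; ``"bonferroni"`` and ``"holm"``
    are accepted for completeness.
    """
    ps = np.asarray(pvalues, dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mapped = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}
    if method not in mapped:
        raise ValueError(f"unknown correction method {method!r}")
    return list(multipletests(ps, method=mapped[method])[1])


def hypergeom_enrich(
    input_genes: Iterable[str],
    gene_sets: Sequence[PathwayGeneSet],
    background: Iterable[str] | None = None,
    method: str = "bh",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of each gene set.

    The background defaults to the union of all genes in the collection.
    Input genes outside the background are dropped (with a logged count);
    pathway membership is likewise restricted to the background.
    """
    bg = frozenset(background) if background is not None else frozenset().union(
        *(gs.genes for gs in gene_sets)
    ) if gene_sets else frozenset()
    if not bg:
        raise ValueError("empty background universe")
    inp = frozenset(input_genes)
    dropped = inp - bg
    if dropped:
        logger.info("dropped %d input genes outside the background", len(dropped))
    inp &= bg
    M, n = len(bg), len(inp)
    results = []
    for gs in gene_sets:
        members = gs.genes & bg
        K = len(members)
        overlap = sorted(inp & members)
        k = len(overlap)
        if K == 0:
            continue
        # P(X >= k), X ~ Hypergeom(M, K, n)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, M, K, n))
        results.append((gs, k, K, min(p, 1.0), overlap))
    corrected = adjust_pvalues([r[3] for r in results], method=method)
    return [
        EnrichmentResult(
            set_id=gs.set_id, name=gs.name, input_number=k, background_number=K,
            p_value=p, corrected_p=cp, rich_factor=k / K,
            overlap_genes=tuple(overlap), correction_method=method,
        )
        for (gs, k, K, p, overlap), cp in zip(results, corrected)
    ]


def top_pathways(results: Iterable[EnrichmentResult], k: int = 30) -> list[EnrichmentResult]:
    """Top-k pathways by corrected p, ties by raw p then set id."""
    ranked = sorted(results, key=lambda r: (r.corrected_p, r.p_value, r.set_id))
    return ranked[:k]


def select_candidates(
    enriched: Iterable[EnrichmentResult],
    relevance_tags: Iterable[str],
) -> list[str]:
    """Union of overlap genes across phenotype-relevant pathways.

    ``relevance_tags`` are set ids judged relevant to the phenotype (a
    configuration input, not an inference).  Tags absent from the results
    are skipped with a warning.  Output is deduplicated and alphabetical.
    """
    by_id = {r.set_id: r for r in enriched}
    genes: set[str] = set()
    for tag in relevance_tags:
        if tag not in by_id:
            logger.warning("relevance tag %s not among enrichment results; skipped", tag)
            continue
        genes.update(by_id[tag].overlap_genes)
    return sorted(genes)
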