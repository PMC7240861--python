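"""Gene-based carrier-collapsing association.

All qualifying variants in a gene are collapsed to a single per-sample
carrier indicator (dosage >= 1 at any qualifying site), and carrier status
is tested case vs control in a 2x2 Fisher exact test, separately at each
MAF stratum.  The odds ratio is the plain cross-product ad/bc with no
continuity correction; it is reported as undefined (NA) when a zero cell
makes it infinite or 0/0, matching how zero-control genes are reported in
published collapsing tables.

The study whose design this pipeline follows printed one-sided upper-tail
p-values, so ``alternative="greater"`` is the default; the two-sided
minimum-likelihood convention is available as ``"two_sided_minlik"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from wesprio.variants import CohortGenotypes, QualifyingSet

ALTERNATIVES = ("greater", "two_sided_minlik")
_SCIPY_ALT = {"greater": "greater", "two_sided_minlik": "two-sided"}


@dataclass(frozen=True)
class FourfoldTable:
    """Carrier 2x2 table: (a, b) = carrier/non-carrier cases, (c, d) controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @classmethod
    def from_carriers(
        cls, carrier_cases: int, carrier_controls: int, n_cases: int, n_controls: int
    ) -> "FourfoldTable":
        return cls(
            carrier_cases,
            n_cases - carrier_cases,
            carrier_controls,
            n_controls - carrier_controls,
        )


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    stratum: str
    table: FourfoldTable
    odds_ratio: float | None  # None encodes NA (zero cell in the denominator)
    p_value: float
    alternative: str

    def row(self) -> dict:
        return {
            "gene": self.gene,
            "stratum": self.stratum,
            "carrier_cases": self.table.a,
            "carrier_controls": self.table.c,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
        }


def fisher_exact(
    table: FourfoldTable, alternative: str = "greater"
) -> tuple[float | None, float]:
    """Exact hypergeometric test on a carrier 2x2 table.

    Returns ``(odds_ratio, p)``.  The odds ratio is ad/bc, or ``None`` when
    bc = 0 (infinite or indeterminate cross-product).  ``"greater"`` sums
    the upper tail P(X >= a); ``"two_sided_minlik"`` sums every table with
    the observed margins whose point probability does not exceed the
    observed table's.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    a, b, c, d = table.a, table.b, table.c, table.d
    odds = (a * d) / (b * c) if b * c > 0 else None
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=_SCIPY_ALT[alternative])
    return odds, float(p)


def gene_burden(
    qualifying: Mapping[str, QualifyingSet],
    genotypes: CohortGenotypes,
    alternative: str = "greater",
) -> list[BurdenResult]:
    """One burden test per gene per stratum.

    Genes whose qualifying set is carried by no sample in either group are
    omitted.  Results are sorted by stratum, then p, then gene symbol (ties
    broken deterministically).
    """
    n_cases, n_controls = genotypes.n_cases, genotypes.n_controls
    out: list[BurdenResult] = []
    for stratum, qset in qualifying.items():
        for gene in sorted(qset.per_gene):
            cc, cu = genotypes.carrier_counts(qset.per_gene[gene])
            if cc == 0 and cu == 0:
                continue
            tbl = FourfoldTable.from_carriers(cc, cu, n_cases, n_controls)
            odds, p = fisher_exact(tbl, alternative=alternative)
            out.append(BurdenResult(gene, stratum, tbl, odds, p, alternative))
    out.sort(key=lambda r: (r.stratum, r.p_value, r.gene))
    return out


def significant_genes(
    results: Iterable[BurdenResult], alpha: float = 0.05
) -> dict[str, list[str]]:
    """Genes with p < alpha (strict), deduplicated, with stratum provenance.

    Returns ``{gene: sorted list of strata in which it was significant}``.
    """
    hits: dict[str, set[str]] = {}
    for r in results:
        if r.p_value < alpha:
            hits.setdefault(r.gene, set()).add(r.stratum)
    return {g: sorted(s) for g, s in sorted(hits.items())}


def burden_table(results: Iterable[BurdenResult]) -> pd.DataFrame:
    """Wide per-gene table with OR / p / carrier counts per stratum."""
    long = pd.DataFrame([r.row() for r in results])
    if long.empty:
        return long
    wide = long.pivot(index="gene", columns="stratum")
    wide.columns = [f"{col}[{stratum}]" for col, stratum in wide.columns]
    return wide.sort_index()
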