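"""Single-variant case-control association with QC and QQ diagnostics.

Mirrors a PLINK-style allelic analysis: variants are filtered on genotype
missingness (> 0.1 removed), pooled minor-allele frequency (< 0.01 removed),
and an exact Hardy-Weinberg test (p < 1e-4 removed), then each surviving
variant is tested with a Fisher exact test on the 2x2 allele-count table
(two copies per called sample; missing genotypes shrink the denominator).
The two-sided minimum-likelihood convention is the default, as in PLINK's
``--fisher``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from wesprio.variants import CohortGenotypes, Variant


@dataclass(frozen=True)
class AssocResult:
    variant_key: str
    a1: str                      # tested (alternate) allele
    f_a: float                   # tested-allele frequency in cases
    f_u: float                   # ... in controls
    a2: str                      # other allele
    odds_ratio: float | None     # None when the cross-product denominator is 0
    p_value: float

    def row(self) -> dict:
        return {
            "variant_key": self.variant_key, "a1": self.a1, "f_a": self.f_a,
            "f_u": self.f_u, "a2": self.a2, "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class AssocSummary:
    lambda_gc: float | None      # None flags an undefined (empty) scan
    qq_points: pd.DataFrame      # columns: expected, observed (-log10 p), sorted
    n_pass_filters: int


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed
    configuration's.  Monomorphic input returns 1.0; all-zero input is
    rejected.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype counts")
    n_a = n_Aa + 2 * n_aa  # minor-allele copies (label-symmetric)
    n_A = n_Aa + 2 * n_AA
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # P(het = h | allele counts) via the standard recurrence; h has the
    # parity of the rare-allele count.
    h0 = rare % 2
    common = max(n_a, n_A)
    probs = {h0: 1.0}
    h = h0
    while h + 2 <= rare:
        # P(h+2)/P(h) = 4*hom_rare*hom_common / ((h+2)(h+1))
        #             = (rare-h)(common-h) / ((h+2)(h+1))
        ratio = ((rare - h) * (common - h)) / ((h + 2.0) * (h + 1.0))
        probs[h + 2] = probs[h] * ratio
        h += 2
    total = sum(probs.values())
    p_obs = probs[n_Aa] / total
    return min(1.0, sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12)) / total)


def _pooled_maf(dosages: np.ndarray) -> float:
    called = dosages[~np.isnan(dosages)]
    if called.size == 0:
        return 0.0
    alt = called.sum()
    tot = 2 * called.size
    af = alt / tot
    return min(af, 1 - af)


def qc_filter(
    variants: Sequence[Variant],
    genotypes: CohortGenotypes,
    geno_max_missing: float = 0.1,
    hwe_min_p: float = 1e-4,
    maf_min: float = 0.01,
) -> tuple[list[Variant], pd.DataFrame]:
    """Marker QC: missingness, pooled MAF, and exact HWE filters.

    HWE is computed on cases and controls pooled (one marker-wide filter),
    the convention of a single pre-association pass.  Returns the surviving
    variants and a per-variant table of the computed QC statistics with a
    ``pass`` flag.
    """
    rows = []
    kept = []
    for v in variants:
        dos = genotypes.dosage[v.key].to_numpy()
        miss = float(np.isnan(dos).mean())
        maf = _pooled_maf(dos)
        called = dos[~np.isnan(dos)].astype(int)
        n_AA = int((called == 0).sum())
        n_Aa = int((called == 1).sum())
        n_aa = int((called == 2).sum())
        hwe_p = hwe_exact(n_AA, n_Aa, n_aa) if called.size else 1.0
        ok = miss <= geno_max_missing and maf >= maf_min and hwe_p >= hwe_min_p
        rows.append({
            "variant_key": v.key, "missingness": miss, "maf": maf,
            "hwe_p": hwe_p, "pass": ok,
        })
        if ok:
            kept.append(v)
    return kept, pd.DataFrame(rows).set_index("variant_key")


def allelic_fisher(
    case_alt: int, case_ref: int, control_alt: int, control_ref: int,
    variant_key: str = "", a1: str = "", a2: str = "",
    alternative: str = "two-sided",
) -> AssocResult:
    """Fisher exact test on a 2x2 allele-count table.

    OR = (case_alt * control_ref) / (case_ref * control_alt); 0 when the
    numerator is 0, ``None`` (NA) when the denominator is 0.
    """
    if case_alt + case_ref == 0 or control_alt + control_ref == 0:
        raise ValueError("zero total alleles in a group")
    denom = case_ref * control_alt
    odds = (case_alt * control_ref) / denom if denom > 0 else None
    _, p = stats.fisher_exact(
        [[case_alt, case_ref], [control_alt, control_ref]], alternative=alternative
    )
    return AssocResult(
        variant_key=variant_key, a1=a1,
        f_a=case_alt / (case_alt + case_ref),
        f_u=control_alt / (control_alt + control_ref),
        a2=a2, odds_ratio=odds, p_value=float(p),
    )


def _variant_assoc(v: Variant, genotypes: CohortGenotypes) -> AssocResult | None:
    dos = genotypes.dosage[v.key].to_numpy()
    case = genotypes.case_mask
    out = []
    for mask in (case, ~case):
        d = dos[mask]
        d = d[~np.isnan(d)]
        out.append((int(d.sum()), int(2 * d.size - d.sum())))
    (ca, cr), (ua, ur) = out
    if ca + cr == 0 or ua + ur == 0:
        return None
    return allelic_fisher(ca, cr, ua, ur, variant_key=v.key, a1=v.alt, a2=v.ref)


LAMBDA_REF = stats.chi2.ppf(0.5, df=1)  # 0.4549: null median of a 1-df chi-square


def lambda_gc(pvalues) -> float | None:
    """Genomic inflation: median observed 1-df chi-square over its null median."""
    ps = np.asarray(pvalues, dtype=float)
    if ps.size == 0:
        return None
    chisq = stats.chi2.isf(np.clip(ps, 1e-300, 1.0), df=1)
    return float(np.median(chisq) / LAMBDA_REF)


def genome_scan(
    variants: Sequence[Variant],
    genotypes: CohortGenotypes,
    significance: float = 1e-6,
    suggestive: float = 0.01,
) -> tuple[list[AssocResult], AssocSummary, list[str], list[str]]:
    """Allelic association across all (QC-passed) variants.

    Returns per-variant results, a QQ/lambda summary, the keys reaching the
    genome-wide threshold, and the genes carrying any variant below the
    suggestive threshold (the input list for pathway enrichment).

    lambda_gc = median observed 1-df chi-square quantile of p divided by the
    null median 0.455.
    """
    gene_of = {v.key: v.gene for v in variants}
    results = []
    for v in variants:
        r = _variant_assoc(v, genotypes)
        if r is not None:
            results.append(r)
    results.sort(key=lambda r: (r.p_value, r.variant_key))
    ps = np.array([r.p_value for r in results])
    if ps.size:
        lam = lambda_gc(ps)
        n = ps.size
        # rank i (1 = smallest p) plots observed -log10 p against the null
        # quantile -log10((i - 0.5)/n); stored ascending in expected
        expected = -np.log10((np.arange(n, 0, -1) - 0.5) / n)
        observed = -np.log10(np.sort(ps)[::-1])
        qq = pd.DataFrame({"expected": expected, "observed": observed})
    else:
        lam = None
        qq = pd.DataFrame(columns=["expected", "observed"])
    summary = AssocSummary(lambda_gc=lam, qq_points=qq, n_pass_filters=len(results))
    significant = [r.variant_key for r in results if r.p_value < significance]
    enrich_genes = sorted({
        gene_of[r.variant_key]
        for r in results
        if r.p_value < suggestive and gene_of.get(r.variant_key)
    })
    return results, summary, significant, enrich_genes


def assoc_table(results: Iterable[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame([r.row() for r in results])
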