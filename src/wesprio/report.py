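"""External variant-overlap validation, cohort summary, and the run report.

Cross-cohort variant matching is keyed on gene symbol plus normalized HGVS
strings rather than genomic coordinates: external tables typically report
transcript-level notation on different transcripts, so an identical
protein-level change is the strongest claim the data support.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from wesprio.variants import CohortGenotypes, Variant

logger = logging.getLogger(__name__)

_AA1TO3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter", "X": "Ter",
}

MATCH_LEVELS = ("protein_exact", "cdna_exact", "gene_only")


@dataclass(frozen=True)
class ExternalVariantRecord:
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    cohort_label: str = "external"

    def __post_init__(self) -> None:
        if not self.gene or not (self.hgvs_c or self.hgvs_p):
            raise ValueError(
                "external record needs a gene and at least one HGVS string"
            )


@dataclass(frozen=True)
class OverlapMatch:
    gene: str
    match_level: str
    internal_key: str
    external: ExternalVariantRecord


def normalize_hgvs(s: str) -> str:
    """Canonicalize an HGVS string for cross-table comparison.

    Strips whitespace (including around '>'), maps unicode dashes and minus
    signs to ASCII, and rewrites one-letter amino-acid codes in simple
    ``p.`` substitutions to three-letter codes.  Idempotent.
    """
    if not s or s == ".":
        return ""
    s = s.replace("‐", "-").replace("‑", "-").replace("−", "-")
    s = re.sub(r"\s+", "", s)
    m = re.fullmatch(r"p\.\(?([A-Z])(\d+)([A-Z*])\)?", s)
    if m and m.group(1) in _AA1TO3 and m.group(3) in _AA1TO3:
        s = f"p.{_AA1TO3[m.group(1)]}{m.group(2)}{_AA1TO3[m.group(3)]}"
    return s


def overlap_validation(
    candidate_variants: Sequence[Variant],
    external: Sequence[ExternalVariantRecord],
) -> list[OverlapMatch]:
    """Match internal variants against an external cohort's variant table.

    Each internal/external pair in the same gene is reported once at the
    strongest level available: identical normalized protein change, else
    identical cDNA change, else gene-level overlap only.
    """
    matches: list[OverlapMatch] = []
    by_gene: dict[str, list[Variant]] = {}
    for v in candidate_variants:
        by_gene.setdefault(v.gene, []).append(v)
    for rec in external:
        ext_p = normalize_hgvs(rec.hgvs_p)
        ext_c = normalize_hgvs(rec.hgvs_c)
        if not (ext_p or ext_c):
            logger.warning("external record in %s has no usable HGVS; skipped", rec.gene)
            continue
        for v in by_gene.get(rec.gene, []):
            int_p = normalize_hgvs(v.hgvs_p)
            int_c = normalize_hgvs(v.hgvs_c)
            if ext_p and int_p and ext_p == int_p:
                level = "protein_exact"
            elif ext_c and int_c and ext_c == int_c:
                level = "cdna_exact"
            else:
                level = "gene_only"
            matches.append(
                OverlapMatch(gene=rec.gene, match_level=level,
                             internal_key=v.key, external=rec)
            )
    order = {lvl: i for i, lvl in enumerate(MATCH_LEVELS)}
    matches.sort(key=lambda m: (order[m.match_level], m.gene, m.internal_key))
    return matches


def cohort_summary(
    genotypes: CohortGenotypes | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
    n_male_cases: int | None = None,
    clinical: pd.DataFrame | None = None,
    median_columns: Iterable[str] = (),
) -> dict:
    """Per-group counts, female:male ratio, and clinical column summaries.

    Numeric clinical columns are reported mean +/- SD, or median (IQR) for
    columns named in ``median_columns``.  The sex ratio is females per male
    to 2 d.p., flagged undefined when there are no males.
    """
    out: dict = {}
    if genotypes is not None:
        out["n_cases"] = genotypes.n_cases
        out["n_controls"] = genotypes.n_controls
    if n_cases is not None:
        out["n_cases"] = n_cases
    if n_controls is not None:
        out["n_controls"] = n_controls
    if n_male_cases is not None:
        total = out.get("n_cases")
        if total is None:
            raise ValueError("n_male_cases given without a case count")
        n_female = total - n_male_cases
        out["n_male_cases"] = n_male_cases
        out["n_female_cases"] = n_female
        if n_male_cases == 0:
            out["female_male_ratio"] = None  # undefined, flagged
        else:
            out["female_male_ratio"] = round(n_female / n_male_cases, 2)
    if clinical is not None:
        stats = {}
        med = set(median_columns)
        for col in clinical.select_dtypes(include=[np.number]).columns:
            x = clinical[col].dropna()
            if col in med:
                stats[col] = {
                    "median": float(x.median()),
                    "iqr": [float(x.quantile(0.25)), float(x.quantile(0.75))],
                }
            else:
                stats[col] = {"mean": float(x.mean()), "sd": float(x.std(ddof=1))}
        out["clinical"] = stats
    return out


def build_report(
    qc: Mapping | None = None,
    burden_results: Sequence | None = None,
    top_pathways: Sequence | None = None,
    ppi_ranking: Sequence | None = None,
    overlap_matches: Sequence[OverlapMatch] | None = None,
    cohort: Mapping | None = None,
    candidate_genes: Sequence[str] | None = None,
    parameters: Mapping | None = None,
) -> dict:
    """Consolidate whatever stage outputs exist into one structured report.

    Sections for stages that did not run are simply absent — a burden-only
    run yields a burden-only report.  Per gene, an evidence trail collects
    burden p-values, pathway tags, combined network score, and external
    matches.  Output is deterministic for identical inputs (no timestamps).
    """
    report: dict = {}
    if parameters is not None:
        report["parameters"] = dict(parameters)
    if cohort is not None:
        report["cohort"] = dict(cohort)
    if qc is not None:
        report["qc"] = dict(qc)

    evidence: dict[str, dict] = {}

    def trail(gene: str) -> dict:
        return evidence.setdefault(gene, {"gene": gene})

    if burden_results is not None:
        report["burden"] = [r.row() for r in burden_results]
        for r in burden_results:
            trail(r.gene).setdefault("burden_p", {})[r.stratum] = r.p_value
    if top_pathways is not None:
        report["pathways"] = [r.row() for r in top_pathways]
        for r in top_pathways:
            for g in r.overlap_genes:
                trail(g).setdefault("pathways", []).append(r.set_id)
    if ppi_ranking is not None:
        report["ppi_ranking"] = [r.row() for r in ppi_ranking]
        for r in ppi_ranking:
            trail(r.gene)["combined_total"] = r.combined_total
            trail(r.gene)["combined_nodes"] = r.combined_nodes
    if overlap_matches is not None:
        report["external_overlap"] = [
            {
                "gene": m.gene, "match_level": m.match_level,
                "internal_key": m.internal_key,
                "external_cohort": m.external.cohort_label,
            }
            for m in overlap_matches
        ]
        for m in overlap_matches:
            trail(m.gene).setdefault("external_matches", []).append(m.match_level)
    if candidate_genes is not None:
        report["candidate_genes"] = sorted(candidate_genes)
    report["evidence"] = [evidence[g] for g in sorted(evidence)]
    return report


def report_to_json(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=float)


def render_text(report: Mapping) -> str:
    """Short human-readable summary of a report bundle."""
    lines = ["run report", "=" * 10]
    if "cohort" in report:
        c = report["cohort"]
        lines.append(
            f"cohort: {c.get('n_cases', '?')} cases / {c.get('n_controls', '?')} controls"
        )
    if "qc" in report:
        lines.append(f"qc: {report['qc']}")
    if "burden" in report:
        sig = [r for r in report["burden"] if r["p_value"] < 0.05]
        lines.append(f"burden: {len(report['burden'])} gene-stratum tests, "
                     f"{len(sig)} with p < 0.05")
    if "pathways" in report:
        lines.append(f"pathways: top {len(report['pathways'])} reported")
    if "ppi_ranking" in report:
        top = report["ppi_ranking"][:5]
        names = ", ".join(r["gene"] for r in top)
        lines.append(f"ppi ranking: {len(report['ppi_ranking'])} genes (top: {names})")
    if "external_overlap" in report:
        n_exact = sum(
            1 for m in report["external_overlap"] if m["match_level"] != "gene_only"
        )
        lines.append(f"external overlap: {len(report['external_overlap'])} matches, "
                     f"{n_exact} exact")
    if "candidate_genes" in report:
        lines.append("candidates: " + ", ".join(report["candidate_genes"]))
    return "\n".join(lines) + "\n"
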