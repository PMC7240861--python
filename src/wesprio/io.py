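"""Readers and writers for the pipeline's file formats.

Formats handled: minimal VCF 4.2 (GT only; read through cyvcf2, written by a
small text writer), annotation TSV, phenotype TSV, GMT gene sets, PPI edge
TSV, external-cohort variant TSV, and one-symbol-per-line gene lists.
Multi-allelic VCF records are split into one variant per alternate allele
with per-allele dosages.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from wesprio.variants import CohortGenotypes, Variant

#: Panel columns written to / read from the annotation TSV, in order.
PANEL_COLUMNS = (("exac", "exac_af"), ("kg", "kg_af"))


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[list[tuple[str, int, str, str]], pd.DataFrame]:
    """Read a VCF with GT genotypes into (site records, dosage matrix).

    Multi-allelic records are split: each alternate allele becomes its own
    column keyed ``chrom:pos:ref:alt``, with dosage = number of copies of
    that allele per sample and NaN for a missing genotype.

    Raises ``ValueError`` on duplicate variant keys.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    records: list[tuple[str, int, str, str]] = []
    columns: dict[str, np.ndarray] = {}
    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        for ai, alt in enumerate(rec.ALT, start=1):
            key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if key in columns:
                raise ValueError(f"{path}: duplicate variant key {key}")
            dos = np.empty(len(samples))
            for si, gt in enumerate(gts):
                alleles = [a for a in gt[:-1]]
                if any(a < 0 for a in alleles):
                    dos[si] = math.nan
                else:
                    dos[si] = sum(a == ai for a in alleles)
            columns[key] = dos
            records.append((rec.CHROM, rec.POS, rec.REF, alt))
    dosage = pd.DataFrame(columns, index=samples)
    return records, dosage


def write_vcf(
    path: str | Path,
    records: Sequence[tuple[str, int, str, str]],
    dosage: pd.DataFrame,
) -> None:
    """Write site records + per-allele dosages as a minimal VCF 4.2.

    Records sharing a (chrom, pos, ref) site are written as separate
    bi-allelic lines in coordinate order (chromosomes in input order of first
    appearance, positions ascending within a chromosome).  Dosage 1 is
    written ``0/1``, 2 as ``1/1``, NaN as ``./.``.
    """
    chrom_order: dict[str, int] = {}
    for chrom, *_ in records:
        chrom_order.setdefault(chrom, len(chrom_order))
    ordered = sorted(records, key=lambda r: (chrom_order[r[0]], r[1], r[2], r[3]))
    samples = list(dosage.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for chrom, pos, ref, alt in ordered:
            key = f"{chrom}:{pos}:{ref}:{alt}"
            col = dosage[key]
            gts = "\t".join(
                "./." if math.isnan(d) else gt_map[int(d)] for d in col
            )
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ----------------------------------------------------------------------
# Annotation / phenotype tables
# ----------------------------------------------------------------------

def _fmt_af(af: float | None) -> str:
    return "." if af is None else format(af, ".17g")


def write_annotations(path: str | Path, variants: Iterable[Variant]) -> None:
    cols = ["variant_key", "gene", "functional_class", "hgvs_c", "hgvs_p"]
    cols += [col for _, col in PANEL_COLUMNS]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            row = [v.key, v.gene, v.functional_class, v.hgvs_c or ".", v.hgvs_p or "."]
            row += [_fmt_af(v.panel_afs.get(panel)) for panel, _ in PANEL_COLUMNS]
            fh.write("\t".join(row) + "\n")


def read_annotations(path: str | Path) -> dict[str, dict]:
    """Map variant key -> annotation fields (panel AF '.' becomes None)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        key = row["variant_key"]
        if key in out:
            raise ValueError(f"{path}: duplicate annotation for {key}")
        afs = {}
        for panel, col in PANEL_COLUMNS:
            raw = row.get(col, ".")
            afs[panel] = None if raw in (".", "") else float(raw)
        out[key] = {
            "gene": row["gene"],
            "functional_class": row["functional_class"],
            "hgvs_c": "" if row["hgvs_c"] == "." else row["hgvs_c"],
            "hgvs_p": "" if row["hgvs_p"] == "." else row["hgvs_p"],
            "panel_afs": afs,
        }
    return out


def write_phenotypes(path: str | Path, genotypes: CohortGenotypes) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, status in genotypes.status.items():
            fh.write(f"{sid}\t{status}\n")


def read_phenotypes(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df["status"].to_numpy(), index=df["sample_id"], name="status")


def read_inputs(
    vcf_path: str | Path,
    annotation_path: str | Path,
    phenotype_path: str | Path,
) -> tuple[list[Variant], CohortGenotypes]:
    """Assemble the cohort data model from the three input files.

    Every genotyped allele must be annotated; sample columns must match the
    phenotype table exactly.
    """
    records, dosage = read_vcf(vcf_path)
    ann = read_annotations(annotation_path)
    status = read_phenotypes(phenotype_path)
    if set(status.index) != set(dosage.index):
        raise ValueError(
            f"{phenotype_path}: phenotype samples do not match VCF samples"
        )
    status = status.reindex(dosage.index)
    variants = []
    for chrom, pos, ref, alt in records:
        key = f"{chrom}:{pos}:{ref}:{alt}"
        if key not in ann:
            raise ValueError(f"{annotation_path}: no annotation for genotyped {key}")
        variants.append(Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, **ann[key]))
    return variants, CohortGenotypes(dosage, list(status))


# ----------------------------------------------------------------------
# Gene sets, edges, external tables, gene lists
# ----------------------------------------------------------------------

def write_gmt(path: str | Path, gene_sets: Iterable) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")


def read_gmt(path: str | Path) -> list:
    from wesprio.enrichment import PathwayGeneSet

    out = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line needs id, name, >=1 gene: {line!r}")
            set_id, name, *genes = fields
            if set_id in seen:
                raise ValueError(f"{path}: duplicate gene-set id {set_id}")
            seen.add(set_id)
            out.append(PathwayGeneSet(set_id=set_id, name=name, genes=frozenset(genes)))
    return out


def write_ppi_edges(path: str | Path, edges: Iterable) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for e in edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{format(e.combined_score, '.17g')}\n")


def read_ppi_edges(path: str | Path) -> list:
    from wesprio.network import PPIEdge

    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str},
                     float_precision="round_trip")
    return [
        PPIEdge(row.gene_a, row.gene_b, float(row.combined_score))
        for row in df.itertuples()
    ]


def write_external_table(path: str | Path, records: Iterable) -> None:
    with open(path, "w") as fh:
        fh.write("gene\thgvs_c\thgvs_p\tcohort_label\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.hgvs_c or '.'}\t{r.hgvs_p or '.'}\t{r.cohort_label}\n"
            )


def read_external_table(path: str | Path) -> list:
    from wesprio.report import ExternalVariantRecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples():
        out.append(
            ExternalVariantRecord(
                gene=row.gene,
                hgvs_c="" if row.hgvs_c == "." else row.hgvs_c,
                hgvs_p="" if row.hgvs_p == "." else row.hgvs_p,
                cohort_label=row.cohort_label,
            )
        )
    return out


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.append(sym)
    return out
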