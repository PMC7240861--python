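"""Synthetic case-control exome cohorts with planted carrier effects.

The generator emulates the statistical structure the downstream analysis
assumes — not sequence data.  Each gene carries a handful of rare sites with
cohort allele frequencies drawn from a configurable spectrum.  Because the
collapsing statistic only consumes per-sample carrier status, carriers are
simulated at the gene level: a control is a carrier with probability
``q = 1 - prod_i (1 - af_i)^2`` over the gene's deleterious sites, and in
cases the carrier odds are multiplied by the planted odds ratio.  A carrier
is assigned one deleterious site (probability proportional to site AF);
non-deleterious sites are filled independently under Hardy-Weinberg at their
cohort AF.  Reference-panel AFs are drawn independently of the cohort (a
panel describes a different population) with a configurable fraction
unreported, exercising the missing-AF qualification rule.

All randomness flows from one integer seed; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from wesprio.enrichment import PathwayGeneSet
from wesprio.network import PPIEdge
from wesprio.report import ExternalVariantRecord
from wesprio.variants import (
    CohortGenotypes, DELETERIOUS_CLASSES, Variant,
)
from wesprio import io as wio

_DELETERIOUS = tuple(sorted(DELETERIOUS_CLASSES))
_NEUTRAL = ("synonymous", "intron", "utr")
_AA3 = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val")
_BASES = ("A", "C", "G", "T")


def af_for_carrier_rate(rate: float, n_sites: int = 1) -> float:
    """Per-site allele frequency giving a target per-gene carrier probability.

    Inverts ``rate = 1 - (1 - af)^(2 * n_sites)`` for equal-AF sites.
    """
    if not 0 <= rate < 1:
        raise ValueError("carrier rate must be in [0, 1)")
    return 1.0 - (1.0 - rate) ** (1.0 / (2 * n_sites))


@dataclass(frozen=True)
class PathwayConfig:
    n_sets: int = 20
    min_size: int = 5
    max_size: int = 40
    #: gene sets indexed < n_planted_sets are guaranteed to contain every
    #: planted-effect gene (so enrichment has signal to find)
    n_planted_sets: int = 1


@dataclass(frozen=True)
class PPIConfig:
    edge_density: float = 0.15
    #: uniform score support on [lo, hi] subset of [0, 1]
    score_range: tuple[float, float] = (0.05, 0.95)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the case-control exome design the pipeline targets:
    82 cases, 100 controls, tens of genes with a few rare deleterious sites
    each, cohort site AFs of a fraction of a percent, and no planted effect.
    """

    n_cases: int = 82
    n_controls: int = 100
    #: gene symbol -> number of rare sites in that gene
    genes: Mapping[str, int] = field(
        default_factory=lambda: {f"GENE{i:03d}": 1 + (i % 5) for i in range(40)}
    )
    #: ("uniform", lo, hi) or ("fixed", af) over cohort site AF in [0, 0.05]
    maf_spectrum: tuple = ("uniform", 0.0002, 0.008)
    deleterious_fraction: float = 0.7
    #: gene -> carrier odds ratio in cases (1 = null)
    planted_effects: Mapping[str, float] = field(default_factory=dict)
    pathway_config: PathwayConfig = field(default_factory=PathwayConfig)
    ppi_config: PPIConfig = field(default_factory=PPIConfig)
    missing_rate: float = 0.0
    #: fraction of panel AF entries written as unreported (".")
    panel_missing_rate: float = 0.15
    #: fraction of sites common in the reference panels (AF in [0.01, 0.05]),
    #: hence excluded from both rarity strata
    panel_common_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample counts must be positive")
        if not self.genes:
            raise ValueError("gene list must be non-empty")
        for g, orr in self.planted_effects.items():
            if orr <= 0:
                raise ValueError(f"planted odds ratio for {g} must be > 0")
        if not 0 <= self.deleterious_fraction <= 1:
            raise ValueError("deleterious_fraction must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticBundle:
    variants: list[Variant]
    genotypes: CohortGenotypes
    gene_sets: list[PathwayGeneSet]
    ppi_edges: list[PPIEdge]
    external_table: list[ExternalVariantRecord]
    truth: pd.DataFrame  # per-gene planted OR and realized carrier model

    def __eq__(self, other: object) -> bool:
        # order-insensitive on variants/edges: persistence stores variants in
        # coordinate order and edges canonically, which need not match
        # generation order
        if not isinstance(other, SyntheticBundle):
            return NotImplemented
        key = lambda v: v.key
        if sorted(self.variants, key=key) != sorted(other.variants, key=key):
            return False
        cols = sorted(self.genotypes.dosage.columns)
        if sorted(other.genotypes.dosage.columns) != cols:
            return False
        a = CohortGenotypes(self.genotypes.dosage[cols], list(self.genotypes.status))
        b = CohortGenotypes(other.genotypes.dosage[cols], list(other.genotypes.status))
        return (
            a == b
            and self.gene_sets == other.gene_sets
            and sorted(self.ppi_edges, key=lambda e: e.pair)
            == sorted(other.ppi_edges, key=lambda e: e.pair)
            and self.external_table == other.external_table
        )


def _draw_af(rng: np.random.Generator, spectrum: tuple) -> float:
    kind = spectrum[0]
    if kind == "uniform":
        return float(rng.uniform(spectrum[1], spectrum[2]))
    if kind == "fixed":
        return float(spectrum[1])
    raise ValueError(f"unknown maf_spectrum {spectrum!r}")


def _hgvs_pair(rng: np.random.Generator, cls: str, ref: str, alt: str) -> tuple[str, str]:
    cpos = int(rng.integers(1, 9000))
    hgvs_c = f"c.{cpos}{ref}>{alt}"
    if cls in ("missense", "nonsense"):
        aa1, aa2 = rng.choice(_AA3, size=2, replace=False)
        target = "Ter" if cls == "nonsense" else aa2
        return hgvs_c, f"p.{aa1}{(cpos + 2) // 3}{target}"
    return hgvs_c, ""


def simulate_cohort(config: SimulationConfig) -> SyntheticBundle:
    """Generate a full synthetic bundle under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    n_cases, n_controls = config.n_cases, config.n_controls
    n = n_cases + n_controls
    sample_ids = [f"case{i:04d}" for i in range(n_cases)] + [
        f"ctrl{i:04d}" for i in range(n_controls)
    ]
    status = ["case"] * n_cases + ["control"] * n_controls
    case_slice = slice(0, n_cases)

    variants: list[Variant] = []
    columns: dict[str, np.ndarray] = {}
    truth_rows = []
    genes = list(config.genes)
    for gi, gene in enumerate(genes):
        n_sites = config.genes[gene]
        chrom = str(gi % 22 + 1)
        base = 1_000_000 + gi * 100_000
        afs = np.array([_draw_af(rng, config.maf_spectrum) for _ in range(n_sites)])
        deleterious = rng.random(n_sites) < config.deleterious_fraction
        classes = [
            str(rng.choice(_DELETERIOUS)) if d else str(rng.choice(_NEUTRAL))
            for d in deleterious
        ]
        site_vars = []
        for si in range(n_sites):
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            # panel AFs are independent of the cohort AF: a case cohort can be
            # enriched for carriers of a variant that is vanishingly rare in a
            # reference population
            panel_common = rng.random() < config.panel_common_fraction
            panel_afs = {}
            for panel in ("exac", "kg"):
                if rng.random() < config.panel_missing_rate:
                    panel_afs[panel] = None
                elif panel_common:
                    panel_afs[panel] = float(rng.uniform(0.01, 0.05))
                else:
                    # log-uniform over [1e-5, 6e-3]: every rare site passes the
                    # loose stratum, ~70% also pass the strict one
                    panel_afs[panel] = float(10 ** rng.uniform(-5.0, -2.22))
            hgvs_c, hgvs_p = _hgvs_pair(rng, classes[si], str(ref), str(alt))
            v = Variant(
                chrom=chrom, pos=base + si * 100, ref=str(ref), alt=str(alt),
                gene=gene, functional_class=classes[si],
                hgvs_c=hgvs_c, hgvs_p=hgvs_p, panel_afs=panel_afs,
            )
            site_vars.append(v)
            variants.append(v)

        # carrier model over the deleterious sites
        del_idx = np.flatnonzero(deleterious)
        dosage = np.zeros((n, n_sites))
        if del_idx.size:
            del_afs = afs[del_idx]
            q_ctrl = 1.0 - float(np.prod((1.0 - del_afs) ** 2))
            orr = float(config.planted_effects.get(gene, 1.0))
            odds = orr * q_ctrl / (1.0 - q_ctrl) if q_ctrl < 1 else np.inf
            q_case = odds / (1.0 + odds)
            p_carrier = np.where(
                np.arange(n) < n_cases, q_case, q_ctrl
            )
            carrier = rng.random(n) < p_carrier
            weights = del_afs / del_afs.sum()
            for si_local, is_carrier in enumerate(carrier):
                if is_carrier:
                    site = del_idx[rng.choice(del_idx.size, p=weights)]
                    dosage[si_local, site] = 2.0 if rng.random() < afs[site] else 1.0
        else:
            q_ctrl = 0.0
            q_case = 0.0
            orr = float(config.planted_effects.get(gene, 1.0))
        # neutral sites: independent Hardy-Weinberg fill
        for si in range(n_sites):
            if not deleterious[si]:
                dosage[:, si] = rng.binomial(2, afs[si], size=n)
        if config.missing_rate > 0:
            mask = rng.random(dosage.shape) < config.missing_rate
            dosage[mask] = np.nan
        for si, v in enumerate(site_vars):
            columns[v.key] = dosage[:, si]
        truth_rows.append({
            "gene": gene, "planted_or": orr, "n_sites": n_sites,
            "n_deleterious_sites": int(del_idx.size),
            "carrier_rate_controls": q_ctrl, "carrier_rate_cases": q_case,
        })

    genotypes = CohortGenotypes(
        pd.DataFrame(columns, index=sample_ids), status
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")

    # pathway gene sets: planted genes concentrated in the first sets
    pc = config.pathway_config
    planted = sorted(config.planted_effects)
    gene_sets = []
    for si in range(pc.n_sets):
        size = int(rng.integers(pc.min_size, pc.max_size + 1))
        members = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        if si < pc.n_planted_sets:
            members.update(planted)
        gene_sets.append(
            PathwayGeneSet(
                set_id=f"SET-{si:04d}", name=f"synthetic pathway {si}",
                genes=frozenset(str(m) for m in members), source="synthetic",
            )
        )

    # PPI edges: Erdos-Renyi over the gene universe with uniform scores
    ppc = config.ppi_config
    edges = []
    lo, hi = ppc.score_range
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < ppc.edge_density:
                edges.append(
                    PPIEdge(genes[i], genes[j], float(rng.uniform(lo, hi)))
                )

    # external validation table: replicate a few case-carried deleterious
    # variants (formatted with the spacing quirks of published tables),
    # plus same-gene non-matching and irrelevant records
    external: list[ExternalVariantRecord] = []
    case_carried = [
        v for v in variants
        if v.functional_class in DELETERIOUS_CLASSES
        and np.nansum(columns[v.key][case_slice]) >= 1
    ]
    n_rep = min(3, len(case_carried))
    for idx in range(n_rep):
        v = case_carried[idx]
        external.append(
            ExternalVariantRecord(
                gene=v.gene,
                hgvs_c=v.hgvs_c.replace(">", " > "),
                hgvs_p=v.hgvs_p,
                cohort_label="replication",
            )
        )
    if case_carried:
        v = case_carried[0]
        external.append(
            ExternalVariantRecord(
                gene=v.gene, hgvs_c="c.1A>G", hgvs_p="p.Met1Val",
                cohort_label="replication",
            )
        )

    return SyntheticBundle(
        variants=variants, genotypes=genotypes, gene_sets=gene_sets,
        ppi_edges=edges, external_table=external, truth=truth,
    )


# ----------------------------------------------------------------------
# Bundle persistence
# ----------------------------------------------------------------------

FILENAMES = {
    "vcf": "cohort.vcf",
    "annotations": "annotations.tsv",
    "phenotypes": "phenotypes.tsv",
    "gene_sets": "pathways.gmt",
    "ppi_edges": "ppi_edges.tsv",
    "external": "external.tsv",
    "truth": "truth.tsv",
}


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as the pipeline's file formats; returns the path map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {k: d / name for k, name in FILENAMES.items()}
    records = [(v.chrom, v.pos, v.ref, v.alt) for v in bundle.variants]
    wio.write_vcf(paths["vcf"], records, bundle.genotypes.dosage)
    wio.write_annotations(paths["annotations"], bundle.variants)
    wio.write_phenotypes(paths["phenotypes"], bundle.genotypes)
    wio.write_gmt(paths["gene_sets"], bundle.gene_sets)
    wio.write_ppi_edges(paths["ppi_edges"], bundle.ppi_edges)
    wio.write_external_table(paths["external"], bundle.external_table)
    bundle.truth.to_csv(paths["truth"], sep="\t")
    return paths


def read_bundle(directory: str | Path) -> SyntheticBundle:
    """Re-read a written bundle (inverse of :func:`write_bundle`)."""
    d = Path(directory)
    variants, genotypes = wio.read_inputs(
        d / FILENAMES["vcf"], d / FILENAMES["annotations"], d / FILENAMES["phenotypes"]
    )
    return SyntheticBundle(
        variants=variants,
        genotypes=genotypes,
        gene_sets=wio.read_gmt(d / FILENAMES["gene_sets"]),
        ppi_edges=wio.read_ppi_edges(d / FILENAMES["ppi_edges"]),
        external_table=wio.read_external_table(d / FILENAMES["external"]),
        truth=pd.read_csv(d / FILENAMES["truth"], sep="\t", index_col="gene"),
    )


def config_to_json(config: SimulationConfig) -> str:
    d = asdict(config)
    d["genes"] = dict(d["genes"])
    d["planted_effects"] = dict(d["planted_effects"])
    return json.dumps(d, indent=2, sort_keys=True)
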