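"""Variant data model, functional classification, and dual-stratum qualification.

A *qualifying* variant is one in a deleterious functional class (nonsense,
missense, splice-site, frameshift, in-frame indel) whose reference-panel
allele frequencies all fall below a rarity threshold.  Qualification is run
at two MAF strata (< 0.001 and < 0.01); the stricter set is always nested
inside the looser one.  A panel AF that is unreported counts as rare: absent
from the reference panel is the strongest evidence of rarity a panel can give.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled vocabulary for functional consequence classes.
FUNCTIONAL_CLASSES = frozenset({
    "nonsense", "missense", "splice_site", "frameshift", "inframe_indel",
    "synonymous", "intron", "utr", "other",
})

#: Classes counted as deleterious for carrier collapsing.
DELETERIOUS_CLASSES = frozenset({
    "nonsense", "missense", "splice_site", "frameshift", "inframe_indel",
})

#: The two rarity strata at which collapsing is run, as (label, threshold).
MAF_STRATA = (("MAF<0.001", 0.001), ("MAF<0.01", 0.01))

MISSING = float("nan")


@dataclass(frozen=True)
class Variant:
    """One annotated alternate allele.

    ``panel_afs`` maps a reference-panel name (e.g. ``"exac"``, ``"kg"``) to
    an allele frequency in [0, 1], or ``None`` when the panel does not report
    the variant.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    functional_class: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    panel_afs: Mapping[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError(f"alleles must be non-empty at {self.chrom}:{self.pos}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"unknown functional class {self.functional_class!r} at "
                f"{self.chrom}:{self.pos}; expected one of {sorted(FUNCTIONAL_CLASSES)}"
            )
        for panel, af in self.panel_afs.items():
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"panel AF out of [0,1]: {panel}={af}")

    @property
    def key(self) -> str:
        """Canonical variant key ``chrom:pos:ref:alt`` (1-based, VCF convention)."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class CohortGenotypes:
    """Samples-by-variants dosage matrix with case/control labels.

    Dosages are 0/1/2 with ``NaN`` for a missing genotype.  A *carrier* of a
    variant set is a sample with dosage >= 1 at any member variant; a missing
    dosage is treated as non-carrier.
    """

    def __init__(
        self,
        dosage: pd.DataFrame,
        status: Sequence[str],
    ) -> None:
        if len(status) != dosage.shape[0]:
            raise ValueError(
                f"{len(status)} status labels for {dosage.shape[0]} samples"
            )
        bad = set(status) - {"case", "control"}
        if bad:
            raise ValueError(f"status labels must be 'case'/'control', got {bad}")
        self.dosage = dosage.astype(float)
        self.status = pd.Series(list(status), index=dosage.index, name="status")

    # -- basic geometry -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def variant_keys(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def case_mask(self) -> np.ndarray:
        return (self.status == "case").to_numpy()

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.case_mask).sum())

    # -- carrier collapsing ---------------------------------------------
    def carrier_mask(self, keys: Iterable[str]) -> np.ndarray:
        """Boolean per-sample indicator of carrying >= 1 allele at any key."""
        cols = [k for k in keys if k in self.dosage.columns]
        if not cols:
            return np.zeros(len(self.dosage), dtype=bool)
        block = self.dosage[cols].to_numpy()
        return np.nan_to_num(block, nan=0.0).max(axis=1) >= 1

    def carrier_counts(self, keys: Iterable[str]) -> tuple[int, int]:
        """(carrier cases, carrier controls) for a variant-key set."""
        mask = self.carrier_mask(keys)
        case = self.case_mask
        return int(mask[case].sum()), int(mask[~case].sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortGenotypes):
            return NotImplemented
        return (
            self.status.equals(other.status)
            and self.dosage.columns.equals(other.dosage.columns)
            and self.dosage.index.equals(other.dosage.index)
            and np.array_equal(
                self.dosage.to_numpy(), other.dosage.to_numpy(), equal_nan=True
            )
        )


@dataclass(frozen=True)
class QualifyingSet:
    """Deleterious rare variants passing one MAF stratum, grouped by gene."""

    stratum: str
    variant_keys: frozenset[str]
    per_gene: Mapping[str, frozenset[str]]

    def genes(self) -> list[str]:
        return sorted(self.per_gene)


def classify_deleterious(variant: Variant | str) -> bool:
    """True iff the functional class is one of the collapsing-eligible classes."""
    cls = variant.functional_class if isinstance(variant, Variant) else variant
    if cls not in FUNCTIONAL_CLASSES:
        raise ValueError(
            f"unknown functional class {cls!r}; expected one of "
            f"{sorted(FUNCTIONAL_CLASSES)}"
        )
    return cls in DELETERIOUS_CLASSES


def stratify_by_maf(
    variant: Variant,
    thresholds: Sequence[tuple[str, float]] = MAF_STRATA,
) -> frozenset[str]:
    """Return the strata whose threshold every *reported* panel AF is below.

    A variant with no reported AF in any panel is treated as AF 0 (rare in
    every stratum).  Membership requires strictly ``af < threshold`` in every
    panel that reports the variant, so the stricter stratum is always a
    subset of the looser one.
    """
    afs = [af for af in variant.panel_afs.values() if af is not None]
    out = set()
    for label, thr in thresholds:
        if all(af < thr for af in afs):  # vacuously true when all missing
            out.add(label)
    return frozenset(out)


def build_qualifying_sets(
    variants: Iterable[Variant],
    genotypes: CohortGenotypes | None = None,
    thresholds: Sequence[tuple[str, float]] = MAF_STRATA,
) -> dict[str, QualifyingSet]:
    """Group deleterious variants passing each stratum by gene.

    Variants with an empty gene label are excluded (counted in a warning).
    When ``genotypes`` is given, variants absent from the dosage matrix are
    dropped so downstream carrier counts refer to genotyped sites only.
    """
    per_stratum: dict[str, dict[str, set[str]]] = {lbl: {} for lbl, _ in thresholds}
    n_no_gene = 0
    genotyped = set(genotypes.variant_keys) if genotypes is not None else None
    for v in variants:
        if not v.gene:
            n_no_gene += 1
            continue
        if genotyped is not None and v.key not in genotyped:
            continue
        if not classify_deleterious(v):
            continue
        for label in stratify_by_maf(v, thresholds):
            per_stratum[label].setdefault(v.gene, set()).add(v.key)
    if n_no_gene:
        logger.warning("excluded %d variants with empty gene label", n_no_gene)
    out = {}
    for label, _ in thresholds:
        per_gene = {g: frozenset(ks) for g, ks in per_stratum[label].items()}
        all_keys = frozenset().union(*per_gene.values()) if per_gene else frozenset()
        out[label] = QualifyingSet(stratum=label, variant_keys=all_keys, per_gene=per_gene)
    return out


def panel_summary(
    qualifying: QualifyingSet,
    genotypes: CohortGenotypes,
    panel_genes: Sequence[str],
) -> pd.DataFrame:
    """Per reference-panel gene: qualifying-variant count and carrier-case count.

    Mirrors the reference-gene tabulation of the study design (number of rare
    variants per gene, and number of cases carrying at least one of them).
    Genes absent from the cohort report (0, 0).
    """
    rows = []
    case = genotypes.case_mask
    for gene in panel_genes:
        keys = qualifying.per_gene.get(gene, frozenset())
        n_cases = int(genotypes.carrier_mask(keys)[case].sum()) if keys else 0
        rows.append({"gene": gene, "n_rare_variants": len(keys), "n_carrier_cases": n_cases})
    return pd.DataFrame(rows).set_index("gene")
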