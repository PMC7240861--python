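"""HGVS normalization, cross-cohort overlap, cohort summary, report assembly."""

import pandas as pd
import pytest

import wesprio as w
from wesprio.datasets import (
    DANISH_COHORT_VARIANTS,
    INTERNAL_CANDIDATE_VARIANTS,
    STUDY_N_CASES,
    STUDY_N_MALE_CASES,
)
from wesprio.report import normalize_hgvs, report_to_json


class TestNormalizeHgvs:
    @pytest.mark.parametrize("raw,expected", [
        ("c.4652A > G", "c.4652A>G"),
        (" c.4652A>G ", "c.4652A>G"),
        ("p.Asn1551Ser", "p.Asn1551Ser"),
        ("p.N1551S", "p.Asn1551Ser"),      # one-letter codes widened
        ("p.R100*", "p.Arg100Ter"),
        ("c.838‐131G > A", "c.838-131G>A"),  # unicode dash
        (".", ""),
        ("", ""),
    ])
    def test_canonical_forms(self, raw, expected):
        assert normalize_hgvs(raw) == expected

    @pytest.mark.parametrize("raw", [
        "c.4652A > G", "p.N1551S", "p.Asn1551Ser", "c.*52_*53insA", "n.616T > C",
    ])
    def test_idempotent(self, raw):
        once = normalize_hgvs(raw)
        assert normalize_hgvs(once) == once


def _internal_variants():
    out = []
    for i, (gene, c, p) in enumerate(INTERNAL_CANDIDATE_VARIANTS):
        out.append(w.Variant(
            chrom="1", pos=1000 + i, ref="A", alt="G", gene=gene,
            functional_class="missense", hgvs_c=c, hgvs_p=p,
        ))
    return out


def _danish_records():
    return [
        w.ExternalVariantRecord(gene=g, hgvs_c=c, hgvs_p=p, cohort_label="danish")
        for g, c, p in DANISH_COHORT_VARIANTS
    ]


class TestOverlapValidation:
    def test_replicated_variant_found_at_protein_level(self):
        """The shared ryanodine-receptor variant matches across cohorts."""
        matches = w.overlap_validation(_internal_variants(), _danish_records())
        exact = [m for m in matches if m.match_level == "protein_exact"]
        assert len(exact) == 1
        assert exact[0].gene == "RYR2"
        assert exact[0].external.hgvs_p == "p.Asn1551Ser"

    def test_same_gene_different_change_is_gene_only(self):
        internal = [w.Variant("1", 1, "A", "G", "RYR2", "missense",
                              hgvs_c="c.100A>G", hgvs_p="p.Lys34Glu")]
        ext = [w.ExternalVariantRecord(gene="RYR2", hgvs_c="c.200C>T",
                                       hgvs_p="p.Pro67Leu")]
        (m,) = w.overlap_validation(internal, ext)
        assert m.match_level == "gene_only"

    def test_spacing_and_letter_code_insensitive(self):
        internal = [w.Variant("1", 1, "A", "G", "RYR2", "missense",
                              hgvs_c="c.4652A>G", hgvs_p="p.N1551S")]
        ext = [w.ExternalVariantRecord(gene="RYR2", hgvs_c="c.4652A > G",
                                       hgvs_p="p.Asn1551Ser")]
        (m,) = w.overlap_validation(internal, ext)
        assert m.match_level == "protein_exact"

    def test_empty_external_table(self):
        assert w.overlap_validation(_internal_variants(), []) == []

    def test_matches_reference_existing_records(self, planted_bundle):
        b = planted_bundle
        keys = {v.key for v in b.variants}
        for m in w.overlap_validation(b.variants, b.external_table):
            assert m.internal_key in keys
            assert m.external in b.external_table

    def test_record_requires_gene_and_hgvs(self):
        with pytest.raises(ValueError):
            w.ExternalVariantRecord(gene="RYR2")


class TestCohortSummary:
    def test_study_sex_ratio(self):
        out = w.cohort_summary(n_cases=STUDY_N_CASES, n_male_cases=STUDY_N_MALE_CASES)
        assert out["female_male_ratio"] == pytest.approx(2.28)

    def test_all_female_flagged_undefined(self):
        out = w.cohort_summary(n_cases=10, n_male_cases=0)
        assert out["female_male_ratio"] is None

    def test_counts_match_simulation_config(self, planted_bundle):
        out = w.cohort_summary(planted_bundle.genotypes)
        assert out["n_cases"] == 82 and out["n_controls"] == 100

    def test_clinical_columns(self):
        clin = pd.DataFrame({"age": [40.0, 50.0, 60.0], "bmi": [20.0, 24.0, 30.0]})
        out = w.cohort_summary(n_cases=3, clinical=clin, median_columns=["bmi"])
        assert out["clinical"]["age"]["mean"] == pytest.approx(50.0)
        assert out["clinical"]["age"]["sd"] == pytest.approx(10.0)
        assert out["clinical"]["bmi"]["median"] == pytest.approx(24.0)


class TestBuildReport:
    def _full_report(self, planted_bundle):
        b = planted_bundle
        q = w.build_qualifying_sets(b.variants, b.genotypes)
        burden = w.gene_burden(q, b.genotypes)
        enr = w.top_pathways(
            w.hypergeom_enrich(["G07", "G01"], b.gene_sets), k=5
        )
        g1 = w.node_scores(b.ppi_edges, set(b.truth.index))
        ranking = w.combine_groups(g1, g1)
        matches = w.overlap_validation(b.variants, b.external_table)
        return w.build_report(
            burden_results=burden, top_pathways=enr, ppi_ranking=ranking,
            overlap_matches=matches, cohort=w.cohort_summary(b.genotypes),
            candidate_genes=["G07"],
        )

    def test_planted_gene_has_complete_evidence_trail(self, planted_bundle):
        rep = self._full_report(planted_bundle)
        trail = {e["gene"]: e for e in rep["evidence"]}["G07"]
        assert "burden_p" in trail and "pathways" in trail
        assert "combined_total" in trail

    def test_burden_only_run_omits_other_sections(self, planted_bundle):
        b = planted_bundle
        q = w.build_qualifying_sets(b.variants, b.genotypes)
        rep = w.build_report(burden_results=w.gene_burden(q, b.genotypes))
        assert "burden" in rep
        for absent in ("ppi_ranking", "pathways", "external_overlap"):
            assert absent not in rep

    def test_rerun_is_byte_identical(self, planted_bundle):
        a = report_to_json(self._full_report(planted_bundle))
        b = report_to_json(self._full_report(planted_bundle))
        assert a == b
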