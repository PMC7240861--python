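"""Single-variant association: HWE exact test, QC filters, allelic Fisher, QQ."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wesprio as w
from wesprio.datasets import ASSOC_ROWS, STUDY_N_CASES, STUDY_N_CONTROLS
from tests.conftest import oracle_hwe


class TestHweExact:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0, 0), 1.0),          # monomorphic
        ((25, 50, 25), 1.0),        # perfect equilibrium is the modal table
    ])
    def test_boundary_cases(self, counts, expected):
        assert w.hwe_exact(*counts) == pytest.approx(expected)

    def test_two_homozygotes_no_het(self):
        # alleles 2A/2a over 2 genotypes; het count in {0, 2}
        assert w.hwe_exact(1, 0, 1) == pytest.approx(oracle_hwe(1, 0, 1))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            w.hwe_exact(0, 0, 0)

    @given(n_AA=st.integers(0, 40), n_Aa=st.integers(0, 40), n_aa=st.integers(0, 40))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration(self, n_AA, n_Aa, n_aa):
        """Exact conditional HWE p equals full enumeration (<= 240 alleles)."""
        if n_AA + n_Aa + n_aa == 0:
            return
        assert w.hwe_exact(n_AA, n_Aa, n_aa) == pytest.approx(
            oracle_hwe(n_AA, n_Aa, n_aa), rel=1e-9
        )

    def test_label_symmetric(self):
        assert w.hwe_exact(3, 5, 1) == pytest.approx(w.hwe_exact(1, 5, 3))


def _mono_cohort(dosages, n_cases=3):
    dosage = pd.DataFrame({"1:1:A:T": dosages}, dtype=float)
    dosage.index = [f"s{i}" for i in range(len(dosages))]
    status = ["case"] * n_cases + ["control"] * (len(dosages) - n_cases)
    return w.CohortGenotypes(dosage, status)


class TestQcFilter:
    def mkvar(self):
        return w.Variant("1", 1, "A", "T", "G1", "missense")

    def test_high_missingness_removed(self):
        # 2 of 10 genotypes missing -> 20% missingness exceeds the 10% cap
        geno = _mono_cohort([1, 0, np.nan, np.nan, 1, 0, 1, 0, 1, 0], n_cases=5)
        kept, stats = w.qc_filter([self.mkvar()], geno)
        assert kept == []
        assert stats.iloc[0]["missingness"] == pytest.approx(0.2)

    def test_monomorphic_removed_by_maf(self):
        geno = _mono_cohort([0.0] * 10, n_cases=5)
        kept, stats = w.qc_filter([self.mkvar()], geno)
        assert kept == [] and stats.iloc[0]["maf"] == 0.0

    def test_hwe_statistic_matches_oracle(self):
        # genotype counts hom-ref 3, het 5, hom-alt 1
        geno = _mono_cohort([0, 0, 0, 1, 1, 1, 1, 1, 2], n_cases=4)
        _, stats = w.qc_filter([self.mkvar()], geno)
        assert stats.iloc[0]["hwe_p"] == pytest.approx(oracle_hwe(3, 5, 1), rel=1e-9)


class TestAllelicFisher:
    def test_published_frequency_rows_reproduce(self):
        """Printed OR and two-sided p reproduce from round(F * 2N) counts."""
        expected = {"SEMA6D": (2.44, 1.10e-4), "ROBO2": (3.23, 3.18e-4),
                    "ATP2B2": (0.00, 7.05e-4)}
        for gene, (a1, fa, fu, a2) in ASSOC_ROWS.items():
            ca = round(fa * 2 * STUDY_N_CASES)
            ua = round(fu * 2 * STUDY_N_CONTROLS)
            r = w.allelic_fisher(ca, 2 * STUDY_N_CASES - ca,
                                 ua, 2 * STUDY_N_CONTROLS - ua, a1=a1, a2=a2)
            orr, pp = expected[gene]
            assert round(r.odds_ratio, 2) == pytest.approx(orr)
            assert r.p_value == pytest.approx(pp, rel=5e-3)

    def test_equal_frequencies_give_unit_or(self):
        r = w.allelic_fisher(10, 90, 10, 90)
        assert r.odds_ratio == pytest.approx(1.0) and r.p_value == pytest.approx(1.0)

    def test_or_equals_cross_product(self):
        r = w.allelic_fisher(7, 157, 23, 177)
        assert r.odds_ratio == pytest.approx((7 * 177) / (157 * 23))

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError):
            w.allelic_fisher(0, 0, 5, 5)


class TestGenomeScan:
    def test_lambda_unity_on_uniform_quantiles(self):
        """lambda = 1 exactly when observed p equal the uniform reference."""
        n = 5001
        ps = (np.arange(1, n + 1) - 0.5) / n
        assert w.lambda_gc(ps) == pytest.approx(1.0, abs=1e-6)

    def test_lambda_near_unity_on_uniform_null(self):
        rng = np.random.default_rng(5)
        ps = rng.uniform(size=6000)
        assert 0.9 <= w.lambda_gc(ps) <= 1.1

    def test_empty_scan_flagged(self):
        geno = _mono_cohort([0.0] * 6, n_cases=3)
        results, summary, sig, genes = w.genome_scan([], geno)
        assert results == [] and summary.lambda_gc is None and sig == [] and genes == []

    def test_significant_and_suggestive_routing(self, planted_bundle):
        b = planted_bundle
        results, summary, sig, genes = w.genome_scan(
            b.variants, b.genotypes, significance=0.05, suggestive=0.2
        )
        assert summary.n_pass_filters == len(results)
        by_key = {r.variant_key: r for r in results}
        for key in sig:
            assert by_key[key].p_value < 0.05
        gene_of = {v.key: v.gene for v in b.variants}
        expected = sorted({gene_of[r.variant_key] for r in results if r.p_value < 0.2})
        assert genes == expected

    def test_qq_points_monotone(self, planted_bundle):
        b = planted_bundle
        _, summary, _, _ = w.genome_scan(b.variants, b.genotypes)
        qq = summary.qq_points
        assert (qq["expected"].diff().dropna() >= 0).all()
        assert (qq["observed"].diff().dropna() >= -1e-12).all()
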