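"""Shared fixtures and independent exact-enumeration oracles.

The oracles work in exact rational arithmetic on ``math.comb`` and never
call the code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest
from hypothesis import settings

import wesprio as w

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


# ----------------------------------------------------------------------
# Oracles
# ----------------------------------------------------------------------

def oracle_fisher(a: int, b: int, c: int, d: int, alternative: str) -> float:
    """Fisher exact p by full enumeration over tables with fixed margins."""
    r1, r2 = a + b, c + d
    k = a + c  # first-column margin
    n = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, k - x), comb(n, k))

    lo, hi = max(0, k - r2), min(k, r1)
    p_obs = prob(a)
    if alternative == "greater":
        total = sum(prob(x) for x in range(a, hi + 1))
    elif alternative == "two_sided_minlik":
        total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    else:
        raise ValueError(alternative)
    return float(min(total, Fraction(1)))


def oracle_hwe(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by enumerating every heterozygote count given allele counts."""
    n = n_AA + n_Aa + n_aa
    na = n_Aa + 2 * n_aa
    nA = n_Aa + 2 * n_AA

    def weight(h: int) -> Fraction:
        # multinomial weight of (hom_A, het, hom_a) given h heterozygotes
        hom_a, rem = divmod(na - h, 2)
        if rem or hom_a < 0:
            return Fraction(0)
        hom_A = n - h - hom_a
        if hom_A < 0:
            return Fraction(0)
        # P proportional to n! / (hom_A! h! hom_a!) * 2^h
        f = Fraction(2 ** h)
        f *= Fraction(comb(n, h) * comb(n - h, hom_a))
        return f

    weights = {h: weight(h) for h in range(0, min(na, nA) + 1)}
    total = sum(weights.values())
    p_obs = weights[n_Aa] / total
    return float(sum(v for v in weights.values() if Fraction(v, 1) / total <= p_obs) / total)


def oracle_hypergeom_upper(M: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), exact."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(M - K, n - j), comb(M, n))
    return float(min(total, Fraction(1)))


def oracle_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, spelled out by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        adj[i] = running
    return adj


# ----------------------------------------------------------------------
# Fixtures
# ----------------------------------------------------------------------

@pytest.fixture(scope="session")
def null_bundle():
    """40-gene cohort at study size with no planted effect."""
    return w.simulate_cohort(w.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def planted_bundle():
    """Cohort with one strong planted gene (carrier OR 5, control rate 0.05)."""
    af = w.af_for_carrier_rate(0.05, n_sites=1)
    cfg = w.SimulationConfig(
        seed=23,
        genes={f"G{i:02d}": 1 for i in range(20)},
        maf_spectrum=("fixed", af),
        deleterious_fraction=1.0,
        panel_missing_rate=0.0,
        panel_common_fraction=0.0,
        planted_effects={"G07": 5.0},
    )
    return w.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def written_bundle(tmp_path_factory, planted_bundle):
    d = tmp_path_factory.mktemp("bundle")
    w.write_bundle(planted_bundle, d)
    return d
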