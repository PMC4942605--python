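"""Exact and asymptotic contingency tests, oracles and scan behaviour.

The Freeman-Halton implementation is cross-checked against three
independent routes: a rational-arithmetic brute-force enumeration written
here, scipy's 2x2 Fisher test (which uses the same two-sided probability
rule), and a Monte-Carlo estimate sampling the margin-conditional null.
"""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from citrinspec.geo_stats import (
    ContingencyTable,
    freeman_halton_exact,
    omnibus_test,
    pearson_chi2,
    scan_genotypes,
    scan_spectrum,
    significant_set,
)

ALLELE_TOTALS = (55, 81, 392)


def brute_force_exact_p(cells) -> Fraction:
    """Rational-arithmetic probability-method p for an Rx2 table."""
    cells = [list(r) for r in cells]
    rows = [sum(r) for r in cells]
    col0 = sum(r[0] for r in cells)
    n = sum(rows)

    def prob(firsts):
        num = 1
        for f, r in zip(firsts, rows):
            num *= math.comb(r, f)
        return Fraction(num, math.comb(n, col0))

    observed = prob([r[0] for r in cells])
    total = Fraction(0)
    ranges = [range(min(r, col0) + 1) for r in rows]
    for firsts in product(*ranges):
        if sum(firsts) != col0:
            continue
        p = prob(firsts)
        if p <= observed:
            total += p
    return total


def carrier_table(counts, totals=ALLELE_TOTALS):
    return [[c, t - c] for c, t in zip(counts, totals)]


@pytest.mark.parametrize(
    "counts,expected_p",
    [
        ((0, 2, 0), 0.034),
        ((2, 0, 1), 0.041),
        ((1, 0, 0), 0.104),
        ((0, 1, 0), 0.258),
        ((0, 0, 1), 1.000),
    ],
)
def test_exact_test_reproduces_hand_verifiable_values(counts, expected_p):
    res = freeman_halton_exact(carrier_table(counts))
    assert res.method == "freeman-halton-exact"
    assert res.p == pytest.approx(expected_p, abs=5e-4)


def test_exact_singleton_p_is_simple_fraction():
    # one carrier in the north: only that table is as improbable as itself
    res = freeman_halton_exact(carrier_table((1, 0, 0)))
    assert res.p == pytest.approx(55 / 528, abs=1e-9)


def test_exact_degenerate_margin_is_one():
    assert freeman_halton_exact([[0, 10], [0, 20]]).p == 1.0
    assert freeman_halton_exact([[5, 0], [7, 0]]).p == 1.0


def test_exact_matches_rational_brute_force_on_3x2():
    for counts in [(0, 2, 0), (2, 0, 1), (3, 2, 2), (0, 5, 3), (9, 6, 30)]:
        table = carrier_table(counts)
        ours = freeman_halton_exact(table).p
        oracle = float(brute_force_exact_p(table))
        assert ours == pytest.approx(oracle, rel=1e-6)


def test_exact_matches_scipy_fisher_on_small_2x2_tables():
    # exhaustive over all 2x2 tables with every cell <= 6 (total <= 24)
    for a, b, c, d in product(range(7), repeat=4):
        table = [[a, b], [c, d]]
        ours = freeman_halton_exact(table).p
        theirs = stats.fisher_exact(table, alternative="two-sided")[1]
        assert ours == pytest.approx(theirs, rel=1e-7, abs=1e-12)


@given(
    st.lists(
        st.tuples(st.integers(0, 12), st.integers(0, 12)), min_size=2, max_size=3
    )
)
@settings(max_examples=150, deadline=None)
def test_exact_p_in_unit_interval_and_permutation_invariant(rows):
    table = np.array(rows)
    p = freeman_halton_exact(table).p
    assert 0.0 <= p <= 1.0
    assert freeman_halton_exact(table[::-1]).p == pytest.approx(p, rel=1e-9)
    assert freeman_halton_exact(table[:, ::-1]).p == pytest.approx(p, rel=1e-9)


def test_exact_matches_monte_carlo_conditional_null():
    counts, totals = (0, 2, 0), ALLELE_TOTALS
    exact = freeman_halton_exact(carrier_table(counts)).p
    rng = np.random.default_rng(20160711)
    k = sum(counts)

    def log_point_prob(cs):
        return sum(
            math.log(math.comb(t, c)) for c, t in zip(cs, totals)
        ) - math.log(math.comb(sum(totals), k))

    obs = log_point_prob(counts)
    draws = rng.multivariate_hypergeometric(totals, k, size=100_000)
    hits = sum(log_point_prob(d) <= obs + 1e-9 for d in draws)
    mc = hits / len(draws)
    se = math.sqrt(exact * (1 - exact) / len(draws))
    assert abs(mc - exact) <= 3 * se


def test_pearson_no_association_is_p_one():
    res = pearson_chi2([[10, 10], [10, 10]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_pearson_reproduces_published_pairwise_values():
    # IVS16ins3kb carriers, south (29/392) vs border (13/81)
    res = pearson_chi2([[29, 363], [13, 68]])
    assert round(res.p, 3) == 0.013
    # observed homozygosity, south (99/187) vs north (4/23)
    res = pearson_chi2([[99, 88], [4, 19]])
    assert round(res.p, 3) == 0.001


def test_pearson_2x2_equals_squared_two_proportion_z():
    a, b = (29, 392), (13, 81)
    res = pearson_chi2([[a[0], a[1] - a[0]], [b[0], b[1] - b[0]]])
    p1, p2 = a[0] / a[1], b[0] / b[1]
    pooled = (a[0] + b[0]) / (a[1] + b[1])
    z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / a[1] + 1 / b[1]))
    assert res.statistic == pytest.approx(z**2, rel=1e-12)


def test_pearson_zero_margin_rejected():
    with pytest.raises(ValueError):
        pearson_chi2([[0, 10], [0, 20]])


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable([[1, -1], [0, 2]])
    with pytest.raises(ValueError):
        ContingencyTable([1, 2, 3])


def test_omnibus_selects_chi2_for_common_variant():
    res = omnibus_test((15, 36, 257), ALLELE_TOTALS)
    assert res.method == "pearson-chi2"
    assert res.p < 0.0005


def test_omnibus_selects_exact_for_sparse_variant():
    res = omnibus_test((0, 2, 0), ALLELE_TOTALS)
    assert res.method == "freeman-halton-exact"
    assert res.p == pytest.approx(0.034, abs=5e-4)


def test_omnibus_all_zero_carriers_is_null():
    assert omnibus_test((0, 0, 0), ALLELE_TOTALS).p == 1.0


def test_scan_flags_the_seven_geographically_structured_variants(allele_fixture):
    reports = scan_spectrum(allele_fixture)
    assert significant_set(reports) == {
        "c.775C>T",
        "c.851_854del4",
        "c.1078C>T",
        "IVS11+1G>A",
        "c.1364G>T",
        "c.1399C>T",
        "IVS16ins3kb",
    }
    # pairwise results exist only below significant omnibus tests
    for ident, rep in reports.items():
        assert bool(rep.pairwise) == rep.significant


def test_scan_includes_unknown_row(allele_fixture):
    reports = scan_spectrum(allele_fixture)
    assert "?" in reports and not reports["?"].significant


def test_scan_flags_exactly_two_genotypes(genotype_fixture):
    sig = significant_set(scan_genotypes(genotype_fixture))
    assert sig == {
        "c.851_854del4/c.851_854del4",
        "c.1399C>T/c.851_854del4",
    }


def test_scan_rejects_empty_region(allele_fixture):
    from citrinspec.spectrum import RegionalSpectrum

    empty = RegionalSpectrum(
        counts={"v": {"a": 2, "b": 0}}, n_alleles={"a": 2, "b": 0}
    )
    with pytest.raises(ValueError, match="no observations"):
        scan_spectrum(empty)


def test_pairwise_threshold_is_bonferroni(allele_fixture):
    rep = scan_spectrum(allele_fixture)["c.851_854del4"]
    assert rep.alpha_pairwise == pytest.approx(0.05 / 3, abs=5e-4)
    south_vs_border = rep.pairwise[("border", "south")]
    assert south_vs_border.p < rep.alpha_pairwise
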