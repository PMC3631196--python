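"""Two-library count tests: oracles, symmetry, correction and DE calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from esimir.annotate import MiRNACountRow
from esimir.diffexp import (
    TestConfig as DecisionConfig,
    ac_pvalue,
    ac_pvalues,
    bonferroni,
    call_de,
    chisq_pvalue,
    fisher_pvalue,
    normalize_cpm,
    venn_classify,
)


# -- normalization -----------------------------------------------------------

def test_cpm_matches_published_accounting_row():
    # 276,160 conserved-miRNA reads of 2,278,581 mappable reads normalize to
    # ~121,198 per million, i.e. the 12.12% printed for that library
    cpm = normalize_cpm(276_160, 2_278_581)
    assert cpm == pytest.approx(276_160 / 2_278_581 * 1e6, rel=1e-12)
    assert round(cpm / 10_000, 2) == 12.12


def test_cpm_edge_values_and_errors():
    assert normalize_cpm(0, 10**6) == 0.0
    assert normalize_cpm(10**6, 10**6) == 10**6
    with pytest.raises(ValueError):
        normalize_cpm(1, 0)
    with pytest.raises(ValueError):
        normalize_cpm(5, 4)


# -- Audic-Claverie ----------------------------------------------------------

def _ac_oracle(x, y, n1, n2):
    """Direct log-space summation of the conditional distribution
    P(k | x) = (n2/n1)^k (x+k)!/(x! k!) / (1+n2/n1)^(x+k+1)."""

    def logpmf(k, x, n1, n2):
        r = n2 / n1
        return (k * math.log(r)
                + math.lgamma(x + k + 1) - math.lgamma(x + 1) - math.lgamma(k + 1)
                - (x + k + 1) * math.log1p(r))

    def tails(x, y, n1, n2):
        lower = sum(math.exp(logpmf(k, x, n1, n2)) for k in range(0, y + 1))
        point = math.exp(logpmf(y, x, n1, n2))
        return lower, 1.0 - lower + point

    lo1, up1 = tails(x, y, n1, n2)
    lo2, up2 = tails(y, x, n2, n1)
    return min(1.0, 2.0 * min(lo1, up1, lo2, up2))


@pytest.mark.parametrize(
    "x,y,n1,n2",
    [
        (5, 0, 10**6, 10**6),
        (0, 7, 10**6, 2 * 10**6),
        (12, 40, 10**6, 10**6),
        (100, 180, 2_278_581, 4_229_351),
        (3, 3, 500, 1500),
        (250, 400, 10**5, 10**5),
    ],
)
def test_ac_equals_direct_summation_oracle(x, y, n1, n2):
    assert ac_pvalue(x, y, n1, n2) == pytest.approx(
        _ac_oracle(x, y, n1, n2), rel=1e-10
    )


def test_ac_trivial_cases():
    assert ac_pvalue(0, 0, 10**6, 10**6) == 1.0
    assert ac_pvalue(100, 100, 10**6, 10**6) == 1.0


def test_ac_input_validation():
    with pytest.raises(ValueError):
        ac_pvalue(-1, 0, 10, 10)
    with pytest.raises(ValueError):
        ac_pvalue(1, 1, 0, 10)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    st.integers(0, 300), st.integers(0, 300),
    st.integers(1, 10**6), st.integers(1, 10**6),
)
def test_ac_symmetric_under_library_swap(x, y, n1, n2):
    p = ac_pvalue(x, y, n1, n2)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(ac_pvalue(y, x, n2, n1), rel=1e-12)


def test_vectorized_ac_matches_scalar():
    rng = np.random.default_rng(1)
    x = rng.poisson(50, 50)
    y = rng.poisson(50, 50)
    vec = ac_pvalues(x, y, 10**6, 10**6)
    for xi, yi, pi in zip(x, y, vec):
        assert pi == pytest.approx(ac_pvalue(int(xi), int(yi), 10**6, 10**6))


# -- Fisher ------------------------------------------------------------------

def _fisher_oracle(x, y, n1, n2):
    """Exhaustive hypergeometric enumeration over fixed-margin tables."""
    s = x + y
    pmf = {k: (math.comb(n1, k) * math.comb(n2, s - k)) / math.comb(n1 + n2, s)
           for k in range(max(0, s - n2), min(s, n1) + 1)}
    obs = pmf[x]
    return min(1.0, sum(p for p in pmf.values() if p <= obs * (1 + 1e-12)))


def test_fisher_extreme_table_closed_form():
    # table [10,0;0,10]: p = 2 / C(20,10)
    assert fisher_pvalue(10, 0, 10, 10) == pytest.approx(2 / math.comb(20, 10))


def test_fisher_balanced_is_one():
    assert fisher_pvalue(7, 7, 1000, 1000) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.data())
def test_fisher_equals_enumeration_small_tables(data):
    n1 = data.draw(st.integers(1, 39))
    n2 = data.draw(st.integers(1, 40 - n1))
    x = data.draw(st.integers(0, n1))
    y = data.draw(st.integers(0, n2))
    assert fisher_pvalue(x, y, n1, n2) == pytest.approx(
        _fisher_oracle(x, y, n1, n2), rel=1e-9
    )


# -- chi-squared -------------------------------------------------------------

def test_chisq_balanced_is_one():
    assert chisq_pvalue(50, 50, 10**6, 10**6) == pytest.approx(1.0)


def test_chisq_abstains_when_expected_below_one():
    assert chisq_pvalue(1, 0, 10**6, 10**6) is None


def test_chisq_matches_scipy_contingency():
    for x, y, n1, n2 in [(120, 80, 10**5, 10**5), (30, 90, 10**4, 3 * 10**4)]:
        expect = stats.chi2_contingency(
            [[x, n1 - x], [y, n2 - y]], correction=False
        ).pvalue
        assert chisq_pvalue(x, y, n1, n2) == pytest.approx(expect)


def test_three_tests_agree_for_large_counts():
    # -log10 p of AC, Fisher and chi-squared within 20% relative at counts >= 500
    x, y, n = 500, 650, 10**6
    logs = [
        -math.log10(p) for p in (
            ac_pvalue(x, y, n, n),
            fisher_pvalue(x, y, n, n),
            chisq_pvalue(x, y, n, n),
        )
    ]
    assert max(logs) - min(logs) <= 0.2 * max(logs)


# -- correction and classification ------------------------------------------

def test_bonferroni():
    assert bonferroni(0.001, 10) == pytest.approx(0.01)
    assert bonferroni(0.5, 240) == 1.0
    assert bonferroni(0.3, 1) == 0.3
    with pytest.raises(ValueError):
        bonferroni(1.2, 3)
    with pytest.raises(ValueError):
        bonferroni(0.5, 0)


def _row(name, f, m):
    return MiRNACountRow(name, "T" * 22, f, m)


def test_venn_partition():
    rows = [_row("a", 5, 0), _row("b", 3, 7), _row("c", 0, 9), _row("d", 0, 0)]
    with pytest.warns(UserWarning):
        venn = venn_classify(rows)
    assert [r.name for r in venn["female_specific"]] == ["a"]
    assert [r.name for r in venn["male_specific"]] == ["c"]
    assert [r.name for r in venn["co_expressed"]] == ["b"]
    assert sum(len(v) for v in venn.values()) == 3


def test_call_de_detects_planted_fold_and_spares_null():
    n = 10**6
    rows = [_row("de-up", 10_000, 80_000), _row("null", 10_000, 10_050),
            _row("only-f", 20, 0)]
    recs = {r.name: r for r in call_de(rows, n, n)}
    assert recs["de-up"].significant and recs["de-up"].direction == "up"
    assert not recs["null"].significant and recs["null"].direction == "NS"
    assert recs["only-f"].venn == "female_specific"
    assert recs["only-f"].p_ac is None  # tests run on co-expressed rows only


def test_balanced_counts_not_significant():
    recs = call_de([_row("m", 400, 400)], 10**6, 10**6)
    assert not recs[0].significant


def test_swap_symmetry_flips_direction_keeps_pvalues():
    rows = [_row("a", 1000, 4000), _row("b", 500, 480)]
    fwd = {r.name: r for r in call_de(rows, 10**6, 2 * 10**6)}
    swapped_rows = [_row("a", 4000, 1000), _row("b", 480, 500)]
    rev = {r.name: r for r in call_de(swapped_rows, 2 * 10**6, 10**6)}
    for name in ("a", "b"):
        assert fwd[name].p_ac == pytest.approx(rev[name].p_ac)
        assert fwd[name].p_fisher == pytest.approx(rev[name].p_fisher)
        assert fwd[name].significant == rev[name].significant
    assert fwd["a"].direction == "up" and rev["a"].direction == "down"


def test_config_validation():
    with pytest.raises(ValueError):
        DecisionConfig(alpha=0.0)
    with pytest.raises(ValueError):
        DecisionConfig(rule="two-of-three")
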