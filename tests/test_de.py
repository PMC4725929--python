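"""Unit and property tests for the no-replicate exact Poisson DE test."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from grazetx import de
from grazetx.io import CountTable
from oracles import ac_two_sided_exact


@pytest.mark.parametrize(
    "count,length,total,expected",
    [(1000, 1000, 1_000_000, 1000.0), (0, 2000, 50_000_000, 0.0), (250, 500, 10_000_000, 50.0)],
)
def test_fpkm_unit_cases(count, length, total, expected):
    assert de.compute_fpkm(count, length, total) == pytest.approx(expected)


def test_fpkm_rejects_degenerate_arguments():
    with pytest.raises(ValueError):
        de.compute_fpkm(1, 0, 1000)
    with pytest.raises(ValueError):
        de.compute_fpkm(1, 100, 0)


@pytest.mark.parametrize(
    "a,b,expected",
    [(1.0, 4.0, 2.0), (0.0, 1.0, np.log2(1 / 0.01)), (0.0, 0.0, 0.0)],
)
def test_log2_fold_change_zero_substitution(a, b, expected):
    assert de.log2_fold_change(a, b) == pytest.approx(expected, rel=1e-12)


@given(
    a=st.floats(min_value=0, max_value=1e6, allow_nan=False),
    b=st.floats(min_value=0, max_value=1e6, allow_nan=False),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_log2_fold_change_antisymmetric(a, b):
    assert de.log2_fold_change(a, b) == pytest.approx(-de.log2_fold_change(b, a), abs=1e-9)


@pytest.mark.parametrize("y,x,expected", [(0, 0, 0.5), (1, 0, 0.25)])
def test_conditional_pmf_closed_form_cases(y, x, expected):
    assert de.ac_pmf(y, x, 10**6, 10**6) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("x", [0, 1, 5, 20])
@pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
def test_conditional_pmf_normalizes(x, ratio):
    ys = np.arange(0, 3000)
    total = de.ac_pmf(ys, x, 1_000_000, int(1_000_000 * ratio)).sum()
    assert total == pytest.approx(1.0, abs=1e-9)


def test_cumulative_matches_pmf_summation_and_limits():
    n1, n2 = 2_000_000, 1_000_000
    for x, y in [(5, 10), (0, 0), (3, 0)]:
        direct = sum(de.ac_pmf(k, x, n1, n2) for k in range(y + 1))
        assert de.ac_cumulative(y, x, n1, n2) == pytest.approx(direct, rel=1e-10)
    assert de.ac_cumulative(5000, 5, n1, n2) == pytest.approx(1.0, abs=1e-9)


def test_cumulative_agrees_with_negative_binomial_reference():
    # independent cross-check: Y | x is NB(x+1, N1/(N1+N2))
    for x, y, n1, n2 in [(5, 12, 10**6, 10**6), (20, 3, 10**6, 2 * 10**6), (0, 7, 3 * 10**6, 10**6)]:
        ref = stats.nbinom.cdf(y, x + 1, n1 / (n1 + n2))
        assert de.ac_cumulative(y, x, n1, n2) == pytest.approx(ref, rel=1e-12)


def test_two_sided_p_matches_exact_oracle_sampled():
    rng = np.random.default_rng(7)
    for _ in range(200):
        x, y = int(rng.integers(0, 40)), int(rng.integers(0, 40))
        n1, n2 = [(10**6, 5 * 10**5), (10**6, 10**6), (10**6, 2 * 10**6)][int(rng.integers(3))]
        exact = float(ac_two_sided_exact(x, y, n1, n2))
        assert de.ac_two_sided_p(x, y, n1, n2) == pytest.approx(exact, rel=1e-10)


def test_two_sided_p_stable_at_large_counts():
    # the log-space/incomplete-beta path must not overflow for x+y ~ 1e6
    p = de.ac_two_sided_p(500_000, 501_000, 10**7, 10**7)
    assert 0 < p <= 1
    exactly_equal = de.ac_two_sided_p(500_000, 500_000, 10**7, 10**7)
    assert exactly_equal == pytest.approx(1.0)


@pytest.mark.parametrize("x,y", [(0, 0), (10, 10)])
def test_two_sided_p_capped_at_one_for_identical_counts(x, y):
    assert de.ac_two_sided_p(x, y, 10**6, 10**6) == pytest.approx(1.0)


@given(
    x=st.integers(min_value=0, max_value=200),
    y=st.integers(min_value=0, max_value=200),
    n1=st.integers(min_value=1000, max_value=10**7),
    n2=st.integers(min_value=1000, max_value=10**7),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_two_sided_p_symmetric_under_sample_swap(x, y, n1, n2):
    assert de.ac_two_sided_p(x, y, n1, n2) == pytest.approx(
        de.ac_two_sided_p(y, x, n2, n1), abs=1e-12
    )


def test_bh_qvalues_step_up():
    assert de.bh_qvalues([0.04]) == pytest.approx([0.04])
    assert de.bh_qvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_qvalues_order_equivariant_and_monotone():
    rng = np.random.default_rng(3)
    p = rng.uniform(1e-6, 1, size=50)
    q = de.bh_qvalues(p)
    perm = rng.permutation(50)
    assert de.bh_qvalues(p[perm]) == pytest.approx(q[perm])
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_bh_qvalues_rejects_invalid():
    with pytest.raises(ValueError):
        de.bh_qvalues([])
    with pytest.raises(ValueError):
        de.bh_qvalues([0.5, 0.0])


@pytest.mark.parametrize(
    "q,lfc,expected",
    [(0.0005, 1.5, True), (0.0005, 0.5, False), (0.002, 3.0, False)],
)
def test_call_de_thresholds(q, lfc, expected):
    df = pd.DataFrame({"q_value": [q], "log2fc": [lfc]})
    assert de.call_de(df)["is_de"].iloc[0] == expected


def _tiny_table():
    counts = pd.DataFrame(
        {"A": [100, 0, 40], "B": [10, 0, 42]},
        index=pd.Index(["t1", "t2", "t3"], name="transcript_id"),
    )
    lengths = pd.Series([1000, 500, 2000], index=counts.index, name="length_bp")
    return CountTable(counts=counts, lengths=lengths, totals={"A": 10**6, "B": 10**6})


def test_de_table_retains_zero_pairs_and_orients_fold_change():
    df = de.de_table(_tiny_table(), "A", "B").set_index("transcript_id")
    assert df.loc["t2", "p_value"] == 1.0
    assert df.loc["t2", "log2fc"] == 0.0
    assert df.loc["t1", "log2fc"] == pytest.approx(np.log2(10 / 100))
    assert 0 < df["q_value"].min() and df["q_value"].max() <= 1


def test_de_table_unknown_sample_errors():
    with pytest.raises(ValueError, match="sample"):
        de.de_table(_tiny_table(), "A", "nope")


def test_planted_large_effect_recovered_with_high_power():
    # |log2 effect| = 3 at expected baseline count >= 50 should be called DE
    # almost always under the default thresholds
    rng = np.random.default_rng(17)
    n = 1000
    base = rng.uniform(50, 500, size=n)
    x = rng.poisson(base)
    y = rng.poisson(base * 8)  # log2 effect of +3
    lengths = np.full(n, 1000)
    counts = pd.DataFrame(
        {"A": x, "B": y},
        index=pd.Index([f"t{i}" for i in range(n)], name="transcript_id"),
    )
    table = CountTable(
        counts=counts,
        lengths=pd.Series(lengths, index=counts.index, name="length_bp"),
        totals={"A": 10**6, "B": 10**6},
    )
    df = de.de_table(table, "A", "B")
    assert df["is_de"].mean() >= 0.95
    assert (df.loc[df["is_de"], "log2fc"] > 0).all()
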