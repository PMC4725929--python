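"""Hypergeometric over-representation and dual-context selection tests."""

import numpy as np
import pandas as pd
import pytest

from grazetx import enrichment as enr
from grazetx.io import AnnotationMap
from oracles import hypergeom_upper_by_enumeration, hypergeom_upper_exact


def test_hypergeom_trivial_cases():
    assert enr.hypergeom_p(100, 10, 5, 0) == 1.0
    assert enr.hypergeom_p(10, 5, 2, 2) == pytest.approx(2 / 9, rel=1e-12)
    assert enr.hypergeom_p(50, 7, 50, 7) == pytest.approx(1.0)


def test_hypergeom_invalid_inputs():
    with pytest.raises(ValueError):
        enr.hypergeom_p(10, 5, 2, 3)  # m > min(n, M)
    with pytest.raises(ValueError):
        enr.hypergeom_p(10, 11, 2, 1)  # n > N


def test_hypergeom_matches_literal_enumeration_of_draws():
    rng = np.random.default_rng(5)
    for _ in range(40):
        N = int(rng.integers(2, 12))
        n = int(rng.integers(1, N + 1))
        M = int(rng.integers(1, N + 1))
        m = int(rng.integers(0, min(n, M) + 1))
        exact = float(hypergeom_upper_by_enumeration(N, n, M, m))
        assert enr.hypergeom_p(N, n, M, m) == pytest.approx(exact, rel=1e-12)


def test_hypergeom_matches_exact_tail_on_sampled_grid():
    rng = np.random.default_rng(6)
    for _ in range(200):
        N = int(rng.integers(2, 26))
        n = int(rng.integers(0, N + 1))
        M = int(rng.integers(0, N + 1))
        m = int(rng.integers(0, min(n, M) + 1))
        exact = float(hypergeom_upper_exact(N, n, M, m))
        assert enr.hypergeom_p(N, n, M, m) == pytest.approx(exact, rel=1e-12)


def test_bonferroni_correction():
    corrected, sig = enr.bonferroni_correct([0.001] + [0.5] * 49)
    assert corrected[0] == pytest.approx(0.05)
    assert sig[0]
    corrected, sig = enr.bonferroni_correct([0.002] + [0.5] * 49)
    assert corrected[0] == pytest.approx(0.10)
    assert not sig[0]
    corrected, _ = enr.bonferroni_correct([0.03])
    assert corrected[0] == pytest.approx(0.03)
    with pytest.raises(ValueError):
        enr.bonferroni_correct([])


def _planted_annotation():
    genes = [f"g{i}" for i in range(100)]
    terms = {
        "T:A": frozenset(genes[:10]),
        "T:B": frozenset(genes[10:50]),
        "T:C": frozenset(genes[50:]),
    }
    return AnnotationMap(name="test", terms=terms, universe=frozenset(genes))


def test_enrich_planted_fixture_matches_oracle():
    ann = _planted_annotation()
    degs = set(f"g{i}" for i in range(8)) | set(f"g{i}" for i in range(60, 72))  # 8 of T:A
    res = enr.enrich(ann, degs).set_index("term_id")
    assert res.loc["T:A", "m"] == 8
    expected = float(hypergeom_upper_exact(100, 20, 10, 8))
    assert res.loc["T:A", "p_value"] == pytest.approx(expected, rel=1e-10)


def test_enrich_empty_deg_set_gives_unit_pvalues():
    res = enr.enrich(_planted_annotation(), set())
    assert (res["p_value"] == 1.0).all()
    assert (res["m"] == 0).all()


def test_enrich_partition_conserves_deg_count():
    ann = _planted_annotation()
    degs = {f"g{i}" for i in range(0, 100, 7)} | {"outside_universe"}
    res = enr.enrich(ann, degs)
    disjoint = res[res["term_id"].isin(["T:B", "T:C"])]
    in_universe = len(degs) - 1
    in_bc = sum(1 for g in degs if g != "outside_universe" and int(g[1:]) >= 10)
    assert disjoint["m"].sum() == in_bc
    assert (res["n"] == in_universe).all()


def test_enrich_empty_universe_errors():
    with pytest.raises(ValueError):
        enr.enrich(AnnotationMap(name="x", terms={}), {"g1"})


def _results(term_ps):
    df = pd.DataFrame(
        {"term_id": list(term_ps), "p_value": list(term_ps.values())}
    )
    df["p_bonferroni"] = df["p_value"]  # single-test scale for direct control
    return df


@pytest.mark.parametrize(
    "rp,tp,expected",
    [(0.01, 0.01, True), (0.01, 0.20, False), (0.05, 0.05, True)],
)
def test_dual_context_selection_rule(rp, tp, expected):
    sel = enr.dual_context_select(_results({"T:X": rp}), _results({"T:X": tp}))
    assert bool(sel.loc[sel["term_id"] == "T:X", "selected"].iloc[0]) is expected


def test_dual_context_missing_term_warns_and_defaults_to_one():
    with pytest.warns(UserWarning, match="one context only"):
        sel = enr.dual_context_select(
            _results({"T:X": 0.01, "T:Y": 0.02}), _results({"T:X": 0.01})
        )
    row = sel[sel["term_id"] == "T:Y"].iloc[0]
    assert row["tolerance_p"] == 1.0
    assert not row["selected"]


def test_dual_context_sorted_by_tolerance_p_then_term():
    sel = enr.dual_context_select(
        _results({"T:A": 0.01, "T:B": 0.01, "T:C": 0.01}),
        _results({"T:A": 0.04, "T:B": 0.02, "T:C": 0.02}),
    )
    assert list(sel["term_id"]) == ["T:B", "T:C", "T:A"]


def test_planted_fourfold_enrichment_survives_dual_context_selection():
    # a term with 4-fold DEG over-representation (universe 2000, term 100,
    # DEG 200) planted in both contexts should essentially always be selected
    rng = np.random.default_rng(12)
    genes = [f"g{i}" for i in range(2000)]
    hits = 0
    n_reps = 50
    for _ in range(n_reps):
        term_genes = set(rng.choice(genes, size=100, replace=False))
        results = {}
        for ctx in ("response", "tolerance"):
            # 4-fold over-representation: 40 of the 200 DEGs in the term
            inside = rng.choice(sorted(term_genes), size=40, replace=False)
            outside = rng.choice(
                sorted(set(genes) - term_genes), size=160, replace=False
            )
            degs = set(inside) | set(outside)
            ann = AnnotationMap(
                name="x",
                terms={"T:planted": frozenset(term_genes)},
                universe=frozenset(genes),
            )
            results[ctx] = enr.enrich(ann, degs)
        sel = enr.dual_context_select(results["response"], results["tolerance"])
        hits += int(sel["selected"].iloc[0])
    assert hits / n_reps >= 0.95
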