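"""Hypergeometric over-representation of terms/pathways in a DEG set.

With N universe genes (genes carrying at least one annotation in the
ontology), n of them differentially expressed, M annotated to a term and m of
the DEGs annotated to it, the enrichment p-value is the upper hypergeometric
tail Pr(X >= m). Bonferroni-corrected p-values and BH q-values are reported
for every term; the dual-context selection keeps terms significant in both the
grazing-response contrast and the tolerance contrast.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

__all__ = [
    "hypergeom_p",
    "bonferroni_correct",
    "enrich",
    "dual_context_select",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def hypergeom_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric p-value Pr(X >= m).

    N: universe size, n: DEGs in the universe, M: universe genes annotated to
    the term, m: DEGs annotated to the term. ``m = 0`` returns 1 exactly.
    """
    if not (0 <= m <= min(n, M) and 0 <= n <= N and 0 <= M <= N):
        raise ValueError(f"invalid enrichment input N={N} n={n} M={M} m={m}")
    if m == 0:
        return 1.0
    p = float(stats.hypergeom.sf(m - 1, N, M, n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bonferroni_correct(p_values, alpha: float = DEFAULT_ALPHA):
    """Bonferroni-corrected p-values (min(1, k*p)) and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    corrected = np.minimum(1.0, p * p.size)
    return corrected, corrected <= alpha


def enrich(
    annotation: AnnotationMap,
    deg_genes: Iterable[str],
    contrast_label: str = "",
) -> pd.DataFrame:
    """Score every term of an ontology for over-representation in a DEG set.

    DEG genes outside the ontology's universe are dropped (with a logged
    count). Every term is reported, including m = 0 terms at p = 1. Output is
    sorted by term_id for determinism and carries raw p, Bonferroni-corrected
    p and BH q columns.
    """
    if not annotation.universe:
        raise ValueError("annotation universe is empty")
    degs = set(deg_genes)
    in_universe = degs & annotation.universe
    dropped = len(degs) - len(in_universe)
    if dropped:
        logger.info(
            "%s: %d DEG genes outside the %s universe dropped",
            contrast_label or "enrich", dropped, annotation.name,
        )
    N = len(annotation.universe)
    n = len(in_universe)
    rows = []
    for term in sorted(annotation.terms):
        genes = annotation.terms[term]
        M = len(genes)
        m = len(genes & in_universe)
        rows.append((term, N, n, M, m, hypergeom_p(N, n, M, m)))
    df = pd.DataFrame(rows, columns=["term_id", "N", "n", "M", "m", "p_value"])
    df["p_bonferroni"] = bonferroni_correct(df["p_value"].to_numpy())[0]
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    if contrast_label:
        df.insert(1, "contrast", contrast_label)
    return df


def dual_context_select(
    response_results: pd.DataFrame,
    tolerance_results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Keep terms significant in both the response and tolerance contexts.

    A term is selected iff its p-value is <= alpha in both contrasts
    (Bonferroni-corrected by default, raw with ``use_corrected=False``).
    Terms present in only one context are kept with the missing p set to 1 and
    a warning. Output is sorted by ascending tolerance p (ties by term_id),
    mirroring the ranked presentation of the selected-term tables.
    """
    col = "p_bonferroni" if use_corrected else "p_value"
    r = response_results.set_index("term_id")[col]
    t = tolerance_results.set_index("term_id")[col]
    all_terms = r.index.union(t.index)
    missing = all_terms.difference(r.index).tolist() + all_terms.difference(t.index).tolist()
    if missing:
        warnings.warn(
            f"terms present in one context only (p set to 1): {sorted(missing)[:10]}",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "term_id": all_terms,
            "response_p": r.reindex(all_terms).fillna(1.0).to_numpy(),
            "tolerance_p": t.reindex(all_terms).fillna(1.0).to_numpy(),
        }
    )
    out["selected"] = (out["response_p"] <= alpha) & (out["tolerance_p"] <= alpha)
    out = out.sort_values(["tolerance_p", "term_id"], kind="mergesort").reset_index(drop=True)
    return out
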