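"""Independent high-precision oracles used only by the test suite.

These deliberately avoid the package's own numerical paths: exact rational
arithmetic (fractions.Fraction, math.comb) for the conditional Poisson test
and the hypergeometric tail, literal draw enumeration for tiny universes, and
whole-CDS translation for coding-effect checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

from Bio.Seq import Seq


def ac_pmf_exact(y: int, x: int, r: Fraction) -> Fraction:
    """P(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)) in exact rationals."""
    return comb(x + y, y) * r**y / (1 + r) ** (x + y + 1)


def ac_lower_exact(y: int, x: int, r: Fraction) -> Fraction:
    return sum(ac_pmf_exact(k, x, r) for k in range(y + 1))


def ac_upper_exact(y: int, x: int, r: Fraction) -> Fraction:
    return 1 - sum(ac_pmf_exact(k, x, r) for k in range(y))


def ac_two_sided_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Doubled smaller tail with the same canonical orientation the package
    uses: condition on the lexicographically smaller (count, total) pair."""
    if (y, n2) < (x, n1):
        x, y, n1, n2 = y, x, n2, n1
    r = Fraction(n2, n1)
    return min(Fraction(1), 2 * min(ac_lower_exact(y, x, r), ac_upper_exact(y, x, r)))


def hypergeom_upper_exact(N: int, n: int, M: int, m: int) -> Fraction:
    """Pr(X >= m) by exact summation of the hypergeometric pmf."""
    if m == 0:
        return Fraction(1)
    total = comb(N, n)
    s = sum(comb(M, i) * comb(N - M, n - i) for i in range(m, min(n, M) + 1))
    return Fraction(s, total)


def hypergeom_upper_by_enumeration(N: int, n: int, M: int, m: int) -> Fraction:
    """Pr(X >= m) by literally enumerating every n-subset of an N-universe
    whose first M elements are 'annotated'. Only feasible for tiny N."""
    annotated = set(range(M))
    hits = sum(1 for draw in combinations(range(N), n) if len(annotated.intersection(draw)) >= m)
    return Fraction(hits, comb(N, n))


def effect_by_full_translation(sequence: str, cds: tuple[int, int], pos: int, alt: str) -> str:
    """'synonymous' or 'nonsynonymous' by translating the whole CDS before and
    after the substitution and comparing protein strings."""
    start, end = cds
    assert start <= pos <= end
    before = str(Seq(sequence[start - 1 : end]).translate())
    mutated = sequence[: pos - 1] + alt + sequence[pos:]
    after = str(Seq(mutated[start - 1 : end]).translate())
    return "synonymous" if before == after else "nonsynonymous"
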