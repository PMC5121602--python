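"""Overlap statistics for gene and peak sets: 2x2 contingency construction,
chi-square with Yates' continuity correction, exact hypergeometric overlap,
and Venn region counts.

The Yates-corrected chi-square uses the 2x2 shortcut form

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d))

with the continuity term floored at zero, and a df = 1 upper-tail p-value.
p-values below 2.2e-16 are formatted as "< 2.2e-16" in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Mapping

from scipy import stats

__all__ = [
    "P_FLOOR",
    "ContingencyTable2x2",
    "OverlapResult",
    "build_contingency",
    "chisq_yates",
    "hypergeom_overlap",
    "overlap_test",
    "venn_counts",
    "format_p",
]

#: Reporting floor for p-values (values below print as "< 2.2e-16").
P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (in both, A only, B only, neither)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.N == 0:
            raise ValueError("empty contingency table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row A, row not-A, col B, col not-B) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class OverlapResult:
    table: ContingencyTable2x2
    chi2_yates: float
    p_chi2: float
    p_hypergeom: float
    jaccard: float | None


def build_contingency(
    set_a: Iterable[Hashable], set_b: Iterable[Hashable], universe: Iterable[Hashable]
) -> ContingencyTable2x2:
    """Classify every universe element by membership in A and B."""
    A, B, U = set(set_a), set(set_b), set(universe)
    outside = (A | B) - U
    if outside:
        raise ValueError(f"elements outside universe: {sorted(outside)[:5]}")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def chisq_yates(t: ContingencyTable2x2) -> tuple[float, float]:
    """Yates-corrected chi-square statistic and df = 1 upper-tail p-value.

    A zero margin leaves the statistic undefined and raises.
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a margin is zero")
    num = max(abs(t.a * t.d - t.b * t.c) - t.N / 2.0, 0.0)
    chi2 = t.N * num * num / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def hypergeom_overlap(t: ContingencyTable2x2) -> float:
    """Exact upper-tail P(X >= a): population N, successes a+b, draws a+c."""
    return float(stats.hypergeom.sf(t.a - 1, t.N, t.a + t.b, t.a + t.c))


def overlap_test(
    set_a: Iterable[Hashable], set_b: Iterable[Hashable], universe: Iterable[Hashable]
) -> OverlapResult:
    """Full overlap report: table, Yates chi-square, hypergeometric, Jaccard."""
    t = build_contingency(set_a, set_b, universe)
    chi2, p_chi2 = chisq_yates(t)
    union = t.a + t.b + t.c
    return OverlapResult(
        table=t,
        chi2_yates=chi2,
        p_chi2=p_chi2,
        p_hypergeom=hypergeom_overlap(t),
        jaccard=t.a / union if union else None,
    )


def venn_counts(named_sets: Mapping[str, Iterable[Hashable]]) -> dict[frozenset, int]:
    """Disjoint-region counts for 2 or 3 named sets.

    Keys are frozensets of the set names whose exclusive intersection the
    count describes; region counts sum to the size of the union.
    """
    sets = {name: set(v) for name, v in named_sets.items()}
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    names = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    inside -= sets[other]
            out[frozenset(combo)] = len(inside)
    return out


def format_p(p: float, floor: float = P_FLOOR) -> str:
    """Render a p-value, flooring tiny values at the reporting convention."""
    if p < floor:
        return f"< {floor:g}"
    return format(p, ".3g")
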