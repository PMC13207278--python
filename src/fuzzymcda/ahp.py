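"""Fuzzy AHP: criterion weights from pairwise-comparison judgments.

An expert compares every pair of criteria on a fuzzy linguistic scale,
producing an n x n reciprocal matrix of TFNs.  A panel of such matrices is
consolidated by the component-wise geometric mean.  Crisp weights are then
derived by Chang's extent analysis:

* fuzzy synthetic extent of criterion i:
  ``S_i = (row-sum of row i) (x) (sum of all entries)^-1``
* degree of possibility that one extent exceeds another:
  ``V(S2 >= S1) = 1`` if ``m2 >= m1``; ``0`` if ``l1 >= u2``; otherwise
  ``(l1 - u2) / ((m2 - u2) - (m1 - l1))``
* minimum degree ``d'(i) = min_{k != i} V(S_i >= S_k)``, normalized to the
  crisp weight vector.

Panel consistency is checked on the defuzzified matrix through the classical
eigenvalue consistency ratio CR = CI / RI with CI = (lambda_max - n)/(n - 1);
CR < 0.10 is the usual acceptance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import WeightVector
from .tfn import TFN, defuzzify, tfn_add, tfn_geometric_mean, tfn_mul, tfn_reciprocal

__all__ = [
    "FuzzyComparisonMatrix",
    "ConsistencyReport",
    "aggregate_panel",
    "chang_extent_weights",
    "consistency_ratio",
    "possibility_degree",
    "RANDOM_INDEX",
    "DegenerateWeightsError",
]

#: Saaty random-index constants for matrix orders 3..10.
RANDOM_INDEX = {3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

_RECIPROCITY_ATOL = 1e-9


class DegenerateWeightsError(ValueError):
    """All minimum possibility degrees are zero; no weight vector can be formed."""


@dataclass
class FuzzyComparisonMatrix:
    """n x n reciprocal grid of TFN pairwise judgments.

    Diagonal entries must be (1,1,1); the lower triangle must be the fuzzy
    reciprocal of the upper triangle within a small floating tolerance.
    """

    entries: list[list[TFN]]

    def __post_init__(self) -> None:
        n = len(self.entries)
        if n == 0 or any(len(row) != n for row in self.entries):
            raise ValueError("comparison matrix must be square and non-empty")
        one = TFN.crisp(1.0)
        for i in range(n):
            if not self.entries[i][i].approx_equal(one, _RECIPROCITY_ATOL):
                raise ValueError(f"diagonal entry ({i},{i}) must be (1,1,1)")
            for j in range(i + 1, n):
                upper = self.entries[i][j]
                if upper.l <= 0:
                    raise ValueError(f"entry ({i},{j}) must be strictly positive")
                if not self.entries[j][i].approx_equal(tfn_reciprocal(upper), _RECIPROCITY_ATOL):
                    raise ValueError(f"entry ({j},{i}) is not the reciprocal of entry ({i},{j})")

    @property
    def n(self) -> int:
        return len(self.entries)

    @classmethod
    def from_upper_triangle(cls, n: int, upper: dict[tuple[int, int], TFN]) -> "FuzzyComparisonMatrix":
        """Build a valid matrix from upper-triangle judgments only."""
        one = TFN.crisp(1.0)
        grid: list[list[TFN]] = [[one] * n for _ in range(n)]
        for (i, j), t in upper.items():
            if not i < j:
                raise ValueError(f"upper-triangle key ({i},{j}) must have i < j")
            grid[i][j] = t
            grid[j][i] = tfn_reciprocal(t)
        return cls(grid)


def aggregate_panel(judgments: Sequence[FuzzyComparisonMatrix]) -> FuzzyComparisonMatrix:
    """Consolidate a panel by entry-wise geometric mean.

    Geometric means of reciprocal entries are reciprocal in exact arithmetic,
    but floating error accumulates; the lower triangle is therefore recomputed
    as the exact reciprocal of the aggregated upper triangle so the type
    invariant holds exactly.
    """
    if not judgments:
        raise ValueError("empty panel")
    n = judgments[0].n
    if any(m.n != n for m in judgments):
        raise ValueError("all panel matrices must have the same dimension")
    upper = {
        (i, j): tfn_geometric_mean(m.entries[i][j] for m in judgments)
        for i in range(n)
        for j in range(i + 1, n)
    }
    return FuzzyComparisonMatrix.from_upper_triangle(n, upper)


def possibility_degree(s2: TFN, s1: TFN) -> float:
    """``V(S2 >= S1)``: degree of possibility that extent S2 exceeds S1."""
    if s2.m >= s1.m:
        return 1.0
    if s1.l >= s2.u:
        return 0.0
    return (s1.l - s2.u) / ((s2.m - s2.u) - (s1.m - s1.l))


def chang_extent_weights(matrix: FuzzyComparisonMatrix) -> WeightVector:
    """Crisp criterion weights by Chang's extent analysis.

    Returns a :class:`WeightVector` whose fuzzy entries are the synthetic
    extents ``S_i`` and whose crisp entries are the normalized minimum
    possibility degrees.  Extent analysis can assign a zero weight to a
    criterion whose extent is dominated by every other; this is surfaced as
    a warning (the zero is genuine, not a numerical artifact).
    """
    n = matrix.n
    zero = TFN.crisp(0.0)
    row_sums = [sum((matrix.entries[i][j] for j in range(n)), zero) for i in range(n)]
    total = sum(row_sums, zero)
    inv_total = tfn_reciprocal(total)
    extents = [tfn_mul(rs, inv_total) for rs in row_sums]

    d_prime = np.array(
        [
            min(possibility_degree(extents[i], extents[k]) for k in range(n) if k != i)
            if n > 1
            else 1.0
            for i in range(n)
        ]
    )
    s = d_prime.sum()
    if s <= 0:
        raise DegenerateWeightsError(
            "all minimum possibility degrees are zero; the comparison matrix is too extreme "
            "for extent analysis to produce weights"
        )
    if np.any(d_prime == 0):
        warnings.warn(
            "extent analysis assigned zero weight to one or more criteria "
            "(their fuzzy extents are dominated); consider revisiting the judgments",
            stacklevel=2,
        )
    crisp = d_prime / s
    ids = [f"C{i+1}" for i in range(n)]
    return WeightVector(ids, extents, list(crisp))


@dataclass(frozen=True)
class ConsistencyReport:
    lambda_max: float
    ci: float
    ri: float
    cr: float
    passed: bool


def consistency_ratio(
    matrix: FuzzyComparisonMatrix, method: str = "centroid", threshold: float = 0.10
) -> ConsistencyReport:
    """Eigenvalue consistency ratio of the defuzzified comparison matrix.

    ``lambda_max`` is the principal eigenvalue of the crisp (defuzzified)
    matrix, CI = (lambda_max - n)/(n - 1) and CR = CI/RI with the standard
    random-index constants (defined for 3 <= n <= 10).
    """
    n = matrix.n
    if n not in RANDOM_INDEX:
        raise ValueError(f"consistency ratio is defined for 3 <= n <= 10, got n = {n}")
    crisp = np.array([[defuzzify(t, method) for t in row] for row in matrix.entries])
    eigvals = np.linalg.eigvals(crisp)
    lam = float(np.max(eigvals.real))
    ci = (lam - n) / (n - 1)
    ri = RANDOM_INDEX[n]
    cr = ci / ri
    return ConsistencyReport(lambda_max=lam, ci=ci, ri=ri, cr=cr, passed=cr < threshold)
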