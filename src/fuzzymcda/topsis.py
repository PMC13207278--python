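"""Fuzzy TOPSIS ranking and its crisp midpoint counterpart.

The fuzzy variant follows the classical four steps on triangular fuzzy
numbers: (i) normalize the decision matrix and weight it by the fuzzy
criterion weights; (ii) take the fuzzy positive and negative ideal solutions
(FPIS/FNIS) as the component-wise maximum and minimum weighted value across
alternatives for each criterion; (iii) measure each alternative's distance to
both ideals as the sum over criteria of vertex distances; (iv) rank by the
closeness coefficient ``CC_i = d_i^- / (d_i^* + d_i^-)``.

Normalization is linear-ratio: a benefit cell ``(l, m, u)`` maps to
``(l/u*, m/u*, u/u*)`` with ``u*`` the column's largest upper vertex, a cost
cell to ``(l^-/u, l^-/m, l^-/l)`` with ``l^-`` the column's smallest lower
vertex.  Target-range criteria (best inside a window, e.g. degradation time
matched to bone healing) are first mapped through a trapezoidal desirability
function onto a [0, 1] benefit scale.

The ideal solutions are data-driven extrema, not the fixed (1,1,1)/(0,0,0)
convention: with heterogeneous fuzzy weights the attainable maximum differs
per criterion, and anchoring the ideals to the data keeps distances
commensurate across criteria.

The crisp counterpart collapses every cell and weight to its modal value and
runs the same pipeline on degenerate (crisp) TFNs — by construction the two
agree exactly on matrices that were crisp to begin with.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Criterion, FuzzyDecisionMatrix, WeightVector
from .tfn import TFN, tfn_mul, vertex_distance

__all__ = [
    "AlternativeScore",
    "RankingResult",
    "target_range_transform",
    "transform_target_columns",
    "normalize_matrix",
    "apply_weights",
    "ideal_solutions",
    "closeness",
    "run_fuzzy_topsis",
    "run_crisp_topsis",
    "DegenerateProblemError",
]


class DegenerateProblemError(ValueError):
    """The problem admits no meaningful ranking (e.g. FPIS equals FNIS)."""


@dataclass(frozen=True)
class AlternativeScore:
    code: str
    name: str
    d_pos: float
    d_neg: float
    cc: float
    rank: int
    label: str = ""


@dataclass
class RankingResult:
    """Per-alternative distances, closeness coefficients and ranks.

    ``intermediates`` holds the normalized and weighted matrices and the two
    ideal-solution profiles for audit.
    """

    scores: list[AlternativeScore]
    intermediates: dict

    def rows_by_rank(self) -> list[AlternativeScore]:
        return sorted(self.scores, key=lambda s: s.rank)

    def score_for(self, code: str) -> AlternativeScore:
        for s in self.scores:
            if s.code == code:
                return s
        raise KeyError(f"no alternative with code {code!r}")

    def rank_of(self, code: str) -> int:
        return self.score_for(code).rank

    def top(self) -> AlternativeScore:
        return self.rows_by_rank()[0]


def target_range_transform(x: TFN, window: tuple[float, float], decay_anchor: float) -> TFN:
    """Map a TFN through a trapezoidal desirability for a target-range criterion.

    Desirability ``g(t)`` is 1 inside the window ``[lo, hi]``, rises linearly
    from 0 at ``t = 0`` below it (``g = t/lo``), and decays linearly above it,
    reaching 0 at ``decay_anchor``.  Each vertex maps through ``g``; because
    ``g`` is not monotone the images are re-sorted to restore the TFN
    ordering.  The output lives on a [0, 1] benefit scale.
    """
    lo, hi = window
    if not 0 < lo < hi:
        raise ValueError(f"invalid target window ({lo}, {hi})")
    if decay_anchor <= hi:
        raise ValueError(f"decay_anchor must exceed the window upper edge {hi}, got {decay_anchor}")
    if x.l < 0:
        raise ValueError(f"target-range transform requires non-negative input, got {x.as_tuple()}")

    def g(t: float) -> float:
        if t < lo:
            return t / lo
        if t <= hi:
            return 1.0
        return max(0.0, 1.0 - (t - hi) / (decay_anchor - hi))

    lo_v, m_v, u_v = sorted((g(x.l), g(x.m), g(x.u)))
    return TFN(lo_v, m_v, u_v)


def transform_target_columns(matrix: FuzzyDecisionMatrix) -> FuzzyDecisionMatrix:
    """Replace every target-range column by its desirability image.

    The transformed columns become benefit criteria on a [0, 1] scale; other
    columns are untouched.
    """
    cells = [list(row) for row in matrix.cells]
    criteria = list(matrix.criteria)
    for j, c in enumerate(criteria):
        if c.direction != "target_range":
            continue
        assert c.target_window is not None
        anchor = c.decay_anchor
        if anchor is None:
            anchor = max(row[j].u for row in matrix.cells)
            if anchor <= c.target_window[1]:
                anchor = c.target_window[1] * 2.0
        for i in range(len(cells)):
            cells[i][j] = target_range_transform(cells[i][j], c.target_window, anchor)
        criteria[j] = Criterion(
            id=c.id,
            name=c.name,
            units="desirability",
            direction="benefit",
            weight=c.weight,
        )
    return FuzzyDecisionMatrix(matrix.alternatives, criteria, cells)


def normalize_matrix(matrix: FuzzyDecisionMatrix) -> FuzzyDecisionMatrix:
    """Linear-ratio normalization onto [0, 1]^3 per column.

    Expects target-range columns to have been transformed already (they are
    rejected here).
    """
    n_a, n_c = matrix.shape
    cells: list[list[TFN]] = [[None] * n_c for _ in range(n_a)]  # type: ignore[list-item]
    for j, c in enumerate(matrix.criteria):
        col = matrix.column(j)
        if c.direction == "benefit":
            u_star = max(t.u for t in col)
            if u_star <= 0:
                raise ValueError(f"benefit column {c.id} has non-positive maximum upper bound")
            for i, t in enumerate(col):
                cells[i][j] = TFN(t.l / u_star, t.m / u_star, t.u / u_star)
        elif c.direction == "cost":
            if any(t.l <= 0 for t in col):
                raise ValueError(f"cost column {c.id} contains a non-positive component")
            l_minus = min(t.l for t in col)
            for i, t in enumerate(col):
                cells[i][j] = TFN(l_minus / t.u, l_minus / t.m, l_minus / t.l)
        else:
            raise ValueError(
                f"column {c.id} is target_range; apply transform_target_columns first"
            )
    return FuzzyDecisionMatrix(matrix.alternatives, matrix.criteria, cells)


def apply_weights(normalized: FuzzyDecisionMatrix, weights: WeightVector) -> FuzzyDecisionMatrix:
    """Multiply each normalized cell by its criterion's fuzzy weight."""
    ids = [c.id for c in normalized.criteria]
    if list(weights.ids) != ids:
        raise ValueError(f"criterion ids mismatch: matrix has {ids}, weights have {list(weights.ids)}")
    cells = [
        [tfn_mul(cell, weights.fuzzy[j]) for j, cell in enumerate(row)]
        for row in normalized.cells
    ]
    return FuzzyDecisionMatrix(normalized.alternatives, normalized.criteria, cells)


def ideal_solutions(weighted: FuzzyDecisionMatrix) -> tuple[list[TFN], list[TFN]]:
    """Component-wise extrema per criterion: (FPIS, FNIS)."""
    if len(weighted.alternatives) < 2:
        raise DegenerateProblemError("ideal solutions need at least 2 alternatives")
    fpis, fnis = [], []
    for j in range(len(weighted.criteria)):
        col = weighted.column(j)
        fpis.append(TFN(max(t.l for t in col), max(t.m for t in col), max(t.u for t in col)))
        fnis.append(TFN(min(t.l for t in col), min(t.m for t in col), min(t.u for t in col)))
    return fpis, fnis


def closeness(d_pos: float, d_neg: float) -> float:
    """``CC = d^- / (d^* + d^-)`` in [0, 1]; undefined when both distances vanish."""
    if d_pos < 0 or d_neg < 0:
        raise ValueError("distances must be non-negative")
    total = d_pos + d_neg
    if total == 0:
        raise DegenerateProblemError(
            "closeness undefined: alternative coincides with both ideal solutions"
        )
    return d_neg / total


def _rank_and_assemble(
    weighted: FuzzyDecisionMatrix,
    intermediates: dict,
    labels: dict[str, str] | None,
) -> RankingResult:
    fpis, fnis = ideal_solutions(weighted)
    raw = []
    for i, alt in enumerate(weighted.alternatives):
        d_pos = sum(vertex_distance(weighted.cells[i][j], fpis[j]) for j in range(len(fpis)))
        d_neg = sum(vertex_distance(weighted.cells[i][j], fnis[j]) for j in range(len(fnis)))
        raw.append((alt, d_pos, d_neg, closeness(d_pos, d_neg)))
    # descending CC; ties broken by ascending alternative code (deterministic)
    order = sorted(range(len(raw)), key=lambda i: (-raw[i][3], raw[i][0].code))
    ranks = {i: r + 1 for r, i in enumerate(order)}
    labels = labels or {}
    scores = [
        AlternativeScore(
            code=alt.code,
            name=alt.name,
            d_pos=d_pos,
            d_neg=d_neg,
            cc=cc,
            rank=ranks[i],
            label=labels.get(alt.code, ""),
        )
        for i, (alt, d_pos, d_neg, cc) in enumerate(raw)
    ]
    intermediates = dict(intermediates)
    intermediates["weighted"] = weighted
    intermediates["fpis"] = fpis
    intermediates["fnis"] = fnis
    return RankingResult(scores=scores, intermediates=intermediates)


def run_fuzzy_topsis(
    matrix: FuzzyDecisionMatrix,
    weights: WeightVector,
    labels: dict[str, str] | None = None,
) -> RankingResult:
    """Full fuzzy TOPSIS pipeline on a fuzzy decision matrix.

    ``labels`` optionally attaches free-text classification annotations
    (report metadata, not computed) to alternative codes.
    """
    transformed = transform_target_columns(matrix)
    normalized = normalize_matrix(transformed)
    weighted = apply_weights(normalized, weights)
    return _rank_and_assemble(
        weighted, {"transformed": transformed, "normalized": normalized}, labels
    )


def run_crisp_topsis(
    matrix: FuzzyDecisionMatrix,
    weights: WeightVector,
    labels: dict[str, str] | None = None,
) -> RankingResult:
    """Crisp midpoint counterpart: collapse cells and weights to their modal
    values, then run the same pipeline on the resulting crisp matrix.

    On crisp inputs the fuzzy machinery degenerates to classical TOPSIS with
    ratio normalization and absolute-difference distances, so this is the
    comparison arm for the fuzzy-vs-crisp ranking question.
    """
    crisp_cells = [[TFN.crisp(cell.m) for cell in row] for row in matrix.cells]
    crisp_matrix = FuzzyDecisionMatrix(matrix.alternatives, matrix.criteria, crisp_cells)
    crisp_weights = WeightVector(
        list(weights.ids), [TFN.crisp(w.m) for w in weights.fuzzy], list(weights.crisp)
    )
    return run_fuzzy_topsis(crisp_matrix, crisp_weights, labels)
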