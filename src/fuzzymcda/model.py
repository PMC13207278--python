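"""Shared domain containers: criteria, decision matrices and weight vectors.

A decision problem is a grid of TFN performance values: rows are candidate
materials (alternatives), columns are evaluation criteria.  Each criterion
carries a direction — ``benefit`` (larger is better), ``cost`` (smaller is
better) or ``target_range`` (values inside a stated window are best, e.g. a
scaffold degradation time synchronized with bone healing) — and optionally a
fuzzy importance weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tfn import TFN, defuzzify

__all__ = [
    "Alternative",
    "Criterion",
    "FuzzyDecisionMatrix",
    "WeightVector",
    "DIRECTIONS",
]

DIRECTIONS = ("benefit", "cost", "target_range")


@dataclass(frozen=True)
class Alternative:
    code: str
    name: str = ""


@dataclass(frozen=True)
class Criterion:
    """One evaluation axis of the decision problem.

    ``target_window`` is required iff ``direction == 'target_range'``;
    ``decay_anchor`` is the abscissa (in criterion units) at which
    desirability above the window reaches zero.
    """

    id: str
    name: str = ""
    units: str = ""
    direction: str = "benefit"
    target_window: Optional[tuple[float, float]] = None
    decay_anchor: Optional[float] = None
    weight: Optional[TFN] = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"criterion {self.id}: unknown direction {self.direction!r}")
        if self.direction == "target_range":
            if self.target_window is None:
                raise ValueError(f"criterion {self.id}: target_range requires a target_window")
            lo, hi = self.target_window
            if not lo < hi:
                raise ValueError(f"criterion {self.id}: target window needs lo < hi, got ({lo}, {hi})")
            if self.decay_anchor is not None and self.decay_anchor <= hi:
                raise ValueError(f"criterion {self.id}: decay_anchor must exceed the window upper edge")
        elif self.target_window is not None:
            raise ValueError(f"criterion {self.id}: target_window only valid for target_range direction")
        if self.weight is not None and self.weight.l < 0:
            raise ValueError(f"criterion {self.id}: weight components must be non-negative")


@dataclass
class FuzzyDecisionMatrix:
    """Alternatives x criteria grid of TFNs plus criterion metadata."""

    alternatives: list[Alternative]
    criteria: list[Criterion]
    cells: list[list[TFN]]  # row-major: cells[i][j] for alternative i, criterion j

    def __post_init__(self) -> None:
        n_a, n_c = len(self.alternatives), len(self.criteria)
        if n_a == 0 or n_c == 0:
            raise ValueError("decision matrix must have at least one alternative and one criterion")
        if len(self.cells) != n_a or any(len(row) != n_c for row in self.cells):
            raise ValueError(f"cells must be a {n_a}x{n_c} rectangular grid")
        for i, row in enumerate(self.cells):
            for j, cell in enumerate(row):
                if not isinstance(cell, TFN):
                    raise TypeError(
                        f"cell ({self.alternatives[i].code}, {self.criteria[j].id}) is not a TFN"
                    )
                if self.criteria[j].direction in ("benefit", "cost") and cell.l < 0:
                    raise ValueError(
                        f"cell ({self.alternatives[i].code}, {self.criteria[j].id}) "
                        f"must be non-negative for a {self.criteria[j].direction} criterion"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.alternatives), len(self.criteria))

    def criterion_index(self, cid: str) -> int:
        for j, c in enumerate(self.criteria):
            if c.id == cid:
                return j
        raise KeyError(f"no criterion with id {cid!r}")

    def alternative_index(self, code: str) -> int:
        for i, a in enumerate(self.alternatives):
            if a.code == code:
                return i
        raise KeyError(f"no alternative with code {code!r}")

    def cell(self, alt_code: str, crit_id: str) -> TFN:
        return self.cells[self.alternative_index(alt_code)][self.criterion_index(crit_id)]

    def column(self, j: int) -> list[TFN]:
        return [row[j] for row in self.cells]

    def to_array(self) -> np.ndarray:
        """(n_alternatives, n_criteria, 3) float array of the TFN vertices."""
        return np.array([[c.as_tuple() for c in row] for row in self.cells], dtype=float)

    def with_cells(self, cells: list[list[TFN]]) -> "FuzzyDecisionMatrix":
        return FuzzyDecisionMatrix(self.alternatives, self.criteria, cells)


@dataclass
class WeightVector:
    """Per-criterion fuzzy local weight and crisp global weight.

    Crisp global weights are kept normalized (sum to 1); the fuzzy triples
    need not sum to one — they are the fuzzy importance values the weighted
    decision matrix is multiplied by.
    """

    ids: list[str]
    fuzzy: list[TFN]
    crisp: list[float]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(self.fuzzy) != n or len(self.crisp) != n:
            raise ValueError("ids, fuzzy and crisp must have equal length")
        if any(w.l < 0 for w in self.fuzzy):
            raise ValueError("fuzzy weight components must be non-negative")
        if any(w < 0 for w in self.crisp):
            raise ValueError("crisp weights must be non-negative")
        total = float(sum(self.crisp))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"crisp global weights must sum to 1, got {total}")

    @classmethod
    def from_fuzzy(
        cls, ids: Sequence[str], fuzzy: Sequence[TFN], method: str = "centroid"
    ) -> "WeightVector":
        """Defuzzify local fuzzy weights and normalize to crisp global weights."""
        crisp = np.array([defuzzify(w, method) for w in fuzzy], dtype=float)
        total = crisp.sum()
        if total <= 0:
            raise ValueError("fuzzy weights defuzzify to a non-positive total")
        return cls(list(ids), list(fuzzy), list(crisp / total))

    @classmethod
    def from_crisp(cls, ids: Sequence[str], crisp: Sequence[float]) -> "WeightVector":
        arr = np.asarray(crisp, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("crisp weights must have a positive sum")
        arr = arr / total
        return cls(list(ids), [TFN.crisp(w) for w in arr], list(arr))

    def weight_for(self, cid: str) -> TFN:
        return self.fuzzy[self.ids.index(cid)]

    def crisp_for(self, cid: str) -> float:
        return self.crisp[self.ids.index(cid)]
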