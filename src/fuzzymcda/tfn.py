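"""Triangular fuzzy numbers (TFNs) and their arithmetic.

A triangular fuzzy number ``Ã = (l, m, u)`` encodes an uncertain quantity by
its pessimistic bound *l*, modal (most plausible) value *m* and optimistic
bound *u*.  It is the atom of every quantity in this package: literature
evidence, expert judgments, criterion weights and all intermediate values of
the fuzzy AHP and fuzzy TOPSIS stages.

Products and reciprocals use the standard component-wise approximation: the
exact product of two triangular numbers is not triangular, but for the
non-negative operands that arise in weighted decision matrices the
component-wise form is the universally adopted convention and preserves the
``l <= m <= u`` ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "TFN",
    "tfn_add",
    "tfn_mul",
    "tfn_scale",
    "tfn_reciprocal",
    "tfn_geometric_mean",
    "vertex_distance",
    "defuzzify",
    "DEFUZZIFY_METHODS",
]

#: absolute tolerance for floating comparisons between TFNs
ATOL = 1e-9


@dataclass(frozen=True, order=False)
class TFN:
    """An ordered triple ``(l, m, u)`` with ``l <= m <= u``, all finite.

    A *crisp* TFN has ``l == m == u`` and behaves exactly like the real
    number it collapses to under every operation in this module.
    """

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        l, m, u = float(self.l), float(self.m), float(self.u)
        if not (math.isfinite(l) and math.isfinite(m) and math.isfinite(u)):
            raise ValueError(f"TFN components must be finite, got ({l}, {m}, {u})")
        if not (l <= m <= u):
            raise ValueError(f"TFN ordering violated: need l <= m <= u, got ({l}, {m}, {u})")
        object.__setattr__(self, "l", l)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "u", u)

    # -- conversions -------------------------------------------------------

    @classmethod
    def crisp(cls, x: float) -> "TFN":
        """The degenerate TFN (x, x, x)."""
        return cls(x, x, x)

    @classmethod
    def from_sequence(cls, seq: Sequence[float]) -> "TFN":
        if len(seq) != 3:
            raise ValueError(f"expected 3 components, got {len(seq)}")
        return cls(*(float(v) for v in seq))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)

    @property
    def is_crisp(self) -> bool:
        return self.l == self.m == self.u

    # -- operators ---------------------------------------------------------

    def __add__(self, other: "TFN") -> "TFN":
        return tfn_add(self, other)

    def __mul__(self, other: "TFN") -> "TFN":
        return tfn_mul(self, other)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TFN({self.l:g}, {self.m:g}, {self.u:g})"

    def approx_equal(self, other: "TFN", atol: float = ATOL) -> bool:
        return (
            abs(self.l - other.l) <= atol
            and abs(self.m - other.m) <= atol
            and abs(self.u - other.u) <= atol
        )


def tfn_add(a: TFN, b: TFN) -> TFN:
    """Component-wise sum; exact for triangular numbers."""
    return TFN(a.l + b.l, a.m + b.m, a.u + b.u)


def tfn_mul(a: TFN, b: TFN) -> TFN:
    """Component-wise product, valid for non-negative operands only.

    Raises
    ------
    ValueError
        If either operand has a negative component; outside the non-negative
        domain the component-wise form no longer brackets the true product.
    """
    if a.l < 0 or b.l < 0:
        raise ValueError(
            f"tfn_mul requires non-negative operands, got {a.as_tuple()} and {b.as_tuple()}"
        )
    return TFN(a.l * b.l, a.m * b.m, a.u * b.u)


def tfn_scale(a: TFN, c: float) -> TFN:
    """Scale by a non-negative crisp scalar."""
    if c < 0:
        raise ValueError(f"scale factor must be non-negative, got {c}")
    return TFN(a.l * c, a.m * c, a.u * c)


def tfn_reciprocal(a: TFN) -> TFN:
    """``(1/u, 1/m, 1/l)`` — the fuzzy reciprocal, for strictly positive TFNs."""
    if a.l <= 0:
        raise ValueError(f"tfn_reciprocal requires a strictly positive TFN, got {a.as_tuple()}")
    return TFN(1.0 / a.u, 1.0 / a.m, 1.0 / a.l)


def tfn_geometric_mean(items: Iterable[TFN]) -> TFN:
    """Component-wise geometric mean of strictly positive TFNs.

    Used to consolidate a panel of expert judgments into one fuzzy value.
    Computed in log space for numerical stability.
    """
    items = list(items)
    if not items:
        raise ValueError("tfn_geometric_mean requires a non-empty collection")
    sl = sm = su = 0.0
    for t in items:
        if t.l <= 0:
            raise ValueError(f"geometric mean requires positive components, got {t.as_tuple()}")
        sl += math.log(t.l)
        sm += math.log(t.m)
        su += math.log(t.u)
    k = len(items)
    return TFN(math.exp(sl / k), math.exp(sm / k), math.exp(su / k))


def vertex_distance(a: TFN, b: TFN) -> float:
    """Vertex distance ``sqrt((1/3) * ((l1-l2)^2 + (m1-m2)^2 + (u1-u2)^2))``.

    A metric on triangular fuzzy numbers: symmetric, non-negative, zero iff
    the operands coincide, and it reduces to ``|a - b|`` on crisp numbers.
    """
    return math.sqrt(
        ((a.l - b.l) ** 2 + (a.m - b.m) ** 2 + (a.u - b.u) ** 2) / 3.0
    )


DEFUZZIFY_METHODS = ("centroid", "graded_mean")


def defuzzify(a: TFN, method: str = "centroid") -> float:
    """Collapse a TFN to a single representative real value.

    ``centroid``     -> (l + m + u) / 3   (default)
    ``graded_mean``  -> (l + 4m + u) / 6
    """
    if method == "centroid":
        return (a.l + a.m + a.u) / 3.0
    if method == "graded_mean":
        return (a.l + 4.0 * a.m + a.u) / 6.0
    raise ValueError(f"unknown defuzzification method {method!r}; choose from {DEFUZZIFY_METHODS}")
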