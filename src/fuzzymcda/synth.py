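"""Synthetic decision problems with known ground-truth structure.

Real multi-criteria studies in this domain draw their numbers from scattered
experimental literature, so there is no deposited dataset to test against.
These generators build decision matrices, evidence intervals and
pairwise-comparison matrices whose correct outcome is known by construction
(a planted dominant alternative, a known generating weight vector, a
degenerate noise level), giving every pipeline stage an independent oracle.

All noise is multiplicative log-normal: the quantities involved (material
properties, importance ratios) are strictly positive, and log-normal
perturbations keep them that way.  ``noise_scale`` is the standard deviation
of the log-perturbation.  Every generator takes an explicit seed and owns a
private generator — identical seeds give identical output, and no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ahp import FuzzyComparisonMatrix
from .fuzzify import EvidenceInterval
from .model import Alternative, Criterion, FuzzyDecisionMatrix
from .tfn import TFN

__all__ = [
    "SyntheticSpec",
    "gen_dominant_matrix",
    "gen_random_matrix",
    "gen_interval_evidence",
    "gen_consistent_comparison_matrix",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic decision problem.

    ``directions`` lists one of ``benefit``/``cost`` per criterion (defaults
    to all-benefit); ``dominant`` optionally plants a weakly dominant
    alternative at that row index; ``noise_scale`` is the log-sd of the
    between-alternative spread (0 makes all non-dominant rows identical).
    """

    n_alternatives: int
    n_criteria: int
    directions: Optional[tuple[str, ...]] = None
    dominant: Optional[int] = None
    noise_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alternatives < 1 or self.n_criteria < 1:
            raise ValueError("need at least one alternative and one criterion")
        dirs = self.directions
        if dirs is not None:
            if len(dirs) != self.n_criteria:
                raise ValueError("directions must list one entry per criterion")
            bad = set(dirs) - {"benefit", "cost"}
            if bad:
                raise ValueError(f"unsupported synthetic directions {sorted(bad)}")
        if self.dominant is not None:
            if self.n_alternatives < 2:
                raise ValueError("a dominant alternative requires at least 2 alternatives")
            if not 0 <= self.dominant < self.n_alternatives:
                raise ValueError(f"dominant index {self.dominant} out of range")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")

    @property
    def resolved_directions(self) -> tuple[str, ...]:
        return self.directions or ("benefit",) * self.n_criteria


def _random_cells(spec: SyntheticSpec, rng: np.random.Generator) -> list[list[TFN]]:
    """One base value per criterion, log-normal row perturbations, fixed
    relative TFN half-width; noise_scale 0 collapses rows to the base."""
    base = rng.lognormal(mean=2.0, sigma=1.0, size=spec.n_criteria)
    cells = []
    for _ in range(spec.n_alternatives):
        noise = np.exp(rng.normal(0.0, spec.noise_scale, size=spec.n_criteria))
        row = []
        for j in range(spec.n_criteria):
            m = base[j] * noise[j]
            row.append(TFN(0.8 * m, m, 1.25 * m))
        cells.append(row)
    return cells


def gen_random_matrix(spec: SyntheticSpec) -> FuzzyDecisionMatrix:
    """A random valid decision matrix without planted structure."""
    rng = np.random.default_rng(spec.seed)
    alts = [Alternative(f"A{i+1}", f"synthetic alternative {i+1}") for i in range(spec.n_alternatives)]
    crits = [
        Criterion(id=f"C{j+1}", name=f"synthetic criterion {j+1}", direction=d)
        for j, d in enumerate(spec.resolved_directions)
    ]
    return FuzzyDecisionMatrix(alts, crits, _random_cells(spec, rng))


def gen_dominant_matrix(spec: SyntheticSpec) -> FuzzyDecisionMatrix:
    """A decision matrix with a planted weakly dominant alternative.

    The designated row is rebuilt as the component-wise maximum of the other
    rows on benefit columns (scaled up by a small margin) and the
    component-wise minimum on cost columns (scaled down), so it weakly
    dominates every competitor and must receive rank 1 under any
    non-negative weighting — the weight-independent oracle for ranking code.
    """
    if spec.dominant is None:
        raise ValueError("gen_dominant_matrix requires spec.dominant to be set")
    rng = np.random.default_rng(spec.seed)
    alts = [Alternative(f"A{i+1}", f"synthetic alternative {i+1}") for i in range(spec.n_alternatives)]
    crits = [
        Criterion(id=f"C{j+1}", name=f"synthetic criterion {j+1}", direction=d)
        for j, d in enumerate(spec.resolved_directions)
    ]
    cells = _random_cells(spec, rng)
    d = spec.dominant
    others = [cells[i] for i in range(spec.n_alternatives) if i != d]
    dom_row = []
    for j, direction in enumerate(spec.resolved_directions):
        col = [row[j] for row in others]
        if direction == "benefit":
            t = TFN(max(c.l for c in col), max(c.m for c in col), max(c.u for c in col))
            dom_row.append(TFN(1.05 * t.l, 1.05 * t.m, 1.05 * t.u))
        else:
            t = TFN(min(c.l for c in col), min(c.m for c in col), min(c.u for c in col))
            dom_row.append(TFN(0.95 * t.l, 0.95 * t.m, 0.95 * t.u))
    cells[d] = dom_row
    return FuzzyDecisionMatrix(alts, crits, cells)


def gen_interval_evidence(
    true_value: float, n_studies: int, noise_scale: float, seed: int
) -> EvidenceInterval:
    """Simulate ``n_studies`` noisy measurements of a property and return
    their (min, max) range as an evidence interval.

    Measurements are ``true_value * exp(N(0, noise_scale))``; as
    ``noise_scale -> 0`` the interval collapses onto the true value, so the
    TFN built from it has modal value converging to the truth.
    """
    if n_studies < 1:
        raise ValueError("need at least one study")
    if true_value <= 0:
        raise ValueError("true_value must be positive for log-normal measurement noise")
    rng = np.random.default_rng(seed)
    measurements = true_value * np.exp(rng.normal(0.0, noise_scale, size=n_studies))
    return EvidenceInterval(
        low=float(measurements.min()),
        high=float(measurements.max()),
        source_note=f"synthetic: {n_studies} simulated studies around {true_value}",
    )


def gen_consistent_comparison_matrix(
    weights: Sequence[float], perturbation: float, spread: float, seed: int
) -> FuzzyComparisonMatrix:
    """A reciprocal fuzzy comparison matrix centred on known weight ratios.

    Upper-triangle entries are TFNs centred on ``(w_i / w_j) * eps_ij`` with
    multiplicative log-normal noise ``eps_ij`` of scale ``perturbation`` and
    relative fuzzy half-width ``spread`` (the TFN is
    ``(c/(1+spread), c, c*(1+spread))``).  The lower triangle is the exact
    fuzzy reciprocal.  With ``perturbation = spread = 0`` the matrix is crisp
    and perfectly consistent (consistency ratio 0).  With zero perturbation
    and a modest positive spread the fuzzy extents overlap and extent
    analysis recovers the generating weight order; at spread 0 the extents
    are disjoint and extent analysis collapses to winner-take-all weights.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise ValueError("need at least two weights")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if perturbation < 0 or spread < 0:
        raise ValueError("perturbation and spread must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(w)
    upper = {}
    for i in range(n):
        for j in range(i + 1, n):
            c = (w[i] / w[j]) * float(np.exp(rng.normal(0.0, perturbation)))
            upper[(i, j)] = TFN(c / (1.0 + spread), c, c * (1.0 + spread))
    return FuzzyComparisonMatrix.from_upper_triangle(n, upper)
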