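"""Turning literature evidence into triangular fuzzy numbers.

Material properties reported across independent experimental studies vary
widely (fabrication route, filler loading, testing protocol).  Rather than
collapsing a reported range to a single number, an interval ``[a, b]``
becomes the TFN ``(a, (a+b)/2, b)``, and qualitative expert assessments map
through a five-term linguistic scale onto fixed TFNs.

The module also ships the packaged case study: five biodegradable
polymer-composite scaffold candidates for load-bearing bone tissue
engineering, scored on six criteria (compressive strength, elastic modulus,
porosity, degradation time, cell viability, manufacturing cost index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Union

from .io import matrix_from_dict, weights_from_dict
from .model import Criterion, FuzzyDecisionMatrix, WeightVector
from .tfn import TFN

__all__ = [
    "EvidenceInterval",
    "LINGUISTIC_SCALE",
    "tfn_from_interval",
    "tfn_from_linguistic",
    "load_study_fixture",
    "load_study_weights",
    "DEFAULT_COST_RATINGS",
]

#: Five-term importance/performance scale for expert judgments.
LINGUISTIC_SCALE: dict[str, tuple[float, float, float]] = {
    "VL": (1, 1, 3),
    "L": (1, 3, 5),
    "M": (3, 5, 7),
    "H": (5, 7, 9),
    "VH": (7, 9, 9),
}

#: Default linguistic cost-index ratings for the packaged study's
#: manufacturing-cost criterion (C6).  The source tables print no numeric C6
#: values, so these are a documented assumption grounded in each composite's
#: processing route: PLA/HA and PCL/HA are cheap melt-processable benchmark
#: systems (L); PLGA/BG and PLA/Mg need co-processing of a reactive filler
#: (M); PLA/CNT requires costly nanotube dispersion and purification (H).
#: Override via ``load_study_fixture(cost_ratings=...)``.
DEFAULT_COST_RATINGS: dict[str, str] = {
    "A1": "L",
    "A2": "L",
    "A3": "M",
    "A4": "H",
    "A5": "M",
}

_FIXTURE_FILE = "bte_scaffold_study.json"


@dataclass(frozen=True)
class EvidenceInterval:
    """A reported property range with free-form provenance."""

    low: float
    high: float
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"invalid interval: low {self.low} > high {self.high}")


def tfn_from_interval(iv: EvidenceInterval) -> TFN:
    """``[a, b]`` -> ``(a, (a+b)/2, b)``; midpoint as the modal value."""
    return TFN(iv.low, (iv.low + iv.high) / 2.0, iv.high)


def tfn_from_linguistic(term: str) -> TFN:
    """Map a linguistic label (VL, L, M, H, VH) onto its scale TFN."""
    try:
        return TFN.from_sequence(LINGUISTIC_SCALE[term])
    except KeyError:
        raise ValueError(
            f"unknown linguistic term {term!r}; expected one of {sorted(LINGUISTIC_SCALE)}"
        ) from None


def _fixture_dict() -> dict:
    with resources.files("fuzzymcda.data").joinpath(_FIXTURE_FILE).open(encoding="utf-8") as fh:
        return json.load(fh)


def load_study_fixture(
    cost_ratings: Optional[Mapping[str, Union[str, TFN]]] = None,
) -> FuzzyDecisionMatrix:
    """The packaged five-composite, six-criterion scaffold-selection matrix.

    Parameters
    ----------
    cost_ratings
        Optional override for the assumed manufacturing-cost column:
        a mapping from alternative code to a linguistic label or a TFN.
        Defaults to :data:`DEFAULT_COST_RATINGS`.
    """
    matrix = matrix_from_dict(_fixture_dict())
    if cost_ratings is not None:
        j = matrix.criterion_index("C6")
        cells = [list(row) for row in matrix.cells]
        for code, rating in cost_ratings.items():
            i = matrix.alternative_index(code)
            cells[i][j] = rating if isinstance(rating, TFN) else tfn_from_linguistic(rating)
        matrix = matrix.with_cells(cells)
    return matrix


def load_study_weights() -> WeightVector:
    """The study's fuzzy criterion weights.

    Fuzzy local weights are the published triples; crisp global weights are
    the published percentages taken as authoritative (they are not re-derived
    by defuzzification, which does not reproduce them exactly).
    """
    return weights_from_dict(_fixture_dict()["weights"])
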