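"""Weight-scenario sensitivity analysis of the fuzzy TOPSIS ranking.

A ranking that flips when criterion weights move modestly is not a robust
basis for material selection.  This module re-runs the ranking under a list
of declarative weight scenarios (per-criterion multiply-by / set-to rules,
with renormalization so crisp weights always sum to one) and summarizes rank
stability per alternative.

The default scenario battery contains five expert priority profiles:
baseline weights, a biological focus (cell-viability and degradation weights
doubled, mechanical weights halved), a mechanical focus (the converse),
equal weights, and a cost focus (manufacturing-cost weight raised to 40%
with the remainder scaled proportionally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import FuzzyDecisionMatrix, WeightVector
from .tfn import TFN, tfn_scale
from .topsis import RankingResult, run_fuzzy_topsis

__all__ = [
    "ScenarioSpec",
    "StabilityReport",
    "apply_scenario",
    "build_default_scenarios",
    "run_sensitivity",
]

#: criterion groups used by the default focus scenarios
MECHANICAL_CRITERIA = ("C1", "C2")
BIOLOGICAL_CRITERIA = ("C5", "C4")


@dataclass(frozen=True)
class ScenarioSpec:
    """A declarative weight transformation.

    ``multiply`` scales a criterion's crisp weight (and its fuzzy triple) by
    a factor; ``set_to`` pins a criterion's crisp weight to an absolute share
    *after* which the remaining criteria are scaled proportionally to fill
    the complement.  Both rules may not name the same criterion.  When
    ``renormalize`` is true (the default) crisp weights are rescaled to sum
    to one, with fuzzy triples scaled by the same factor.
    """

    name: str
    multiply: dict[str, float] = field(default_factory=dict)
    set_to: dict[str, float] = field(default_factory=dict)
    renormalize: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.multiply) & set(self.set_to)
        if overlap:
            raise ValueError(f"scenario {self.name!r}: criteria {sorted(overlap)} in both rules")
        if any(f < 0 for f in self.multiply.values()):
            raise ValueError(f"scenario {self.name!r}: negative multiply factor")
        if any(not 0 <= v <= 1 for v in self.set_to.values()):
            raise ValueError(f"scenario {self.name!r}: set_to shares must lie in [0, 1]")
        if sum(self.set_to.values()) > 1:
            raise ValueError(f"scenario {self.name!r}: set_to shares exceed 1")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "multiply": dict(self.multiply),
            "set_to": dict(self.set_to),
            "renormalize": self.renormalize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            name=d["name"],
            multiply={k: float(v) for k, v in d.get("multiply", {}).items()},
            set_to={k: float(v) for k, v in d.get("set_to", {}).items()},
            renormalize=bool(d.get("renormalize", True)),
        )


def apply_scenario(baseline: WeightVector, scenario: ScenarioSpec) -> WeightVector:
    """Transform a weight vector according to a scenario rule.

    Per-criterion factors act on crisp weights and scale the fuzzy triples by
    the same scalar; the final renormalization divides both by the crisp
    total, so relative fuzzy spreads are preserved.
    """
    ids = list(baseline.ids)
    for cid in list(scenario.multiply) + list(scenario.set_to):
        if cid not in ids:
            raise KeyError(f"scenario {scenario.name!r} names unknown criterion {cid!r}")
    factors = {cid: 1.0 for cid in ids}
    for cid, f in scenario.multiply.items():
        factors[cid] = f

    if scenario.set_to:
        pinned_total = sum(scenario.set_to.values())
        free = [cid for cid in ids if cid not in scenario.set_to]
        free_total = sum(
            baseline.crisp_for(cid) * factors[cid] for cid in free
        )
        for cid, share in scenario.set_to.items():
            base = baseline.crisp_for(cid)
            factors[cid] = share / base if base > 0 else 0.0
        if free:
            if free_total <= 0:
                raise ValueError(f"scenario {scenario.name!r}: free criteria carry no weight")
            scale_free = (1.0 - pinned_total) / free_total
            for cid in free:
                factors[cid] *= scale_free

    crisp = [baseline.crisp_for(cid) * factors[cid] for cid in ids]
    fuzzy = [tfn_scale(baseline.weight_for(cid), factors[cid]) for cid in ids]
    total = sum(crisp)
    if total <= 0:
        raise ValueError(f"scenario {scenario.name!r} annihilates all weight")
    if scenario.renormalize:
        crisp = [w / total for w in crisp]
        fuzzy = [tfn_scale(w, 1.0 / total) for w in fuzzy]
    return WeightVector(ids, fuzzy, crisp)


def build_default_scenarios(baseline: WeightVector) -> list[ScenarioSpec]:
    """The five-profile battery used by the packaged study.

    Requires the baseline to cover criteria C1...C6 (the packaged study's
    criterion ids); focus scenarios leave porosity (C3) and cost (C6) at
    baseline before renormalization.
    """
    required = set(MECHANICAL_CRITERIA) | set(BIOLOGICAL_CRITERIA) | {"C3", "C6"}
    missing = required - set(baseline.ids)
    if missing:
        raise ValueError(f"baseline weights missing criteria {sorted(missing)}")
    n = len(baseline.ids)
    return [
        ScenarioSpec(name="Baseline"),
        ScenarioSpec(
            name="Biological Focus",
            multiply={**{c: 2.0 for c in BIOLOGICAL_CRITERIA}, **{c: 0.5 for c in MECHANICAL_CRITERIA}},
        ),
        ScenarioSpec(
            name="Mechanical Focus",
            multiply={**{c: 2.0 for c in MECHANICAL_CRITERIA}, **{c: 0.5 for c in BIOLOGICAL_CRITERIA}},
        ),
        ScenarioSpec(name="Equal Weights", set_to={cid: 1.0 / n for cid in baseline.ids}),
        ScenarioSpec(name="Cost Focus", set_to={"C6": 0.40}),
    ]


@dataclass
class StabilityReport:
    """Rankings per scenario plus per-alternative rank-stability summaries."""

    scenario_names: list[str]
    results: list[RankingResult]
    rank_range: dict[str, tuple[int, int]]
    top_rank_count: dict[str, int]

    def cc_grid(self) -> dict[str, dict[str, float]]:
        """scenario -> alternative code -> closeness coefficient."""
        return {
            name: {s.code: s.cc for s in res.scores}
            for name, res in zip(self.scenario_names, self.results)
        }


def run_sensitivity(
    matrix: FuzzyDecisionMatrix,
    baseline: WeightVector,
    scenarios: Optional[Sequence[ScenarioSpec]] = None,
    labels: Optional[dict[str, str]] = None,
) -> StabilityReport:
    """Re-rank the matrix under each scenario and summarize rank stability."""
    if scenarios is None:
        scenarios = build_default_scenarios(baseline)
    results = [
        run_fuzzy_topsis(matrix, apply_scenario(baseline, sc), labels) for sc in scenarios
    ]
    codes = [a.code for a in matrix.alternatives]
    ranks = {code: [res.rank_of(code) for res in results] for code in codes}
    return StabilityReport(
        scenario_names=[sc.name for sc in scenarios],
        results=results,
        rank_range={c: (min(r), max(r)) for c, r in ranks.items()},
        top_rank_count={c: sum(1 for x in r if x == 1) for c, r in ranks.items()},
    )
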