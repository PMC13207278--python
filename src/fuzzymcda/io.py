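"""Reading and writing the package's file formats.

Everything is plain text: JSON for structured objects (decision matrices,
weight vectors, expert panels, scenario lists, result bundles), CSV mirrors
for the tabular ones, YAML accepted for scenarios and run configuration.
TFNs serialize as 3-element arrays ``[l, m, u]`` in JSON and as three
adjacent columns ``<name>_l, <name>_m, <name>_u`` in CSV.  Numbers are
written at full precision; report tables add separate rounded display
columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import pandas as pd
import yaml

from .model import Alternative, Criterion, FuzzyDecisionMatrix, WeightVector
from .tfn import TFN

__all__ = [
    "matrix_to_dict",
    "matrix_from_dict",
    "read_matrix_json",
    "write_matrix_json",
    "read_matrix_csv",
    "write_matrix_csv",
    "weights_to_dict",
    "weights_from_dict",
    "read_weights_json",
    "write_weights_json",
    "read_weights_csv",
    "write_weights_csv",
    "read_panel_json",
    "write_panel_json",
    "read_scenarios",
    "write_scenarios",
    "ranking_to_frame",
    "write_ranking_csv",
]

PathLike = Union[str, Path]

MATRIX_SCHEMA = "fuzzymcda/decision-matrix@1"
WEIGHTS_SCHEMA = "fuzzymcda/weights@1"
PANEL_SCHEMA = "fuzzymcda/panel@1"
SCENARIOS_SCHEMA = "fuzzymcda/scenarios@1"


def _tfn_to_json(t: TFN) -> list[float]:
    return [t.l, t.m, t.u]


def _tfn_from_json(v: Sequence[float], where: str) -> TFN:
    try:
        return TFN.from_sequence(v)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid TFN at {where}: {exc}") from exc


# ---------------------------------------------------------------------------
# decision matrix


def matrix_to_dict(matrix: FuzzyDecisionMatrix, notes: Optional[dict] = None) -> dict:
    crits = []
    for c in matrix.criteria:
        d: dict[str, Any] = {
            "id": c.id,
            "name": c.name,
            "units": c.units,
            "direction": c.direction,
        }
        if c.target_window is not None:
            d["target_window"] = list(c.target_window)
        if c.decay_anchor is not None:
            d["decay_anchor"] = c.decay_anchor
        if c.weight is not None:
            d["weight"] = _tfn_to_json(c.weight)
        crits.append(d)
    out = {
        "schema": MATRIX_SCHEMA,
        "alternatives": [{"code": a.code, "name": a.name} for a in matrix.alternatives],
        "criteria": crits,
        "matrix": [[_tfn_to_json(cell) for cell in row] for row in matrix.cells],
    }
    if notes:
        out["notes"] = notes
    return out


def matrix_from_dict(data: dict) -> FuzzyDecisionMatrix:
    alts = [Alternative(a["code"], a.get("name", "")) for a in data["alternatives"]]
    crits = []
    for c in data["criteria"]:
        crits.append(
            Criterion(
                id=c["id"],
                name=c.get("name", ""),
                units=c.get("units", ""),
                direction=c.get("direction", "benefit"),
                target_window=tuple(c["target_window"]) if "target_window" in c else None,
                decay_anchor=c.get("decay_anchor"),
                weight=_tfn_from_json(c["weight"], f"criterion {c['id']} weight")
                if "weight" in c
                else None,
            )
        )
    raw = data["matrix"]
    if len(raw) != len(alts):
        raise ValueError(f"matrix has {len(raw)} rows but {len(alts)} alternatives are declared")
    cells = []
    for i, row in enumerate(raw):
        if len(row) != len(crits):
            raise ValueError(
                f"row {alts[i].code} has {len(row)} cells but {len(crits)} criteria are declared"
            )
        cells.append(
            [
                _tfn_from_json(v, f"cell ({alts[i].code}, {crits[j].id})")
                for j, v in enumerate(row)
            ]
        )
    return FuzzyDecisionMatrix(alts, crits, cells)


def read_matrix_json(path: PathLike) -> FuzzyDecisionMatrix:
    with open(path, encoding="utf-8") as fh:
        return matrix_from_dict(json.load(fh))


def write_matrix_json(matrix: FuzzyDecisionMatrix, path: PathLike, notes: Optional[dict] = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(matrix_to_dict(matrix, notes), fh, indent=1)
        fh.write("\n")


def write_matrix_csv(matrix: FuzzyDecisionMatrix, path: PathLike) -> None:
    """Flat CSV mirror: one row per alternative, three columns per criterion."""
    cols: dict[str, list] = {"code": [], "name": []}
    for c in matrix.criteria:
        for part in ("l", "m", "u"):
            cols[f"{c.id}_{part}"] = []
    for a, row in zip(matrix.alternatives, matrix.cells):
        cols["code"].append(a.code)
        cols["name"].append(a.name)
        for c, cell in zip(matrix.criteria, row):
            cols[f"{c.id}_l"].append(cell.l)
            cols[f"{c.id}_m"].append(cell.m)
            cols[f"{c.id}_u"].append(cell.u)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_matrix_csv(path: PathLike, criteria: Sequence[Criterion]) -> FuzzyDecisionMatrix:
    """Read the CSV mirror; criterion metadata is not stored in CSV and must be supplied."""
    df = pd.read_csv(path)
    alts = [Alternative(str(r.code), str(getattr(r, "name", ""))) for r in df.itertuples(index=False)]
    cells = []
    for _, rec in df.iterrows():
        row = []
        for c in criteria:
            row.append(
                _tfn_from_json(
                    [rec[f"{c.id}_l"], rec[f"{c.id}_m"], rec[f"{c.id}_u"]],
                    f"cell ({rec['code']}, {c.id})",
                )
            )
        cells.append(row)
    return FuzzyDecisionMatrix(alts, list(criteria), cells)


# ---------------------------------------------------------------------------
# weight vectors


def weights_to_dict(weights: WeightVector) -> dict:
    return {
        "schema": WEIGHTS_SCHEMA,
        "criteria": [
            {"id": cid, "local_weight": _tfn_to_json(fz), "global_weight": cr}
            for cid, fz, cr in zip(weights.ids, weights.fuzzy, weights.crisp)
        ],
    }


def weights_from_dict(data: dict) -> WeightVector:
    ids = [c["id"] for c in data["criteria"]]
    fuzzy = [_tfn_from_json(c["local_weight"], f"weight {c['id']}") for c in data["criteria"]]
    crisp = [float(c["global_weight"]) for c in data["criteria"]]
    total = sum(crisp)
    if total <= 0:
        raise ValueError("global weights must have a positive sum")
    return WeightVector(ids, fuzzy, [w / total for w in crisp])


def read_weights_json(path: PathLike) -> WeightVector:
    with open(path, encoding="utf-8") as fh:
        return weights_from_dict(json.load(fh))


def write_weights_json(weights: WeightVector, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(weights_to_dict(weights), fh, indent=1)
        fh.write("\n")


def write_weights_csv(weights: WeightVector, path: PathLike) -> None:
    pd.DataFrame(
        {
            "id": weights.ids,
            "local_l": [w.l for w in weights.fuzzy],
            "local_m": [w.m for w in weights.fuzzy],
            "local_u": [w.u for w in weights.fuzzy],
            "global_weight": weights.crisp,
        }
    ).to_csv(path, index=False)


def read_weights_csv(path: PathLike) -> WeightVector:
    df = pd.read_csv(path)
    ids = [str(v) for v in df["id"]]
    fuzzy = [
        _tfn_from_json([r.local_l, r.local_m, r.local_u], f"weight {r.id}")
        for r in df.itertuples(index=False)
    ]
    crisp = [float(v) for v in df["global_weight"]]
    total = sum(crisp)
    return WeightVector(ids, fuzzy, [w / total for w in crisp])


# ---------------------------------------------------------------------------
# expert panels (pairwise-comparison judgments)


def write_panel_json(matrices: Sequence["FuzzyComparisonMatrix"], path: PathLike) -> None:  # noqa: F821
    data = {
        "schema": PANEL_SCHEMA,
        "experts": [
            [[_tfn_to_json(t) for t in row] for row in m.entries] for m in matrices
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def read_panel_json(path: PathLike) -> list["FuzzyComparisonMatrix"]:  # noqa: F821
    """Read a panel of expert comparison matrices.

    Entries may be ``[l, m, u]`` triples or linguistic labels from the
    five-term importance scale (VL/L/M/H/VH); labels are mapped through the
    standard scale, and reciprocal lower-triangle labels are inverted.
    """
    from .ahp import FuzzyComparisonMatrix
    from .fuzzify import LINGUISTIC_SCALE
    from .tfn import tfn_reciprocal

    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    out = []
    for k, grid in enumerate(data["experts"]):
        n = len(grid)
        entries: list[list[TFN]] = [[None] * n for _ in range(n)]  # type: ignore[list-item]
        for i, row in enumerate(grid):
            if len(row) != n:
                raise ValueError(f"expert {k}: matrix is not square")
            for j, v in enumerate(row):
                if isinstance(v, str):
                    label = v.lstrip("~")
                    if label not in LINGUISTIC_SCALE:
                        raise ValueError(f"expert {k} entry ({i},{j}): unknown label {v!r}")
                    t = TFN.from_sequence(LINGUISTIC_SCALE[label])
                    entries[i][j] = tfn_reciprocal(t) if v.startswith("~") else t
                else:
                    entries[i][j] = _tfn_from_json(v, f"expert {k} entry ({i},{j})")
        out.append(FuzzyComparisonMatrix(entries))
    return out


# ---------------------------------------------------------------------------
# scenarios


def write_scenarios(scenarios: Sequence["ScenarioSpec"], path: PathLike) -> None:  # noqa: F821
    data = {
        "schema": SCENARIOS_SCHEMA,
        "scenarios": [s.to_dict() for s in scenarios],
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(data, fh, sort_keys=False)
        else:
            json.dump(data, fh, indent=1)
            fh.write("\n")


def read_scenarios(path: PathLike) -> list["ScenarioSpec"]:  # noqa: F821
    from .sensitivity import ScenarioSpec

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    return [ScenarioSpec.from_dict(d) for d in data["scenarios"]]


# ---------------------------------------------------------------------------
# rankings


def ranking_to_frame(result: "RankingResult") -> pd.DataFrame:  # noqa: F821
    """Tabular view of a ranking: full precision plus 3-decimal display columns."""
    rows = result.rows_by_rank()
    return pd.DataFrame(
        {
            "rank": [r.rank for r in rows],
            "code": [r.code for r in rows],
            "name": [r.name for r in rows],
            "cc": [r.cc for r in rows],
            "d_pos": [r.d_pos for r in rows],
            "d_neg": [r.d_neg for r in rows],
            "label": [r.label for r in rows],
            "cc_display": [round(r.cc, 3) for r in rows],
        }
    )


def write_ranking_csv(result: "RankingResult", path: PathLike) -> None:  # noqa: F821
    ranking_to_frame(result).to_csv(path, index=False)
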