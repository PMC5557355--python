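"""Dendritic-spine filtering, morphological classification, and densities.

Spines arrive as per-spine morphometric records (length, head/neck/minimum
widths, optional volume) produced by a tracing tool; detection from raw
images is out of scope.  Classification follows three published rule
predicates evaluated in a fixed precedence:

* stubby:    length < 1 μm  and  0.9 < min_width / mean_width(head) < 1.1
* mushroom:  length < 3 μm  and  mean_width(head) / max_width(neck) > 0.75
* thin:      mean_width(head) / length < 0.5

The rule regions overlap, so the first satisfied rule wins (stubby, then
mushroom, then thin — the stubby condition being the most specific); a spine
satisfying none is reported as "unclassified" rather than forced into a
class.  The precedence is configurable and recorded in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SpineRecord",
    "SpineFilter",
    "CLASS_LABELS",
    "DEFAULT_PRECEDENCE",
    "filter_spines",
    "classify_spine",
    "classify_table",
    "spine_density",
    "class_composition",
]

CLASS_LABELS = ("stubby", "mushroom", "thin", "unclassified")
DEFAULT_PRECEDENCE = ("stubby", "mushroom", "thin")


@dataclass
class SpineRecord:
    """Morphometrics of a single dendritic spine (lengths in μm)."""

    length_um: float
    mean_width_head_um: float
    max_width_neck_um: float
    min_width_um: float
    volume_um3: float | None = None
    is_branched: bool = False
    parent_dendrite_id: str | int = 0


@dataclass
class SpineFilter:
    """Acceptance window applied before classification."""

    min_spine_diameter_um: float = 0.1
    max_length_um: float = 3.0
    min_dendrite_diameter_um: float = 0.25

    def __post_init__(self) -> None:
        if min(self.min_spine_diameter_um, self.max_length_um,
               self.min_dendrite_diameter_um) <= 0:
            raise ValueError("filter thresholds must be positive")


def filter_spines(candidates: list[SpineRecord],
                  f: SpineFilter | None = None) -> list[SpineRecord]:
    """Keep spines with min_width >= 0.1 μm and length <= 3 μm (defaults)."""
    if f is None:
        f = SpineFilter()
    return [
        s for s in candidates
        if s.min_width_um >= f.min_spine_diameter_um
        and s.length_um <= f.max_length_um
    ]


def _require(record: SpineRecord, fields: tuple[str, ...]) -> None:
    for name in fields:
        value = getattr(record, name, None)
        if value is None:
            raise ValueError(f"spine record is missing required field '{name}'")
        if value <= 0:
            raise ValueError(f"spine field '{name}' must be > 0, got {value!r}")


def _rule_stubby(s: SpineRecord) -> bool:
    return s.length_um < 1.0 and 0.9 < s.min_width_um / s.mean_width_head_um < 1.1


def _rule_mushroom(s: SpineRecord) -> bool:
    return s.length_um < 3.0 and s.mean_width_head_um / s.max_width_neck_um > 0.75


def _rule_thin(s: SpineRecord) -> bool:
    return s.mean_width_head_um / s.length_um < 0.5


_RULES = {"stubby": _rule_stubby, "mushroom": _rule_mushroom, "thin": _rule_thin}
_RULE_FIELDS = {
    "stubby": ("length_um", "min_width_um", "mean_width_head_um"),
    "mushroom": ("length_um", "mean_width_head_um", "max_width_neck_um"),
    "thin": ("mean_width_head_um", "length_um"),
}


def classify_spine(s: SpineRecord,
                   precedence: tuple[str, ...] = DEFAULT_PRECEDENCE) -> str:
    """Label one spine by the first satisfied rule under ``precedence``."""
    if set(precedence) != set(DEFAULT_PRECEDENCE):
        raise ValueError("precedence must be a permutation of "
                         f"{DEFAULT_PRECEDENCE}")
    for name in precedence:
        _require(s, _RULE_FIELDS[name])
        if _RULES[name](s):
            return name
    return "unclassified"


def classify_table(table: pd.DataFrame,
                   precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
                   ) -> pd.DataFrame:
    """Classify every row of a morphometry table; adds a 'class' column."""
    records = [
        SpineRecord(
            length_um=row.length_um,
            mean_width_head_um=row.mean_width_head_um,
            max_width_neck_um=row.max_width_neck_um,
            min_width_um=row.min_width_um,
        )
        for row in table.itertuples()
    ]
    out = table.copy()
    out["class"] = [classify_spine(r, precedence) for r in records]
    return out


def spine_density(n_spines: int, dendrite_length_um: float) -> float:
    """Spines per μm of measured dendrite."""
    if dendrite_length_um <= 0:
        raise ValueError("dendrite_length_um must be > 0")
    return n_spines / dendrite_length_um


def class_composition(labels: list[str],
                      dendrite_length_um: float | None = None,
                      ) -> dict[str, dict[str, float]]:
    """Per-class counts (and densities when a dendrite length is given)."""
    out: dict[str, dict[str, float]] = {}
    for cls in CLASS_LABELS:
        n = sum(1 for lab in labels if lab == cls)
        entry: dict[str, float] = {"count": n}
        if dendrite_length_um is not None:
            entry["density_per_um"] = spine_density(n, dendrite_length_um)
        out[cls] = entry
    return out
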