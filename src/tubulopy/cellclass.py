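"""Marker-based object classification.

Each detected cell is assigned exactly one class from an ordered rule
list; a rule fires when its intensity statistic (nuclear or cytosolic
mean by default) meets its RFU threshold on the rule's marker channel.
Sertoli and germ-cell markers are biologically disjoint, so multi-rule
ties resolve to the rule with the greatest fold over its own threshold
(or rule order, configurable); cells firing no rule are unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .cellseg import CellDetection
from .errors import TubulopyError

__all__ = [
    "ClassRule",
    "ClassifierSpec",
    "classify_cells",
    "class_counts",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"


@dataclass
class ClassRule:
    class_name: str
    channel: str
    compartment: str = "nuclear"  # nuclear | cytosolic
    statistic: str = "mean"  # mean | max | sum
    threshold_rfu: float = 2000.0

    def __post_init__(self) -> None:
        if self.threshold_rfu <= 0:
            raise TubulopyError("threshold must be > 0")
        if self.compartment not in ("nuclear", "cytosolic"):
            raise TubulopyError(f"unknown compartment {self.compartment!r}")
        if self.statistic not in ("mean", "max", "sum"):
            raise TubulopyError(f"unknown statistic {self.statistic!r}")

    def value(self, det: CellDetection) -> float:
        stats = (
            det.nuclear_stats if self.compartment == "nuclear" else det.cytosolic_stats
        )
        if self.channel not in stats:
            raise TubulopyError(
                f"rule {self.class_name!r} references unmeasured channel "
                f"{self.channel!r}"
            )
        return stats[self.channel][self.statistic]


@dataclass
class ClassifierSpec:
    rules: list[ClassRule] = field(default_factory=list)
    tie_break: str = "max_fold_over_threshold"  # or rule_order
    unclassified_label: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        names = [r.class_name for r in self.rules]
        if len(set(names)) != len(names):
            raise TubulopyError("duplicate class names in rules")
        if self.tie_break not in ("max_fold_over_threshold", "rule_order"):
            raise TubulopyError(f"unknown tie_break {self.tie_break!r}")

    @classmethod
    def from_yaml(cls, path) -> "ClassifierSpec":
        doc = yaml.safe_load(open(path, encoding="utf-8"))
        rules = [ClassRule(**r) for r in doc.get("rules", [])]
        return cls(
            rules=rules,
            tie_break=doc.get("tie_break", "max_fold_over_threshold"),
            unclassified_label=doc.get("unclassified_label", UNCLASSIFIED),
        )


def classify_cells(
    detections: list[CellDetection], spec: ClassifierSpec
) -> list[CellDetection]:
    """Assign one class label per detection, in place; returns the list."""
    for det in detections:
        fired = []
        for rule in spec.rules:
            v = rule.value(det)
            if v >= rule.threshold_rfu:
                fired.append((rule, v / rule.threshold_rfu))
        if not fired:
            det.class_label = spec.unclassified_label
        elif len(fired) == 1 or spec.tie_break == "rule_order":
            det.class_label = fired[0][0].class_name
        else:
            det.class_label = max(fired, key=lambda t: t[1])[0].class_name
    return detections


def class_counts(
    detections: list[CellDetection], by: tuple[str, ...] = ("class",)
) -> pd.DataFrame:
    """Count detections per class (optionally per region).

    Counts always partition the input: per-class counts plus unclassified
    sum to the number of detections.
    """
    if any(d.class_label is None for d in detections):
        raise TubulopyError("detections must be classified first")
    cols = {"class": [d.class_label for d in detections]}
    if "region" in by:
        cols["region"] = [d.region_label for d in detections]
    df = pd.DataFrame(cols)
    if df.empty:
        return pd.DataFrame(columns=[*by, "count"])
    out = df.value_counts(list(by)).rename("count").reset_index()
    return out.sort_values(list(by)).reset_index(drop=True)
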