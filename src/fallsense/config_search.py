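"""Sensor-configuration x test-battery search.

Ranks the best model obtainable from every combination of a sensor
configuration (one to three anatomical slots; bilateral pairs such as the
thighs count as a single slot) and a test subset of up to three of the ten
task variants.  Clinical features are available under every configuration;
a motion feature is available iff one of its sensor-requirement alternatives
is covered by the configuration and its task variant is in the subset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .features import CATALOGUE, CatalogueEntry
from .modeling import ModelSpec, forward_select
from .recording import TASK_VARIANTS

#: Anatomical slots in the Table-style vocabulary; a slot is one selectable
#: unit even when it covers a bilateral sensor pair.
SENSOR_SLOTS: Dict[str, FrozenSet[str]] = {
    "Thorax": frozenset({"thorax"}),
    "Pelvic": frozenset({"pelvis"}),
    "Upper Legs": frozenset({"thigh_L", "thigh_R"}),
    "Lower Legs": frozenset({"shank_L", "shank_R"}),
    "Feet": frozenset({"foot_L", "foot_R"}),
}

_ARITY = {1: "single", 2: "double", 3: "triple"}


@dataclass(frozen=True)
class SensorConfig:
    name: str
    placements: FrozenSet[str]
    n_slots: int

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValueError("placements must be nonempty")

    @property
    def arity(self) -> str:
        return _ARITY.get(self.n_slots, f"{self.n_slots}-slot")


def config_from_slots(slots: Sequence[str]) -> SensorConfig:
    unknown = [s for s in slots if s not in SENSOR_SLOTS]
    if unknown:
        raise ValueError(f"unknown sensor slots: {unknown}")
    placements = frozenset().union(*(SENSOR_SLOTS[s] for s in slots))
    return SensorConfig(name=" and ".join(slots), placements=placements,
                        n_slots=len(slots))


def named_configs(max_slots: int = 3) -> List[SensorConfig]:
    """All slot combinations of 1..max_slots slots (5 + 10 + 10 by default)."""
    out = []
    names = list(SENSOR_SLOTS)
    for k in range(1, max_slots + 1):
        for combo in itertools.combinations(names, k):
            out.append(config_from_slots(combo))
    return out


def _entry_available(entry: CatalogueEntry, placements: FrozenSet[str],
                     tests: FrozenSet[str]) -> bool:
    if entry.clinical:
        return True
    variant = f"{entry.task}_{'dual' if entry.dual else 'single'}"
    if variant not in tests:
        return False
    return any(req <= placements for req in entry.requires)


def available_features(catalogue: Sequence[CatalogueEntry],
                       config: SensorConfig,
                       tests: Iterable[str]) -> List[str]:
    """Feature names extractable under a sensor config and test subset.

    ``tests`` holds task-variant ids (e.g. ``BAL_EO_dual``); the single and
    dual form of a test are distinct options.  The 8 clinical features are
    always included.
    """
    tests = frozenset(tests)
    unknown = tests - set(TASK_VARIANTS)
    if unknown:
        raise ValueError(f"unknown task variants: {sorted(unknown)}")
    return [e.name for e in catalogue
            if _entry_available(e, config.placements, tests)]


def search(table: pd.DataFrame, configs: Sequence[SensorConfig],
           max_tests: int = 3, spec: Optional[ModelSpec] = None,
           test_variants: Sequence[str] = TASK_VARIANTS,
           min_motion_features: int = 0) -> pd.DataFrame:
    """Exhaustive search over (config, test subset) pairs.

    For every pair the forward selection runs on the available features and
    the best model is recorded; rows are sorted by accuracy, then
    specificity, then sensitivity.  Set ``min_motion_features`` > 0 to skip
    pairs whose battery contributes no motion feature under the
    configuration (those rows otherwise fall back to clinical-only pools).
    """
    spec = spec or ModelSpec()
    rows = []
    n_clinical = sum(1 for e in CATALOGUE if e.clinical)
    for config in configs:
        for k in range(1, max_tests + 1):
            for subset in itertools.combinations(test_variants, k):
                feats = available_features(CATALOGUE, config, subset)
                if len(feats) - n_clinical < min_motion_features:
                    continue
                result = forward_select(table, spec, candidates=feats)
                rows.append({
                    "sensor_config": config.name,
                    "arity": config.arity,
                    "tests": " + ".join(subset),
                    "n_tests": k,
                    "selected_features": "; ".join(result.selected_features),
                    "accuracy": result.accuracy,
                    "sensitivity": result.sensitivity,
                    "specificity": result.specificity,
                })
    report = pd.DataFrame(rows)
    if len(report):
        report = report.sort_values(
            ["accuracy", "specificity", "sensitivity"],
            ascending=False, kind="mergesort",
        ).reset_index(drop=True)
    return report
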