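"""Presence filtering of species calls by a metric threshold.

A species whose filter metric (template identity or relative abundance)
falls below the threshold is considered absent.  A call exactly at the
threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .postprocess import Metric, SpeciesCall


@dataclass(frozen=True)
class FilterSpec:
    metric: Metric
    threshold_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_pct <= 100.0:
            raise ValueError(
                f"threshold_pct must lie in [0, 100], got {self.threshold_pct}"
            )
        if self.metric not in ("template_id", "abundance"):
            raise ValueError(f"unknown metric {self.metric!r}")


def apply_filter(calls: Sequence[SpeciesCall], spec: FilterSpec) -> list[SpeciesCall]:
    """Retain calls with metric_value_pct >= threshold; order preserved.

    Threshold 0 is the identity (the unfiltered baseline).
    """
    mismatched = [c.species_name for c in calls if c.metric != spec.metric]
    if mismatched:
        raise ValueError(
            f"calls carry metric other than {spec.metric!r}: {mismatched[:5]}"
        )
    return [c for c in calls if c.metric_value_pct >= spec.threshold_pct]
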