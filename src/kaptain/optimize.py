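"""Threshold scanning and selection strategies.

Per yield, precision/recall/F1 are evaluated across the full 0-100% range
of filter thresholds.  Because every per-sample metric is a step function
that only changes where an observed metric value is crossed, scanning the
finite grid {0} ∪ {observed values} is exactly equivalent to a continuous
scan.  Two selection strategies pick the operating threshold:

* ``max_f1`` — the threshold maximizing the median F1 across samples,
  breaking ties by the highest mean F1, then by the lowest threshold;
* ``fdrX`` (X in 15, 10, 5, 1) — the lowest threshold whose median
  precision across samples reaches 100 - X.  An FDR of 5% corresponds to a
  precision of 95%.  A target no threshold can reach is reported as
  explicitly unattainable, never silently substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .evaluation import (
    AggregateResult,
    EvaluationResult,
    aggregate_median,
    score_sample,
)
from .filtering import FilterSpec, apply_filter
from .io_formats import GroundTruthEntry
from .postprocess import Metric, SpeciesCall

#: (calls, ground truth) for one sample
Sample = tuple[Sequence[SpeciesCall], Sequence[GroundTruthEntry]]

STRATEGIES = ("none", "max_f1", "fdr15", "fdr10", "fdr5", "fdr1")


@dataclass(frozen=True)
class CurvePoint:
    threshold_pct: float
    per_sample: tuple[EvaluationResult, ...]
    median: EvaluationResult
    mean: EvaluationResult


@dataclass(frozen=True)
class ThresholdCurve:
    metric: Metric
    points: tuple[CurvePoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    @property
    def thresholds(self) -> list[float]:
        return [p.threshold_pct for p in self.points]


def evaluate_at_threshold(
    samples: Sequence[Sample],
    metric: Metric,
    threshold_pct: float,
    synonyms: Mapping[str, str] | None = None,
) -> tuple[tuple[EvaluationResult, ...], AggregateResult]:
    """Filter and score every sample at one threshold."""
    spec = FilterSpec(metric=metric, threshold_pct=threshold_pct)
    per_sample = []
    for calls, truth in samples:
        retained = apply_filter(calls, spec)
        _, result = score_sample(
            (c.species_name for c in retained), truth, synonyms
        )
        per_sample.append(result)
    return tuple(per_sample), aggregate_median(per_sample)


def scan_thresholds(
    samples: Sequence[Sample],
    metric: Metric,
    synonyms: Mapping[str, str] | None = None,
) -> ThresholdCurve:
    """Evaluate every sample at each candidate threshold.

    Candidates are 0 plus every distinct metric value observed across
    samples, in increasing order, so the curve covers the whole range over
    which the step functions change.
    """
    if not samples:
        raise ValueError("scan_thresholds needs at least one sample")
    candidates = {0.0}
    for calls, _ in samples:
        candidates.update(float(c.metric_value_pct) for c in calls)
    points = []
    for threshold in sorted(candidates):
        per_sample, aggregate = evaluate_at_threshold(
            samples, metric, threshold, synonyms
        )
        points.append(
            CurvePoint(
                threshold_pct=threshold,
                per_sample=per_sample,
                median=aggregate.median,
                mean=aggregate.mean,
            )
        )
    return ThresholdCurve(metric=metric, points=tuple(points))


def select_max_f1(curve: ThresholdCurve) -> float:
    """Threshold with the highest median F1; ties broken by highest mean
    F1, remaining ties by the lowest threshold."""
    if not curve.points:
        raise ValueError("empty threshold curve")

    def key(p: CurvePoint) -> tuple[float, float, float]:
        median_f1 = p.median.f1_pct if p.median.f1_pct is not None else -math.inf
        mean_f1 = p.mean.f1_pct if p.mean.f1_pct is not None else -math.inf
        return (-median_f1, -mean_f1, p.threshold_pct)

    return min(curve.points, key=key).threshold_pct


def select_fdr(curve: ThresholdCurve, target_fdr_pct: float) -> float | None:
    """Lowest threshold whose median precision >= 100 - target FDR.

    Returns None when no threshold attains the target precision.
    """
    if not 0.0 < target_fdr_pct < 100.0:
        raise ValueError(f"target FDR must lie in (0, 100), got {target_fdr_pct}")
    required = 100.0 - target_fdr_pct
    for point in curve.points:
        precision = point.median.precision_pct
        if precision is not None and precision >= required:
            return point.threshold_pct
    return None


def _point_at(curve: ThresholdCurve, threshold: float) -> CurvePoint:
    for point in curve.points:
        if point.threshold_pct == threshold:
            return point
    raise KeyError(f"threshold {threshold} not on curve")


@dataclass(frozen=True)
class ThresholdRow:
    yield_label: str
    strategy: str
    threshold_pct: float | None  # None = unattainable target
    median: EvaluationResult

    @property
    def attainable(self) -> bool:
        return self.threshold_pct is not None


@dataclass
class ThresholdTable:
    """Optimized thresholds keyed by (yield label, strategy)."""

    rows: list[ThresholdRow]

    def lookup(self, yield_label: str, strategy: str) -> ThresholdRow:
        for row in self.rows:
            if row.yield_label == yield_label and row.strategy == strategy:
                return row
        raise KeyError(f"no threshold for yield {yield_label!r}, "
                       f"strategy {strategy!r}")


def build_threshold_table(
    samples_by_yield: Mapping[str, Sequence[Sample]],
    metric: Metric,
    strategies: Sequence[str] = STRATEGIES,
    synonyms: Mapping[str, str] | None = None,
) -> ThresholdTable:
    """Optimize thresholds for every yield label under each strategy.

    Strategy ``none`` is the unfiltered baseline (threshold 0); ``fdrX``
    rows whose target precision is unattainable are kept with a missing
    threshold and the statistics of the strictest available point.
    """
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    rows: list[ThresholdRow] = []
    for yield_label, samples in samples_by_yield.items():
        curve = scan_thresholds(samples, metric, synonyms)
        for strategy in strategies:
            if strategy == "none":
                threshold: float | None = 0.0
            elif strategy == "max_f1":
                threshold = select_max_f1(curve)
            else:
                threshold = select_fdr(curve, float(strategy.removeprefix("fdr")))
            if threshold is None:
                median = curve.points[-1].median
            else:
                median = _point_at(curve, threshold).median
            rows.append(ThresholdRow(yield_label, strategy, threshold, median))
    return ThresholdTable(rows)


_TABLE_COLUMNS = ("yield_label", "strategy", "threshold_pct",
                  "median_precision_pct", "median_recall_pct", "median_f1_pct")


def write_threshold_table(path: str | Path, table: ThresholdTable) -> None:
    df = pd.DataFrame(
        [
            {
                "yield_label": r.yield_label,
                "strategy": r.strategy,
                "threshold_pct": r.threshold_pct,
                "median_precision_pct": r.median.precision_pct,
                "median_recall_pct": r.median.recall_pct,
                "median_f1_pct": r.median.f1_pct,
            }
            for r in table.rows
        ],
        columns=list(_TABLE_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_threshold_table(path: str | Path) -> ThresholdTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"yield_label": str, "strategy": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing threshold-table columns {missing}")

    def opt(value: float) -> float | None:
        return None if pd.isna(value) else float(value)

    return ThresholdTable(
        [
            ThresholdRow(
                yield_label=row.yield_label,
                strategy=row.strategy,
                threshold_pct=opt(row.threshold_pct),
                median=EvaluationResult(
                    opt(row.median_precision_pct),
                    opt(row.median_recall_pct),
                    opt(row.median_f1_pct),
                ),
            )
            for row in df.itertuples(index=False)
        ]
    )
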