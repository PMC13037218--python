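"""Scoring of detected species against mock-community ground truth.

Species both expected and detected are true positives (TP); expected but
undetected, false negatives (FN); detected but unexpected, false positives
(FP).  Precision = TP / (TP + FP), recall = TP / (TP + FN), F1 their
harmonic mean, all reported on the 0-100 scale.  The false discovery rate
is FP / (TP + FP) = 100 - precision.  Metrics with a zero denominator are
undefined and propagate as missing — never as 0 — and are skipped when
aggregating across samples by the median.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GroundTruthEntry, apply_synonyms


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class EvaluationResult:
    """Precision/recall/F1 in percent; None where the denominator was 0."""

    precision_pct: float | None
    recall_pct: float | None
    f1_pct: float | None

    @property
    def fdr_pct(self) -> float | None:
        """False discovery rate = 100 - precision."""
        if self.precision_pct is None:
            return None
        return 100.0 - self.precision_pct


def evaluation_from_counts(counts: ConfusionCounts) -> EvaluationResult:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return EvaluationResult(precision, recall, f1)


def score_sample(
    detected: Iterable[str],
    truth: Sequence[GroundTruthEntry],
    synonyms: Mapping[str, str] | None = None,
) -> tuple[ConfusionCounts, EvaluationResult]:
    """Score one sample's detected species set against its ground truth.

    Names on both sides are harmonized through the optional synonym table.
    Expected species absent from the reference database still count as FNs
    here (only the limit-of-detection analysis excludes them).
    """
    if not truth:
        raise ValueError("ground truth is empty: a mock community must "
                         "declare expected species")
    detected_set = apply_synonyms(detected, synonyms)
    truth_set = apply_synonyms((e.species_name for e in truth), synonyms)
    counts = ConfusionCounts(
        tp=len(detected_set & truth_set),
        fp=len(detected_set - truth_set),
        fn=len(truth_set - detected_set),
    )
    return counts, evaluation_from_counts(counts)


@dataclass(frozen=True)
class AggregateResult:
    """Across-sample aggregation: medians (the headline statistic) plus
    means, which break ties during threshold optimization."""

    median: EvaluationResult
    mean: EvaluationResult
    n_samples: int


def _agg(values: list[float | None], fn) -> float | None:
    defined = [v for v in values if v is not None]
    return fn(defined) if defined else None


def aggregate_median(results: Sequence[EvaluationResult]) -> AggregateResult:
    """Elementwise median (and mean) of per-sample results.

    Undefined per-sample values are skipped rather than treated as 0; the
    median of an even-length list is the mean of the two central values.
    """
    if not results:
        raise ValueError("cannot aggregate an empty result list")
    cols = {
        name: [getattr(r, name) for r in results]
        for name in ("precision_pct", "recall_pct", "f1_pct")
    }
    median = EvaluationResult(
        *(_agg(cols[name], statistics.median) for name in cols)
    )
    mean = EvaluationResult(*(_agg(cols[name], statistics.fmean) for name in cols))
    return AggregateResult(median=median, mean=mean, n_samples=len(results))
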