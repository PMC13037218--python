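"""Pooled limit-of-detection (LOD) estimation.

The LOD is the lowest ground-truth sequence abundance at which every
species with an equal or higher abundance was still detected, computed on
detection outcomes pooled across samples rather than per sample.  Expected
species absent from the reference database are excluded first — their
misses reflect database completeness, not detection sensitivity — and so
are samples without abundance information.  Candidate LOD values are the
observed ground-truth abundances; a separate helper bins outcomes into
abundance intervals for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GroundTruthEntry, apply_synonyms
from .postprocess import SpeciesCall


@dataclass(frozen=True)
class DetectionOutcome:
    """Whether one expected species of one sample survived filtering."""

    sample_id: str
    species_name: str
    truth_abundance_pct: float
    detected: bool
    in_database: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.truth_abundance_pct <= 100.0:
            raise ValueError(
                f"{self.sample_id}/{self.species_name}: abundance must lie "
                f"in (0, 100], got {self.truth_abundance_pct}"
            )


def detection_outcomes(
    sample_id: str,
    retained_calls: Sequence[SpeciesCall],
    truth: Sequence[GroundTruthEntry],
    synonyms: Mapping[str, str] | None = None,
) -> list[DetectionOutcome]:
    """Turn one sample's filtered calls into detection outcomes.

    Ground-truth entries without abundance information yield no outcome
    (such samples cannot inform the LOD).
    """
    detected = apply_synonyms((c.species_name for c in retained_calls), synonyms)
    outcomes = []
    for entry in truth:
        if entry.sequence_abundance_pct is None:
            continue
        name = next(iter(apply_synonyms([entry.species_name], synonyms)))
        outcomes.append(
            DetectionOutcome(
                sample_id=sample_id,
                species_name=entry.species_name,
                truth_abundance_pct=entry.sequence_abundance_pct,
                detected=name in detected,
                in_database=entry.in_database,
            )
        )
    return outcomes


def compute_lod(outcomes: Iterable[DetectionOutcome]) -> float | None:
    """Lowest abundance a such that every pooled in-database outcome with
    abundance >= a was detected; None when even the most abundant species
    was missed."""
    retained = [o for o in outcomes if o.in_database]
    if not retained:
        raise ValueError("no in-database outcomes with abundance information")
    # descending abundance; within a tie an undetected outcome comes first so
    # it invalidates its own abundance level
    ordered = sorted(retained, key=lambda o: (-o.truth_abundance_pct, o.detected))
    lod: float | None = None
    for outcome in ordered:  # stop at the first miss
        if not outcome.detected:
            break
        lod = outcome.truth_abundance_pct
    return lod


def detection_fraction_bins(
    outcomes: Iterable[DetectionOutcome],
    bin_edges: Sequence[float] = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0),
) -> pd.DataFrame:
    """Fraction of expected in-database species detected per abundance
    interval (presentation companion to the exact pooled LOD)."""
    retained = [o for o in outcomes if o.in_database]
    rows = []
    edges = list(bin_edges)
    for low, high in zip([0.0] + edges[:-1], edges):
        members = [o for o in retained if low < o.truth_abundance_pct <= high]
        rows.append(
            {
                "abundance_low_pct": low,
                "abundance_high_pct": high,
                "n_species": len(members),
                "detected_fraction": (
                    sum(o.detected for o in members) / len(members)
                    if members
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def read_outcomes(path: str) -> list[DetectionOutcome]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species_name": str})
    required = ["sample_id", "species_name", "truth_abundance_pct", "detected"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing outcome columns {missing}")
    return [
        DetectionOutcome(
            sample_id=row.sample_id,
            species_name=row.species_name,
            truth_abundance_pct=float(row.truth_abundance_pct),
            detected=bool(row.detected),
            in_database=bool(getattr(row, "in_database", True)),
        )
        for row in df.itertuples(index=False)
    ]


def write_outcomes(path: str, outcomes: Sequence[DetectionOutcome]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": o.sample_id,
                "species_name": o.species_name,
                "truth_abundance_pct": o.truth_abundance_pct,
                "detected": o.detected,
                "in_database": o.in_database,
            }
            for o in outcomes
        ]
    ).to_csv(path, sep="\t", index=False)
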