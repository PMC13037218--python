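"""End-to-end orchestration of the post-classification workflow.

A run reads a per-template hit table and reference metadata, applies the
chosen processing route (template-identity or relative-abundance), resolves
the filter threshold (explicit value, preset threshold table, or on-the-fly
optimization against a supplied ground truth), filters, and reports the
retained species together with a provenance block (tool version, config
hash, selected threshold and per-stage row counts).  An optional subprocess
hook invokes an external KMA classifier; it is never required.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

from . import __version__
from .evaluation import EvaluationResult, score_sample
from .filtering import FilterSpec, apply_filter
from .io_formats import (
    ReferenceMetadata,
    TemplateHit,
    read_ground_truth,
    read_hits,
    read_reference_metadata,
    read_synonyms,
)
from .optimize import (
    read_threshold_table,
    scan_thresholds,
    select_fdr,
    select_max_f1,
)
from .postprocess import (
    SpeciesCall,
    standard_abundance,
    template_id_calls,
    write_calls,
)

logger = logging.getLogger(__name__)

Mode = Literal["novel", "standard"]
Strategy = Literal["none", "max_f1", "fdr15", "fdr10", "fdr5", "fdr1"]
ThresholdSource = Literal["preset_table", "optimize", "explicit"]

#: parameter set used to invoke the external KMA classifier
CLASSIFIER_FLAGS: tuple[str, ...] = (
    "-mrs", "0.0", "-bcNano", "-bc", "0.7", "-ef", "-a",
    "-mem_mode", "-1t1", "-matrix", "-tsv", "-shm",
)


class MissingClassifierError(RuntimeError):
    """The external classifier binary is not installed."""


class PipelineConfigError(ValueError):
    """The run configuration is inconsistent."""


@dataclass
class RunConfig:
    hits_path: str
    metadata_path: str
    mode: Mode = "novel"
    strategy: Strategy = "none"
    yield_label: str = ""
    threshold_source: ThresholdSource = "explicit"
    explicit_threshold_pct: float | None = 0.0
    threshold_table_path: str | None = None
    truth_path: str | None = None
    synonyms_path: str | None = None
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.threshold_source == "explicit" and self.explicit_threshold_pct is None:
            raise PipelineConfigError("explicit threshold source needs a value")
        if self.threshold_source == "preset_table" and not self.threshold_table_path:
            raise PipelineConfigError("preset_table threshold source needs a "
                                      "threshold-table file")
        if self.threshold_source == "optimize" and not self.truth_path:
            raise PipelineConfigError("optimize threshold source needs a "
                                      "ground-truth file")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    retained_calls: list[SpeciesCall]
    threshold_pct: float
    strategy: str
    evaluation: EvaluationResult | None
    stage_counts: dict[str, int]
    provenance: dict = field(default_factory=dict)


def _resolve_threshold(
    config: RunConfig,
    calls: list[SpeciesCall],
    truth,
    synonyms: Mapping[str, str] | None,
) -> float:
    if config.strategy == "none":
        return 0.0
    if config.threshold_source == "explicit":
        return float(config.explicit_threshold_pct)
    if config.threshold_source == "preset_table":
        table = read_threshold_table(config.threshold_table_path)
        row = table.lookup(config.yield_label, config.strategy)
        if row.threshold_pct is None:
            raise PipelineConfigError(
                f"preset table marks ({config.yield_label}, {config.strategy}) "
                f"as unattainable"
            )
        return row.threshold_pct
    # optimize on the sample itself
    metric = "template_id" if config.mode == "novel" else "abundance"
    curve = scan_thresholds([(calls, truth)], metric, synonyms)
    if config.strategy == "max_f1":
        return select_max_f1(curve)
    target = float(config.strategy.removeprefix("fdr"))
    threshold = select_fdr(curve, target)
    if threshold is None:
        raise PipelineConfigError(
            f"target precision for {config.strategy} unattainable on this sample"
        )
    return threshold


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the fixed stage order: read, route-specific post-processing,
    threshold resolution, filtering, optional evaluation, reporting."""
    config.validate()
    hits = read_hits(config.hits_path)
    meta = read_reference_metadata(config.metadata_path)
    synonyms = read_synonyms(config.synonyms_path) if config.synonyms_path else None
    truth = read_ground_truth(config.truth_path) if config.truth_path else None

    stage_counts: dict[str, int] = {"hits": len(hits)}
    if config.mode == "novel":
        calls = template_id_calls(hits, meta)
        metric = "template_id"
    else:
        calls = standard_abundance(hits, meta)
        metric = "abundance"
    stage_counts["species_calls"] = len(calls)

    threshold = _resolve_threshold(config, calls, truth, synonyms)
    retained = apply_filter(calls, FilterSpec(metric=metric,
                                              threshold_pct=threshold))
    stage_counts["retained_calls"] = len(retained)
    logger.info("pipeline stages: %s", stage_counts)

    evaluation = None
    if truth is not None:
        _, evaluation = score_sample(
            (c.species_name for c in retained), truth, synonyms
        )

    provenance = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "strategy": config.strategy,
        "yield_label": config.yield_label,
        "threshold_source": config.threshold_source,
        "threshold_pct": threshold,
        "seed": config.seed,
        "stage_counts": stage_counts,
    }
    report = PipelineReport(
        retained_calls=retained,
        threshold_pct=threshold,
        strategy=config.strategy,
        evaluation=evaluation,
        stage_counts=stage_counts,
        provenance=provenance,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_calls(out / "retained_calls.tsv", retained)
        with open(out / "provenance.json", "w") as handle:
            json.dump(provenance, handle, indent=2, sort_keys=True)
    return report


def classify_external(
    fastq: str | Path,
    db: str | Path,
    output_prefix: str | Path,
    binary: str = "kma",
) -> list[TemplateHit]:
    """Invoke an external KMA classifier and parse its result table.

    Optional integration hook: raises :class:`MissingClassifierError` with a
    clear message when the binary is not installed.
    """
    resolved = shutil.which(str(binary))
    if resolved is None:
        raise MissingClassifierError(
            f"external classifier not installed: {binary!r} not found on PATH"
        )
    command = [resolved, "-i", str(fastq), "-t_db", str(db),
               "-o", str(output_prefix), *CLASSIFIER_FLAGS]
    logger.info("running external classifier: %s", " ".join(command))
    subprocess.run(command, check=True)
    return read_hits(f"{output_prefix}.res", schema="kma")
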