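"""Post-processing of per-template classifier output.

The template-identity ("novel") route applies three steps to the raw
per-template hits:

1. remove hits on plasmid references (low discriminatory power — plasmids
   circulate among several host bacteria) and on viral references (phage
   hits are frequent and often non-specific);
2. group the remaining templates by source genome and recompute the metrics
   at the genome level, i.e. template identity = summed identical bases over
   summed template lengths (a length-weighted recomputation, never an
   average of per-template percentages);
3. per species, keep only the genome with the highest genome-level template
   identity.

The conventional relative-abundance ("standard") route skips grouping and
best-genome selection: after removing viral hits only, reads are summed per
species and divided by the total retained reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .io_formats import ReferenceMetadata, TemplateHit

logger = logging.getLogger(__name__)

Metric = Literal["template_id", "abundance"]


@dataclass(frozen=True)
class GenomeRecord:
    """Per-genome metrics recomputed from the genome's member templates."""

    genome_accession: str
    species_name: str
    total_identical_bases: int
    total_template_length: int
    genome_template_id_pct: float
    mapped_reads: int
    genome_coverage_pct: float
    n_templates: int


@dataclass(frozen=True)
class SpeciesCall:
    """One detected species with the metric used for presence filtering.

    ``metric_value_pct`` is the genome-level template identity for the
    template-identity route and the relative sequence abundance for the
    standard route; ``metric`` records which.
    """

    species_name: str
    metric_value_pct: float
    mapped_reads: int
    metric: Metric = "template_id"
    best_genome: str | None = None


class UnknownTemplateError(KeyError):
    """Hit templates absent from the reference metadata."""

    def __init__(self, unknown: Sequence[str]):
        self.unknown = list(unknown)
        super().__init__(
            f"{len(self.unknown)} hit template(s) absent from reference "
            f"metadata: {self.unknown[:10]}"
        )


def _check_known(hits: Sequence[TemplateHit], meta: ReferenceMetadata) -> None:
    unknown = sorted({h.template_id for h in hits if h.template_id not in meta})
    if unknown:
        raise UnknownTemplateError(unknown)


def remove_nontarget(
    hits: Sequence[TemplateHit],
    meta: ReferenceMetadata,
    drop_plasmids: bool = True,
    drop_viruses: bool = True,
) -> list[TemplateHit]:
    """Drop hits assigned to plasmid and/or viral references."""
    _check_known(hits, meta)
    kept = [
        h
        for h in hits
        if not (drop_plasmids and meta.is_plasmid(h.template_id))
        and not (drop_viruses and meta.is_viral(h.template_id))
    ]
    logger.info("remove_nontarget: %d -> %d hits", len(hits), len(kept))
    return kept


def group_by_genome(
    hits: Sequence[TemplateHit],
    meta: ReferenceMetadata,
    genome_lengths: Mapping[str, int] | None = None,
) -> list[GenomeRecord]:
    """Group hits by source genome and recompute metrics from the sums.

    By default the denominator is the summed length of the genome's
    templates that appear in the hit table.  ``genome_lengths`` optionally
    supplies full per-genome lengths so that templates without any hit
    contribute their length (and zero identical bases) to the denominator.
    """
    _check_known(hits, meta)
    by_genome: dict[str, list[TemplateHit]] = {}
    for h in hits:
        by_genome.setdefault(meta.genome_of(h.template_id), []).append(h)

    records: list[GenomeRecord] = []
    for accession in sorted(by_genome):
        members = by_genome[accession]
        identical = sum(h.identical_bases for h in members)
        covered = sum(h.covered_bases for h in members)
        length = sum(h.template_length for h in members)
        if genome_lengths is not None:
            full = int(genome_lengths[accession])
            if full < length:
                raise ValueError(
                    f"{accession}: supplied genome length {full} smaller than "
                    f"summed hit template lengths {length}"
                )
            length = full
        records.append(
            GenomeRecord(
                genome_accession=accession,
                species_name=meta.species_of_genome(accession),
                total_identical_bases=identical,
                total_template_length=length,
                genome_template_id_pct=100.0 * identical / length,
                mapped_reads=sum(h.mapped_reads for h in members),
                genome_coverage_pct=100.0 * covered / length,
                n_templates=len(members),
            )
        )
    return records


def select_best_genome(genomes: Sequence[GenomeRecord]) -> list[SpeciesCall]:
    """Per species keep the genome with the highest genome-level template
    identity; ties go to the genome with more mapped reads, then to the
    lexicographically smallest accession (for determinism)."""
    by_species: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        by_species.setdefault(g.species_name, []).append(g)
    calls: list[SpeciesCall] = []
    for species in sorted(by_species):
        best = min(
            by_species[species],
            key=lambda g: (-g.genome_template_id_pct, -g.mapped_reads,
                           g.genome_accession),
        )
        calls.append(
            SpeciesCall(
                species_name=species,
                metric_value_pct=best.genome_template_id_pct,
                mapped_reads=best.mapped_reads,
                metric="template_id",
                best_genome=best.genome_accession,
            )
        )
    return calls


def template_id_calls(
    hits: Sequence[TemplateHit],
    meta: ReferenceMetadata,
    genome_lengths: Mapping[str, int] | None = None,
) -> list[SpeciesCall]:
    """The full template-identity route: non-target removal, genome
    grouping, best-genome selection."""
    retained = remove_nontarget(hits, meta, drop_plasmids=True, drop_viruses=True)
    return select_best_genome(group_by_genome(retained, meta, genome_lengths))


def standard_abundance(
    hits: Sequence[TemplateHit], meta: ReferenceMetadata
) -> list[SpeciesCall]:
    """Relative sequence abundance per species (standard route).

    Only viral hits are removed first; plasmid hits are retained and no
    genome grouping or selection happens.  The abundances sum to 100 over
    the detected species whenever any reads remain.
    """
    retained = remove_nontarget(hits, meta, drop_plasmids=False, drop_viruses=True)
    reads_by_species: dict[str, int] = {}
    for h in retained:
        species = meta.species_of_genome(meta.genome_of(h.template_id))
        reads_by_species[species] = reads_by_species.get(species, 0) + h.mapped_reads
    total = sum(reads_by_species.values())
    if total == 0:
        logger.warning("standard_abundance: zero aligned reads; no calls")
        return []
    return [
        SpeciesCall(
            species_name=species,
            metric_value_pct=100.0 * reads / total,
            mapped_reads=reads,
            metric="abundance",
        )
        for species, reads in sorted(reads_by_species.items())
    ]


def write_calls(path, calls: Sequence[SpeciesCall]) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "species_name": c.species_name,
                "metric": c.metric,
                "metric_value_pct": c.metric_value_pct,
                "mapped_reads": c.mapped_reads,
                "best_genome": c.best_genome,
            }
            for c in calls
        ],
        columns=["species_name", "metric", "metric_value_pct",
                 "mapped_reads", "best_genome"],
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_calls(path) -> list[SpeciesCall]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"species_name": str, "metric": str})
    required = ["species_name", "metric", "metric_value_pct", "mapped_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing call-table columns {missing}")
    return [
        SpeciesCall(
            species_name=row.species_name,
            metric_value_pct=float(row.metric_value_pct),
            mapped_reads=int(row.mapped_reads),
            metric=row.metric,
            best_genome=(None if pd.isna(getattr(row, "best_genome", None))
                         else str(row.best_genome)),
        )
        for row in df.itertuples(index=False)
    ]
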