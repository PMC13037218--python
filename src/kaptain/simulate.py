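"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, what a long-read classifier emits on
a defined mock community: per-template hit tables whose genome-level
template identities separate true positives from false positives.  True
species receive template identities from a high truncated-normal
distribution scaled by a breadth-of-coverage cap, min(1, allocated bases /
genome length) — low-abundance species at low yield cover only part of
their genome, so their template identity drops, while false-positive
identities stay low and essentially yield-independent (a small outlier tail
grows slowly with yield).  With the default ten samples, a geometric
abundance profile over 30 true species and a 4 Mb genome, the true-positive
median rises from roughly half at a 200M-base yield towards the high
nineties at 2000M bases while the false-positive median stays near 3%.

Genome-level intended identities are decomposed into per-template identical
bases and lengths such that regrouping the templates reconstructs the
intended value exactly (up to integer rounding of the total).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io_formats import GroundTruthEntry, ReferenceMetadata, TemplateHit
from .preprocess import ReadRecord


def _default_abundance_profile(n: int = 30, spread: float = 3e-3) -> list[float]:
    """Geometric profile from dominant to rare, normalized to 100%."""
    raw = np.geomspace(1.0, spread, n)
    return list(raw / raw.sum() * 100.0)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic mock communities.

    Defaults mirror a ten-community benchmark with about thirty expected
    species per community spanning four orders of magnitude in sequence
    abundance, a handful of false-positive species per sample, and a
    1000M-base sequencing yield on ~4 Mb genomes.
    """

    n_samples: int = 10
    n_true_species: int = 30
    n_false_species: int = 6
    genomes_per_species: int = 3
    templates_per_genome: int = 4
    tp_template_id_location: float = 99.0
    tp_template_id_scale: float = 2.0
    fp_template_id_location: float = 3.0
    fp_template_id_scale: float = 2.5
    fp_outlier_prob: float = 0.08
    abundance_profile: list[float] | None = None  # None -> geometric default
    plasmid_fraction: float = 0.5
    viral_fraction: float = 0.05
    yield_bases: float = 1_000_000_000.0
    genome_length: int = 4_000_000
    mean_read_length: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abundance_profile is None:
            self.abundance_profile = _default_abundance_profile(self.n_true_species)
        if len(self.abundance_profile) != self.n_true_species:
            raise ValueError(
                f"abundance_profile has {len(self.abundance_profile)} entries "
                f"for {self.n_true_species} true species"
            )
        total = sum(self.abundance_profile)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"abundance_profile sums to {total}, expected 100")
        for name in ("tp_template_id_location", "fp_template_id_location"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {value}")


@dataclass
class SimulatedDataset:
    """Hit tables, shared metadata and ground truths for all samples."""

    hits_per_sample: list[list[TemplateHit]]
    metadata: ReferenceMetadata
    truths: list[list[GroundTruthEntry]]
    true_species: list[str]
    false_species: list[str]
    template_lengths: dict[str, int]


def _truncnorm_pct(rng: np.random.Generator, loc: float, scale: float) -> float:
    """One draw from a normal truncated to [0, 100]."""
    a, b = (0.0 - loc) / scale, (100.0 - loc) / scale
    return float(truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng))


def _build_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ReferenceMetadata, dict[str, int], list[str], list[str]]:
    """Reference metadata plus concrete template lengths.

    Each genome is split unevenly into ``templates_per_genome`` replicons;
    ``plasmid_fraction`` of genomes additionally carry a flagged plasmid
    template, and a few phage templates exercise viral removal.
    """
    true_species = [f"Species_tp_{i:03d}" for i in range(config.n_true_species)]
    false_species = [f"Species_fp_{i:03d}" for i in range(config.n_false_species)]
    rows: list[dict] = []
    lengths: dict[str, int] = {}
    for s_idx, species in enumerate(true_species + false_species):
        for g in range(config.genomes_per_species):
            accession = f"GCF_{s_idx:03d}{g:02d}"
            weights = rng.dirichlet(np.full(config.templates_per_genome, 5.0))
            tpl_lengths = np.maximum(
                (weights * config.genome_length).astype(int), 1000
            )
            for t, length in enumerate(tpl_lengths):
                template_id = f"{accession}.tpl{t}"
                lengths[template_id] = int(length)
                rows.append(
                    {
                        "template_id": template_id,
                        "genome_accession": accession,
                        "species_name": species,
                        "taxid": 10_000 + s_idx,
                        "is_plasmid": False,
                        "superkingdom": "bacteria",
                    }
                )
            if rng.random() < config.plasmid_fraction:
                template_id = f"{accession}.plasmid"
                lengths[template_id] = int(rng.integers(2_000, 200_000))
                rows.append(
                    {
                        "template_id": template_id,
                        "genome_accession": accession,
                        "species_name": species,
                        "taxid": 10_000 + s_idx,
                        "is_plasmid": True,
                        "superkingdom": "bacteria",
                    }
                )
    n_viral = max(1, int(config.viral_fraction * config.n_true_species))
    for v in range(n_viral):
        template_id = f"NC_virus_{v:03d}"
        lengths[template_id] = int(rng.integers(5_000, 80_000))
        rows.append(
            {
                "template_id": template_id,
                "genome_accession": f"GCF_virus_{v:03d}",
                "species_name": f"Phage_{v:03d}",
                "taxid": 90_000 + v,
                "is_plasmid": False,
                "superkingdom": "virus",
            }
        )
    return ReferenceMetadata(pd.DataFrame(rows)), lengths, true_species, false_species


def _decompose_identity(
    intended_pct: float, lengths: Sequence[int], rng: np.random.Generator
) -> list[int]:
    """Split a genome-level identity into per-template identical bases so
    that sum(identical) / sum(lengths) reproduces it exactly after integer
    rounding of the total."""
    total_length = int(sum(lengths))
    total_identical = int(round(intended_pct / 100.0 * total_length))
    if total_identical > total_length:
        raise ValueError(
            f"infeasible decomposition: identity {intended_pct}% on total "
            f"length {total_length}"
        )
    shares = [int(np.floor(intended_pct / 100.0 * l)) for l in lengths]
    remainder = total_identical - sum(shares)
    for idx in rng.permutation(len(lengths)):
        if remainder <= 0:
            break
        add = min(lengths[idx] - shares[idx], remainder)
        shares[idx] += add
        remainder -= add
    return shares


def _hits_for_genome(
    accession: str,
    meta: ReferenceMetadata,
    template_lengths: dict[str, int],
    intended_pct: float,
    reads: int,
    rng: np.random.Generator,
) -> list[TemplateHit]:
    """Per-template hits whose regrouped genome-level identity equals
    ``intended_pct``; every template receives at least one mapped read so
    the genome is always detectable at threshold 0."""
    table = meta.table
    templates = sorted(
        table.index[(table["genome_accession"] == accession)
                    & (~table["is_plasmid"])]
    )
    lengths = [template_lengths[t] for t in templates]
    identical = _decompose_identity(intended_pct, lengths, rng)
    extra_reads = rng.multinomial(
        max(reads - len(templates), 0), np.array(lengths) / sum(lengths)
    )
    hits = []
    for t, length, ident, extra in zip(templates, lengths, identical, extra_reads):
        covered = min(length, int(round(ident * (1.0 + 0.02 * rng.random()))))
        covered = max(covered, ident)
        hits.append(
            TemplateHit(
                template_id=t,
                mapped_reads=1 + int(extra),
                template_length=length,
                template_identity_pct=100.0 * ident / length,
                template_coverage_pct=100.0 * covered / length,
                identical_bases=ident,
            )
        )
    return hits


def simulate_hits(config: SimulationConfig) -> SimulatedDataset:
    """Generate hit tables, reference metadata and ground truths.

    True species get genome-level template identities from the high
    distribution scaled by the coverage cap; within a species the first
    genome is dominant and sibling genomes receive attenuated identities,
    so best-genome selection has real work to do.  False species draw from
    the low distribution.  Plasmid evidence rides along with dominant
    genomes and phage hits are sprinkled in, so both non-target removal
    flags are exercised.  Everything is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    meta, template_lengths, true_species, false_species = _build_reference(
        config, rng
    )
    table = meta.table
    genome_accessions = {
        species: sorted(
            table.loc[table["species_name"] == species, "genome_accession"].unique()
        )
        for species in true_species + false_species
    }
    viral_templates = sorted(table.index[table["superkingdom"] == "virus"])

    hits_per_sample: list[list[TemplateHit]] = []
    truths: list[list[GroundTruthEntry]] = []
    for _ in range(config.n_samples):
        sample_hits: list[TemplateHit] = []
        for species, abundance in zip(true_species, config.abundance_profile):
            allocated = config.yield_bases * abundance / 100.0
            cap = min(1.0, allocated / config.genome_length)
            intended = _truncnorm_pct(
                rng, config.tp_template_id_location, config.tp_template_id_scale
            ) * cap
            reads = max(1, int(round(allocated / config.mean_read_length)))
            for g_idx, accession in enumerate(genome_accessions[species]):
                genome_pct = (
                    intended if g_idx == 0
                    else intended * float(rng.uniform(0.4, 0.85))
                )
                genome_reads = (
                    reads if g_idx == 0
                    else max(1, int(reads * rng.uniform(0.05, 0.3)))
                )
                sample_hits.extend(
                    _hits_for_genome(accession, meta, template_lengths,
                                     genome_pct, genome_reads, rng)
                )
                plasmid_id = f"{accession}.plasmid"
                if g_idx == 0 and plasmid_id in meta:
                    plen = template_lengths[plasmid_id]
                    pident = int(round(min(99.0, intended) / 100.0 * plen))
                    sample_hits.append(
                        TemplateHit(
                            template_id=plasmid_id,
                            mapped_reads=max(1, int(reads * 0.02)),
                            template_length=plen,
                            template_identity_pct=100.0 * pident / plen,
                            identical_bases=pident,
                        )
                    )
        for species in false_species:
            base = _truncnorm_pct(
                rng, config.fp_template_id_location, config.fp_template_id_scale
            )
            if rng.random() < config.fp_outlier_prob:
                # the FP upper range creeps up with yield
                upper = 5.0 + 25.0 * min(1.0, config.yield_bases / 2e9)
                base = float(rng.uniform(5.0, upper))
            accession = genome_accessions[species][0]
            sample_hits.extend(
                _hits_for_genome(accession, meta, template_lengths, base,
                                 int(rng.integers(1, 20)), rng)
            )
        for template_id in viral_templates:
            if rng.random() < 0.5:
                vlen = template_lengths[template_id]
                vident = int(round(rng.uniform(1.0, 30.0) / 100.0 * vlen))
                sample_hits.append(
                    TemplateHit(
                        template_id=template_id,
                        mapped_reads=int(rng.integers(1, 10)),
                        template_length=vlen,
                        template_identity_pct=100.0 * vident / vlen,
                        identical_bases=vident,
                    )
                )
        hits_per_sample.append(sample_hits)
        truths.append(
            [
                GroundTruthEntry(species_name=s, sequence_abundance_pct=a)
                for s, a in zip(true_species, config.abundance_profile)
            ]
        )
    return SimulatedDataset(
        hits_per_sample=hits_per_sample,
        metadata=meta,
        truths=truths,
        true_species=list(true_species),
        false_species=list(false_species),
        template_lengths=template_lengths,
    )


@dataclass
class ReadSimProfile:
    """Length/quality profile for synthetic nanopore-like reads."""

    n_reads: int = 1000
    length_mean: int = 5000
    length_sigma: float = 0.5  # lognormal shape
    quality_mean: float = 18.0
    quality_sd: float = 4.0
    short_fraction: float = 0.0  # reads forced to 500 bp
    low_quality_fraction: float = 0.0  # reads forced to Q5


def simulate_reads(config: SimulationConfig,
                   profile: ReadSimProfile) -> list[ReadRecord]:
    """Generate reads whose filter pass rate is predictable in expectation:
    ``short_fraction`` reads fail the length rule and
    ``low_quality_fraction`` of the rest fail the quality rule."""
    rng = np.random.default_rng(config.seed)
    reads = []
    bases = np.array(list("ACGT"))
    for i in range(profile.n_reads):
        short = rng.random() < profile.short_fraction
        low_q = rng.random() < profile.low_quality_fraction
        if short:
            length = 500
        else:
            length = max(
                1001,
                int(rng.lognormal(np.log(profile.length_mean),
                                  profile.length_sigma)),
            )
        if low_q:
            q_target = 5.0
        else:
            q_target = max(10.5, rng.normal(profile.quality_mean,
                                            profile.quality_sd))
        seq = "".join(rng.choice(bases, size=length))
        # constant per-base quality: the error-rate mean equals q_target
        quals = tuple([int(round(q_target))] * length)
        reads.append(ReadRecord(read_id=f"read_{i:06d}", sequence=seq,
                                qualities=quals))
    return reads
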