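import pandas as pd
import pytest

from kaptain.io_formats import ReferenceMetadata, TemplateHit
from kaptain.simulate import SimulationConfig, simulate_hits


def make_metadata(rows):
    """rows: (template_id, genome, species, is_plasmid, superkingdom)."""
    return ReferenceMetadata(
        pd.DataFrame(
            [
                {
                    "template_id": t,
                    "genome_accession": g,
                    "species_name": s,
                    "is_plasmid": p,
                    "superkingdom": k,
                }
                for t, g, s, p, k in rows
            ]
        )
    )


def make_hit(template_id, length=100, identity=50.0, reads=10, coverage=None):
    return TemplateHit(
        template_id=template_id,
        mapped_reads=reads,
        template_length=length,
        template_identity_pct=identity,
        template_coverage_pct=coverage if coverage is not None else min(
            100.0, identity + 1.0
        ),
    )


@pytest.fixture(scope="session")
def simulated_dataset():
    """Default-condition synthetic benchmark (ten communities, 1000M yield)."""
    return simulate_hits(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Quick dataset for plumbing tests."""
    config = SimulationConfig(
        n_samples=3,
        n_true_species=8,
        n_false_species=3,
        genomes_per_species=2,
        templates_per_genome=2,
        abundance_profile=None,
        seed=5,
    )
    return simulate_hits(config)
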