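import numpy as np
import pytest

from kaptain.io_formats import TemplateHit
from kaptain.postprocess import (
    UnknownTemplateError,
    group_by_genome,
    read_calls,
    remove_nontarget,
    select_best_genome,
    standard_abundance,
    template_id_calls,
    write_calls,
)
from tests.conftest import make_hit, make_metadata

META = make_metadata(
    [
        ("c1", "G1", "Escherichia coli", False, "bacteria"),
        ("c2", "G1", "Escherichia coli", False, "bacteria"),
        ("p1", "G1", "Escherichia coli", True, "bacteria"),
        ("c3", "G2", "Escherichia coli", False, "bacteria"),
        ("c4", "G3", "Salmonella enterica", False, "bacteria"),
        ("v1", "V1", "PhiX", False, "virus"),
    ]
)


class TestRemoveNontarget:
    def test_plasmid_hit_removed(self):
        hits = [make_hit("c1"), make_hit("p1"), make_hit("c4")]
        kept = remove_nontarget(hits, META)
        assert [h.template_id for h in kept] == ["c1", "c4"]

    def test_flags_off_is_identity(self):
        hits = [make_hit("c1"), make_hit("p1"), make_hit("v1")]
        assert remove_nontarget(hits, META, drop_plasmids=False,
                                drop_viruses=False) == hits

    def test_matches_brute_force_on_mixed_hits(self):
        rng = np.random.default_rng(3)
        pool = ["c1", "c2", "p1", "c3", "c4", "v1"]
        hits = [make_hit(t, identity=float(rng.uniform(1, 99)))
                for t in rng.choice(pool, size=20)]
        kept = remove_nontarget(hits, META)
        expected = [h for h in hits
                    if not META.is_plasmid(h.template_id)
                    and not META.is_viral(h.template_id)]
        assert kept == expected

    def test_unknown_template_is_error(self):
        with pytest.raises(UnknownTemplateError, match="zz"):
            remove_nontarget([make_hit("zz")], META)


class TestGroupByGenome:
    def test_identity_recomputed_from_sums_not_averaged(self):
        # two 100-base templates at 70% and 90% -> (70+90)/200 = 80%
        hits = [make_hit("c1", length=100, identity=70.0, reads=4),
                make_hit("c2", length=100, identity=90.0, reads=6)]
        (record,) = group_by_genome(hits, META)
        assert record.genome_template_id_pct == pytest.approx(80.0)
        assert record.total_identical_bases == 160
        assert record.total_template_length == 200
        assert record.mapped_reads == 10
        assert record.n_templates == 2

    def test_single_covered_template_diluted_by_sibling(self):
        # only c1 covered at 75/100 identical, c2 uncovered but present in
        # the hit table with zero identity -> 75/200 = 37.5%
        hits = [make_hit("c1", length=100, identity=75.0, coverage=75.0),
                make_hit("c2", length=100, identity=0.0, coverage=0.0)]
        (record,) = group_by_genome(hits, META)
        assert record.genome_template_id_pct == pytest.approx(37.5)

    def test_single_template_genome_keeps_template_metrics(self):
        hits = [make_hit("c4", length=250, identity=40.0, coverage=44.0)]
        (record,) = group_by_genome(hits, META)
        assert record.genome_template_id_pct == pytest.approx(40.0)
        assert record.genome_coverage_pct == pytest.approx(44.0)

    def test_read_conservation_and_exact_ratio(self):
        rng = np.random.default_rng(7)
        hits = [
            make_hit(t, length=int(rng.integers(50, 5000)),
                     identity=float(rng.uniform(0, 95)),
                     reads=int(rng.integers(0, 50)))
            for t in ["c1", "c2", "c3", "c4"]
        ]
        records = group_by_genome(hits, META)
        assert sum(r.mapped_reads for r in records) == \
            sum(h.mapped_reads for h in hits)
        for record in records:
            members = [h for h in hits
                       if META.genome_of(h.template_id) == record.genome_accession]
            assert record.genome_template_id_pct == pytest.approx(
                100.0 * sum(h.identical_bases for h in members)
                / sum(h.template_length for h in members)
            )
            assert record.genome_template_id_pct <= record.genome_coverage_pct

    def test_full_genome_lengths_enlarge_denominator(self):
        hits = [make_hit("c1", length=100, identity=80.0)]
        (record,) = group_by_genome(hits, META, genome_lengths={"G1": 400})
        assert record.total_template_length == 400
        assert record.genome_template_id_pct == pytest.approx(20.0)
        with pytest.raises(ValueError, match="smaller"):
            group_by_genome(hits, META, genome_lengths={"G1": 50})


class TestSelectBestGenome:
    def test_highest_template_id_wins(self):
        hits = [make_hit("c1", identity=80.0), make_hit("c3", identity=60.0),
                make_hit("c4", identity=50.0)]
        calls = select_best_genome(group_by_genome(hits, META))
        by_species = {c.species_name: c for c in calls}
        assert by_species["Escherichia coli"].best_genome == "G1"
        assert by_species["Escherichia coli"].metric_value_pct == pytest.approx(80.0)
        assert by_species["Salmonella enterica"].best_genome == "G3"
        assert len(calls) == 2

    def test_tie_broken_by_reads_then_accession(self):
        tie_reads = [make_hit("c1", identity=60.0, reads=5),
                     make_hit("c3", identity=60.0, reads=9)]
        (call,) = select_best_genome(group_by_genome(tie_reads, META))
        assert call.best_genome == "G2"
        full_tie = [make_hit("c1", identity=60.0, reads=5),
                    make_hit("c3", identity=60.0, reads=5)]
        (call,) = select_best_genome(group_by_genome(full_tie, META))
        assert call.best_genome == "G1"

    def test_matches_brute_force_on_random_genomes(self, small_dataset):
        hits = small_dataset.hits_per_sample[0]
        meta = small_dataset.metadata
        genomes = group_by_genome(remove_nontarget(hits, meta), meta)
        calls = select_best_genome(genomes)
        assert len(calls) == len({g.species_name for g in genomes})
        for call in calls:
            best = max(g.genome_template_id_pct for g in genomes
                       if g.species_name == call.species_name)
            assert call.metric_value_pct == best


class TestStandardAbundance:
    def test_read_ratios(self):
        hits = [make_hit("c1", reads=50), make_hit("p1", reads=25),
                make_hit("c4", reads=25)]
        calls = standard_abundance(hits, META)
        by_species = {c.species_name: c.metric_value_pct for c in calls}
        # plasmid reads are retained in the standard route
        assert by_species["Escherichia coli"] == pytest.approx(75.0)
        assert by_species["Salmonella enterica"] == pytest.approx(25.0)

    def test_viral_reads_removed_before_normalization(self):
        hits = [make_hit("c1", reads=75), make_hit("v1", reads=100)]
        (call,) = standard_abundance(hits, META)
        assert call.species_name == "Escherichia coli"
        assert call.metric_value_pct == pytest.approx(100.0)

    def test_abundances_sum_to_100(self, small_dataset):
        for hits in small_dataset.hits_per_sample:
            calls = standard_abundance(hits, small_dataset.metadata)
            assert sum(c.metric_value_pct for c in calls) == pytest.approx(
                100.0, abs=1e-9
            )

    def test_zero_reads_gives_empty_calls(self, caplog):
        hits = [make_hit("c1", reads=0)]
        with caplog.at_level("WARNING"):
            assert standard_abundance(hits, META) == []


def test_calls_round_trip(tmp_path):
    hits = [make_hit("c1", identity=80.0), make_hit("c4", identity=10.0)]
    calls = template_id_calls(hits, META)
    path = tmp_path / "calls.tsv"
    write_calls(path, calls)
    assert read_calls(path) == calls
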