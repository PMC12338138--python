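import numpy as np
import pytest

from amoalink.classify import ClassifierParams
from amoalink.formats import SequenceRecord, TaxMap, TaxonomyLabel, reverse_complement
from amoalink.pairdb import (
    AMOA,
    SSU,
    MarkerHit,
    PairedDatabase,
    ReferenceRecord,
    assign_clade_to_records,
    build_database,
    dereplicate,
    filter_flagged,
    locate_marker,
    pair_genomes,
    validate_database,
)


def _random_seq(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def gene_pool(sim_db):
    """Real-ish marker genes borrowed from the synthetic reference set."""
    return sim_db.exported


class TestLocateMarker:
    def test_exact_embedded_copy_found_forward(self, gene_pool):
        rng = np.random.default_rng(5)
        gene = gene_pool[0].ssu.seq[:1500] if len(gene_pool[0].ssu.seq) >= 1500 \
            else gene_pool[0].ssu.seq
        genome = SequenceRecord("g", _random_seq(1000, rng) + gene + _random_seq(2600, rng))
        seeds = [SequenceRecord("seed", gene)]
        hits = locate_marker(genome, seeds, SSU, 80.0)
        assert len(hits) == 1
        h = hits[0]
        # oracle: exact substring search
        assert genome.seq.index(gene) == h.start - 1
        assert (h.end, h.strand, h.identity_to_seed) == (h.start - 1 + len(gene), "+", 100.0)

    def test_exact_embedded_copy_found_reverse(self, gene_pool):
        rng = np.random.default_rng(6)
        gene = gene_pool[0].ssu.seq
        genome = SequenceRecord(
            "g", _random_seq(1000, rng) + reverse_complement(gene) + _random_seq(500, rng)
        )
        hits = locate_marker(genome, [SequenceRecord("seed", gene)], SSU, 80.0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (1001, 1000 + len(gene), "-")
        assert h.identity_to_seed == 100.0

    def test_unrelated_genome_gives_no_hit(self, gene_pool):
        rng = np.random.default_rng(7)
        genome = SequenceRecord("g", _random_seq(5000, rng))
        hits = locate_marker(genome, [SequenceRecord("seed", gene_pool[0].ssu.seq)],
                             SSU, 80.0)
        assert hits == []

    def test_empty_seed_set_rejected(self, gene_pool):
        genome = SequenceRecord("g", gene_pool[0].ssu.seq)
        with pytest.raises(ValueError):
            locate_marker(genome, [], SSU)


class TestPairGenomes:
    def _genome_with(self, rng, ssu=None, amoa=None, gid="g"):
        parts = [_random_seq(400, rng)]
        if ssu:
            parts += [ssu, _random_seq(300, rng)]
        if amoa:
            parts += [amoa, _random_seq(300, rng)]
        return SequenceRecord(gid, "".join(parts))

    def test_only_genomes_with_both_markers_pair(self, gene_pool):
        rng = np.random.default_rng(8)
        genomes, hits = [], []
        for i, rec in enumerate(gene_pool[:3]):
            g = self._genome_with(rng, rec.ssu.seq, rec.amoa.seq, gid=f"g{i}")
            genomes.append(g)
            hits += locate_marker(g, [SequenceRecord("s", rec.ssu.seq)], SSU)
            hits += locate_marker(g, [SequenceRecord("a", rec.amoa.seq)], AMOA)
        lonely = self._genome_with(rng, ssu=gene_pool[0].ssu.seq, gid="g_ssu_only")
        genomes.append(lonely)
        hits += locate_marker(lonely, [SequenceRecord("s", gene_pool[0].ssu.seq)], SSU)
        records = pair_genomes(hits, genomes)
        assert [r.ref_id for r in records] == ["g0", "g1", "g2"]
        for r, src in zip(records, gene_pool):
            assert r.ssu.seq == src.ssu.seq
            assert r.amoa.seq == src.amoa.seq

    def test_longest_marker_copy_wins(self):
        hits = [
            MarkerHit("g", SSU, 1, 1500, "+", 99.0, "s"),
            MarkerHit("g", SSU, 2000, 2900, "+", 100.0, "s"),
            MarkerHit("g", AMOA, 3000, 3600, "+", 100.0, "a"),
        ]
        genome = SequenceRecord("g", "ACGT" * 1000)
        records = pair_genomes(hits, [genome])
        assert len(records) == 1
        assert len(records[0].ssu.seq) == 1500

    def test_empty_hits_empty_output(self):
        assert pair_genomes([], [SequenceRecord("g", "ACGT" * 600)]) == []

    def test_out_of_bounds_hit_rejected(self):
        hits = [
            MarkerHit("g", SSU, 1, 900, "+", 100.0, "s"),
            MarkerHit("g", AMOA, 1000, 99999, "+", 100.0, "a"),
        ]
        with pytest.raises(ValueError, match="exceeds"):
            pair_genomes(hits, [SequenceRecord("g", "ACGT" * 600)])


class TestAssignClade:
    def test_identical_amoa_recovers_reference_label(self, sim_db):
        amoa_refs = sim_db.amoa_records()
        taxmap = sim_db.taxmap()
        rec = sim_db.exported[5]
        fresh = ReferenceRecord("new", "new", rec.ssu, rec.amoa)
        out = assign_clade_to_records([fresh], amoa_refs, taxmap)
        assert out[0].taxonomy == taxmap[rec.ref_id]

    def test_divergent_amoa_flagged_unassignable(self, sim_db):
        rng = np.random.default_rng(9)
        junk = SequenceRecord("junk", _random_seq(600, rng))
        fresh = ReferenceRecord("new", "new", sim_db.exported[0].ssu, junk)
        out = assign_clade_to_records([fresh], sim_db.amoa_records(), sim_db.taxmap())
        assert "unassignable" in out[0].flags
        assert not out[0].exportable

    def test_missing_amoa_requires_environmental_flag(self, sim_db):
        rec = ReferenceRecord("env", "env", sim_db.exported[0].ssu, None)
        with pytest.raises(ValueError, match="environmental_16s_only"):
            assign_clade_to_records([rec], sim_db.amoa_records(), sim_db.taxmap())
        rec.flags.add("environmental_16s_only")
        out = assign_clade_to_records([rec], sim_db.amoa_records(), sim_db.taxmap())
        assert out[0].flags == {"environmental_16s_only"}

    def test_mutated_amoa_recovers_generating_clade(self, sim_db):
        from amoalink.simulate import evolve_sequence

        rng = np.random.default_rng(10)
        taxmap = sim_db.taxmap()
        records = []
        for rec in sim_db.exported[::5]:
            evolved = SequenceRecord(
                f"{rec.ref_id}.mut", evolve_sequence(rec.amoa.seq, 0.02, rng)
            )
            records.append(ReferenceRecord(evolved.id, evolved.id, rec.ssu, evolved))
        out = assign_clade_to_records(records, sim_db.amoa_records(), taxmap)
        for rec, src in zip(out, sim_db.exported[::5]):
            assert rec.taxonomy == taxmap[src.ref_id]


def _toy_records(n, clade="NS;NS-gamma"):
    rng = np.random.default_rng(n)
    out = []
    for i in range(n):
        seq = SequenceRecord(f"r{i}", _random_seq(900, rng))
        amoa = SequenceRecord(f"r{i}", _random_seq(450, rng))
        out.append(ReferenceRecord(f"r{i}", f"r{i}", seq, amoa,
                                   TaxonomyLabel.parse(clade)))
    return out


class TestFilterFlagged:
    def test_partition_conserves_records(self):
        records = _toy_records(10)
        kept, removed = filter_flagged(records, ["r2", "r7"])
        assert len(kept) + len(removed) == 10
        assert {r.ref_id for r in removed} == {"r2", "r7"}
        assert all("contaminant" in r.flags for r in removed)

    def test_empty_flag_list_keeps_all(self):
        records = _toy_records(5)
        kept, removed = filter_flagged(records, [])
        assert len(kept) == 5 and removed == []

    def test_absent_flagged_id_warns_not_raises(self, caplog):
        records = _toy_records(3)
        with caplog.at_level("WARNING"):
            kept, removed = filter_flagged(records, ["nope"])
        assert len(kept) == 3 and removed == []
        assert any("nope" in r.message for r in caplog.records)


class TestValidateAndDereplicate:
    def test_undersupported_clade_flagged(self):
        records = _toy_records(2, "NP;NP-delta") + _toy_records(4, "NS;NS-gamma")
        # _toy_records reuses ids; make them unique
        for i, r in enumerate(records):
            r.ref_id = f"u{i}"
        db = PairedDatabase(records)
        report = validate_database(db, min_support=3)
        flagged = {clade for clade, _n, bad in report if bad}
        assert flagged == {"NP-delta"}
        assert db.undersupported_clades(3) == {"NP-delta"}

    def test_all_supported_gives_no_flags(self, sim_db):
        report = validate_database(sim_db, min_support=3)
        assert not any(bad for _c, _n, bad in report)

    def test_empty_database_reports_zero_clades(self, caplog):
        with caplog.at_level("WARNING"):
            report = validate_database(PairedDatabase([]))
        assert report == []

    def test_identical_seq_same_clade_collapses(self):
        a, b = _toy_records(2)
        b.ssu = SequenceRecord(b.ref_id, a.ssu.seq)
        kept, conflicts = dereplicate([a, b])
        assert [r.ref_id for r in kept] == ["r0"]
        assert conflicts == []

    def test_identical_seq_conflicting_clade_kept_and_logged(self):
        a, b = _toy_records(2)
        b.ssu = SequenceRecord(b.ref_id, a.ssu.seq)
        b.taxonomy = TaxonomyLabel.parse("NT;NT-alpha")
        kept, conflicts = dereplicate([a, b])
        assert len(kept) == 2
        assert conflicts == [("r0", "r1")]

    def test_unique_input_unchanged(self):
        records = _toy_records(4)
        kept, conflicts = dereplicate(records)
        assert kept == records and conflicts == []


class TestBuildDatabase:
    def test_end_to_end_three_genome_fixture(self, sim_db):
        rng = np.random.default_rng(12)
        sources = sim_db.exported[:3]  # one clade, so one seed pair suffices
        genomes = []
        for i, rec in enumerate(sources):
            genomes.append(SequenceRecord(
                f"g{i}",
                _random_seq(500, rng) + rec.ssu.seq + _random_seq(200, rng)
                + rec.amoa.seq + _random_seq(200, rng),
            ))
        db, removed = build_database(
            genomes,
            ssu_seeds=[SequenceRecord("sseed", sources[0].ssu.seq)],
            amoa_seeds=[SequenceRecord("aseed", sources[0].amoa.seq)],
            amoa_refs=sim_db.amoa_records(),
            amoa_taxmap=sim_db.taxmap(),
            flag_ids=["g1"],
        )
        assert {r.ref_id for r in db.exported} == {"g0", "g2"}
        assert [r.ref_id for r in removed] == ["g1"]
        # export ids and taxonomy-map ids form a bijection
        assert {r.id for r in db.ssu_records()} == set(db.taxmap())
        # clade labels follow the generating references
        taxmap = sim_db.taxmap()
        for rec in db.exported:
            i = int(rec.ref_id[1])
            assert rec.taxonomy == taxmap[sources[i].ref_id]

    def test_pipeline_count_consistency(self, sim_db):
        """identified pairs - removals + manual additions == exported size."""
        rng = np.random.default_rng(13)
        sources = sim_db.exported[:4]
        genomes = [
            SequenceRecord(
                f"g{i}",
                _random_seq(300, rng) + rec.ssu.seq + _random_seq(150, rng)
                + rec.amoa.seq + _random_seq(150, rng),
            )
            for i, rec in enumerate(sources)
        ]
        extra = ReferenceRecord(
            "env1", "env1", sim_db.exported[20].ssu, None,
            taxonomy=sim_db.exported[20].taxonomy,
            flags={"environmental_16s_only"},
        )
        db, removed = build_database(
            genomes,
            ssu_seeds=[SequenceRecord("sseed", sources[0].ssu.seq)],
            amoa_seeds=[SequenceRecord("aseed", sources[0].amoa.seq)],
            amoa_refs=sim_db.amoa_records(),
            amoa_taxmap=sim_db.taxmap(),
            flag_ids=["g2"],
            external_records=[extra],
        )
        n_identified = 4
        assert len(db.exported) == n_identified - len(removed) + 1
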