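"""Generator properties: determinism, truth-table closure, planted dosage."""

import numpy as np
import pytest

from telscope.simulate import (
    CirclePlan,
    InsertionPlan,
    InsertionSite,
    SeqParams,
    build_reference,
    default_circle_plan,
    plant_insertions,
    random_insertion_plan,
    revcomp,
    simulate_eccdna,
    simulate_wgs,
)


class TestBuildReference:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        d1 = build_reference(200_000, 1, 3, 10, seed=7).save(tmp_path / "a")
        d2 = build_reference(200_000, 1, 3, 10, seed=7).save(tmp_path / "b")
        for name in ("genome.fa", "te_library.fa", "ige.fa", "plasmids.fa", "ige.bed"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_ige_bed_has_requested_records(self, tmp_path, bundle):
        out = bundle.save(tmp_path / "ref")
        assert len((out / "ige.bed").read_text().splitlines()) == 20

    def test_each_family_has_a_genomic_copy(self, bundle):
        families = {fam for _c, _s, _e, fam in bundle.te_annotation}
        assert families == set(bundle.te_library)
        for chrom, start, end, fam in bundle.te_annotation:
            assert bundle.genome[chrom][start:end] == bundle.te_library[fam]

    def test_degenerate_genome_size_rejected(self):
        with pytest.raises(ValueError):
            build_reference(genome_length=50)

    def test_roundtrip_through_disk(self, tmp_path, bundle):
        from telscope.simulate import ReferenceBundle

        out = bundle.save(tmp_path / "rt")
        loaded = ReferenceBundle.load(out)
        assert loaded.genome == bundle.genome
        assert loaded.te_library == bundle.te_library
        assert loaded.te_annotation == bundle.te_annotation
        assert {p.name: p.role for p in loaded.plasmids.values()} == {
            p.name: p.role for p in bundle.plasmids.values()
        }


class TestPlantInsertions:
    def test_full_penetrance_reaches_every_haplotype(self, bundle):
        plan = random_insertion_plan(bundle, 5, 1.0, seed=1)
        sample = plant_insertions(bundle, plan, 10, seed=2)
        assert all(len(c) == 20 for c in sample.carriers)

    def test_rare_penetrance_rounds_to_single_carrier(self, bundle):
        plan = random_insertion_plan(bundle, 5, 0.05, seed=1)
        sample = plant_insertions(bundle, plan, 10, seed=2)
        assert all(len(c) == 1 for c in sample.carriers)
        assert np.allclose(sample.truth_table()["carrier_frequency"], 0.05)

    def test_too_close_entries_rejected(self, bundle):
        plan = InsertionPlan(
            [
                InsertionSite("chr1", 50_000, "TE1"),
                InsertionSite("chr1", 50_050, "TE2"),
            ],
            min_spacing=150,
        )
        with pytest.raises(ValueError, match="min_spacing"):
            plant_insertions(bundle, plan, 10)

    def test_haplotype_carries_spliced_consensus(self, bundle):
        site = InsertionSite("chr1", 50_000, "TE1", orientation="-")
        sample = plant_insertions(bundle, InsertionPlan([site]), 1, seed=3)
        hap = sample.haplotype(0)["chr1"]
        te = revcomp(bundle.te_library["TE1"])
        assert hap[50_000 : 50_000 + len(te)] == te
        assert len(hap) == len(bundle.genome["chr1"]) + len(te)


class TestSimulateWgs:
    def test_pair_count_matches_depth_arithmetic(self, wgs_reads):
        # depth * L / (2 * read_length) at 20X over 200 kb with 75 bp reads
        expected = 20 * 200_000 / (2 * 75)
        assert abs(len(wgs_reads) - expected) <= 0.01 * expected

    def test_error_free_reads_substring_of_source_haplotype(self, penetrant_sample, wgs_reads):
        for i in range(0, len(wgs_reads), 997):
            parts = wgs_reads.names[i].split(":")
            hap = penetrant_sample.haplotype(int(parts[1][1:]))[parts[2]]
            start, ilen = int(parts[3]), int(parts[4])
            frag = hap[start : start + ilen]
            assert wgs_reads.r1[i] == frag[:75]
            assert wgs_reads.r2[i] == revcomp(frag[-75:])

    def test_fixed_seed_reproduces_fastq_bytes(self, penetrant_sample, tmp_path):
        params = SeqParams(depth=2.0, seed=99)
        for d in ("x", "y"):
            simulate_wgs(penetrant_sample, params, out_dir=tmp_path / d)
        assert (tmp_path / "x/reads_1.fastq").read_bytes() == (tmp_path / "y/reads_1.fastq").read_bytes()
        assert (tmp_path / "x/reads_2.fastq").read_bytes() == (tmp_path / "y/reads_2.fastq").read_bytes()

    def test_chimeric_fraction_of_pairs(self, penetrant_sample):
        reads, _ = simulate_wgs(penetrant_sample, SeqParams(depth=5.0, seed=3, chimera_rate=0.02))
        n_chim = sum(":chim" in name for name in reads.names)
        assert n_chim == round(0.02 * len(reads))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SeqParams(read_length=20)
        with pytest.raises(ValueError):
            SeqParams(depth=0)
        with pytest.raises(ValueError):
            SeqParams(error_rate=1.5)


class TestSimulateEccdna:
    def test_junction_wrap_fraction_matches_binomial_oracle(self, bundle):
        # single 5 kb circle: P(read crosses the origin) = (rl - 1) / L per read
        plan = CirclePlan([("TE1", 50.0)], n_read_pairs=30_000)
        reads, _ = simulate_eccdna(bundle, plan, SeqParams(read_length=36, seed=5, insert_mean=300, insert_sd=30, depth=1))
        L = len(bundle.te_library["TE1"])
        rl = 36
        n_reads = 2 * len(reads)
        crossing = 0
        for name, r1 in zip(reads.names, reads.r1):
            start = int(name.split(":")[3])
            crossing += start > L - rl
        # r2 start is also uniform; check r1 only against the per-read probability
        p = (rl - 1) / L
        mean, sd = len(reads) * p, np.sqrt(len(reads) * p * (1 - p))
        assert abs(crossing - mean) <= 3 * sd

    def test_no_background_means_no_linear_reads(self, bundle):
        plan = default_circle_plan(bundle, n_read_pairs=2000, linear_background_rate=0.0)
        reads, _ = simulate_eccdna(bundle, plan, SeqParams(read_length=36, seed=6, depth=1))
        assert not any(":lin:" in n for n in reads.names)

    def test_read_share_proportional_to_copies_times_length(self, bundle):
        plan = CirclePlan([("TE1", 40.0), ("TE2", 20.0)], n_read_pairs=40_000)
        _, truth = simulate_eccdna(bundle, plan, SeqParams(read_length=36, seed=7, depth=1))
        drawn = dict(zip(truth["source"], truth["pairs_drawn"]))
        ratio = drawn["TE1"] / drawn["TE2"]  # equal lengths, so copies ratio = 2
        assert 1.9 <= ratio <= 2.1

    def test_doubling_copies_doubles_raw_count_between_samples(self, bundle):
        params = SeqParams(read_length=36, seed=8, depth=1)
        base = CirclePlan([("TE1", 30.0), ("TE2", 30.0)], n_read_pairs=30_000)
        doubled = CirclePlan([("TE1", 60.0), ("TE2", 30.0)], n_read_pairs=30_000)
        _, t1 = simulate_eccdna(bundle, base, params)
        _, t2 = simulate_eccdna(bundle, doubled, SeqParams(read_length=36, seed=9, depth=1))
        share1 = dict(zip(t1["source"], t1["pairs_drawn"]))
        share2 = dict(zip(t2["source"], t2["pairs_drawn"]))
        # TE1:TE2 odds double when TE1 copies double
        odds1 = share1["TE1"] / share1["TE2"]
        odds2 = share2["TE1"] / share2["TE2"]
        assert 1.85 <= odds2 / odds1 <= 2.15

    def test_all_zero_plan_rejected(self, bundle):
        with pytest.raises(ValueError):
            CirclePlan([("TE1", 0.0)]).validate(bundle)
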