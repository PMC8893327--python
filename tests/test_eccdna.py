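"""eccDNA quantitation: junction counting, spike-in normalization, QC."""

import numpy as np
import pandas as pd
import pytest

from telscope.eccdna import (
    EccQuantResult,
    eccdna_aging_ratio,
    quantify_eccdna,
    spikein_normalize,
    spikein_qc,
)
from telscope.simulate import (
    PRE_EXTRACTION_REFERENCE,
    ReadPairs,
    SeqParams,
    default_circle_plan,
    simulate_eccdna,
)

RL = 36
N_PAIRS = 40_000


def _library(bundle, seed, te_copies=30.0, plasmid_scale=55.0, **plan_kwargs):
    plan = default_circle_plan(
        bundle, te_copies=te_copies, plasmid_scale=plasmid_scale,
        n_read_pairs=N_PAIRS, **plan_kwargs,
    )
    reads, _ = simulate_eccdna(
        bundle, plan,
        SeqParams(read_length=RL, insert_mean=300.0, insert_sd=30.0, depth=1.0, seed=seed),
    )
    return reads


@pytest.fixture(scope="module")
def ecc_young(bundle):
    return quantify_eccdna(_library(bundle, seed=101), bundle)


@pytest.fixture(scope="module")
def ecc_aged(bundle):
    # TE1 circles doubled, spike-ins unchanged
    return quantify_eccdna(
        _library(bundle, seed=102, te_copies={"TE1": 60.0, "TE2": 30.0, "TE3": 30.0}),
        bundle,
    )


@pytest.fixture(scope="module")
def ecc_overspiked(bundle):
    # same TE composition as aged, but all plasmids spiked at twice the mass
    return quantify_eccdna(
        _library(bundle, seed=103, te_copies={"TE1": 60.0, "TE2": 30.0, "TE3": 30.0},
                 plasmid_scale=110.0),
        bundle,
    )


class TestSpikeinNormalize:
    def test_formula(self):
        assert spikein_normalize(500, 10**6, 10) == pytest.approx(50.0)

    def test_zero_reads_give_zero(self):
        assert spikein_normalize(0, 10**6, 10) == 0.0

    def test_doubling_library_total_halves_v(self):
        assert spikein_normalize(500, 2 * 10**6, 10) == pytest.approx(
            spikein_normalize(500, 10**6, 10) / 2
        )

    def test_invalid_denominators_rejected(self):
        with pytest.raises(ValueError):
            spikein_normalize(1, 0, 10)
        with pytest.raises(ValueError):
            spikein_normalize(1, 10, 0)


class TestCircleCounting:
    def test_junction_fraction_matches_wrap_probability(self, ecc_young, bundle):
        # P(junction read | family read) = (rl - 2m + 1) / L for m=10 overhang
        for fam, row in ecc_young.families.iterrows():
            L = len(bundle.te_library[fam])
            p = (RL - 2 * 10 + 1) / L
            mean, sd = row["x"] * p, np.sqrt(row["x"] * p * (1 - p))
            assert abs(row["j"] - mean) <= 3 * sd

    def test_junction_never_exceeds_total(self, ecc_young):
        assert (ecc_young.families["j"] <= ecc_young.families["x"]).all()

    def test_fully_digested_library_has_zero_ige_reads(self, ecc_young):
        assert ecc_young.ige_reads == 0
        assert ecc_young.genome_reads == 0

    def test_linear_background_reaches_ige_tally(self, bundle):
        res = quantify_eccdna(
            _library(bundle, seed=104, linear_background_rate=0.2), bundle
        )
        assert res.genome_reads > 0
        assert res.ige_reads > 0  # 20 IGEs cover a noticeable genome share

    def test_every_read_is_assigned(self, ecc_young):
        fam = ecc_young.families["x"].sum()
        spike = ecc_young.spikeins["site_normalized"].sum()
        assert ecc_young.total_aligned == 2 * N_PAIRS
        assert fam + spike + ecc_young.genome_reads == pytest.approx(ecc_young.total_aligned)

    def test_short_reads_disable_junction_detection(self, bundle):
        plan = default_circle_plan(bundle, n_read_pairs=50)
        reads, _ = simulate_eccdna(bundle, plan, SeqParams(read_length=30, seed=9, depth=1))
        with pytest.warns(UserWarning, match="junction detection disabled"):
            res = quantify_eccdna(reads, bundle, m=16)
        assert (res.families["j"] == 0).all()


class TestSpikeinCounting:
    def test_backbone_read_split_across_sharing_plasmids(self, bundle):
        backbone_read = bundle.plasmids["pUC19"].seq[:RL]
        reads = ReadPairs(["p0:test"], [backbone_read], [backbone_read])
        res = quantify_eccdna(reads, bundle)
        post = res.spikeins[res.spikeins["role"] == "post_extraction"]
        pre = res.spikeins[res.spikeins["role"] == "pre_extraction"]
        # the cocktail backbone is shared by the 4 post-extraction plasmids only
        assert np.allclose(post["site_normalized"], 2 / len(post))
        assert (post["raw_reads"] == 2).all()
        assert (pre["site_normalized"] == 0).all()

    def test_insert_read_unique_to_one_plasmid(self, bundle):
        insert_read = bundle.plasmids["pUC19"].seq[900 : 900 + RL]
        reads = ReadPairs(["p0:test"], [insert_read], [insert_read])
        res = quantify_eccdna(reads, bundle)
        assert res.spikeins.loc["pUC19", "site_normalized"] == pytest.approx(2.0)
        others = res.spikeins.drop("pUC19")
        assert (others["site_normalized"] == 0).all()

    def test_site_normalized_counts_track_planted_mass(self, ecc_young, bundle):
        # unique-insert contributions scale with copies * length ~ mass;
        # compare the two most abundant post-extraction plasmids
        s = ecc_young.spikeins
        ratio = s.loc["pUC19", "site_normalized"] / s.loc["pMaxGFP", "site_normalized"]
        # planted mass ratio is 10; backbone sharing compresses it, so only
        # require strong ordering consistent with abundance
        assert ratio > 3

    def test_no_spikein_reads_withholds_z(self, bundle, penetrant_sample):
        from telscope.simulate import CirclePlan

        plan = CirclePlan([("TE1", 10.0)], n_read_pairs=200)
        reads, _ = simulate_eccdna(bundle, plan, SeqParams(read_length=36, seed=10, depth=1))
        with pytest.warns(UserWarning, match="withheld"):
            res = quantify_eccdna(reads, bundle)
        assert res.z is None
        assert res.families["v"].isna().all()
        assert (res.families["rpm"] >= 0).all()  # rpm still reported


class TestAgingRatios:
    def test_identical_samples_give_unit_ratios_in_every_mode(self, ecc_young):
        for mode in ("rpm", "spikein", "preextraction_plasmid"):
            table = eccdna_aging_ratio(ecc_young, ecc_young, mode)
            assert np.allclose(table["ratio"].dropna(), 1.0)

    def test_doubled_family_recovered_by_spikein_mode(self, ecc_aged, ecc_young):
        table = eccdna_aging_ratio(ecc_aged, ecc_young, "spikein")
        assert 1.8 <= table.loc["TE1", "ratio_spikein"] <= 2.2
        assert table.loc["TE1", "x_aged"] >= 10_000

    def test_overspiking_shifts_spikein_but_not_rpm_mode(self, ecc_overspiked, ecc_aged):
        table = eccdna_aging_ratio(ecc_overspiked, ecc_aged, "spikein")
        # same TE composition: rpm ratios stay near 1, spike-in ratios halve
        assert table["ratio_rpm"].dropna().mean() == pytest.approx(1.0, abs=0.1)
        assert table["ratio_spikein"].dropna().mean() == pytest.approx(0.5, abs=0.1)

    def test_rpm_and_spikein_modes_agree_when_z_equal(self):
        fams = pd.DataFrame(
            {"x": [100, 50], "j": [1, 1], "rpm": [1000.0, 500.0], "v": [100.0, 50.0]},
            index=pd.Index(["TE1", "TE2"], name="family"),
        )
        spikes = pd.DataFrame(
            {"role": ["post_extraction"], "raw_reads": [10], "mean_sites": [1.0],
             "site_normalized": [10.0], "rpm": [100.0]},
            index=pd.Index([PRE_EXTRACTION_REFERENCE], name="plasmid"),
        )
        a = EccQuantResult(fams, spikes, 10**5, 10.0, 0, 0)
        b = EccQuantResult(fams * 2, spikes, 10**5, 10.0, 0, 0)
        table = eccdna_aging_ratio(b, a, "spikein")
        assert np.allclose(table["ratio_spikein"], table["ratio_rpm"])

    def test_missing_family_universe_rejected(self, ecc_young):
        trimmed = EccQuantResult(
            ecc_young.families.iloc[:-1], ecc_young.spikeins,
            ecc_young.total_aligned, ecc_young.z, 0, 0,
        )
        with pytest.raises(ValueError):
            eccdna_aging_ratio(ecc_young, trimmed)


def test_external_circle_score_filter(ecc_young):
    from telscope.eccdna import filter_by_circle_score

    scores = pd.DataFrame({"family": ["TE1", "TE2", "TE3"], "circle_score": [80.0, 49.0, 60.0]})
    kept = filter_by_circle_score(ecc_young.families, scores, min_score=50.0)
    assert list(kept.index) == ["TE1", "TE3"]
    with pytest.raises(ValueError):
        filter_by_circle_score(ecc_young.families, scores.rename(columns={"family": "f"}))


class TestSpikeinQC:
    def test_identically_prepared_samples_have_low_cv(self, ecc_young, ecc_aged):
        qc = spikein_qc({"young": ecc_young, "aged": ecc_aged})
        abundant = ["pUC19", "pMaxGFP"]
        assert (qc.cv[abundant] < 0.15).all()
        assert not qc.flagged[abundant].any().any()
        assert not any(qc.failed.values())

    def test_extraction_loss_sample_flagged(self, bundle, ecc_young, ecc_aged):
        lossy = quantify_eccdna(
            _library(bundle, seed=105, extraction_loss=0.1), bundle
        )
        qc = spikein_qc({"a": ecc_young, "b": ecc_aged, "lossy": lossy})
        # pre-extraction reference depleted 10x -> post/pre ratio ~10x high
        ratio_shift = qc.ratios.loc["lossy"] / qc.ratios.loc[["a", "b"]].median()
        assert (ratio_shift > 5).all()
        assert qc.flagged.loc["lossy"].all()

    def test_subsampled_library_keeps_v_stable(self, bundle, ecc_young):
        reads = _library(bundle, seed=101)
        rng = np.random.default_rng(0)
        half = reads.subset(rng.random(len(reads)) < 0.5)
        res_half = quantify_eccdna(half, bundle)
        v_full = ecc_young.families["v"]
        v_half = res_half.families["v"]
        assert np.allclose(v_half, v_full, rtol=0.05)
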