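"""Simulator contracts: conservation, determinism, the exponential-growth
oracle, read-sampling behaviour, evidence generation, fluctuation assay."""

import math

import numpy as np
import pandas as pd
import pytest

from serialevo import popsim


class TestSerialTransfer:
    def test_frequencies_sum_to_one_at_every_timepoint(self):
        cfg = popsim.SimConfig(n_test_barcodes=40, n_transfers=3, seed=5,
                               bottleneck_size=100_000)
        _, traj = popsim.simulate_serial_transfer(cfg)
        sums = traj.true_frequencies.groupby(["replicate", "timepoint"])["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_no_selection_no_sampling_is_static(self, two_lineage_config):
        lins = [
            popsim.TrueLineage("n", "n", 0.0, is_neutral_reference=True),
            popsim.TrueLineage("b", "b", 0.0),
        ]
        _, traj = popsim.simulate_serial_transfer(two_lineage_config, lins)
        m = traj.frequency_matrix(0)
        assert np.allclose(m.to_numpy(), m.to_numpy()[:, [0]])

    def test_deterministic_growth_matches_closed_form(self, two_lineage_config):
        # fit/neutral frequency ratio multiplies by exp(s*g) per transfer
        lins = [
            popsim.TrueLineage("n", "n", 0.0, is_neutral_reference=True),
            popsim.TrueLineage("b", "b", 0.05),
        ]
        _, traj = popsim.simulate_serial_transfer(two_lineage_config, lins)
        m = traj.frequency_matrix(0)
        ratio = (m.loc["b"] / m.loc["n"]).to_numpy()
        np.testing.assert_allclose(ratio[1:] / ratio[:-1], math.exp(0.05 * 8.0), rtol=1e-12)

    def test_log_ratio_linear_in_time_without_sampling(self):
        cfg = popsim.SimConfig(n_neutral_barcodes=2, n_test_barcodes=3,
                               deterministic=True, n_replicates=1,
                               bottleneck_size=1000, seed=0)
        lins = popsim.build_remeasurement_pool(cfg, s_values=[0.02, 0.04, -0.03])
        _, traj = popsim.simulate_serial_transfer(cfg, lins)
        m = traj.frequency_matrix(0)
        neutral = m.loc[["neutral_000", "neutral_001"]].sum()
        for ln in lins:
            if ln.is_neutral_reference:
                continue
            slope = np.diff(np.log(m.loc[ln.barcode] / neutral))
            np.testing.assert_allclose(slope, ln.true_s * 8.0, atol=1e-10)

    def test_default_config_mirrors_remeasurement_design(self):
        cfg = popsim.SimConfig()
        assert cfg.n_neutral_barcodes == 48
        assert cfg.unbarcoded_fraction == 0.9
        assert cfg.n_transfers == 4
        assert cfg.n_replicates == 3

    def test_identical_seed_bit_identical_output(self):
        cfg = popsim.SimConfig(n_test_barcodes=30, seed=9, bottleneck_size=50_000)
        _, a = popsim.simulate_serial_transfer(cfg)
        _, b = popsim.simulate_serial_transfer(cfg)
        pd.testing.assert_frame_equal(a.true_frequencies, b.true_frequencies)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(unbarcoded_fraction=1.0),
            dict(generations_per_transfer=0),
            dict(bottleneck_size=10, n_test_barcodes=345),
            dict(read_depth=-1),
            dict(mode="chaos"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            popsim.SimConfig(**kwargs)


class TestReadSampling:
    def _tiny_traj(self):
        cfg = popsim.SimConfig(n_neutral_barcodes=1, n_test_barcodes=2,
                               n_replicates=1, n_transfers=1,
                               bottleneck_size=1000, deterministic=True, seed=0)
        return popsim.simulate_serial_transfer(cfg)[1]

    def test_depth_zero_gives_all_zero(self):
        counts = popsim.sample_barcode_reads(self._tiny_traj(), 0, seed=1)
        assert (counts["count"] == 0).all()

    def test_unbarcoded_ancestor_invisible_and_depth_conserved(self):
        traj = self._tiny_traj()
        counts = popsim.sample_barcode_reads(traj, 1000, seed=1)
        assert popsim.UNBARCODED not in set(counts["barcode"])
        assert (counts.groupby(["replicate", "timepoint"])["count"].sum() == 1000).all()

    def test_single_lineage_takes_all_reads(self):
        freq = pd.DataFrame(
            {"barcode": ["only"], "replicate": [0], "timepoint": [0], "frequency": [1.0]}
        )
        counts = popsim.sample_barcode_reads(popsim.TrajectorySet(freq), 1000, seed=3)
        assert counts["count"].tolist() == [1000]

    def test_deep_sampling_within_three_standard_errors(self):
        p = np.array([0.2, 0.3, 0.5])
        freq = pd.DataFrame(
            {
                "barcode": ["a", "b", "c"],
                "replicate": 0,
                "timepoint": 0,
                "frequency": p,
            }
        )
        depth = 10_000_000
        counts = popsim.sample_barcode_reads(popsim.TrajectorySet(freq), depth, seed=8)
        phat = counts["count"].to_numpy() / depth
        se = np.sqrt(p * (1 - p) / depth)
        assert (np.abs(phat - p) <= 3 * se).all()

    def test_same_seed_same_counts(self):
        traj = self._tiny_traj()
        a = popsim.sample_barcode_reads(traj, 5000, seed=2)
        b = popsim.sample_barcode_reads(traj, 5000, seed=2)
        pd.testing.assert_frame_equal(a, b)


class TestEvolvedCohort:
    def test_planted_loci_have_requested_recurrence(self, rng):
        cfg = popsim.SimConfig(n_test_barcodes=100, seed=1)
        loci = {"GATX": 3, "PARX": 5}
        _, muts = popsim.simulate_evolved_cohort(cfg, adaptive_loci=loci, rng=rng)
        adaptive = muts[muts["adaptive"]]
        assert adaptive.groupby("locus")["barcode"].nunique().to_dict() == loci

    def test_adaptive_effects_in_configured_range(self, rng):
        cfg = popsim.SimConfig(n_test_barcodes=100, seed=1)
        lins, muts = popsim.simulate_evolved_cohort(
            cfg, adaptive_loci={"A": 4}, effect_range=(0.03, 0.08), rng=rng
        )
        carriers = set(muts.loc[muts["adaptive"], "barcode"])
        for ln in lins:
            if ln.barcode in carriers:
                assert 0.03 <= ln.true_s <= 0.08
            elif not ln.is_neutral_reference:
                assert ln.true_s == 0.0

    def test_evolution_mode_spawns_sublineages_with_parent_barcode(self):
        spec = popsim.MutationClassSpec("missense", rate=0.5, effect_range=(0.05, 0.05),
                                        loci=("LOC1",))
        cfg = popsim.SimConfig(n_neutral_barcodes=2, n_test_barcodes=5, n_replicates=1,
                               mode="evolution", mutation_classes=(spec,),
                               bottleneck_size=100_000, seed=6)
        lins, traj = popsim.simulate_serial_transfer(cfg)
        children = [ln for ln in lins if ".m" in ln.clone_id]
        assert children, "high spawn rate should create mutant sub-lineages"
        barcodes = {ln.barcode for ln in lins if ".m" not in ln.clone_id}
        assert all(ch.barcode in barcodes for ch in children)
        # effects accumulate: each sub-lineage carries +0.05 per mutation
        for ch in children:
            assert ch.true_s == pytest.approx(0.05 * len(ch.mutations))
            assert len(ch.mutations) >= 1


class TestBreakpointEvidence:
    def test_clean_evidence_is_exact_ltr_substring(self, ltr_library, rng):
        ins = popsim.plant_ty_insertions(30, rng)
        ev = popsim.generate_breakpoint_evidence(ins, ltr_library, 0.0, 0.0, seed=1)
        from Bio.Seq import reverse_complement

        for rec in ev.itertuples(index=False):
            seq = rec.unaligned_sequence
            if rec.true_strand == "-":
                seq = reverse_complement(seq)
            assert seq in ltr_library[rec.true_family]
            assert len(seq) >= 25

    def test_mapped_fraction_respects_ploidy_caps(self, ltr_library, rng):
        ins = popsim.plant_ty_insertions(50, rng, diploid_fraction=0.5)
        ev = popsim.generate_breakpoint_evidence(ins, ltr_library, 0.0, 0.0, seed=2)
        caps = ev["ploidy"].map({"haploid": 0.15, "diploid": 0.70})
        assert (ev["mapped_perfectly_fraction"] <= caps).all()

    def test_decoys_labelled_should_reject(self, ltr_library, rng):
        ins = popsim.plant_ty_insertions(20, rng)
        ev = popsim.generate_breakpoint_evidence(ins, ltr_library, 0.0, 0.5, seed=3)
        decoys = ev[ev["is_decoy"]]
        assert len(decoys) == 10
        assert (~decoys["should_retain"]).all()

    def test_error_rate_out_of_range_rejected(self, ltr_library, rng):
        ins = popsim.plant_ty_insertions(2, rng)
        with pytest.raises(ValueError):
            popsim.generate_breakpoint_evidence(ins, ltr_library, 0.7, 0.0, seed=1)


class TestFluctuationAssay:
    def test_zero_rate_zero_colonies(self):
        counts = popsim.simulate_fluctuation_assay(0.0, 16, 1_024_000, 1000, seed=1)
        assert len(counts) == 16
        assert (counts == 0).all()

    def test_zero_mutant_fraction_matches_analytic_p0(self):
        rate, final, inoc, n = 1e-7, 10_000_000, 1000, 10_000
        counts = popsim.simulate_fluctuation_assay(rate, n, final, inoc, seed=5)
        m = rate * (final - inoc)
        p0 = math.exp(-m)
        se = math.sqrt(p0 * (1 - p0) / n)
        assert abs((counts == 0).mean() - p0) <= 3 * se

    def test_jackpot_overdispersion(self):
        counts = popsim.simulate_fluctuation_assay(1e-6, 1000, 1_024_000, 1000, seed=9)
        assert counts.var() > counts.mean()

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            popsim.simulate_fluctuation_assay(1.5, 16, 1_024_000, 1000)


class TestIO:
    def test_count_table_round_trip(self, tmp_path):
        cfg = popsim.SimConfig(n_neutral_barcodes=1, n_test_barcodes=2, n_replicates=1,
                               n_transfers=1, bottleneck_size=1000, seed=0)
        _, traj = popsim.simulate_serial_transfer(cfg)
        counts = popsim.sample_barcode_reads(traj, 1000, seed=1)
        path = tmp_path / "counts.tsv"
        popsim.write_count_table(counts, path)
        back = popsim.read_count_table(path)
        pd.testing.assert_frame_equal(back, counts)

    def test_ltr_library_round_trip(self, ltr_library, tmp_path):
        path = tmp_path / "ltr.fa"
        popsim.write_ltr_library(ltr_library, path)
        assert popsim.read_ltr_library(path) == ltr_library
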