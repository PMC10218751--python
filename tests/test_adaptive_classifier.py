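"""Locus classification: recurrence counting, the three-criterion rule,
label exclusivity, threshold monotonicity and cohort accounting."""

import numpy as np
import pandas as pd
import pytest

from serialevo import adaptive_classifier as ac


def fitness_table(values: dict[str, float], sd: float = 0.003) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": list(values),
            "s_mean": list(values.values()),
            "s_sd": sd,
            "n_replicates": 3,
            "detectable": [v > 0.01 for v in values.values()],
        }
    )


def mutation_rows(locus, barcodes, cls="missense", start_pos=1):
    return [
        {"clone_id": b, "barcode": b, "locus": locus, "class": cls, "position": start_pos + i}
        for i, b in enumerate(barcodes)
    ]


class TestSummarize:
    def test_recurrence_counts_distinct_barcodes_not_events(self):
        muts = pd.DataFrame(
            mutation_rows("LOC", ["b1"], start_pos=1) + mutation_rows("LOC", ["b1"], start_pos=50)
        )
        fit = {"nitrogen": fitness_table({"b1": 0.05})}
        out = ac.summarize_by_locus(muts, fit)
        assert out["n_unique_lineages"].item() == 1
        assert out["n_alleles"].item() == 2

    def test_five_independent_lineages(self):
        barcodes = [f"b{i}" for i in range(5)]
        muts = pd.DataFrame(mutation_rows("X", barcodes))
        fit = {"nitrogen": fitness_table({b: 0.05 for b in barcodes})}
        assert ac.summarize_by_locus(muts, fit)["n_unique_lineages"].item() == 5

    def test_duplicate_event_deduplicated(self):
        rows = mutation_rows("X", ["b1"])
        muts = pd.DataFrame(rows + rows)
        fit = {"nitrogen": fitness_table({"b1": 0.05})}
        assert ac.summarize_by_locus(muts, fit)["n_alleles"].item() == 1

    def test_unknown_barcode_raises_with_name(self):
        muts = pd.DataFrame(mutation_rows("X", ["ghost"]))
        fit = {"nitrogen": fitness_table({"b1": 0.05})}
        with pytest.raises(ValueError, match="ghost"):
            ac.summarize_by_locus(muts, fit)

    def test_many_lineage_locus_reproducible(self):
        # a heavily recurrent locus with consistent ~0.06 gains across lineages
        barcodes = [f"g{i}" for i in range(73)]
        muts = pd.DataFrame(mutation_rows("GAT1", barcodes))
        fit = {"nitrogen": fitness_table({b: 0.06 for b in barcodes}, sd=0.004)}
        out = ac.summarize_by_locus(muts, fit)
        assert out["reproducible_fitness"].item()
        assert out["median_s_nitrogen"].item() == pytest.approx(0.06)


class TestClassify:
    def _classify(self, s_n, s_g, n_lineages=None):
        n_lineages = n_lineages or len(s_n)
        barcodes = [f"b{i}" for i in range(n_lineages)]
        muts = pd.DataFrame(mutation_rows("LOC", barcodes))
        fit = {
            "nitrogen": fitness_table(dict(zip(barcodes, s_n))),
            "glucose": fitness_table(dict(zip(barcodes, s_g))),
        }
        summ = ac.summarize_by_locus(muts, fit)
        return ac.classify_loci(summ)["label"].item()

    def test_single_lineage_never_nitrogen_adaptive(self):
        assert self._classify([0.07], [0.0]) == "neutral"

    def test_two_lineage_condition_specific_locus_is_nitrogen_adaptive(self):
        # two independent hits, 0.04-0.07 in nitrogen, ~0 in glucose
        assert self._classify([0.04, 0.07], [0.0, 0.002]) == "nitrogen_adaptive"

    def test_both_condition_locus_is_shared_adaptive(self):
        assert self._classify([0.05, 0.05, 0.04], [0.05, 0.045, 0.05]) == "shared_adaptive"

    def test_recurrent_without_reproducible_fitness_is_inconclusive(self):
        assert self._classify([0.004, 0.006, 0.002], [0.0, 0.0, 0.0]) == "inconclusive"

    def test_labels_are_exclusive_and_exhaustive(self):
        barcodes = [f"b{i}" for i in range(4)]
        muts = pd.DataFrame(
            mutation_rows("A", barcodes[:2]) + mutation_rows("B", barcodes[2:])
        )
        fit = {
            "nitrogen": fitness_table({"b0": 0.05, "b1": 0.06, "b2": 0.0, "b3": 0.001}),
            "glucose": fitness_table({b: 0.0 for b in barcodes}),
        }
        labelled = ac.classify_loci(ac.summarize_by_locus(muts, fit))
        assert labelled["label"].isin(
            ["nitrogen_adaptive", "shared_adaptive", "inconclusive", "neutral"]
        ).all()
        assert len(labelled) == labelled["locus"].nunique()

    def test_raising_threshold_never_adds_adaptive_loci(self):
        barcodes = [f"b{i}" for i in range(6)]
        muts = pd.DataFrame(
            mutation_rows("A", barcodes[:3]) + mutation_rows("B", barcodes[3:])
        )
        fit = {
            "nitrogen": fitness_table(
                {"b0": 0.02, "b1": 0.025, "b2": 0.03, "b3": 0.06, "b4": 0.07, "b5": 0.05}
            ),
            "glucose": fitness_table({b: 0.0 for b in barcodes}),
        }
        summ = ac.summarize_by_locus(muts, fit)
        called = {}
        for thr in (0.01, 0.02, 0.04, 0.06):
            cfg = ac.ClassifierConfig(fitness_threshold=thr)
            lab = ac.classify_loci(ac.summarize_by_locus(muts, fit, thr), cfg)
            called[thr] = set(lab.loc[lab["label"] == "nitrogen_adaptive", "locus"])
        thresholds = sorted(called)
        for lo, hi in zip(thresholds, thresholds[1:]):
            assert called[hi] <= called[lo]

    def test_lower_median_guards_against_single_hitchhiker(self):
        # one adaptive + one neutral carrier must not average past threshold
        assert self._classify([0.05, 0.0], [0.0, 0.0]) == "inconclusive"


class TestCohort:
    def _cohort(self, pairs):
        """pairs: ploidy -> (explained, adaptive)."""
        labelled = pd.DataFrame(
            [{"locus": "L1", "label": "nitrogen_adaptive", "n_alleles": 1, "n_unique_lineages": 2}]
        )
        muts, fit_rows, ploidy = [], [], {}
        for pl, (expl, adapt) in pairs.items():
            for j in range(adapt):
                b = f"{pl}_{j}"
                fit_rows.append({"barcode": b, "s_mean": 0.05, "s_sd": 0.004})
                ploidy[b] = pl
                if j < expl:
                    muts.append(
                        {"clone_id": b, "barcode": b, "locus": "L1", "class": "missense", "position": 1}
                    )
        return ac.summarize_cohort(
            labelled, pd.DataFrame(muts), pd.DataFrame(fit_rows), ploidy
        )

    def test_published_fractions_give_76_percent(self):
        rep = self._cohort({"haploid": (178, 224), "diploid": (15, 29)})
        assert rep["combined"]["percent_explained"] == 76
        assert rep["by_ploidy"]["haploid"]["n_adaptive"] == 224
        assert rep["by_ploidy"]["diploid"]["n_explained"] == 15

    def test_zero_adaptive_lineages_percentage_undefined(self):
        labelled = pd.DataFrame(
            [{"locus": "L1", "label": "nitrogen_adaptive", "n_alleles": 1, "n_unique_lineages": 2}]
        )
        fit = pd.DataFrame({"barcode": ["b0"], "s_mean": [0.0], "s_sd": [0.0]})
        rep = ac.summarize_cohort(labelled, pd.DataFrame(columns=["barcode", "locus"]), fit,
                                  {"b0": "haploid"})
        assert rep["combined"]["percent_explained"] is None

    def test_fully_explained_cohort_is_100_percent(self):
        rep = self._cohort({"haploid": (10, 10)})
        assert rep["combined"]["percent_explained"] == 100

    def test_autodiploid_only_diploids_counted_separately(self):
        labelled = pd.DataFrame(
            [{"locus": "L1", "label": "nitrogen_adaptive", "n_alleles": 1, "n_unique_lineages": 2}]
        )
        fit = pd.DataFrame(
            {
                "barcode": ["d0", "d1"],
                "s_mean": [0.031, 0.06],  # d0 within +/-0.005 of autodiploid 0.03
                "s_sd": [0.002, 0.002],
            }
        )
        muts = pd.DataFrame(
            [{"clone_id": "d1", "barcode": "d1", "locus": "L1", "class": "missense", "position": 1}]
        )
        rep = ac.summarize_cohort(labelled, muts, fit, {"d0": "diploid", "d1": "diploid"})
        assert rep["autodiploid_only"] == 1
        assert rep["by_ploidy"]["diploid"]["n_adaptive"] == 1
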