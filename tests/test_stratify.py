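"""PD-L1 categories, proliferation strata, cold flags and accuracy rows."""

import numpy as np
import pandas as pd
import pytest

import prolifsig as ps
from prolifsig.stratify import TERTILE_TO_STATUS


class TestPdl1Category:
    @pytest.mark.parametrize("tps,expected", [
        (0.0, "negative"), (0.99, "negative"),
        (1.0, "weak_positive"), (49.99, "weak_positive"),
        (50.0, "strong_positive"), (100.0, "strong_positive"),
    ])
    def test_exact_boundaries(self, tps, expected):
        assert ps.pdl1_category(tps) == expected

    def test_missing_and_invalid(self):
        assert ps.pdl1_category(None) == "missing"
        assert ps.pdl1_category(float("nan")) == "missing"
        with pytest.raises(ValueError):
            ps.pdl1_category(101.0)


class TestColdFlags:
    @pytest.mark.parametrize("rank,expected", [
        (14.9, (True, True)), (20.0, (False, True)),
        (33.0, (False, False)), (90.0, (False, False)),
    ])
    def test_strict_cuts(self, rank, expected):
        assert ps.cold_tumor_flags(rank) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ps.cold_tumor_flags(-1.0)


class TestProliferationStatus:
    def test_missing_signature_gene_rejected(self, tiny_reference):
        with pytest.raises(KeyError):
            ps.proliferation_status({"BUB1": 50.0}, tiny_reference)

    def test_status_follows_signature_rank(self, ranks, reference):
        sig = ps.signature_rank_cohort(ranks, reference)
        status = ps.proliferation_status_cohort(ranks, reference)
        for sid in ranks.columns:
            expected = TERTILE_TO_STATUS[ps.tertile_of(sig[sid])]
            assert status[sid] == expected

    def test_deterministic_under_cohort_shuffle(self, ranks, reference):
        base = ps.proliferation_status_cohort(ranks, reference)
        rng = np.random.default_rng(2)
        cols = list(rng.permutation(ranks.columns))
        redo = ps.proliferation_status_cohort(ranks[cols], reference)
        assert redo.sort_index().equals(base.sort_index())

    def test_stratum_prevalences_near_cohort_targets(self):
        """Default cohorts reproduce realistic stratum frequencies.

        Targets 22.5 / 38.3 / 39.2% poorly/moderately/highly, within 5
        points. A single 120-patient study carries ~4 points of binomial
        noise plus ~3.5 points of tertile-cut wiggle from its one finite
        reference, so the calibration is checked on prevalences pooled
        over several independent studies.
        """
        counts = {"poorly": 0, "moderately": 0, "highly": 0}
        total = 0
        for seed in range(30, 42):
            study = ps.simulate_study(seed=seed)
            ref = study.reference
            ranks = ref.rank_samples(study.cohort_expression)
            eligible = ps.eligible_for_survival(study.clinical)
            status = ps.proliferation_status_cohort(
                ranks[list(eligible.patient_id)], ref)
            for k, v in status.value_counts().items():
                counts[k] += int(v)
            total += len(status)
        assert counts["poorly"] / total == pytest.approx(0.225, abs=0.05)
        assert counts["moderately"] / total == pytest.approx(0.383, abs=0.05)
        assert counts["highly"] / total == pytest.approx(0.392, abs=0.05)


class TestStratumTable:
    def test_columns_and_flag_consistency(self, study, ranks, reference):
        eligible = ps.eligible_for_survival(study.clinical)
        table = ps.assign_strata(ranks, eligible, reference)
        assert len(table) == len(eligible)
        assert set(table.proliferation) <= {"poorly", "moderately", "highly"}
        assert set(table.pd_l1) <= {"negative", "weak_positive",
                                    "strong_positive", "missing"}
        # flags re-derivable from the cd8 rank
        for _, row in table.iterrows():
            assert (row.cold_15, row.cold_33) == ps.cold_tumor_flags(row.cd8_rank)
        # strict cut implies tertile cut
        assert (~table.cold_15 | table.cold_33).all()

    def test_unknown_patient_rejected(self, study, ranks, reference):
        bad = study.clinical.copy()
        bad.loc[bad.index[0], "patient_id"] = "GHOST"
        with pytest.raises(KeyError):
            ps.assign_strata(ranks, bad, reference)


class TestSingleGeneAccuracy:
    def _reference(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.permuted(np.tile(np.arange(1.0, 101.0), (1, 1)), axis=1),
            index=["G1"], columns=[f"r{i}" for i in range(100)])
        return ps.ReferencePopulation(expr)

    def test_perfect_predictions(self):
        reference = self._reference()
        samples = [f"s{i}" for i in range(10)]
        # DC patients sit mid-rank (-> medium -> predicted DC), NDC high
        vals = [50.0] * 4 + [90.0] * 6
        ranks = pd.DataFrame([vals], index=["G1"], columns=samples)
        labels = pd.Series(["DC"] * 4 + ["NDC"] * 6, index=samples)
        table = ps.single_gene_accuracy(ranks, labels, reference,
                                        gene_set=("G1",))
        assert (table.accuracy == 1.0).all()

    def test_all_predicted_dc_accuracy_is_prevalence(self):
        reference = self._reference()
        n, n_dc = 110, 35
        samples = [f"s{i}" for i in range(n)]
        ranks = pd.DataFrame([[50.0] * n], index=["G1"], columns=samples)
        labels = pd.Series(["DC"] * n_dc + ["NDC"] * (n - n_dc), index=samples)
        table = ps.single_gene_accuracy(ranks, labels, reference,
                                        gene_set=("G1",))
        assert table.accuracy.iloc[0] == pytest.approx(n_dc / n)

    def test_counts_partition_and_markers(self, study, ranks, reference,
                                          dc_labels):
        table = ps.single_gene_accuracy(ranks, dc_labels, reference)
        assert list(table.marker) == list(ps.PROLIFERATION_GENES) + ["10-gene mean"]
        n = len(dc_labels)
        assert ((table.tp + table.tn + table.fp + table.fn) == n).all()
        assert table.accuracy.between(0, 1).all()
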