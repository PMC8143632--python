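"""Prevalence filter and Bayesian Poisson enrichment scoring."""

import numpy as np
import pandas as pd
import pytest

from apmskit.enrichment import (
    McmcSettings,
    call_enriched,
    enrich_count_matrix,
    fit_poisson_enrichment,
    prevalence_filter,
    score_bait,
)
from apmskit.io import CONTROL, RunRecord, StudyDesign

FAST = McmcSettings(burn_in=500, iterations=2000, seed=11)


def design_with(n_baits=1, n_reps=3, n_controls=3, reps_per_bait=None):
    runs = []
    for b in range(1, n_baits + 1):
        for k in range(1, (reps_per_bait or {}).get(f"bait{b}", n_reps) + 1):
            runs.append(RunRecord(f"b{b}_r{k}", f"bait{b}", k))
    for k in range(1, n_controls + 1):
        runs.append(RunRecord(f"ctrl_r{k}", CONTROL, k))
    return StudyDesign(runs)


class TestPrevalenceFilter:
    def test_half_of_four_replicates_retained(self):
        design = design_with(reps_per_bait={"bait1": 4})
        counts = pd.DataFrame(
            {"b1_r1": [1], "b1_r2": [2], "b1_r3": [0], "b1_r4": [0],
             "ctrl_r1": [0], "ctrl_r2": [0], "ctrl_r3": [0]},
            index=["prey"],
        )
        assert prevalence_filter(counts, design) == ["prey"]

    def test_everywhere_detected_retained(self):
        design = design_with()
        counts = pd.DataFrame(1, index=["prey"], columns=design.run_ids)
        assert prevalence_filter(counts, design) == ["prey"]

    def test_one_of_three_everywhere_excluded(self):
        # ceil(3/2) = 2, so a single detection per bait is not enough
        design = design_with(n_baits=2)
        counts = pd.DataFrame(0, index=["prey"], columns=design.run_ids)
        counts.loc["prey", "b1_r1"] = 3
        counts.loc["prey", "b2_r2"] = 3
        assert prevalence_filter(counts, design) == []


class TestPoissonFit:
    def test_null_identical_vectors(self):
        y = np.array([[5, 6, 5, 4]])
        res = fit_poisson_enrichment(y, y, FAST)
        assert abs(res.loc[0, "log2fc"]) < 0.2
        assert abs(res.loc[0, "z_stat"]) < 1.0

    def test_recovers_planted_threefold_log2(self, rng):
        """Controls Poisson(1), bait Poisson(8), n=4: the mean estimated
        log2 fold change over 50 simulated preys is within 0.5 of 3."""
        yc = rng.poisson(1.0, size=(50, 4))
        yb = rng.poisson(8.0, size=(50, 4))
        res = fit_poisson_enrichment(yb, yc, McmcSettings(1000, 4000, seed=3))
        assert np.nanmean(res["log2fc"]) == pytest.approx(3.0, abs=0.5)

    def test_z_median_monotone_in_fold_change(self, rng):
        """Doubling the planted fold change never decreases the median z
        over a 5-point effect grid with 50 simulations each."""
        folds = [1, 2, 4, 8, 16]
        blocks_b, blocks_c = [], []
        for f in folds:
            blocks_c.append(rng.poisson(2.0, size=(50, 3)))
            blocks_b.append(rng.poisson(2.0 * f, size=(50, 3)))
        res = fit_poisson_enrichment(
            np.vstack(blocks_b), np.vstack(blocks_c), McmcSettings(1000, 4000, seed=5)
        )
        medians = [
            np.median(res["z_stat"].to_numpy()[i * 50:(i + 1) * 50])
            for i in range(len(folds))
        ]
        assert all(m2 >= m1 for m1, m2 in zip(medians, medians[1:]))

    def test_all_zero_prey_skipped(self):
        res = fit_poisson_enrichment(
            np.array([[0, 0, 0], [3, 4, 5]]), np.array([[0, 0, 0], [0, 1, 0]]), FAST
        )
        assert bool(res.loc[0, "skipped"]) and np.isnan(res.loc[0, "log2fc"])
        assert not res.loc[1, "skipped"]

    def test_deterministic_given_seed(self):
        yb = np.array([[9, 11, 10], [3, 0, 1]])
        yc = np.array([[1, 2, 0], [2, 1, 3]])
        a = fit_poisson_enrichment(yb, yc, FAST)
        b = fit_poisson_enrichment(yb, yc, FAST)
        pd.testing.assert_frame_equal(a, b)

    def test_offsets_shift_fold_change(self):
        # bait runs twice as deep as controls: identical raw counts should
        # score as depletion once offsets are supplied
        yb = np.array([[4, 4, 4]])
        yc = np.array([[4, 4, 4]])
        res = fit_poisson_enrichment(
            yb, yc, FAST,
            bait_offsets=np.log(np.array([2.0, 2.0, 2.0])),
            control_offsets=np.zeros(3),
        )
        assert res.loc[0, "log2fc"] == pytest.approx(-1.0, abs=0.3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson_enrichment(np.array([[-1, 2]]), np.array([[1, 1]]), FAST)


class TestCallEnriched:
    @pytest.mark.parametrize(
        "z,fc,expected",
        [(3.1, 2.5, True), (2.9, 5.0, False), (5.0, 1.9, False),
         (3.0, 2.0, True)],  # thresholds are inclusive
    )
    def test_threshold_rule(self, z, fc, expected):
        df = pd.DataFrame({"z_stat": [z], "log2fc": [fc]})
        assert bool(call_enriched(df)["enriched"].iloc[0]) is expected

    def test_monotone_in_thresholds(self, rng):
        df = pd.DataFrame(
            {"z_stat": rng.normal(3, 2, 200), "log2fc": rng.normal(2, 2, 200)}
        )
        base = set(call_enriched(df, 3, 2).index[call_enriched(df, 3, 2)["enriched"]])
        for z_min, fc_min in [(4, 2), (3, 3), (5, 4)]:
            tighter = call_enriched(df, z_min, fc_min)
            assert set(tighter.index[tighter["enriched"]]) <= base


class TestScoreBait:
    def test_bait_excluded_and_detection_counts(self):
        design = design_with()
        counts = pd.DataFrame(
            {r: [50, 8, 0] for r in design.runs_for_bait("bait1")}
            | {"ctrl_r1": [0, 0, 2], "ctrl_r2": [0, 1, 2], "ctrl_r3": [0, 1, 0]},
            index=["bait1", "preyX", "preyY"],
        )
        res = score_bait(counts, design, "bait1", FAST)
        assert "bait1" not in set(res["prey_id"])
        row = res.set_index("prey_id").loc["preyX"]
        assert row["n_bait_runs_detected"] == 3
        assert row["n_control_runs_detected"] == 2

    def test_requires_controls(self):
        design = StudyDesign([RunRecord("b1_r1", "bait1", 1)])
        counts = pd.DataFrame({"b1_r1": [1]}, index=["p"])
        with pytest.raises(Exception, match="CONTROL"):
            score_bait(counts, design, "bait1", FAST)


def test_enrich_count_matrix_reproducible():
    design = design_with(n_baits=2, n_reps=3)
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(2.0, size=(12, len(design.run_ids))),
        index=[f"p{i}" for i in range(12)],
        columns=design.run_ids,
    )
    a = enrich_count_matrix(counts, design, FAST)
    b = enrich_count_matrix(counts, design, FAST)
    pd.testing.assert_frame_equal(a, b)
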