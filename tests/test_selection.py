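"""Information criteria, weights, evidence ratios and table reconstruction."""

import math

import numpy as np
import pandas as pd
import pytest

from cspc_lba import reference
from cspc_lba.lba import simulate_trials
from cspc_lba.model_space import build_condition_params
from cspc_lba.selection import (
    aggregate_best_fit,
    b_vs_v_ratio,
    ic_weights,
    information_criteria,
    predicted_moments,
    predicted_quantiles,
    quantile_summary,
    selection_records,
)


class TestInformationCriteria:
    def test_no_penalty_at_k_zero(self):
        aic, bic = information_criteria(-12.5, 0, 100)
        assert aic == bic == 25.0

    def test_direct_arithmetic(self):
        aic, bic = information_criteria(-100.0, 8, 445)
        assert aic == 216.0
        assert bic == pytest.approx(8 * math.log(445) + 200, abs=1e-10)
        assert bic == pytest.approx(248.78, abs=0.01)

    def test_bic_penalty_exceeds_aic_exactly_when_log_n_above_two(self):
        # k ln N > 2k iff ln N > 2, i.e. N >= 8 for integer N
        for n in (2, 7, 8, 9, 445):
            aic, bic = information_criteria(-50.0, 5, n)
            assert bic - aic == pytest.approx(5 * (math.log(n) - 2))
            assert (bic > aic) == (math.log(n) > 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 3, 0)
        with pytest.raises(ValueError):
            information_criteria(-1.0, -1, 10)


class TestIcWeights:
    def test_equal_ics_give_uniform_weights(self):
        assert np.allclose(ic_weights([100.0] * 4), 0.25)

    def test_two_model_closed_form(self):
        w = ic_weights([10.0, 12.0])
        e = math.exp(-1.0)
        assert w[0] == pytest.approx(1 / (1 + e), rel=1e-12)
        assert w[1] == pytest.approx(e / (1 + e), rel=1e-12)
        assert w[1] == pytest.approx(0.2689, abs=5e-5)

    def test_shift_invariance_and_normalization(self):
        ics = np.array([210.0, 215.5, 208.2, 230.0])
        w = ic_weights(ics)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, ic_weights(ics + 1000.0))

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            ic_weights([1.0])


class TestBvsVRatio:
    def test_published_aic_weights_dataset_one(self):
        w = {"V1": 0.059, "V2": 0.106, "B1": 0.412, "B2": 0.422}
        assert b_vs_v_ratio(w) == pytest.approx(5.06, abs=0.01)

    def test_published_bic_weights_dataset_one(self):
        w = {"V1": 0.027, "V2": 0.313, "B1": 0.123, "B2": 0.537}
        assert b_vs_v_ratio(w) == pytest.approx(1.94, abs=0.01)

    def test_equal_weights_tie_at_one(self):
        assert b_vs_v_ratio({m: 0.25 for m in ("V1", "V2", "B1", "B2")}) == 1.0

    def test_zero_drift_class_flagged(self):
        r = b_vs_v_ratio({"V1": 0.0, "V2": 0.0, "B1": 0.6, "B2": 0.4})
        assert math.isnan(r)


class TestAggregation:
    def _records(self):
        # three participants over two datasets, synthetic IC values
        rows = []
        ics = {
            ("p1", "I"): {"V1": 10.0, "V2": 8.0, "B1": 9.0, "B2": 7.0},
            ("p2", "I"): {"V1": 4.0, "V2": 6.0, "B1": 3.0, "B2": 5.0},
            ("p3", "II"): {"V1": 2.0, "V2": 1.0, "B1": 3.0, "B2": 4.0},
        }
        for (pid, ds), vals in ics.items():
            for m, ic in vals.items():
                rows.append({"participant": pid, "dataset": ds, "model": m, "aic": ic, "bic": ic})
        return selection_records(pd.DataFrame(rows))

    def test_weights_sum_to_one_and_best_has_zero_delta(self):
        rec = self._records()
        for crit in ("aic", "bic"):
            w = rec[[f"w{crit}_{m}" for m in ("V1", "V2", "B1", "B2")]].sum(axis=1)
            assert np.allclose(w, 1.0, atol=1e-12)
            for _, row in rec.iterrows():
                assert row[f"d{crit}_{row[f'best_{crit}']}"] == 0.0

    def test_pooled_percentages(self):
        summary = aggregate_best_fit(self._records())
        pct = summary["BIC"]["pooled_pct"]
        assert pct["B2"] == pytest.approx(100 / 3)
        assert pct["B1"] == pytest.approx(100 / 3)
        assert pct["V2"] == pytest.approx(100 / 3)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_single_winner_takes_all(self):
        rows = [
            {"participant": p, "model": m, "aic": 0.0 if m == "B1" else 50.0,
             "bic": 0.0 if m == "B1" else 50.0}
            for p in ("p1", "p2")
            for m in ("V1", "V2", "B1", "B2")
        ]
        summary = aggregate_best_fit(selection_records(pd.DataFrame(rows)))
        assert summary["AIC"]["pooled_pct"]["B1"] == 100.0
        assert summary["AIC"]["pooled_pct"]["V1"] == 0.0

    def test_ties_split_equally(self):
        rows = [
            {"participant": "p1", "model": m, "aic": 1.0 if m in ("B1", "B2") else 9.0,
             "bic": 1.0 if m in ("B1", "B2") else 9.0}
            for m in ("V1", "V2", "B1", "B2")
        ]
        summary = aggregate_best_fit(selection_records(pd.DataFrame(rows)))
        counts = summary["BIC"]["best_counts"]
        assert counts.loc["all", "B1"] == pytest.approx(0.5)
        assert counts.loc["all", "B2"] == pytest.approx(0.5)


class TestPublishedTableReconstruction:
    """The published weight/count table must reproduce its own derived cells."""

    @pytest.mark.parametrize("crit", ["AIC", "BIC"])
    def test_b_vs_v_cells(self, crit):
        for ds in reference.DATASETS:
            got = b_vs_v_ratio(reference.IC_WEIGHTS[(crit, ds)])
            assert got == pytest.approx(reference.PUBLISHED_B_VS_V[(crit, ds)], rel=0.005)

    @pytest.mark.parametrize("crit", ["AIC", "BIC"])
    def test_mean_ratio(self, crit):
        ratios = [b_vs_v_ratio(reference.IC_WEIGHTS[(crit, ds)]) for ds in reference.DATASETS]
        assert np.mean(ratios) == pytest.approx(
            reference.PUBLISHED_B_VS_V_MEAN[crit], abs=0.015 if crit == "BIC" else 0.05
        )

    @pytest.mark.parametrize("crit", ["AIC", "BIC"])
    def test_pooled_percentages_from_counts(self, crit):
        n_total = sum(reference.N_PARTICIPANTS.values())
        assert n_total == 87
        for m in ("V1", "V2", "B1", "B2"):
            count = sum(reference.BEST_COUNTS[(crit, ds)][m] for ds in reference.DATASETS)
            # one published cell (38.0%) rounds 33/87 = 37.93% up; allow 0.1
            assert 100.0 * count / n_total == pytest.approx(
                reference.PUBLISHED_POOLED_PCT[crit][m], abs=0.1
            )

    def test_counts_per_dataset_sum_to_sample_sizes(self):
        for crit in ("AIC", "BIC"):
            for ds in reference.DATASETS:
                assert sum(reference.BEST_COUNTS[(crit, ds)].values()) == reference.N_PARTICIPANTS[ds]


class TestQuantileSummary:
    def test_all_correct_trials(self):
        rng = np.random.default_rng(0)
        rt = rng.gamma(5, 100, 100)
        q = quantile_summary(rt, np.ones(100, dtype=bool))
        assert set(q["class"]) == {"correct"}
        assert np.allclose(q["cumulative_height"], [0.1, 0.3, 0.5, 0.7, 0.9])

    def test_heights_scale_with_class_proportion(self):
        rng = np.random.default_rng(1)
        rt = rng.gamma(5, 100, 1000)
        correct = np.zeros(1000, dtype=bool)
        correct[:800] = True
        q = quantile_summary(rt, correct)
        hc = q.loc[q["class"] == "correct", "cumulative_height"].to_numpy()
        assert np.allclose(hc, [0.08, 0.24, 0.40, 0.56, 0.72])

    def test_sparse_class_flagged_unreliable_not_dropped(self):
        rt = np.linspace(300, 900, 53)
        correct = np.ones(53, dtype=bool)
        correct[:3] = False
        q = quantile_summary(rt, correct)
        err = q[q["class"] == "error"]
        assert len(err) == 5 and not err["reliable"].any()
        assert q[q["class"] == "correct"]["reliable"].all()

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            quantile_summary(np.array([]), np.array([], dtype=bool))

    def test_model_quantiles_match_simulation(self, b2_mapping):
        """Closed-form defective quantiles vs simulation, within 5 ms.

        The error class holds ~8% of trials, so its extreme quantiles need
        ~1e5 draws of their own for a 5 ms band; 2e6 total trials keeps the
        Monte-Carlo noise well inside the tolerance for both classes.
        """
        accs = b2_mapping[("high", "incongruent")]
        rng = np.random.default_rng(12)
        correct, rt = simulate_trials(accs, 2 * 10**6, rng)
        sim = quantile_summary(1000.0 * rt, correct)
        pred = predicted_quantiles(accs)
        for cls in ("correct", "error"):
            s = sim[sim["class"] == cls]["rt_ms"].to_numpy()
            p = pred[pred["class"] == cls]["rt_ms"].to_numpy()
            assert np.max(np.abs(s - p)) < 5.0


class TestPredictedMoments:
    def test_quadrature_matches_large_simulation(self, b2_mapping):
        accs = b2_mapping[("low", "congruent")]
        rng = np.random.default_rng(21)
        correct, rt = simulate_trials(accs, 10**6, rng)
        pm = predicted_moments({("low", "congruent"): accs})
        assert pm["mean_rt_ms"].iloc[0] == pytest.approx(1000.0 * rt.mean(), abs=2.0)
        assert pm["accuracy"].iloc[0] == pytest.approx(correct.mean(), abs=0.002)

    def test_shared_parameters_give_identical_predictions(self, b2_mapping):
        accs = b2_mapping[("low", "congruent")]
        pm = predicted_moments({("low", "congruent"): accs, ("high", "congruent"): accs})
        assert pm["mean_rt_ms"].nunique() == 1
        assert pm["accuracy"].nunique() == 1

    def test_raising_threshold_slows_and_improves(self, b2_theta):
        """Speed-accuracy tradeoff: larger b -> slower and more accurate."""
        from cspc_lba.lba import Accumulator, AccumulatorSet

        base = build_condition_params(b2_theta)[("low", "congruent")]
        higher = AccumulatorSet(
            correct=Accumulator(base.correct.b + 0.15, base.correct.A, base.correct.v, base.correct.s),
            error=Accumulator(base.error.b + 0.15, base.error.A, base.error.v, base.error.s),
            t0=base.t0,
        )
        pm = predicted_moments({("lo", "x"): base, ("hi", "x"): higher})
        assert pm.iloc[1]["mean_rt_ms"] > pm.iloc[0]["mean_rt_ms"]
        assert pm.iloc[1]["accuracy"] > pm.iloc[0]["accuracy"]
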