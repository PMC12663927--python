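"""One-hot encoding, the four predictors, and the LOO benchmark."""

import numpy as np
import pytest

from rubiscope import predict as pr
from rubiscope.predict import (
    ModelSpec,
    decode,
    fit_svr,
    loo_crossval,
    one_hot_encode,
    predict_all,
    predict_mean,
    predict_nn,
    predict_weighted_mean,
)
from rubiscope.seqspace import AlignedSeqSet, identity_matrix, pairwise_identity

from conftest import random_alignment


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

class TestOneHotEncode:
    def test_single_sequence_positions(self):
        aln = AlignedSeqSet(ids=["s"], rows=["AC"])
        enc = one_hot_encode(aln)
        assert enc.X.shape == (1, 2 * 21)
        hot = np.flatnonzero(enc.X[0])
        assert [enc.feature_index[k] for k in hot] == [(0, "A"), (1, "C")]

    def test_row_sums_equal_alignment_length(self):
        aln = random_alignment(10, 25, seed=1, gap_frac=0.2)
        enc = one_hot_encode(aln)
        np.testing.assert_array_equal(enc.X.sum(axis=1), np.full(10, 25.0))

    def test_position_blocks_have_one_hot(self):
        aln = random_alignment(6, 12, seed=2, gap_frac=0.3)
        enc = one_hot_encode(aln)
        blocks = enc.X.reshape(6, 12, 21)
        np.testing.assert_array_equal(blocks.sum(axis=2), np.ones((6, 12)))

    def test_decode_round_trip(self):
        aln = random_alignment(8, 20, seed=3, gap_frac=0.25)
        assert decode(one_hot_encode(aln)) == aln.rows

    def test_ambiguity_encodes_as_zero_block(self):
        aln = AlignedSeqSet(ids=["s"], rows=["AXC"])
        enc = one_hot_encode(aln)
        block = enc.X[0].reshape(3, 21)
        assert block[1].sum() == 0
        assert decode(enc) == ["AXC"]


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

class TestNearestNeighbor:
    def test_exact_match_returns_its_rate(self):
        s = np.array([0.7, 1.0, 0.4])
        y = np.array([1.0, 2.0, 3.0])
        assert predict_nn(s, y) == pytest.approx(2.0)

    def test_tie_averages_in_log_space(self):
        s = np.array([0.8, 0.8])
        y = np.log([2.0, 8.0])
        assert predict_nn(s, y) == pytest.approx(np.log(4.0))

    def test_matches_brute_force_argmax(self):
        aln = random_alignment(21, 30, seed=4, n_states=4)
        rng = np.random.default_rng(5)
        y = rng.normal(size=20)
        sim = identity_matrix(aln)
        s = sim[20, :20]
        scan = [pairwise_identity(aln.rows[20], aln.rows[i]) for i in range(20)]
        best = max(scan)
        expected = np.mean([y[i] for i in range(20) if scan[i] == best])
        assert predict_nn(s, y) == pytest.approx(expected)

    def test_empty_train_is_error(self):
        with pytest.raises(ValueError):
            predict_nn(np.array([]), np.array([]))


class TestWeightedMean:
    def test_lambda_zero_equals_unweighted_mean(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(0, 1, 15)
        y = rng.normal(size=15)
        assert predict_weighted_mean(s, y, 0.0) == predict_mean(y)

    def test_hand_evaluated_weights(self):
        # identities {1.0, 0.5}, ln-rates {0, 1}, lam = ln(4)/0.5
        # -> weights {1, 0.25}, prediction 0.25/1.25 = 0.2
        s = np.array([1.0, 0.5])
        y = np.array([0.0, 1.0])
        lam = np.log(4.0) / 0.5
        assert predict_weighted_mean(s, y, lam) == pytest.approx(0.2)

    def test_large_lambda_converges_to_nearest_neighbor(self):
        rng = np.random.default_rng(7)
        s = rng.uniform(0, 0.9, 10)
        s[3] = 0.95  # unique top-identity neighbour
        y = rng.normal(size=10)
        assert predict_weighted_mean(s, y, 500.0) == pytest.approx(
            predict_nn(s, y), abs=1e-6
        )


class TestSVR:
    def test_constant_targets_predicted_within_epsilon(self):
        aln = random_alignment(12, 20, seed=8)
        enc = one_hot_encode(aln)
        y = np.full(12, 1.7)
        model = fit_svr(enc.X, y)
        np.testing.assert_allclose(model.predict(enc.X), y, atol=0.1 + 1e-9)

    def test_deterministic_refit(self):
        aln = random_alignment(15, 25, seed=9)
        enc = one_hot_encode(aln)
        rng = np.random.default_rng(10)
        y = rng.normal(size=15)
        p1 = fit_svr(enc.X, y).predict(enc.X)
        p2 = fit_svr(enc.X, y).predict(enc.X)
        np.testing.assert_array_equal(p1, p2)

    def test_gamma_scale_matches_pinned_formula(self):
        aln = random_alignment(15, 25, seed=11, gap_frac=0.1)
        enc = one_hot_encode(aln)
        rng = np.random.default_rng(12)
        y = rng.normal(size=15)
        gamma = 1.0 / (enc.X.shape[1] * enc.X.var())
        explicit = fit_svr(enc.X, y, ModelSpec(kind="svr_rbf", svr_gamma=gamma))
        default = fit_svr(enc.X, y)
        np.testing.assert_allclose(
            default.predict(enc.X), explicit.predict(enc.X), rtol=1e-10
        )

    def test_separable_toy_fits_training_points(self):
        # two well-separated clusters with distinct targets
        aln = AlignedSeqSet(
            ids=[f"s{i}" for i in range(8)],
            rows=["AAAAAAAAAA"] * 2 + ["AAAAAAAAAC"] * 2
            + ["CCCCCCCCCC"] * 2 + ["CCCCCCCCCA"] * 2,
        )
        enc = one_hot_encode(aln)
        y = np.array([0.0, 0.0, 0.0, 0.0, 2.0, 2.0, 2.0, 2.0])
        model = fit_svr(enc.X, y)
        resid = np.abs(model.predict(enc.X) - y)
        assert resid.mean() <= 0.15

    def test_too_few_rows_is_error(self):
        with pytest.raises(ValueError):
            fit_svr(np.ones((1, 4)), np.ones(1))


# ---------------------------------------------------------------------------
# LOO cross-validation
# ---------------------------------------------------------------------------

class TestLooCrossval:
    def test_equal_rates_give_zero_rmse_for_averaging_models(self):
        aln = random_alignment(10, 20, seed=13)
        y = {s: 1.3 for s in aln.ids}
        for kind in ("mean", "weighted_mean", "nn"):
            cv = loo_crossval(aln, y, ModelSpec(kind=kind), thresholds=[0.0])
            assert cv.rmse_ln[0] == pytest.approx(0.0)
            assert cv.fold_error[0] == pytest.approx(1.0)

    def test_three_variant_nn_hand_computation(self):
        # id(s1,s2)=0.9, id(s1,s3)=id(s2,s3)=0.5
        aln = AlignedSeqSet(
            ids=["s1", "s2", "s3"],
            rows=["AAAAAAAAAA", "AAAAAAAAAC", "AAAAACCCCG"],
        )
        y = {"s1": 0.0, "s2": 1.0, "s3": 4.0}
        cv = loo_crossval(aln, y, ModelSpec(kind="nn"), thresholds=[0.0])
        # leave-outs: s1 -> nn s2 -> err 1 ; s2 -> nn s1 -> err -1 ;
        # s3 -> tie (s1, s2) -> 0.5 -> err -3.5
        expected = np.sqrt((1 + 1 + 3.5**2) / 3)
        assert cv.rmse_ln[0] == pytest.approx(expected)

    def test_skipped_targets_reduce_n_evaluable(self):
        aln = AlignedSeqSet(
            ids=["s1", "s2", "s3"],
            rows=["AAAAAAAAAA", "AAAAAAAAAC", "CCCCCCCCCC"],
        )
        y = {"s1": 0.0, "s2": 1.0, "s3": 2.0}
        cv = loo_crossval(aln, y, ModelSpec(kind="nn"), thresholds=[0.85])
        assert cv.n_evaluable[0] == 2  # s3 has no neighbour at 0.85

    def test_no_evaluable_targets_is_error(self):
        aln = AlignedSeqSet(
            ids=["s1", "s2", "s3"],
            rows=["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG"],
        )
        y = {s: 0.0 for s in aln.ids}
        with pytest.raises(ValueError):
            loo_crossval(aln, y, ModelSpec(kind="nn"), thresholds=[0.9])

    def test_fold_error_at_least_one(self, small_dataset):
        char = small_dataset.aln.subset_ids(small_dataset.characterized_ids)
        y = {v: small_dataset.true_ln_rates[v] for v in char.ids}
        cv = loo_crossval(char, y, ModelSpec(kind="weighted_mean"), thresholds=[0.5, 0.9])
        assert all(
            f >= 1.0 for f, n in zip(cv.fold_error, cv.n_evaluable) if n > 0
        )

    def test_bit_identical_reruns(self, small_dataset):
        char = small_dataset.aln.subset_ids(small_dataset.characterized_ids)
        y = {v: small_dataset.true_ln_rates[v] for v in char.ids}
        spec = ModelSpec(kind="svr_rbf")
        a = loo_crossval(char, y, spec, thresholds=[0.5, 0.8])
        b = loo_crossval(char, y, spec, thresholds=[0.5, 0.8])
        assert a.rmse_ln == b.rmse_ln and a.n_evaluable == b.n_evaluable


# ---------------------------------------------------------------------------
# Per-form prediction
# ---------------------------------------------------------------------------

class TestPredictAll:
    def make_aln(self):
        rows = ["AAAAAAAAAA", "AAAAAAAAAC", "AAAAAAAACC", "AAAAAAAAAA",
                "CCCCCCCCCC", "CCCCCCCCCA", "CCCCCCCCAA", "CCCCCCCCCC"]
        return AlignedSeqSet(
            ids=[f"s{i}" for i in range(8)],
            rows=rows,
            form=["II"] * 4 + ["III"] * 4,
            characterized=[True, True, True, False, True, True, True, False],
        )

    def test_identical_query_with_nn_reproduces_rate(self):
        aln = self.make_aln()
        y = {"s0": 0.0, "s1": 0.5, "s2": 1.0, "s4": 2.0, "s5": 2.5, "s6": 3.0}
        out = predict_all(aln, y, ModelSpec(kind="nn"))
        preds = out.predictions.set_index("variant_id")["predicted_kcat_c"]
        assert preds["s3"] == pytest.approx(np.exp(0.0))  # duplicates s0
        assert preds["s7"] == pytest.approx(np.exp(2.0))  # duplicates s4

    def test_output_size_and_positive_rates(self):
        aln = self.make_aln()
        y = {"s0": 0.0, "s1": 0.5, "s2": 1.0, "s4": 2.0, "s5": 2.5, "s6": 3.0}
        out = predict_all(aln, y, ModelSpec(kind="svr_rbf"))
        assert len(out.predictions) == 2
        assert (out.predictions["predicted_kcat_c"] > 0).all()

    def test_small_forms_refused_not_extrapolated(self):
        aln = self.make_aln()
        aln.form = ["II"] * 4 + ["I'"] * 4
        aln.characterized = [True, True, True, False, True, False, False, False]
        y = {"s0": 0.0, "s1": 0.5, "s2": 1.0, "s4": 2.0}
        out = predict_all(aln, y, ModelSpec(kind="nn"), min_train=3)
        assert set(out.predictions["variant_id"]) == {"s3"}
        assert set(out.skipped["variant_id"]) == {"s5", "s6", "s7"}

    def test_unknown_form_reported(self):
        aln = self.make_aln()
        aln.form[3] = "unknown"
        y = {"s0": 0.0, "s1": 0.5, "s2": 1.0, "s4": 2.0, "s5": 2.5, "s6": 3.0}
        out = predict_all(aln, y, ModelSpec(kind="nn"))
        assert "s3" in set(out.skipped["variant_id"])

    def test_svr_beats_unweighted_mean_on_phylogenetic_signal(self, small_dataset):
        ds = small_dataset
        aln = ds.aln
        y_all = ds.true_ln_rates
        y_char = {v: y_all[v] for v, c in zip(aln.ids, aln.characterized) if c}
        corr = {}
        for kind in ("svr_rbf", "mean"):
            out = predict_all(aln, y_char, ModelSpec(kind=kind), min_train=3)
            df = out.predictions
            truth = np.array([y_all[v] for v in df["variant_id"]])
            corr[kind] = np.corrcoef(np.log(df["predicted_kcat_c"]), truth)[0, 1]
        assert corr["svr_rbf"] > corr["mean"]
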