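"""Q10 correction, control normalization, assay calibration, summaries."""

import numpy as np
import pandas as pd
import pytest

from rubiscope import kinetics as kin
from rubiscope.seqspace import AlignedSeqSet


def table(rows):
    return kin.make_rate_table(
        pd.DataFrame(rows, columns=["variant_id", "kcat_c", "temp_c", "assay", "batch_id", "source"])
    )


# ---------------------------------------------------------------------------
# Q10 temperature correction
# ---------------------------------------------------------------------------

class TestQ10Correct:
    def test_at_target_temperature_unchanged(self):
        df = table([("v1", 5.0, 30.0, "coupled", "b1", "pipeline")])
        out = kin.q10_correct(df)
        assert out["kcat_c"].iloc[0] == pytest.approx(5.0)

    def test_one_decade_multiplies_by_q10(self):
        df = table([("v1", 10.0, 20.0, "coupled", "b1", "pipeline")])
        out = kin.q10_correct(df, q10=2.2)
        assert out["kcat_c"].iloc[0] == pytest.approx(22.0)

    def test_half_decade(self):
        df = table([("v1", 5.0, 25.0, "coupled", "b1", "pipeline")])
        out = kin.q10_correct(df, q10=2.2)
        assert out["kcat_c"].iloc[0] == pytest.approx(5 * 2.2**0.5)

    def test_round_trip_recovers_input(self):
        rng = np.random.default_rng(0)
        temps = rng.uniform(10, 45, size=20)
        rates = rng.lognormal(1.0, 0.5, size=20)
        df = table(
            [(f"v{i}", r, t, "coupled", "b", "pipeline") for i, (r, t) in enumerate(zip(rates, temps))]
        )
        fwd = kin.q10_correct(df, t_target=30.0)
        # send each record back to its original temperature
        back = fwd.copy()
        for i, t in enumerate(temps):
            row = kin.q10_correct(fwd.iloc[[i]], t_target=t, force=True)
            back.iloc[i] = row.iloc[0]
        np.testing.assert_allclose(back["kcat_c"].to_numpy(float), rates, rtol=1e-12)

    def test_double_correction_refused(self):
        df = table([("v1", 5.0, 25.0, "coupled", "b1", "pipeline")])
        once = kin.q10_correct(df)
        with pytest.raises(ValueError, match="already"):
            kin.q10_correct(once)
        kin.q10_correct(once, force=True)  # no-op at 30, allowed when forced


# ---------------------------------------------------------------------------
# Control normalization
# ---------------------------------------------------------------------------

class TestNormalizeToControl:
    def test_control_at_reference_leaves_rates_unchanged(self):
        df = table(
            [("ctrl", 10.0, 30.0, "coupled", "b1", "pipeline"),
             ("v1", 4.0, 30.0, "coupled", "b1", "pipeline")]
        )
        out, report = kin.normalize_to_control(df, "ctrl", 10.0)
        assert out["kcat_c"].tolist() == pytest.approx([10.0, 4.0])
        assert len(report) == 0

    def test_control_at_double_reference_halves_batch(self):
        df = table(
            [("ctrl", 20.0, 30.0, "coupled", "b1", "pipeline"),
             ("v1", 4.0, 30.0, "coupled", "b1", "pipeline")]
        )
        out, _ = kin.normalize_to_control(df, "ctrl", 10.0)
        assert out["kcat_c"].tolist() == pytest.approx([10.0, 2.0])

    def test_two_batch_hand_scaling(self):
        df = table(
            [("ctrl", 8.0, 30.0, "coupled", "b1", "pipeline"),
             ("v1", 3.0, 30.0, "coupled", "b1", "pipeline"),
             ("ctrl", 12.5, 30.0, "coupled", "b2", "pipeline"),
             ("v2", 3.0, 30.0, "coupled", "b2", "pipeline")]
        )
        out, _ = kin.normalize_to_control(df, "ctrl", 10.0)
        v1 = out.loc[out["variant_id"] == "v1", "kcat_c"].iloc[0]
        v2 = out.loc[out["variant_id"] == "v2", "kcat_c"].iloc[0]
        assert v1 == pytest.approx(3.0 * 1.25)
        assert v2 == pytest.approx(3.0 * 0.8)

    def test_missing_control_batch_reported_and_untouched(self):
        df = table(
            [("ctrl", 8.0, 30.0, "coupled", "b1", "pipeline"),
             ("v1", 3.0, 30.0, "coupled", "b1", "pipeline"),
             ("v2", 5.0, 30.0, "coupled", "b2", "pipeline")]
        )
        out, report = kin.normalize_to_control(df, "ctrl", 10.0)
        assert report["batch_id"].tolist() == ["b2"]
        v2 = out.loc[out["variant_id"] == "v2"]
        assert v2["kcat_c"].iloc[0] == pytest.approx(5.0)
        assert not v2["control_normalized"].iloc[0]

    def test_batch_control_geometric_mean_hits_reference(self):
        rng = np.random.default_rng(1)
        rows = []
        for b in range(4):
            for _ in range(3):
                rows.append(("ctrl", float(rng.lognormal(2, 0.4)), 30.0, "coupled", f"b{b}", "pipeline"))
            rows.append((f"v{b}", float(rng.lognormal(1, 0.4)), 30.0, "coupled", f"b{b}", "pipeline"))
        out, _ = kin.normalize_to_control(table(rows), "ctrl", 10.0)
        for b, sub in out.groupby("batch_id"):
            ctrl = sub.loc[sub["variant_id"] == "ctrl", "kcat_c"].to_numpy(float)
            assert np.exp(np.log(ctrl).mean()) == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# Assay correction
# ---------------------------------------------------------------------------

class TestFitAssayCorrection:
    def test_equal_pairs_give_factor_one_point_interval(self):
        fit = kin.fit_assay_correction([(3.0, 3.0), (7.0, 7.0), (1.0, 1.0)])
        assert fit.factor == pytest.approx(1.0)
        assert fit.ci_low == pytest.approx(1.0)
        assert fit.ci_high == pytest.approx(1.0)

    def test_constant_log_ratio(self):
        fit = kin.fit_assay_correction([(1.0, 2.0), (2.0, 4.0)])
        assert fit.factor == pytest.approx(2.0)

    def test_scale_invariance_of_both_members(self):
        rng = np.random.default_rng(2)
        pairs = rng.lognormal(1, 0.3, size=(8, 2))
        a = kin.fit_assay_correction(pairs)
        b = kin.fit_assay_correction(pairs * 37.5)
        assert a.factor == pytest.approx(b.factor)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_scaling_direct_scales_factor(self):
        rng = np.random.default_rng(3)
        pairs = rng.lognormal(1, 0.3, size=(8, 2))
        a = kin.fit_assay_correction(pairs)
        scaled = pairs.copy()
        scaled[:, 1] *= 3.0
        b = kin.fit_assay_correction(scaled)
        assert b.factor == pytest.approx(3.0 * a.factor)

    def test_t_interval_matches_direct_formula(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        pairs = rng.lognormal(1, 0.3, size=(11, 2))
        fit = kin.fit_assay_correction(pairs)
        lr = np.log(pairs[:, 1] / pairs[:, 0])
        half = stats.t.ppf(0.975, 10) * lr.std(ddof=1) / np.sqrt(11)
        assert fit.ci_low == pytest.approx(np.exp(lr.mean() - half))
        assert fit.ci_high == pytest.approx(np.exp(lr.mean() + half))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kin.fit_assay_correction([(1.0, 2.0)])
        with pytest.raises(ValueError):
            kin.fit_assay_correction([(1.0, 2.0), (0.0, 1.0)])


class TestApplyCorrection:
    def test_factor_one_is_identity(self):
        df = table([("v1", 10.0, 30.0, "coupled", "b1", "pipeline")])
        out = kin.apply_correction(df, 1.0)
        assert out["kcat_c"].iloc[0] == pytest.approx(10.0)

    def test_study_scale_factor(self):
        df = table([("v1", 10.0, 30.0, "coupled", "b1", "pipeline")])
        out = kin.apply_correction(df, 2.1)
        assert out["kcat_c"].iloc[0] == pytest.approx(21.0)

    def test_order_preserved_and_double_application_refused(self):
        df = table(
            [(f"v{i}", float(i + 1), 30.0, "coupled", "b1", "pipeline") for i in range(5)]
        )
        out = kin.apply_correction(df, 2.0)
        assert out["variant_id"].tolist() == [f"v{i}" for i in range(5)]
        with pytest.raises(ValueError, match="already"):
            kin.apply_correction(out, 2.0)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

class TestSummarizeRates:
    def test_odd_and_even_medians(self):
        df = table([(f"v{i}", r, 30.0, "direct", None, "literature") for i, r in enumerate([1.0, 2.0, 3.0])])
        assert kin.summarize_rates(df)[0].median == pytest.approx(2.0)
        df = table([(f"v{i}", r, 30.0, "direct", None, "literature") for i, r in enumerate([4.0, 6.0])])
        assert kin.summarize_rates(df)[0].median == pytest.approx(5.0)

    def test_quantiles_match_sort_based_oracle(self):
        rng = np.random.default_rng(5)
        rates = rng.lognormal(1.5, 0.6, size=100)
        df = table([(f"v{i}", float(r), 30.0, "direct", None, "literature") for i, r in enumerate(rates)])
        s = kin.summarize_rates(df)[0]

        def interp_quantile(values, q):
            v = sorted(values)
            h = (len(v) - 1) * q
            lo = int(np.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

        assert s.median == pytest.approx(interp_quantile(rates, 0.5))
        assert s.q25 == pytest.approx(interp_quantile(rates, 0.25))
        assert s.q75 == pytest.approx(interp_quantile(rates, 0.75))
        assert s.q25 <= s.median <= s.q75

    def test_mixed_temperatures_refused(self):
        df = table(
            [("v1", 1.0, 30.0, "direct", None, "literature"),
             ("v2", 1.0, 25.0, "direct", None, "literature")]
        )
        with pytest.raises(ValueError, match="temperature"):
            kin.summarize_rates(df)

    def test_per_form_grouping(self):
        df = table(
            [("a", 2.0, 30.0, "direct", None, "literature"),
             ("b", 8.0, 30.0, "direct", None, "literature")]
        )
        out = kin.summarize_rates(df, forms={"a": "II", "b": "III"}, group_by="form")
        assert {s.group for s in out} == {"II", "III"}

    def test_literature_replicates_collapse_by_median(self):
        df = table(
            [("v1", 2.0, 30.0, "direct", None, "literature"),
             ("v1", 4.0, 30.0, "direct", None, "literature"),
             ("v1", 9.0, 30.0, "direct", None, "literature")]
        )
        collapsed = kin.collapse_replicates(df)
        assert collapsed["v1"] == pytest.approx(4.0)

    def test_pipeline_replicates_collapse_by_geometric_mean(self):
        df = table(
            [("v1", 2.0, 30.0, "coupled", "b1", "pipeline"),
             ("v1", 8.0, 30.0, "coupled", "b2", "pipeline")]
        )
        collapsed = kin.collapse_replicates(df)
        assert collapsed["v1"] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# Rate ratio vs identity
# ---------------------------------------------------------------------------

class TestRateRatioVsIdentity:
    def make_aln(self):
        return AlignedSeqSet(
            ids=["v1", "v2", "v3"],
            rows=["AAAAAAAAAA", "GAAAAAAAAA", "AAAAACCCCC"],
        )  # id(v1,v2)=0.9, id(v1,v3)=0.5, id(v2,v3)=0.4

    def rates(self, values):
        return table(
            [(f"v{i+1}", v, 30.0, "direct", None, "literature") for i, v in enumerate(values)]
        )

    def test_equal_rates_all_ratios_one(self):
        res = kin.rate_ratio_vs_identity(self.rates([5.0, 5.0, 5.0]), self.make_aln())
        assert all(r == 1.0 for bin_ in res.ratios for r in bin_)

    def test_hand_enumeration_of_three_pairs(self):
        res = kin.rate_ratio_vs_identity(
            self.rates([2.0, 4.0, 8.0]), self.make_aln(), bins=(0.0, 0.45, 0.8, 1.0)
        )
        # pairs: (v1,v2) id .9 ratio 2 ; (v1,v3) id .5 ratio 4 ; (v2,v3) id .4 ratio 2
        assert res.n_pairs == 3
        assert res.medians[0] == pytest.approx(2.0)  # [0, .45): (v2,v3)
        assert res.medians[1] == pytest.approx(4.0)  # [.45, .8): (v1,v3)
        assert res.medians[2] == pytest.approx(2.0)  # [.8, 1]: (v1,v2)

    def test_pair_count(self):
        rng = np.random.default_rng(6)
        n = 10
        ids = [f"v{i+1}" for i in range(n)]
        aln = AlignedSeqSet(ids=ids, rows=["A" * 10] * 1 + [
            "".join(rng.choice(list("ACDE"), 10)) for _ in range(n - 1)
        ])
        df = table([(v, float(rng.lognormal(1, 0.3)), 30.0, "direct", None, "literature") for v in ids])
        res = kin.rate_ratio_vs_identity(df, aln, bins=(0.0, 1.0))
        assert res.n_pairs == n * (n - 1) // 2

    def test_missing_variants_excluded_and_reported(self):
        df = self.rates([2.0, 4.0, 8.0])
        df.loc[len(df)] = ["zz", 1.0, 30.0, "direct", None, "literature", False, False, False]
        res = kin.rate_ratio_vs_identity(df, self.make_aln())
        assert res.excluded_variants == ["zz"]

    def test_all_ratios_at_least_one(self, small_dataset):
        res = kin.rate_ratio_vs_identity(small_dataset.records[
            small_dataset.records["variant_id"] != "control"
        ], small_dataset.aln)
        assert all(r >= 1.0 for bin_ in res.ratios for r in bin_)
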