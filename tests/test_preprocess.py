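import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exonmark import preprocess as pp

from conftest import measurement_frame, track


class TestEnrichmentRatio:
    def test_hand_computed_ratios(self):
        df = measurement_frame(
            ["a", "b"], chip=[200, 100], input_=[300, 150], chip_bg=50, input_bg=[100, 50]
        )
        t = pp.enrichment_ratio(df)
        # raw ratios 0.75 and 0.50, median 0.625
        np.testing.assert_allclose(t.values.to_numpy(), [1.2, 0.8])
        assert t.state == "ratio"

    def test_self_ratio_is_one(self):
        df = measurement_frame(["a"], chip=[200], input_=[200], chip_bg=50, input_bg=50)
        assert pp.enrichment_ratio(df).values.iloc[0] == 1.0

    def test_zero_denominator_is_missing(self):
        df = measurement_frame(["a", "b"], chip=[200, 200], input_=[100, 300], input_bg=100)
        t = pp.enrichment_ratio(df)
        assert np.isnan(t.values["a"]) and np.isfinite(t.values["b"])

    def test_negative_ratio_and_flag_excluded(self):
        df = measurement_frame(
            ["a", "b", "c"], chip=[50, 200, 200], input_=[200, 200, 200],
            chip_bg=100, flag=["ok", "not_found", "ok"],
        )
        t = pp.enrichment_ratio(df)
        assert np.isnan(t.values["a"])  # chip below background
        assert np.isnan(t.values["b"])  # flagged spot
        assert t.values["c"] == 1.0

    def test_duplicate_spots_averaged_before_median_scaling(self):
        df = pd.concat(
            [
                measurement_frame(["a", "b"], chip=[100, 300], input_=[100, 100]),
                measurement_frame(["a"], chip=[300, ], input_=[100]),
            ],
            ignore_index=True,
        )
        t = pp.enrichment_ratio(df)  # a: mean(1,3)=2; b: 3; median 2.5
        np.testing.assert_allclose(t.values.to_numpy(), [0.8, 1.2])

    def test_all_missing_raises(self):
        df = measurement_frame(["a"], chip=[10], input_=[100], chip_bg=50)
        with pytest.raises(ValueError, match="empty track"):
            pp.enrichment_ratio(df)


class TestCompositeMedian:
    def test_odd_count_median(self):
        tracks = [track({"a": v}, state="ratio") for v in (0.8, 1.0, 1.4)]
        assert pp.composite_median(tracks).values["a"] == 1.0

    def test_median_ignores_missing(self):
        tracks = [track({"a": 0.8}, state="ratio"),
                  track({"a": np.nan}, state="ratio"),
                  track({"a": 1.4}, state="ratio")]
        np.testing.assert_allclose(pp.composite_median(tracks).values["a"], 1.1)

    def test_single_replicate_identity(self):
        t = track({"a": 0.7, "b": 1.3}, state="ratio")
        pd.testing.assert_series_equal(pp.composite_median([t]).values, t.values)

    def test_mismatched_tiles_raise(self):
        with pytest.raises(ValueError, match="mismatched"):
            pp.composite_median([track({"a": 1.0}), track({"b": 1.0})])


class TestNormalizeByTrack:
    def test_quotient(self):
        t = pp.normalize_by_track(track({"a": 2.0, "b": 4.0}, state="composite"),
                                  track({"a": 1.0, "b": 2.0}, state="composite"))
        np.testing.assert_allclose(t.values.to_numpy(), [2.0, 2.0])
        assert t.state == "normalized"

    def test_unit_denominator_identity(self):
        vals = {"a": 0.5, "b": 2.0}
        t = pp.normalize_by_track(track(vals, state="composite"),
                                  track({"a": 1.0, "b": 1.0}, state="composite"))
        np.testing.assert_allclose(t.values.to_numpy(), list(vals.values()))

    def test_nonpositive_denominator_propagates_missing(self):
        t = pp.normalize_by_track(track({"a": 2.0, "b": 2.0}, state="composite"),
                                  track({"a": 0.0, "b": np.nan}, state="composite"))
        assert t.values.isna().all()

    def test_self_normalization_is_unity(self):
        t = track({"a": 0.5, "b": 2.0, "c": np.nan}, state="composite")
        out = pp.normalize_by_track(t, t)
        np.testing.assert_allclose(out.values[["a", "b"]].to_numpy(), [1.0, 1.0])


class TestZScores:
    def test_unit_sd_case(self):
        t = track({k: 2.0 ** v for k, v in zip("abc", [1, 2, 3])}, state="composite")
        z = pp.to_zscores(t)
        np.testing.assert_allclose(z.values.to_numpy(), [-1, 0, 1], atol=1e-12)

    def test_hand_computed_four_values(self):
        t = track({k: 2.0 ** v for k, v in zip("abcd", [1, 3, 5, 7])}, state="composite")
        z = pp.to_zscores(t)
        np.testing.assert_allclose(
            z.values.to_numpy(), [-1.162, -0.387, 0.387, 1.162], atol=5e-4
        )

    def test_invariant_median_zero_sd_one(self, small_study):
        from exonmark.pipeline import preprocess_mark
        m = small_study.measurements
        z = preprocess_mark(m["mark"], m["h2b"], m["h3"]).zscore
        assert abs(z.values.median()) < 1e-9
        assert abs(z.values.std(ddof=1) - 1.0) < 1e-9

    def test_constant_track_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            pp.to_zscores(track({"a": 1.0, "b": 1.0, "c": 1.0}, state="composite"))

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError, match="degenerate|fewer"):
            pp.to_zscores(track({"a": 1.0, "b": 2.0}, state="composite"))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=20)
    def test_scale_invariance_of_zscores(self, factor):
        """Multiplying one channel's intensities rescales ratios but not Z."""
        rng = np.random.default_rng(0)
        chip = rng.uniform(50, 500, size=20)
        inp = rng.uniform(50, 500, size=20)
        ids = [f"t{i}" for i in range(20)]
        base = pp.to_zscores(pp.enrichment_ratio(measurement_frame(ids, chip, inp)))
        scaled = pp.to_zscores(
            pp.enrichment_ratio(measurement_frame(ids, chip * factor, inp))
        )
        np.testing.assert_allclose(
            base.values.to_numpy(), scaled.values.to_numpy(), rtol=1e-9
        )


class TestSeqChip:
    def test_control_subtraction_hand_example(self):
        exp = measurement_frame(["a", "b"], chip=[300, 150], input_=[200, 100])
        ctrl = measurement_frame(["a", "b"], chip=[100, 50], input_=[200, 100])
        t = pp.seqchip_ratio(exp, ctrl)
        # corrected chip (200, 100) over inputs (200, 100) -> ratios equal,
        # median-centred to 1; log2 centring would give zeros
        np.testing.assert_allclose(t.values.to_numpy(), [1.0, 1.0])
        np.testing.assert_allclose(np.log2(t.values.to_numpy()), [0.0, 0.0])

    def test_zero_control_reduces_to_standard_chain(self):
        exp = measurement_frame(["a", "b", "c"], chip=[300, 150, 220], input_=[200, 100, 200])
        ctrl = measurement_frame(["a", "b", "c"], chip=[1e-9, 1e-9, 1e-9], input_=[200, 100, 200])
        plain = pp.enrichment_ratio(exp)
        seq = pp.seqchip_ratio(exp, ctrl)
        np.testing.assert_allclose(seq.values.to_numpy(), plain.values.to_numpy(), rtol=1e-6)

    def test_equal_exp_and_control_is_empty(self):
        exp = measurement_frame(["a", "b"], chip=[300, 150], input_=[200, 100])
        with pytest.raises(ValueError, match="empty track"):
            pp.seqchip_ratio(exp, exp.copy())

    def test_replicate_input_scaling(self):
        # second replicate has double intensities; scaling by median input
        # makes the replicate average equal the single-replicate signal
        r1 = measurement_frame(["a", "b", "c"], chip=[300, 150, 200], input_=[200, 100, 150], replicate=1)
        r2 = measurement_frame(["a", "b", "c"], chip=[600, 300, 400], input_=[400, 200, 300], replicate=2)
        exp = pd.concat([r1, r2], ignore_index=True)
        ctrl = measurement_frame(["a", "b", "c"], chip=[1e-9] * 3, input_=[200, 100, 150])
        ctrl2 = ctrl.copy(); ctrl2["replicate"] = 2
        both = pp.seqchip_ratio(exp, pd.concat([ctrl, ctrl2], ignore_index=True))
        single = pp.seqchip_ratio(r1, ctrl)
        np.testing.assert_allclose(both.values.to_numpy(), single.values.to_numpy(), rtol=1e-6)


class TestAuditTrail:
    def test_record_is_append_only_chain(self, small_study):
        from exonmark.pipeline import preprocess_mark
        m = small_study.measurements
        z = preprocess_mark(m["mark"], m["h2b"], m["h3"], m["igg"],
                            histone_normalize=True, igg_normalize=True).zscore
        names = [name for name, _ in z.record]
        assert names == [
            "enrichment_ratio", "enrichment_ratio", "enrichment_ratio",
            "composite_median", "normalize_by_track", "normalize_by_track",
            "log2_centred", "zscore",
        ]

    def test_replay_reproduces_output_bitwise(self, small_study):
        from exonmark.pipeline import preprocess_mark
        m = small_study.measurements
        res = preprocess_mark(m["mark"], m["h2b"], m["h3"], histone_normalize=True)
        reps = [sub for _, sub in m["mark"].groupby("replicate", sort=True)]
        replayed = pp.replay_record(
            res.zscore.record, replicates=reps, controls=res.controls
        )
        assert (
            replayed.values.to_numpy().tobytes()
            == res.zscore.values.to_numpy().tobytes()
        )
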