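import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from exonmark import stats
from exonmark.annotation import ALTERNATIVE, BODY, CANONICAL, INTRON

from conftest import track


def assignment(rows):
    df = pd.DataFrame(
        rows, columns=["tile_id", "gene_id", "feature", "ordinal",
                       "rev_ordinal", "region"]
    )
    return df.set_index("tile_id")


class TestRandomizeTrack:
    def test_rows_are_permutations(self):
        tr = track({f"t{i}": float(i) for i in range(6)})
        out = stats.randomize_track(tr, R=5, seed=0)
        assert out.shape == (5, 6)
        for row in out:
            assert sorted(row) == [0, 1, 2, 3, 4, 5]

    def test_seed_determinism(self):
        tr = track({f"t{i}": float(i) for i in range(6)})
        a = stats.randomize_track(tr, R=3, seed=11)
        b = stats.randomize_track(tr, R=3, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs(self):
        tr = track({f"t{i}": float(i) for i in range(6)})
        with pytest.raises(ValueError):
            stats.randomize_track(tr, R=0)
        with pytest.raises(ValueError):
            stats.randomize_track(track({"a": 1.0, "b": np.nan}), R=2)


class TestBootstrap:
    @pytest.fixture
    def four_tile(self):
        """4 tiles, values 0..3; exon = the two low tiles."""
        tr = track({"t0": 0.0, "t1": 1.0, "t2": 2.0, "t3": 3.0})
        asn = assignment(
            [
                ("t0", "g", CANONICAL, 1, 1, BODY),
                ("t1", "g", CANONICAL, 1, 1, BODY),
                ("t2", "g", INTRON, 1, 1, BODY),
                ("t3", "g", INTRON, 1, 1, BODY),
            ]
        )
        return tr, asn

    def test_empirical_p_matches_exact_enumeration(self, four_tile):
        tr, asn = four_tile
        # exact permutation null of the exon mean (2 of 4 values):
        v = tr.values.to_numpy()
        means = [np.mean(p[:2]) for p in itertools.permutations(v)]
        means = np.asarray(means)
        centre = means.mean()
        obs = 0.5
        exact = np.mean(np.abs(means - centre) >= abs(obs - centre))  # = 1/3
        assert exact == pytest.approx(1 / 3)
        R = 4000
        res = stats.bootstrap_pvalues(tr, asn, R=R, seed=5,
                                      classes=(CANONICAL,))
        p = res.classes[CANONICAL].p_empirical
        mc_se = np.sqrt(exact * (1 - exact) / R)
        assert abs(p - exact) < 3 * mc_se + 2 / (R + 1)

    def test_observed_means_and_counts(self, four_tile):
        tr, asn = four_tile
        res = stats.bootstrap_pvalues(tr, asn, R=10, seed=0)
        assert res.classes[CANONICAL].observed == 0.5
        assert res.classes[INTRON].observed == 2.5
        assert res.classes[CANONICAL].n_tiles == 2
        assert ALTERNATIVE not in res.classes  # no tiles of that class

    def test_one_sided_options(self, four_tile):
        tr, asn = four_tile
        lo = stats.bootstrap_pvalues(tr, asn, R=200, seed=1, side="less")
        hi = stats.bootstrap_pvalues(tr, asn, R=200, seed=1, side="greater")
        assert lo.classes[CANONICAL].p_empirical < hi.classes[CANONICAL].p_empirical

    def test_seed_determinism_and_frame(self, four_tile):
        tr, asn = four_tile
        a = stats.bootstrap_pvalues(tr, asn, R=50, seed=7)
        b = stats.bootstrap_pvalues(tr, asn, R=50, seed=7)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
        cols = set(a.to_frame().columns)
        assert {"feature", "observed_mean", "p_empirical", "p_parametric"} <= cols

    def test_planted_effect_has_tiny_parametric_p(self, small_study):
        from exonmark.pipeline import preprocess_mark
        m = small_study.measurements
        tr = preprocess_mark(m["mark"], m["h2b"], m["h3"]).zscore
        res = stats.bootstrap_pvalues(tr, small_study.assignment, R=100, seed=3)
        assert res.classes[CANONICAL].p_parametric < 1e-10
        assert res.classes[CANONICAL].p_empirical <= 1 / 101 + 1e-12

    def test_empirical_p_never_zero_and_bounded(self, four_tile):
        tr, asn = four_tile
        res = stats.bootstrap_pvalues(tr, asn, R=20, seed=2)
        for cb in res.classes.values():
            assert 1 / 21 <= cb.p_empirical <= 1.0


class TestPairTTests:
    def test_welch_hand_example(self):
        rows = (
            [(f"e{i}", "g", CANONICAL, 2, 1, BODY) for i in range(3)]
            + [(f"i{i}", "g", INTRON, 1, 1, BODY) for i in range(3)]
        )
        tr = track({"e0": 1.0, "e1": 2.0, "e2": 3.0,
                    "i0": 0.0, "i1": 0.0, "i2": 1.0})
        res = stats.adjacent_pair_ttests(tr, assignment(rows), k_max=2)
        row = res.pairs.iloc[0]
        assert row["pair"] == "exon_2_vs_intron_1"
        np.testing.assert_allclose(row["t"], 2.5)
        np.testing.assert_allclose(row["df"], 3.2)
        np.testing.assert_allclose(row["p"], 0.0824417, atol=1e-6)
        assert res.median_p == row["p"]

    def test_nine_pairs_by_default(self, small_study):
        from exonmark.pipeline import preprocess_mark
        m = small_study.measurements
        tr = preprocess_mark(m["mark"], m["h2b"], m["h3"]).zscore
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = stats.adjacent_pair_ttests(tr, small_study.assignment)
        assert len(res.pairs) <= 9
        assert set(res.pairs["pair"]) <= {
            f"exon_{k}_vs_intron_{k - 1}" for k in range(2, 11)
        }
        # planted exon effect: exon means exceed preceding intron means
        assert res.pairs["t"].median() > 0
        assert res.median_p < 0.5

    def test_three_prime_mode_four_pairs(self, small_study):
        from exonmark.pipeline import preprocess_mark
        m = small_study.measurements
        tr = preprocess_mark(m["mark"], m["h2b"], m["h3"]).zscore
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = stats.adjacent_pair_ttests(
                tr, small_study.assignment, mode="three_prime"
            )
        assert len(res.pairs) <= 4
        assert res.mode == "three_prime"

    def test_degenerate_pairs_skipped_with_warning(self):
        rows = [
            ("e0", "g", CANONICAL, 2, 1, BODY),
            ("i0", "g", INTRON, 1, 1, BODY),
            ("i1", "g", INTRON, 1, 1, BODY),
        ]
        tr = track({"e0": 1.0, "i0": 0.0, "i1": 0.5})
        with pytest.warns(UserWarning, match="skipped"):
            res = stats.adjacent_pair_ttests(tr, assignment(rows), k_max=2)
        assert res.pairs.empty and np.isnan(res.median_p)


class TestBiasCalls:
    @pytest.mark.parametrize(
        "delta, p, expected",
        [
            (0.5, 0.01, "exon_bias"),
            (-0.5, 0.01, "intron_bias"),
            (0.5, 0.2, "none"),
            (0.0, 0.001, "none"),
            (np.nan, 0.001, "none"),
            (0.5, np.nan, "none"),
        ],
    )
    def test_bias_call(self, delta, p, expected):
        assert stats.bias_call(delta, p) == expected

    def test_alpha_is_strict(self):
        assert stats.bias_call(1.0, 0.05) == "none"
        assert stats.bias_call(1.0, 0.049) == "exon_bias"

    def test_concordance_counts(self):
        summaries = pd.DataFrame(
            {
                "dataset": ["A"] * 3 + ["B"] * 3,
                "mark": ["m1", "m2", "m3"] * 2,
                "delta_z": [0.5, -0.5, 0.4, 0.6, -0.4, -0.3],
                "p": [0.01, 0.01, 0.5, 0.01, 0.01, 0.01],
            }
        )
        calls, conc = stats.bias_call_and_concordance(summaries)
        # m1 agrees (exon bias both), m2 agrees (intron bias both),
        # m3 disagrees (none vs intron bias)
        row = conc.iloc[0]
        assert (row["dataset_a"], row["dataset_b"]) == ("A", "B")
        assert row["concordant"] == 2 and row["n_marks"] == 3

    def test_concordance_split_by_state(self):
        summaries = pd.DataFrame(
            {
                "dataset": ["A", "B"] * 2,
                "mark": ["m1"] * 4,
                "state": ["ON", "ON", "OFF", "OFF"],
                "delta_z": [0.5, 0.5, 0.5, -0.5],
                "p": [0.01] * 4,
            }
        )
        _, conc = stats.bias_call_and_concordance(summaries)
        by_state = conc.set_index("state")["concordant"]
        assert by_state["ON"] == 1 and by_state["OFF"] == 0
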