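import numpy as np
import pandas as pd
import pytest

from exonmark import io, simulate
from exonmark.annotation import ALTERNATIVE, CANONICAL, INTRON
from exonmark.pipeline import preprocess_mark
from exonmark.profiles import class_means


class TestSimConfig:
    def test_defaults_are_valid(self):
        simulate.SimConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"exon_count_range": (0, 3)},
            {"exon_count_range": (5, 3)},
            {"tile_length": 0},
            {"noise_sd": -1.0},
            {"n_transcripts_range": (0, 2)},
            {"alt_coupling": "sometimes"},
            {"p_alt": 1.5},
            {"alt_inclusion_levels": (0.0, 0.5)},
        ],
    )
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ValueError):
            simulate.SimConfig(**kwargs)

    def test_dict_round_trip(self):
        cfg = simulate.SimConfig(seed=9, n_genes=7, exon_effect=0.3)
        assert simulate.SimConfig.from_dict(cfg.to_dict()) == cfg


class TestAnnotationGenerator:
    def test_seed_determinism_byte_identical_gff(self, tmp_path):
        cfg = simulate.SimConfig(seed=5, n_genes=10)
        a = simulate.simulate_annotation(cfg)
        b = simulate.simulate_annotation(cfg)
        io.write_gff3(a, tmp_path / "a.gff3")
        io.write_gff3(b, tmp_path / "b.gff3")
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_gene_count_span_and_strands(self):
        cfg = simulate.SimConfig(seed=1, n_genes=20)
        genes = simulate.simulate_annotation(cfg)
        assert len(genes) == 20
        strands = [g.span.strand for g in genes.values()]
        assert strands[:4] == ["+", "-", "+", "-"]
        for g in genes.values():
            assert len(g.span) >= cfg.min_gene_span
            assert g.n_exons >= cfg.exon_count_range[0]

    def test_genes_do_not_overlap(self):
        genes = simulate.simulate_annotation(simulate.SimConfig(seed=2, n_genes=15))
        spans = sorted((g.span.start, g.span.end) for g in genes.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_round_trip_through_gff3(self, tmp_path):
        cfg = simulate.SimConfig(seed=7, n_genes=8, n_transcripts_range=(3, 3), p_alt=0.6)
        genes = simulate.simulate_annotation(cfg)
        io.write_gff3(genes, tmp_path / "g.gff3")
        back = io.read_annotation(tmp_path / "g.gff3")
        assert set(back) == set(genes)
        for gid, g in genes.items():
            h = back[gid]
            orig = {(e.interval.start, e.interval.end, e.cls, e.inclusion_fraction)
                    for e in g.exons}
            rt = {(e.interval.start, e.interval.end, e.cls, e.inclusion_fraction)
                  for e in h.exons}
            assert orig == rt

    def test_alternative_exons_exist_with_high_p_alt(self):
        cfg = simulate.SimConfig(seed=3, n_genes=15, n_transcripts_range=(4, 4), p_alt=0.8)
        genes = simulate.simulate_annotation(cfg)
        alts = [e for g in genes.values() for e in g.exons if e.cls == ALTERNATIVE]
        assert len(alts) > 0
        assert all(0 < e.inclusion_fraction < 1 for e in alts)


class TestTruthAndMeasurements:
    def test_tile_truth_effects(self):
        cfg = simulate.SimConfig(
            seed=4, n_genes=6, exon_effect=0.7, intron_effect=-0.2,
            density_exon_mult=1.5,
        )
        genes = simulate.simulate_annotation(cfg)
        tiles = simulate.make_tiles(cfg, genes)
        truth = simulate.tile_truth(cfg, genes, tiles)
        by = truth.groupby("feature")
        assert (by.get_group(CANONICAL)["true_log2"] == 0.7).all()
        assert (by.get_group(INTRON)["true_log2"] == -0.2).all()
        assert (by.get_group("intergenic")["true_log2"] == 0.0).all()
        assert (by.get_group(CANONICAL)["density"] == 1.5).all()
        assert (by.get_group(INTRON)["density"] == 1.0).all()

    def test_alternative_effect_is_inclusion_weighted(self):
        cfg = simulate.SimConfig(
            seed=4, n_genes=10, exon_effect=0.8,
            n_transcripts_range=(4, 4), p_alt=0.8,
        )
        genes = simulate.simulate_annotation(cfg)
        tiles = simulate.make_tiles(cfg, genes)
        truth = simulate.tile_truth(cfg, genes, tiles)
        alt = truth[truth["feature"] == ALTERNATIVE]
        assert len(alt) > 0
        assert ((alt["true_log2"] > 0) & (alt["true_log2"] < 0.8)).all()

    def test_zero_noise_chain_recovers_truth_exactly(self):
        cfg = simulate.SimConfig(
            seed=6, n_genes=10, exon_effect=0.7, intron_effect=-0.2,
            noise_sd=0.0, n_replicates=3,
        )
        study = simulate.simulate_study(cfg)
        m = study.measurements
        res = preprocess_mark(m["mark"], m["h2b"], m["h3"])
        t = study.truth["true_log2"]
        expected = t - np.median(t)
        got = res.log2_centred.values.reindex(t.index)
        np.testing.assert_allclose(got.to_numpy(), expected.to_numpy(), atol=1e-12)
        cs = class_means(res.log2_centred, study.assignment)
        np.testing.assert_allclose(cs.delta_z, 0.7 - (-0.2), atol=1e-12)

    def test_density_confound_removed_by_histone_normalization(self):
        cfg = simulate.SimConfig(
            seed=8, n_genes=10, exon_effect=0.0, intron_effect=0.0,
            density_exon_mult=1.5, noise_sd=0.0,
        )
        study = simulate.simulate_study(cfg)
        m = study.measurements
        # with zero noise the normalized track is exactly constant, so build
        # the log2-centred tracks directly (the Z step rightly refuses a
        # zero-variance track)
        from exonmark import preprocess as pp
        comp = pp.composite_from_measurements(m["mark"], "histone_mod")
        dens = pp.histone_density(
            pp.composite_from_measurements(m["h2b"], "histone_density"),
            pp.composite_from_measurements(m["h3"], "histone_density"),
        )
        raw = pp.log2_centred(comp)
        norm = pp.log2_centred(pp.normalize_by_track(comp, dens))
        d_raw = class_means(raw, study.assignment).delta_z
        d_norm = class_means(norm, study.assignment).delta_z
        np.testing.assert_allclose(d_raw, np.log2(1.5), atol=1e-12)
        np.testing.assert_allclose(d_norm, 0.0, atol=1e-12)

    def test_study_determinism(self):
        cfg = simulate.SimConfig(seed=11, n_genes=8)
        a = simulate.simulate_study(cfg)
        b = simulate.simulate_study(cfg)
        for name in a.measurements:
            pd.testing.assert_frame_equal(a.measurements[name], b.measurements[name])
        pd.testing.assert_series_equal(a.expression, b.expression)


class TestReads:
    def test_exact_count_and_domain(self):
        cfg = simulate.SimConfig(seed=12, n_genes=6, n_reads=5000)
        study = simulate.simulate_study(cfg)
        reads = simulate.simulate_reads(cfg, study.truth, np.random.default_rng(0))
        assert len(reads) == 5000
        lo = study.truth["start"].min()
        hi = study.truth["end"].max()
        assert (reads["start"] >= lo).all() and (reads["start"] < hi).all()
        assert (reads["end"] - reads["start"] == cfg.read_length).all()

    def test_reads_follow_planted_enrichment(self):
        cfg = simulate.SimConfig(seed=13, n_genes=10, exon_effect=2.0,
                                 noise_sd=0.0, n_reads=40_000)
        study = simulate.simulate_study(cfg)
        reads = simulate.simulate_reads(cfg, study.truth, np.random.default_rng(1))
        from exonmark import chipseq
        bt = chipseq.bin_reads(reads, bin_size=cfg.tile_length)
        assignment, _ = chipseq.assign_bins(bt, study.genes)
        assert chipseq.class_mean_difference(assignment) > 0


class TestExpression:
    def test_percentile_range_and_determinism(self):
        cfg = simulate.SimConfig(seed=14, n_genes=40)
        genes = simulate.simulate_annotation(cfg)
        v1, t1 = simulate.simulate_expression(cfg, genes, np.random.default_rng(5))
        v2, t2 = simulate.simulate_expression(cfg, genes, np.random.default_rng(5))
        pd.testing.assert_series_equal(v1, v2)
        assert t1["percentile"].between(0, 100, inclusive="left").all()
        assert t1["decile"].between(0, 9).all()

    def test_expression_coupling_is_monotone(self):
        cfg = simulate.SimConfig(seed=15, n_genes=40, expr_coupling=0.5)
        genes = simulate.simulate_annotation(cfg)
        _, truth = simulate.simulate_expression(cfg, genes, np.random.default_rng(2))
        srt = truth.sort_values("percentile")
        assert (np.diff(srt["effect_scale"]) >= 0).all()
        assert srt["effect_scale"].between(0.5, 1.5).all()

    def test_zero_coupling_gives_unit_scale(self):
        cfg = simulate.SimConfig(seed=16, n_genes=10)
        genes = simulate.simulate_annotation(cfg)
        _, truth = simulate.simulate_expression(cfg, genes, np.random.default_rng(3))
        np.testing.assert_allclose(truth["effect_scale"], 1.0)
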