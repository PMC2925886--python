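"""Statistical validation of the pipeline on synthetic data with known truth.

Each function here runs one self-contained property check end to end on
generated datasets and returns plain summary numbers, so the same code path
backs both the automated test suite and the command-line summary script:

- :func:`null_calibration` — the coordinate-randomization test rejects at
  its nominal rate when no exon/intron effect is planted.
- :func:`enumeration_check` — the Monte-Carlo empirical p converges to the
  exhaustively enumerated permutation p on a small instance.
- :func:`effect_recovery` — a planted exon effect is recovered within a
  stated tolerance and flagged as significant.
- :func:`confound_removal` — a pure nucleosome-density confound is reported
  by the unnormalized chain and removed by histone-density normalization.
- :func:`alt_intermediacy` — inclusion-weighted alternative exons score
  between canonical exons and introns.
- :func:`exactness` — at zero noise the normalization chain recovers the
  planted log2 difference to machine precision and Z-tracks are exactly
  standardized.
- :func:`platform_concordance` — tiling-array and short-read paths driven by
  the same occupancy agree on the direction of exon bias.
- :func:`micro_examples` — the hand-computed worked examples from the module
  documentation.

Effect-recovery checks use a tile/feature geometry guaranteeing at least
five tiles per exon and per intron (100 b tiles over fixed 600 b exons and
1500 b introns) so per-class means are estimable run by run; calibration and
concordance checks run on the default study geometry. All randomness derives
from a single integer seed.
"""

from __future__ import annotations

import itertools
from typing import Callable

import numpy as np
import pandas as pd

from . import annotation, chipseq, preprocess, profiles, simulate, stats
from .pipeline import preprocess_mark

#: geometry with >= 5 tiles in every exon and intron (tile midpoints fall
#: every 100 b, so a 600 b exon holds 5-6 and a 1500 b intron 14-15)
DENSE_GEOMETRY = dict(
    tile_length=100,
    exon_length_median=600.0,
    exon_length_sigma=0.0,
    intron_length_median=1500.0,
    intron_length_sigma=0.0,
)


def _spawn(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit run seeds from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _mark_zscore(study) -> preprocess.TileTrack:
    m = study.measurements
    return preprocess_mark(m["mark"], m["h2b"], m["h3"]).zscore


def _mark_log2(study, histone_normalize: bool = True) -> preprocess.TileTrack:
    m = study.measurements
    comp = preprocess.composite_from_measurements(m["mark"], "histone_mod")
    if histone_normalize:
        dens = preprocess.histone_density(
            preprocess.composite_from_measurements(m["h2b"], "histone_density"),
            preprocess.composite_from_measurements(m["h3"], "histone_density"),
        )
        comp = preprocess.normalize_by_track(comp, dens)
    return preprocess.log2_centred(comp)


def null_calibration(
    seed: int = 0,
    n_datasets: int = 200,
    n_genes: int = 50,
    R: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Empirical-p rejection rate for the canonical-exon mean with no effect.

    Returns the fraction of datasets whose two-sided empirical p falls at or
    below ``alpha``; for a calibrated test this tracks ``alpha``.
    """
    rejections = 0
    for s in _spawn(seed, n_datasets):
        cfg = simulate.SimConfig(seed=int(s), n_genes=n_genes)
        study = simulate.simulate_study(cfg)
        tr = _mark_zscore(study)
        boot = stats.bootstrap_pvalues(
            tr, study.assignment, R=R, seed=np.random.default_rng([int(s), 1]),
            classes=(annotation.CANONICAL,),
        )
        if boot.classes[annotation.CANONICAL].p_empirical <= alpha:
            rejections += 1
    return {"value": rejections / n_datasets, "n": n_datasets}


def enumeration_check(seed: int = 0, R: int = 10_000, n_tiles: int = 8, k: int = 3) -> dict:
    """|Monte-Carlo empirical p - exact enumerated p| on a small instance.

    Returns the absolute difference together with the 3-SE + discreteness
    bound it should fall under.
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(size=n_tiles)
    ids = [f"t{i}" for i in range(n_tiles)]
    tr = preprocess.TileTrack(
        values=pd.Series(values, index=ids),
        assay_kind="histone_mod",
        state="zscore",
    )
    asn = pd.DataFrame(
        {
            "gene_id": "g",
            "feature": [annotation.CANONICAL] * k + [annotation.INTRON] * (n_tiles - k),
            "ordinal": 1,
            "rev_ordinal": 1,
            "region": annotation.BODY,
        },
        index=pd.Index(ids, name="tile_id"),
    )
    p_exact = stats.exact_permutation_pvalue(tr, asn)
    boot = stats.bootstrap_pvalues(
        tr, asn, R=R, seed=rng, classes=(annotation.CANONICAL,)
    )
    p_mc = boot.classes[annotation.CANONICAL].p_empirical
    bound = 3 * np.sqrt(p_exact * (1 - p_exact) / R) + 2 / (R + 1)
    return {
        "value": abs(p_mc - p_exact),
        "n": R,
        "p_exact": p_exact,
        "p_monte_carlo": p_mc,
        "bound": float(bound),
    }


def _per_run(seed: int, n_runs: int, fn: Callable[[int], bool]) -> dict:
    ok = sum(bool(fn(int(s))) for s in _spawn(seed, n_runs))
    return {"value": ok / n_runs, "n": n_runs}


def effect_recovery(
    seed: int = 0,
    n_runs: int = 100,
    delta: float = 0.5,
    n_genes: int = 100,
    tolerance: float = 0.1,
    p_threshold: float = 0.01,
    R: int = 100,
) -> dict:
    """Fraction of runs recovering a planted exon effect.

    A run succeeds when the log2-scale exon-intron difference lies within
    ``tolerance`` of ``delta`` and the canonical-class parametric p is below
    ``p_threshold``.
    """

    def one(s: int) -> bool:
        cfg = simulate.SimConfig(
            seed=s, n_genes=n_genes, exon_effect=delta, **DENSE_GEOMETRY
        )
        study = simulate.simulate_study(cfg)
        lc = _mark_log2(study)
        d = profiles.class_means(lc, study.assignment).delta_z
        boot = stats.bootstrap_pvalues(
            lc, study.assignment, R=R, seed=np.random.default_rng([s, 1]),
            classes=(annotation.CANONICAL,),
        )
        p = boot.classes[annotation.CANONICAL].p_parametric
        return abs(d - delta) <= tolerance and p < p_threshold

    return _per_run(seed, n_runs, one)


def confound_removal(
    seed: int = 0,
    n_runs: int = 100,
    density_mult: float = 1.5,
    n_genes: int = 50,
    R: int = 100,
) -> dict:
    """Detection and removal rates for a pure nucleosome-density confound.

    Each run plants no modification effect but multiplies exon nucleosome
    density by ``density_mult``. The unnormalized chain must report
    |difference| > 0.2 with p < 0.01; the histone-normalized chain must
    report |difference| < 0.05 with p > 0.05. Returns both success
    fractions (``value`` is their minimum).
    """
    unnorm_ok = 0
    norm_ok = 0
    for s in _spawn(seed, n_runs):
        s = int(s)
        # the +/-0.05 clean-run tolerance needs a per-run standard error well
        # below 0.05, hence the dense tile-per-feature geometry
        cfg = simulate.SimConfig(
            seed=s, n_genes=n_genes, density_exon_mult=density_mult,
            **DENSE_GEOMETRY,
        )
        study = simulate.simulate_study(cfg)
        for normalized in (False, True):
            lc = _mark_log2(study, histone_normalize=normalized)
            d = profiles.class_means(lc, study.assignment).delta_z
            boot = stats.bootstrap_pvalues(
                lc, study.assignment, R=R,
                seed=np.random.default_rng([s, int(normalized)]),
                classes=(annotation.CANONICAL,),
            )
            p = boot.classes[annotation.CANONICAL].p_parametric
            if normalized:
                norm_ok += abs(d) < 0.05 and p > 0.05
            else:
                unnorm_ok += abs(d) > 0.2 and p < 0.01
    return {
        "value": min(unnorm_ok, norm_ok) / n_runs,
        "n": n_runs,
        "unnormalized_detect_rate": unnorm_ok / n_runs,
        "normalized_clean_rate": norm_ok / n_runs,
    }


def alt_intermediacy(
    seed: int = 0, n_runs: int = 100, delta: float = 0.5, n_genes: int = 50
) -> dict:
    """Fraction of runs where alternative exons score strictly between
    canonical exons and introns under inclusion-weighted marking."""

    def one(s: int) -> bool:
        cfg = simulate.SimConfig(
            seed=s,
            n_genes=n_genes,
            exon_effect=delta,
            n_transcripts_range=(4, 4),
            p_alt=0.5,
            **DENSE_GEOMETRY,
        )
        study = simulate.simulate_study(cfg)
        cs = profiles.class_means(_mark_zscore(study), study.assignment)
        can = cs.class_mean(annotation.CANONICAL)
        alt = cs.class_mean(annotation.ALTERNATIVE)
        intr = cs.class_mean(annotation.INTRON)
        return intr < alt < can

    return _per_run(seed, n_runs, one)


def exactness(
    seed: int = 0, exon_effect: float = 0.7, intron_effect: float = -0.2
) -> dict:
    """Machine-precision checks on a zero-noise run.

    Returns the absolute error of the recovered exon-intron log2 difference
    against the planted value, plus the Z-track's |median| and |SD - 1|.
    """
    cfg = simulate.SimConfig(
        seed=seed, n_genes=50, exon_effect=exon_effect,
        intron_effect=intron_effect, noise_sd=0.0,
    )
    study = simulate.simulate_study(cfg)
    lc = _mark_log2(study)
    d = profiles.class_means(lc, study.assignment).delta_z
    z = preprocess.to_zscores(lc)
    zv = z.values.to_numpy(float)
    return {
        "value": abs(d - (exon_effect - intron_effect)),
        "n": int(np.isfinite(zv).sum()),
        "z_median_abs": float(abs(np.nanmedian(zv))),
        "z_sd_abs_error": float(abs(np.nanstd(zv, ddof=1) - 1.0)),
    }


def platform_concordance(
    seed: int = 0, n_runs: int = 100, delta: float = 0.5, n_genes: int = 50
) -> dict:
    """Fraction of runs where array and sequencing paths agree on bias sign."""

    def one(s: int) -> bool:
        cfg = simulate.SimConfig(seed=s, n_genes=n_genes, exon_effect=delta)
        study = simulate.simulate_study(cfg)
        d_chip = profiles.class_means(_mark_zscore(study), study.assignment).delta_z
        reads = simulate.simulate_reads(
            cfg, study.truth, np.random.default_rng([s, 2])
        )
        bt = chipseq.bin_reads(reads, bin_size=200)
        bin_assign, _ = chipseq.assign_bins(bt, study.genes)
        d_seq = chipseq.class_mean_difference(bin_assign)
        return np.sign(d_chip) == np.sign(d_seq) != 0

    return _per_run(seed, n_runs, one)


def micro_examples() -> dict:
    """Recompute the worked examples from the module documentation.

    Returns the computed numbers; their reference values are asserted by the
    test suite (ratios 1.2/0.8; Z set +/-1.162, +/-0.387; Welch t 1.964 with
    df 2.88; one-sided enumeration p 1/6).
    """
    # two-spot enrichment ratio example
    frame = pd.DataFrame(
        {
            "tile_id": ["a", "b"],
            "chrom": "chr1",
            "start": [0, 100],
            "end": [100, 200],
            "replicate": 1,
            "chip": [200.0, 100.0],
            "chip_bg": [50.0, 50.0],
            "input": [300.0, 150.0],
            "input_bg": [100.0, 50.0],
            "flag": "ok",
        }
    )
    ratios = preprocess.enrichment_ratio(frame).values

    # four-tile Z-score example from log2 values {1, 3, 5, 7}
    t = preprocess.TileTrack(
        values=pd.Series(
            np.exp2([1.0, 3.0, 5.0, 7.0]), index=["a", "b", "c", "d"]
        ),
        assay_kind="histone_mod",
        state="composite",
    )
    zs = preprocess.to_zscores(t).values

    # Welch t-test example: exon {1,2,3} vs intron {0,1}
    from scipy import stats as sps

    welch = sps.ttest_ind([1.0, 2.0, 3.0], [0.0, 1.0], equal_var=False)

    # one-sided enumeration example: values {1,2,3,4}, exon holds {3,4}
    means = [np.mean(c) for c in itertools.combinations([1.0, 2.0, 3.0, 4.0], 2)]
    p_enum = float(np.mean(np.asarray(means) >= 3.5))

    return {
        "ratios": [float(x) for x in ratios],
        "zscores": [float(x) for x in zs],
        "welch_t": float(welch.statistic),
        "welch_df": float(welch.df),
        "enumeration_p_greater": p_enum,
    }


def run_all(seed: int, quick: bool = False) -> dict:
    """Run every validation check with seeds derived from one master seed.

    Returns short-named summary quantities; ``quick`` shrinks the run counts
    for smoke testing.
    """
    seeds = _spawn(seed, 8)
    n = 10 if quick else 100
    nd = 20 if quick else 200
    cal = null_calibration(int(seeds[0]), n_datasets=nd)
    enum_res = enumeration_check(int(seeds[1]))
    rec = effect_recovery(int(seeds[2]), n_runs=n)
    conf = confound_removal(int(seeds[3]), n_runs=n)
    alt = alt_intermediacy(int(seeds[4]), n_runs=n)
    exact = exactness(int(seeds[5]))
    conc = platform_concordance(int(seeds[6]), n_runs=n)
    micro = micro_examples()
    return {
        "null_rejection_rate": {"value": cal["value"], "n": cal["n"]},
        "enumeration_p_abs_error": {"value": enum_res["value"], "n": enum_res["n"]},
        "effect_recovery_rate": {"value": rec["value"], "n": rec["n"]},
        "confound_unnormalized_detect_rate": {
            "value": conf["unnormalized_detect_rate"],
            "n": conf["n"],
        },
        "confound_normalized_clean_rate": {
            "value": conf["normalized_clean_rate"],
            "n": conf["n"],
        },
        "alt_exon_intermediacy_rate": {"value": alt["value"], "n": alt["n"]},
        "zero_noise_delta_abs_error": {"value": exact["value"], "n": exact["n"]},
        "zscore_sd_abs_error": {"value": exact["z_sd_abs_error"], "n": exact["n"]},
        "platform_concordance_rate": {"value": conc["value"], "n": conc["n"]},
        "welch_example_t": {"value": micro["welch_t"], "n": 5},
        "enumeration_example_p": {"value": micro["enumeration_p_greater"], "n": 6},
    }
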