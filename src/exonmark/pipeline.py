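"""End-to-end orchestration: simulate -> preprocess -> assign -> profile -> stats.

A run is driven by a YAML/JSON config with up to three blocks:

``simulate``
    :class:`exonmark.simulate.SimConfig` fields; when present, fixtures are
    generated into the output directory.
``inputs``
    Paths to externally supplied annotation/tiles/measurements/expression/
    reads. Referenced files are checked before any computation.
``analysis``
    Switches: ``randomizations`` (R), ``mode``, ``alpha``, ``min_span``,
    ``min_exons``, ``relaxed``, ``histone_normalize``, ``igg_normalize``,
    ``expression_split`` and ``bin_size``.

Every emitted table starts with a ``# seed=...`` comment and the applied
normalization steps are dumped alongside as JSON, so any stage can be
re-run from the previous stage's files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from types import SimpleNamespace
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotation, chipseq, expression, io, profiles, simulate, stats
from .preprocess import (
    TileTrack,
    composite_from_measurements,
    histone_density,
    log2_centred,
    normalize_by_track,
    to_zscores,
)

logger = logging.getLogger("exonmark")


class PipelineError(RuntimeError):
    pass


class MissingInputError(PipelineError):
    pass


class SchemaError(PipelineError):
    pass


def _write_table(df: pd.DataFrame, path: Path, seed, record=None, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        if record is not None:
            steps = ";".join(name for name, _ in record)
            fh.write(f"# normalization={steps}\n")
        df.to_csv(fh, sep="\t", index=index)


def preprocess_mark(
    measurements: pd.DataFrame,
    h2b: pd.DataFrame | None = None,
    h3: pd.DataFrame | None = None,
    igg: pd.DataFrame | None = None,
    histone_normalize: bool = True,
    igg_normalize: bool = False,
    assay_kind: str = "histone_mod",
) -> SimpleNamespace:
    """Run the full array chain for one mark from raw measurement tables.

    Returns a namespace with ``composite``, ``log2_centred`` and ``zscore``
    tracks (plus the control composites that were applied).
    """
    controls = {}
    track = composite_from_measurements(measurements, assay_kind)
    comp = track
    if histone_normalize:
        if h2b is None or h3 is None:
            raise MissingInputError("histone normalization requires H2B and H3 measurements")
        dens = histone_density(
            composite_from_measurements(h2b, "histone_density"),
            composite_from_measurements(h3, "histone_density"),
        )
        controls["histone_density"] = dens
        track = normalize_by_track(track, dens)
    if igg_normalize:
        if igg is None:
            raise MissingInputError("IgG normalization requires IgG measurements")
        iggc = composite_from_measurements(igg, "igg_control")
        controls["igg_control"] = iggc
        track = normalize_by_track(track, iggc)
    lc = log2_centred(track)
    return SimpleNamespace(
        composite=comp, controls=controls, log2_centred=lc, zscore=to_zscores(lc)
    )


def _check_inputs(inputs: Mapping) -> None:
    def walk(v):
        if isinstance(v, Mapping):
            for x in v.values():
                walk(x)
        elif v is not None:
            if not Path(v).exists():
                raise MissingInputError(f"input file not found: {v}")

    walk(inputs)


def run(config: Mapping | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns a dict of result tables.

    Raises distinct errors for missing inputs, schema mismatches and
    degenerate tracks; the CLI converts these into a nonzero exit status.
    """
    if not isinstance(config, Mapping):
        config = io.load_config(config)
    seed = int(config.get("seed", 0))
    outdir = Path(output_dir or config.get("output_dir", "exonmark_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = dict(config.get("analysis", {}))
    results: dict = {}
    t0 = time.time()

    # --- stage: simulate ----------------------------------------------------
    study = None
    if "simulate" in config:
        sim_cfg = simulate.SimConfig.from_dict({"seed": seed, **config["simulate"]})
        study = simulate.simulate_study(sim_cfg)
        io.write_gff3(study.genes, outdir / "annotation.gff3")
        io.write_tiles(study.tiles, outdir / "tiles.tsv")
        for name, df in study.measurements.items():
            io.write_measurements(df, outdir / f"measurements_{name}.tsv")
        io.write_expression(study.expression, outdir / "expression.tsv")
        _write_table(
            study.truth.reset_index(), outdir / "truth.tsv", seed
        )
        reads = simulate.simulate_reads(sim_cfg, study.truth, study.rng)
        io.write_bed(reads, outdir / "reads.bed")
        logger.info("simulate: %d genes, %d tiles (%.1fs)", len(study.genes), len(study.tiles), time.time() - t0)
        if not analysis and "inputs" not in config:
            return {"study": study}

    # --- stage: load inputs ---------------------------------------------------
    if study is not None:
        genes, tiles = study.genes, study.tiles
        meas = {"mark": study.measurements["mark"]}
        h2b, h3, igg = (
            study.measurements["h2b"],
            study.measurements["h3"],
            study.measurements["igg"],
        )
        expr = study.expression
        reads_df = None
    else:
        inputs = config.get("inputs")
        if not inputs:
            raise MissingInputError("config has neither a simulate block nor inputs")
        _check_inputs(inputs)
        genes = io.read_annotation(inputs["annotation"])
        tiles = io.read_tiles(inputs["tiles"])
        marks = inputs.get("marks") or {}
        meas = {name: io.read_measurements(p) for name, p in marks.items()}
        h2b = io.read_measurements(inputs["h2b"]) if inputs.get("h2b") else None
        h3 = io.read_measurements(inputs["h3"]) if inputs.get("h3") else None
        igg = io.read_measurements(inputs["igg"]) if inputs.get("igg") else None
        expr = io.read_expression(inputs["expression"]) if inputs.get("expression") else None
        reads_df = io.read_bed(inputs["reads"]) if inputs.get("reads") else None

    # --- stage: assign --------------------------------------------------------
    kept = annotation.filter_genes(
        genes,
        min_span=analysis.get("min_span", 6000),
        min_exons=analysis.get("min_exons", 3),
        relaxed=analysis.get("relaxed", False),
    )
    assignment = annotation.assign_tiles(tiles, kept)
    io.write_assignment(assignment, outdir / "assignment.tsv")
    io.write_assignment_bed(assignment, tiles, outdir / "assignment.bed")
    results["assignment"] = assignment

    gene_sets: dict[str, list[str] | None] = {"all": None}
    if expr is not None and analysis.get("expression_split", True) and len(expr) >= 4:
        calls = expression.call_on_off(expr, force=True)
        gene_sets = {
            "ON": list(calls.index[calls["status"] == "ON"]),
            "OFF": list(calls.index[calls["status"] == "OFF"]),
        }
        _write_table(calls, outdir / "expression_calls.tsv", seed, index=True)

    # --- stage: preprocess / profile / stats ---------------------------------
    R = int(analysis.get("randomizations", 100))
    mode = analysis.get("mode", "five_prime")
    alpha = float(analysis.get("alpha", 0.05))
    summary_rows = []
    for name, df in meas.items():
        tr = preprocess_mark(
            df,
            h2b,
            h3,
            igg,
            histone_normalize=analysis.get("histone_normalize", True),
            igg_normalize=analysis.get("igg_normalize", False),
        )
        io.write_bedgraph(tr.zscore, tiles, outdir / f"track_{name}.bedGraph", name=name)
        io.write_wiggle(tr.zscore, tiles, outdir / f"track_{name}.wig", name=name)
        for state, gene_set in gene_sets.items():
            try:
                prof = profiles.exon_intron_profile(tr.zscore, assignment, gene_set, mode=mode)
            except ValueError:
                continue
            _write_table(
                prof.slots, outdir / f"profile_{name}_{state}.tsv", seed, tr.zscore.record
            )
            summ = profiles.class_means(tr.zscore, assignment, gene_set)
            boot = stats.bootstrap_pvalues(
                tr.zscore, assignment, gene_set, R=R, seed=seed
            )
            _write_table(
                boot.to_frame(), outdir / f"bootstrap_{name}_{state}.tsv", seed, tr.zscore.record
            )
            tt = stats.adjacent_pair_ttests(tr.zscore, assignment, gene_set, mode=mode)
            _write_table(tt.pairs, outdir / f"ttests_{name}_{state}.tsv", seed)
            can = boot.classes.get(annotation.CANONICAL)
            summary_rows.append(
                {
                    "dataset": "run",
                    "mark": name,
                    "state": state,
                    "delta_z": summ.delta_z,
                    "p": can.p_parametric if can else np.nan,
                    "median_ttest_p": tt.median_p,
                }
            )
            results[f"profile_{name}_{state}"] = prof
            results[f"class_means_{name}_{state}"] = summ
            results[f"bootstrap_{name}_{state}"] = boot
            results[f"ttests_{name}_{state}"] = tt

    if summary_rows:
        summary = pd.DataFrame(summary_rows)
        calls_df, conc = stats.bias_call_and_concordance(summary, alpha=alpha)
        _write_table(calls_df, outdir / "bias_calls.tsv", seed)
        _write_table(conc, outdir / "concordance.tsv", seed)
        results["bias_calls"] = calls_df
        results["concordance"] = conc

    # --- stage: ChIP-seq ------------------------------------------------------
    if reads_df is not None:
        bt = chipseq.bin_reads(reads_df, bin_size=int(analysis.get("bin_size", 200)))
        bin_assign, bin_summary = chipseq.assign_bins(bt, kept)
        _write_table(bin_summary, outdir / "chipseq_feature_means.tsv", seed)
        results["chipseq_summary"] = bin_summary

    report(results, outdir, seed)
    logger.info("run complete in %.1fs -> %s", time.time() - t0, outdir)
    return results


def report(results: Mapping, outdir: str | Path, seed) -> Path:
    """One summary table per figure-analogue, with explicit +/- dZ signs."""
    outdir = Path(outdir)
    lines = [f"# exonmark report (seed={seed})"]
    for key in sorted(results):
        if key.startswith("class_means_"):
            summ = results[key]
            sign = "+" if summ.delta_z >= 0 else "-"
            lines.append(
                f"{key}\tdelta_z={sign}{abs(summ.delta_z):.4f}\t"
                f"({'exon bias' if summ.delta_z > 0 else 'intron bias' if summ.delta_z < 0 else 'no bias'})"
            )
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
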