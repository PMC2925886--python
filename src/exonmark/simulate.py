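"""Synthetic data with the statistical structure the analysis assumes.

The generator plants a known per-tile log2 enrichment truth (baseline plus
exon/intron effects, inclusion-weighted on alternative exons) and constructs
two-channel intensities so the preprocessing chain recovers it exactly at
zero noise: the ChIP channel carries nucleosome density x 2^truth x
replicate noise over a flat genomic-input channel, while the H2B/H3 density
assays carry density alone and IgG carries a flat background. Dividing the
modification ratio by the combined H2B/H3 ratio therefore removes the
density confound by construction, which is the property the analysis is
designed to measure.

Everything is deterministic from the seed; emitted files round-trip through
the package's readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from types import SimpleNamespace
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotation
from .annotation import GeneModel

_SCALE_CHIP = 1000.0
_SCALE_INPUT = 1000.0
_BACKGROUND = 100.0


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Lengths are in bases; effects are log2 enrichment units; ``noise_sd`` is
    the per-replicate log2-normal SD applied independently to each channel.
    Defaults emulate a PCR-product tiling array (contiguous 500 b tiles) over
    multi-exon genes of realistic human geometry (median exon 150 b, median
    intron 1.5 kb), three bioreplicates, and 36 b sequencing reads.
    """

    seed: int = 0
    n_genes: int = 50
    exon_count_range: tuple[int, int] = (3, 12)
    exon_length_median: float = 150.0
    exon_length_sigma: float = 0.4
    intron_length_median: float = 1500.0
    intron_length_sigma: float = 0.6
    n_transcripts_range: tuple[int, int] = (1, 4)
    p_alt: float = 0.3  # chance an internal exon is alternatively spliced
    alt_inclusion_levels: tuple[float, ...] = (0.25, 0.5, 0.75)
    min_gene_span: int = 6000
    intergenic_gap: int = 2000
    chrom: str = "chr1"
    tile_length: int = 500
    read_length: int = 36
    n_reads: int = 50_000
    baseline_log2: float = 0.0
    exon_effect: float = 0.0
    intron_effect: float = 0.0
    alt_coupling: str = "inclusion_weighted"  # or "independent"
    alt_effect: float = 0.0  # used when alt_coupling == "independent"
    density_exon_mult: float = 1.0
    density_intron_mult: float = 1.0
    igg_baseline: float = 1.0
    noise_sd: float = 0.3
    n_replicates: int = 3
    expr_log2_mean: float = 5.0
    expr_log2_sd: float = 2.0
    expr_coupling: float = 0.0  # 0 = marks independent of expression

    def __post_init__(self) -> None:
        if self.exon_count_range[0] < 1 or self.exon_count_range[0] > self.exon_count_range[1]:
            raise ValueError("infeasible exon count range")
        for name in ("exon_length_median", "intron_length_median", "tile_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"infeasible length constraint: {name} must be > 0")
        if self.noise_sd < 0 or self.expr_log2_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.n_transcripts_range[0] < 1:
            raise ValueError("need at least one transcript per gene")
        if self.alt_coupling not in ("inclusion_weighted", "independent"):
            raise ValueError(f"unknown alt_coupling {self.alt_coupling!r}")
        if not 0 <= self.p_alt <= 1:
            raise ValueError("p_alt must be a probability")
        for lv in self.alt_inclusion_levels:
            if not 0 < lv < 1:
                raise ValueError("inclusion levels must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("exon_count_range", "n_transcripts_range", "alt_inclusion_levels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def _lognormal_lengths(rng, n, median, sigma, minimum=20):
    if sigma == 0:
        vals = np.full(n, median)
    else:
        vals = median * np.exp(rng.normal(0.0, sigma, size=n))
    return np.maximum(np.round(vals).astype(int), minimum)


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, GeneModel]:
    """Generate a deterministic set of multi-transcript gene models.

    Genes are laid out sequentially on one chromosome, strands alternating.
    Internal exons become alternative with probability ``p_alt``; each is
    carried by the subset of transcripts closest to a configured inclusion
    level (the first transcript always carries every exon so the gene span
    is stable). Intron lengths are stretched when needed so every gene meets
    the configured minimum span.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes: dict[str, GeneModel] = {}
    cursor = config.intergenic_gap
    lo, hi = config.exon_count_range
    tlo, thi = config.n_transcripts_range
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(lo, hi + 1))
        ex_len = _lognormal_lengths(
            rng, n_ex, config.exon_length_median, config.exon_length_sigma
        )
        in_len = _lognormal_lengths(
            rng, max(n_ex - 1, 0), config.intron_length_median, config.intron_length_sigma
        )
        span = int(ex_len.sum() + in_len.sum())
        if span < config.min_gene_span and len(in_len) > 0:
            factor = (config.min_gene_span - ex_len.sum()) / max(in_len.sum(), 1)
            in_len = np.ceil(in_len * max(factor, 1.0)).astype(int)

        starts = np.empty(n_ex, dtype=int)
        pos = cursor
        exon_ivs = []
        for i in range(n_ex):
            starts[i] = pos
            exon_ivs.append((pos, pos + int(ex_len[i])))
            pos += int(ex_len[i])
            if i < n_ex - 1:
                pos += int(in_len[i])
        strand = "+" if gi % 2 == 0 else "-"

        n_tx = int(rng.integers(tlo, thi + 1))
        membership = np.ones((n_tx, n_ex), dtype=bool)
        if n_tx > 1 and n_ex > 2:
            for i in range(1, n_ex - 1):  # internal exons only
                if rng.random() < config.p_alt:
                    target = float(rng.choice(config.alt_inclusion_levels))
                    c = int(np.clip(round(target * n_tx), 1, n_tx - 1))
                    carriers = rng.choice(n_tx, size=c, replace=False)
                    membership[:, i] = False
                    membership[carriers, i] = True
        transcripts = [
            [exon_ivs[i] for i in range(n_ex) if membership[t, i]]
            for t in range(n_tx)
        ]
        # guarantee a transcript carrying all exons so the union is the gene
        transcripts[0] = list(exon_ivs)
        gid = f"gene_{gi + 1:04d}"
        genes[gid] = GeneModel.from_transcripts(gid, config.chrom, strand, transcripts)
        cursor = pos + config.intergenic_gap
    return genes


def make_tiles(config: SimConfig, genes: Mapping[str, GeneModel]) -> pd.DataFrame:
    """Contiguous fixed-length tiles covering the simulated region."""
    end = max(g.span.end for g in genes.values()) + config.intergenic_gap
    starts = np.arange(0, end, config.tile_length)
    return pd.DataFrame(
        {
            "tile_id": [f"t{i:06d}" for i in range(len(starts))],
            "chrom": config.chrom,
            "start": starts,
            "end": starts + config.tile_length,
        }
    )


def _inclusion_map(genes: Mapping[str, GeneModel]) -> dict[tuple[str, int], float]:
    return {
        (gid, e.ordinal): e.inclusion_fraction
        for gid, g in genes.items()
        for e in g.exons
    }


def tile_truth(
    config: SimConfig,
    genes: Mapping[str, GeneModel],
    tiles: pd.DataFrame,
    assignment: pd.DataFrame | None = None,
    effect_scale: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Planted per-tile truth: feature class, log2 effect, density multiplier."""
    if assignment is None:
        assignment = annotation.assign_tiles(tiles, genes)
    incl = _inclusion_map(genes)
    truth = tiles.set_index("tile_id")[["chrom", "start", "end"]].copy()
    truth["feature"] = assignment["feature"].reindex(truth.index).fillna("intergenic")
    truth["gene_id"] = assignment["gene_id"].reindex(truth.index)

    eff = np.full(len(truth), config.baseline_log2)
    dens = np.ones(len(truth))
    feats = truth["feature"].to_numpy()
    gids = truth["gene_id"].to_numpy(object)
    ords = assignment["ordinal"].reindex(truth.index).to_numpy()
    for i, f in enumerate(feats):
        scale = 1.0
        if effect_scale is not None and isinstance(gids[i], str):
            scale = float(effect_scale.get(gids[i], 1.0))
        if f == annotation.CANONICAL:
            eff[i] += scale * config.exon_effect
            dens[i] = config.density_exon_mult
        elif f == annotation.ALTERNATIVE:
            if config.alt_coupling == "inclusion_weighted":
                frac = incl[(gids[i], int(ords[i]))]
                eff[i] += scale * frac * config.exon_effect
            else:
                eff[i] += scale * config.alt_effect
            dens[i] = config.density_exon_mult
        elif f == annotation.INTRON:
            eff[i] += scale * config.intron_effect
            dens[i] = config.density_intron_mult
    truth["true_log2"] = eff
    truth["density"] = dens
    return truth


def _noise(rng, n, sd):
    if sd == 0:
        return np.ones(n)
    return np.exp2(rng.normal(0.0, sd, size=n))


def _measurement_frame(
    tiles: pd.DataFrame, replicate: int, chip_level: np.ndarray, input_level: np.ndarray
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tile_id": tiles["tile_id"].to_numpy(),
            "chrom": tiles["chrom"].to_numpy(),
            "start": tiles["start"].to_numpy(),
            "end": tiles["end"].to_numpy(),
            "replicate": replicate,
            "chip": _BACKGROUND + chip_level,
            "chip_bg": _BACKGROUND,
            "input": _BACKGROUND + input_level,
            "input_bg": _BACKGROUND,
            "flag": "ok",
        }
    )


def simulate_chipchip(
    config: SimConfig,
    genes: Mapping[str, GeneModel],
    tiles: pd.DataFrame,
    rng: np.random.Generator,
    effect_scale: Mapping[str, float] | None = None,
    assignment: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Two-channel measurements for the mark, H2B, H3 and IgG assays.

    Returns (measurements, truth); ``measurements`` maps assay name to a long
    replicate table in the standard schema.
    """
    truth = tile_truth(config, genes, tiles, assignment, effect_scale)
    n = len(tiles)
    dens = truth["density"].to_numpy()
    signal = dens * np.exp2(truth["true_log2"].to_numpy())
    sd = config.noise_sd

    assays: dict[str, list[pd.DataFrame]] = {"mark": [], "h2b": [], "h3": [], "igg": []}
    levels = {
        "mark": _SCALE_CHIP * signal,
        "h2b": _SCALE_CHIP * dens,
        "h3": _SCALE_CHIP * dens,
        "igg": _SCALE_CHIP * config.igg_baseline,
    }
    for rep in range(1, config.n_replicates + 1):
        for name, base in levels.items():
            chip = base * _noise(rng, n, sd)
            inp = _SCALE_INPUT * _noise(rng, n, sd)
            assays[name].append(_measurement_frame(tiles, rep, chip, inp))
    measurements = {
        name: pd.concat(frames, ignore_index=True) for name, frames in assays.items()
    }
    return measurements, truth


def simulate_reads(
    config: SimConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
    n_reads: int | None = None,
) -> pd.DataFrame:
    """Read starts sampled from per-tile occupancy (density x 2^truth).

    The per-base intensity is piecewise constant on tiles, matching the
    array-side truth exactly, so both platforms measure the same occupancy.
    The requested read count is honoured exactly.
    """
    n_reads = config.n_reads if n_reads is None else n_reads
    w = truth["density"].to_numpy() * np.exp2(truth["true_log2"].to_numpy())
    lengths = (truth["end"] - truth["start"]).to_numpy()
    p = w * lengths
    p = p / p.sum()
    idx = rng.choice(len(truth), size=n_reads, p=p)
    offset = rng.integers(0, lengths[idx], size=n_reads)
    start = truth["start"].to_numpy()[idx] + offset
    return pd.DataFrame(
        {
            "chrom": truth["chrom"].to_numpy()[idx],
            "start": start,
            "end": start + config.read_length,
            "strand": "+",
        }
    ).sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


def simulate_expression(
    config: SimConfig, genes: Mapping[str, GeneModel], rng: np.random.Generator
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene expression values with known decile truth.

    With ``expr_coupling`` c > 0 the generator also returns per-gene marking
    multipliers 1 + c*(percentile/100 - 0.5)*2 in [1-c, 1+c], a monotone
    coupling of effect size to expression rank.
    """
    gids = list(genes)
    log2v = rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=len(gids))
    values = pd.Series(np.exp2(log2v), index=gids, name="expression")
    rank = values.rank(method="first") - 1
    pct = 100.0 * rank / len(values)
    decile = np.minimum((pct // 10).astype(int), 9)
    scale = 1.0 + config.expr_coupling * (pct / 100.0 - 0.5) * 2.0
    truth = pd.DataFrame(
        {"expression": values, "percentile": pct, "decile": decile, "effect_scale": scale}
    )
    return values, truth


def simulate_study(config: SimConfig) -> SimpleNamespace:
    """One end-to-end synthetic dataset: annotation, tiles, arrays, expression.

    All randomness flows from ``config.seed`` through a single generator, so
    re-running with the same config reproduces every table bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    genes = simulate_annotation(config, rng)
    tiles = make_tiles(config, genes)
    assignment = annotation.assign_tiles(tiles, genes)
    expression, expr_truth = simulate_expression(config, genes, rng)
    effect_scale = (
        expr_truth["effect_scale"].to_dict() if config.expr_coupling != 0 else None
    )
    measurements, truth = simulate_chipchip(
        config, genes, tiles, rng, effect_scale=effect_scale, assignment=assignment
    )
    return SimpleNamespace(
        config=config,
        rng=rng,
        genes=genes,
        tiles=tiles,
        assignment=assignment,
        measurements=measurements,
        truth=truth,
        expression=expression,
        expression_truth=expr_truth,
    )
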