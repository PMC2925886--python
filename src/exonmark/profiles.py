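"""Consensus exon-intron metaprofiles and feature-class summaries.

A metaprofile averages a Z-score track over ordered feature slots across
many genes: exon 1, intron 1, ..., exon 10 (5' mode) or the last five exons
and four introns (3' mode). Profiles use canonical exons only; alternative
exons enter the per-class summaries, whose headline number is the exon-intron
bias dZ = mean(canonical exons) - mean(introns). Positive dZ is an exon bias,
negative dZ an intron bias.

Slot and class means weight tiles equally (each tile one observation);
gene-equal weighting is available as an option on class summaries.
Confidence intervals use the normal approximation, mean +/- 1.96 SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation
from .preprocess import TileTrack

FIVE_PRIME_MODE = "five_prime"
THREE_PRIME_MODE = "three_prime"


def _tile_values(
    track: TileTrack, assignment: pd.DataFrame, gene_set: Sequence[str] | None
) -> pd.DataFrame:
    df = assignment.copy()
    if gene_set is not None:
        gene_set = list(gene_set)
        if not gene_set:
            raise ValueError("empty gene set")
        df = df[df["gene_id"].isin(gene_set)]
        if df.empty:
            raise ValueError("empty gene set: no assigned tiles remain")
    df["z"] = track.values.reindex(df.index)
    return df.dropna(subset=["z"])


def _agg(z: pd.core.groupby.SeriesGroupBy) -> pd.DataFrame:
    out = z.agg(mean="mean", n="size", sd=lambda s: s.std(ddof=1))
    out["ci95"] = 1.96 * out["sd"] / np.sqrt(out["n"])
    return out


@dataclass
class MetaProfile:
    """Ordered feature slots with mean Z, tile count and 95% CI."""

    mode: str
    slots: pd.DataFrame  # columns: slot, feature, ordinal, mean, n, ci95
    tile_values: pd.DataFrame  # per-tile rows retained for significance tests

    def __len__(self) -> int:
        return len(self.slots)


def exon_intron_profile(
    track: TileTrack,
    assignment: pd.DataFrame,
    gene_set: Sequence[str] | None = None,
    mode: str = FIVE_PRIME_MODE,
    n_exons: int = 10,
) -> MetaProfile:
    """Consensus profile over exon/intron ordinal slots (canonical exons).

    5' mode covers exons 1..``n_exons`` interleaved with introns 1..n-1
    counted from the 5' end; 3' mode covers the last five exons and four
    introns counted from the 3' end. Genes with fewer features contribute to
    as many slots as they have.
    """
    df = _tile_values(track, assignment, gene_set)
    can = df[df["feature"] == annotation.CANONICAL]
    intr = df[df["feature"] == annotation.INTRON]

    rows = []
    if mode == FIVE_PRIME_MODE:
        e = _agg(can.groupby("ordinal")["z"])
        i = _agg(intr.groupby("ordinal")["z"])
        for k in range(1, n_exons + 1):
            rows.append(("exon_%d" % k, annotation.CANONICAL, k, e))
            if k < n_exons:
                rows.append(("intron_%d" % k, annotation.INTRON, k, i))
    elif mode == THREE_PRIME_MODE:
        n_e, n_i = 5, 4
        e = _agg(can.groupby("rev_ordinal")["z"])
        i = _agg(intr.groupby("rev_ordinal")["z"])
        for k in range(n_e, 0, -1):  # exon_last-4 ... exon_last
            label = "exon_last" if k == 1 else f"exon_last-{k - 1}"
            rows.append((label, annotation.CANONICAL, k, e))
            if k > 1 and k - 1 <= n_i:
                ilab = "intron_last" if k - 1 == 1 else f"intron_last-{k - 2}"
                rows.append((ilab, annotation.INTRON, k - 1, i))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    records = []
    for slot, feature, ordinal, stats in rows:
        if ordinal in stats.index:
            s = stats.loc[ordinal]
            records.append(
                (slot, feature, ordinal, s["mean"], int(s["n"]), s["ci95"])
            )
        else:
            records.append((slot, feature, ordinal, np.nan, 0, np.nan))
    slots = pd.DataFrame(
        records, columns=["slot", "feature", "ordinal", "mean", "n", "ci95"]
    )
    return MetaProfile(mode=mode, slots=slots, tile_values=df)


@dataclass
class ClassSummary:
    """Per feature-class means with the exon-intron bias dZ."""

    table: pd.DataFrame  # index: feature (or feature, region)
    delta_z: float  # canonical-exon mean minus intron mean (pooled)
    region_split: bool = False

    def class_mean(self, feature: str, region: str | None = None) -> float:
        if region is None:
            sub = self.table.loc[self.table.index.get_level_values("feature") == feature] \
                if self.region_split else self.table.loc[[feature]]
            if self.region_split:
                w = sub["n"].to_numpy(float)
                m = sub["mean"].to_numpy(float)
                ok = w > 0
                return float(np.average(m[ok], weights=w[ok])) if ok.any() else np.nan
            return float(sub["mean"].iloc[0])
        return float(self.table.loc[(feature, region), "mean"])


def class_means(
    track: TileTrack,
    assignment: pd.DataFrame,
    gene_set: Sequence[str] | None = None,
    region_split: bool = False,
    gene_weighted: bool = False,
) -> ClassSummary:
    """Mean Z per feature class, with 95% CIs and the exon-intron bias dZ.

    With ``region_split`` means are reported separately for the 5'-most 25%
    of genes and the remaining body. ``gene_weighted`` averages per-gene
    means instead of pooling tiles.
    """
    df = _tile_values(track, assignment, gene_set)
    if df.empty:
        raise ValueError("no assigned tiles with values")
    keys = ["feature", "region"] if region_split else ["feature"]
    if gene_weighted:
        per_gene = df.groupby(keys + ["gene_id"])["z"].mean().reset_index()
        table = _agg(per_gene.groupby(keys)["z"])
    else:
        table = _agg(df.groupby(keys)["z"])

    pooled_source = per_gene if gene_weighted else df
    pooled = pooled_source.groupby("feature")["z"].mean()
    delta = float(
        pooled.get(annotation.CANONICAL, np.nan)
        - pooled.get(annotation.INTRON, np.nan)
    )
    return ClassSummary(table=table, delta_z=delta, region_split=region_split)


def gene_percent_profile(
    track: TileTrack,
    genes: Mapping[str, annotation.GeneModel],
    tiles: pd.DataFrame,
    n_bins: int = 40,
    flank_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean Z over proportional gene coordinates with flanking regions.

    Tile midpoints are mapped strand-aware onto an axis running from
    ``-100*flank_fraction`` (upstream flank) through 0-100% (gene body) to
    ``100*(1+flank_fraction)`` (downstream flank), then averaged in
    ``n_bins`` equal bins across genes.
    """
    lo = -100.0 * flank_fraction
    hi = 100.0 * (1 + flank_fraction)
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = (tiles["start"].to_numpy(float) + tiles["end"].to_numpy(float)) / 2
    chroms = tiles["chrom"].to_numpy()
    vals = track.values.reindex(tiles["tile_id"]).to_numpy(float)

    rel_all = []
    z_all = []
    for g in genes.values():
        L = len(g.span)
        flank = flank_fraction * L
        on = (
            (chroms == g.span.chrom)
            & (mids >= g.span.start - flank)
            & (mids < g.span.end + flank)
        )
        if not on.any():
            continue
        m = mids[on]
        if g.span.strand == "+":
            rel = 100.0 * (m - g.span.start) / L
        else:
            rel = 100.0 * (g.span.end - m) / L
        rel_all.append(rel)
        z_all.append(vals[on])
    if not rel_all:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "mean", "n"])
    rel = np.concatenate(rel_all)
    z = np.concatenate(z_all)
    ok = np.isfinite(z)
    rel, z = rel[ok], z[ok]
    idx = np.clip(np.searchsorted(edges, rel, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=z, minlength=n_bins)
    ns = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / ns
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "mean": means, "n": ns}
    )
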