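"""Expression ranking, ON/OFF calls and percentile binning.

Expression values are consumed, not computed: any platform-scale number per
gene works because everything downstream is rank-based. Genes are called ON
(top two quartiles) or OFF (bottom quartile); a whole-genome mode uses the
top and bottom 25%. Two platforms' calls can be intersected so only genes
with concordant states keep them. For marking-versus-expression analyses,
genes are placed into percentile bins (12 by default, resolving the extreme
deciles into 5% bins).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation
from .preprocess import TileTrack

logger = logging.getLogger(__name__)

ON, OFF, NEITHER = "ON", "OFF", "neither"

#: default percentile edges: 12 bins, deciles with split top/bottom deciles
DEFAULT_EDGES = (0, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 100)


def _percentiles(values: pd.Series) -> pd.Series:
    """Percentile rank in [0, 100): 100*(rank-1)/n, stable-tie-broken by id."""
    df = pd.DataFrame({"v": values})
    df = df.sort_index(kind="mergesort").sort_values("v", kind="mergesort")
    rank = pd.Series(np.arange(len(df)), index=df.index, dtype=float)
    return 100.0 * rank.reindex(values.index) / len(df)


def call_on_off(
    values: pd.Series, whole_genome: bool = False, force: bool = False
) -> pd.DataFrame:
    """Quartile-based expression state calls.

    ON = top two quartiles, OFF = bottom quartile, the third quartile is
    ``neither``. In ``whole_genome`` mode ON/OFF are the top and bottom 25%.
    Ties spanning a quartile edge are broken by stable gene-id order and
    logged; a fully tied ranking raises unless ``force`` is set.
    """
    if len(values) < 4:
        raise ValueError("need at least 4 genes for quartile calls")
    if values.nunique() == 1 and not force:
        raise ValueError("untiable ranking: all expression values are equal")
    pct = _percentiles(values)
    edges = np.percentile(values.to_numpy(float), [25, 50, 75])
    if len(np.unique(edges)) < 3:
        logger.warning("ties span quartile edges; broken by stable gene order")
    if whole_genome:
        status = np.where(pct >= 75, ON, np.where(pct < 25, OFF, NEITHER))
    else:
        status = np.where(pct >= 50, ON, np.where(pct < 25, OFF, NEITHER))
    return pd.DataFrame(
        {"value": values, "percentile": pct, "status": status}, index=values.index
    )


def intersect_calls(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Keep a gene's state only when both platforms agree on it.

    Genes absent from either table are dropped; disagreeing genes become
    ``neither``. Commutative and idempotent.
    """
    common = table_a.index.intersection(table_b.index)
    a = table_a.loc[common]
    b = table_b.loc[common]
    status = np.where(a["status"] == b["status"], a["status"], NEITHER)
    out = a.copy()
    out["status"] = status
    return out


def encode_array_expression(
    oligo_dt: TileTrack,
    random_primed: TileTrack,
    genes: Mapping[str, annotation.GeneModel],
    tiles: pd.DataFrame,
    window: int = 2000,
) -> pd.Series:
    """Tiling-array expression score per gene.

    The score is the mean of two components: the mean oligo-dT Z over tiles
    whose midpoint lies in the 3'-most ``window`` bases of the gene (the
    whole gene when shorter), and the mean random-primed Z over all tiles in
    the gene. Genes with no tiles in the window are missing.
    """
    mids = (tiles["start"].to_numpy(float) + tiles["end"].to_numpy(float)) / 2
    tid = tiles["tile_id"].to_numpy()
    chroms = tiles["chrom"].to_numpy()
    scores = {}
    for gid, g in genes.items():
        on_chrom = chroms == g.span.chrom
        in_gene = on_chrom & (mids >= g.span.start) & (mids < g.span.end)
        if g.span.strand == "+":
            wstart = max(g.span.start, g.span.end - window)
            in_win = in_gene & (mids >= wstart)
        else:
            wend = min(g.span.end, g.span.start + window)
            in_win = in_gene & (mids < wend)
        win_ids = tid[in_win]
        gene_ids = tid[in_gene]
        odt = oligo_dt.values.reindex(win_ids).mean(skipna=True)
        rp = random_primed.values.reindex(gene_ids).mean(skipna=True)
        if np.isnan(odt) or np.isnan(rp):
            scores[gid] = np.nan
        else:
            scores[gid] = (odt + rp) / 2
    return pd.Series(scores, name="expression")


def expression_bins(
    values: pd.Series, edges: Sequence[float] = DEFAULT_EDGES
) -> pd.DataFrame:
    """Assign genes to percentile bins by rank.

    Bins are half-open ``[lo, hi)`` with the last bin closed at 100. The
    default 12-bin layout resolves the top and bottom deciles into 5% bins.
    """
    edges = list(edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("percentile edges must be strictly increasing")
    if edges[0] != 0 or edges[-1] != 100:
        raise ValueError("percentile edges must run from 0 to 100")
    n_bins = len(edges) - 1
    if len(values) < n_bins:
        raise ValueError("fewer genes than bins")
    pct = _percentiles(values)
    bin_idx = np.clip(
        np.searchsorted(edges, pct.to_numpy(), side="right") - 1, 0, n_bins - 1
    )
    return pd.DataFrame(
        {"value": values, "percentile": pct, "bin": bin_idx}, index=values.index
    )


def stratify_inclusion(
    alt_exons: Sequence[annotation.ExonFeature],
    cutoffs: Sequence[float] = (0.0, 50.0, 100.0),
) -> dict[str, list[annotation.ExonFeature]]:
    """Partition alternative exons by inclusion fraction.

    Default groups are [0, 50)% and [50, 100]% inclusion. Canonical exons
    are a domain violation and raise.
    """
    for e in alt_exons:
        if e.cls != annotation.ALTERNATIVE:
            raise ValueError(f"not an alternative exon: {e}")
    cuts = [c / 100.0 for c in cutoffs]
    groups: dict[str, list[annotation.ExonFeature]] = {}
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        label = f"{lo * 100:g}-{hi * 100:g}%"
        last = hi == cuts[-1]
        groups[label] = [
            e
            for e in alt_exons
            if lo <= e.inclusion_fraction < hi
            or (last and e.inclusion_fraction == hi)
        ]
    return groups
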