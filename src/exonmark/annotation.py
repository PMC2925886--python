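"""Gene models and tile-to-feature assignment.

Genes are represented as sets of transcripts (exon interval lists). Exons
present in every transcript of a gene are *canonical*; exons present in some
but not all transcripts are *alternative*, with an inclusion fraction equal
to the proportion of transcripts containing them. Introns are the gaps
between consecutive segments of the union of all exon intervals. Bases where
two distinct exon intervals overlap (e.g. a canonical exon nested in a longer
alternative variant) are ambiguous and excluded from all assignments.

Coordinates are 0-based half-open throughout; GFF/GTF input is converted on
read (see :mod:`exonmark.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL = "canonical_exon"
ALTERNATIVE = "alternative_exon"
INTRON = "intron"
FIVE_PRIME = "five_prime"
BODY = "body"

#: columns of a FeatureAssignment frame (indexed by tile/bin id)
ASSIGNMENT_COLUMNS = ["gene_id", "feature", "ordinal", "rev_ordinal", "region"]


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ExonFeature:
    interval: GenomeInterval
    cls: str  # CANONICAL or ALTERNATIVE
    ordinal: int  # 1-based from the gene's 5' end
    inclusion_fraction: float

    def __post_init__(self) -> None:
        if self.cls == CANONICAL and self.inclusion_fraction != 1.0:
            raise ValueError("canonical exon must have inclusion 1.0")
        if self.cls == ALTERNATIVE and not 0.0 < self.inclusion_fraction < 1.0:
            raise ValueError("alternative exon inclusion must be in (0, 1)")


@dataclass(frozen=True)
class IntronFeature:
    interval: GenomeInterval
    ordinal: int  # 1-based from the gene's 5' end


@dataclass
class GeneModel:
    """A gene: transcripts plus derived exon/intron features.

    ``transcripts`` hold (start, end) exon tuples sorted by genomic start.
    ``excluded_zones`` are merged overlap regions between distinct exon
    intervals; tiles whose midpoint lands there are never assigned.
    """

    gene_id: str
    span: GenomeInterval
    transcripts: list[list[tuple[int, int]]]
    exons: list[ExonFeature] = field(default_factory=list)
    introns: list[IntronFeature] = field(default_factory=list)
    excluded_zones: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_transcripts(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        transcripts: Sequence[Sequence[tuple[int, int]]],
    ) -> "GeneModel":
        if not transcripts:
            raise ValueError("no transcripts")
        txs = [sorted((int(s), int(e)) for s, e in tx) for tx in transcripts]
        for tx in txs:
            for s, e in tx:
                if s >= e:
                    raise ValueError(f"empty exon [{s}, {e}) in {gene_id}")
        start = min(s for tx in txs for s, _ in tx)
        end = max(e for tx in txs for _, e in tx)
        span = GenomeInterval(chrom, start, end, strand)
        gene = cls(gene_id=gene_id, span=span, transcripts=txs)
        gene.exons, gene.excluded_zones = classify_exons(
            txs, chrom=chrom, strand=strand
        )
        gene.introns = derive_introns(gene)
        return gene

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def canonical_exons(self) -> list[ExonFeature]:
        return [e for e in self.exons if e.cls == CANONICAL]

    def alternative_exons(self) -> list[ExonFeature]:
        return [e for e in self.exons if e.cls == ALTERNATIVE]


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def classify_exons(
    transcripts: Sequence[Sequence[tuple[int, int]]],
    chrom: str = "chr",
    strand: str = "+",
) -> tuple[list[ExonFeature], list[tuple[int, int]]]:
    """Classify distinct exon intervals as canonical or alternative.

    Exon identity is exact interval equality across transcripts. The
    inclusion fraction of an interval is the proportion of transcripts whose
    exon list contains it; 1.0 means canonical. Overlap between two distinct
    intervals is returned as a merged list of excluded zones.

    Ordinals are 1-based from the gene's 5' end, respecting ``strand``.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    n_tx = len(transcripts)
    counts: dict[tuple[int, int], int] = {}
    for tx in transcripts:
        seen = {(int(s), int(e)) for s, e in tx}
        for iv in seen:
            if iv[0] >= iv[1]:
                raise ValueError(f"empty exon interval {iv}")
            counts[iv] = counts.get(iv, 0) + 1

    distinct = sorted(counts)
    overlaps: list[tuple[int, int]] = []
    for i, a in enumerate(distinct):
        for b in distinct[i + 1 :]:
            if b[0] >= a[1]:
                break
            overlaps.append((max(a[0], b[0]), min(a[1], b[1])))
    excluded = _merge_intervals(overlaps)

    ordered = distinct if strand == "+" else list(reversed(distinct))
    exons = []
    for ordinal, iv in enumerate(ordered, start=1):
        frac = counts[iv] / n_tx
        exons.append(
            ExonFeature(
                interval=GenomeInterval(chrom, iv[0], iv[1], strand),
                cls=CANONICAL if frac == 1.0 else ALTERNATIVE,
                ordinal=ordinal,
                inclusion_fraction=frac,
            )
        )
    return exons, excluded


def derive_introns(gene: GeneModel) -> list[IntronFeature]:
    """Gaps between consecutive segments of the union of all exon intervals."""
    if not gene.exons:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    merged = _merge_intervals(
        (e.interval.start, e.interval.end) for e in gene.exons
    )
    gaps = [
        (merged[i][1], merged[i + 1][0]) for i in range(len(merged) - 1)
    ]
    if gene.span.strand == "-":
        gaps = list(reversed(gaps))
    return [
        IntronFeature(
            interval=GenomeInterval(
                gene.span.chrom, s, e, gene.span.strand
            ),
            ordinal=k,
        )
        for k, (s, e) in enumerate(gaps, start=1)
    ]


def filter_genes(
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    min_span: int = 6000,
    min_exons: int = 3,
    relaxed: bool = False,
) -> dict[str, GeneModel]:
    """Keep genes spanning >= ``min_span`` bases with >= ``min_exons`` exons.

    In ``relaxed`` mode only the exon-count constraint applies (used for
    whole-genome runs where the span requirement is dropped).
    """
    if isinstance(genes, Mapping):
        genes = genes.values()
    kept = {}
    for g in genes:
        if g.n_exons < min_exons:
            continue
        if not relaxed and len(g.span) < min_span:
            continue
        kept[g.gene_id] = g
    return kept


def _feature_rows(genes: Mapping[str, GeneModel]) -> pd.DataFrame:
    """One row per exon/intron feature across all genes."""
    rows = []
    for g in genes.values():
        n_can = len(g.canonical_exons())
        n_int = g.n_introns
        can_seen = 0
        for e in g.exons:
            if e.cls == CANONICAL:
                can_seen += 1
                rev = n_can - can_seen + 1
            else:
                rev = -1  # reverse ordinals defined for canonical exons only
            rows.append(
                (
                    e.interval.chrom,
                    e.interval.start,
                    e.interval.end,
                    g.gene_id,
                    e.cls,
                    e.ordinal,
                    rev,
                )
            )
        for i in g.introns:
            rows.append(
                (
                    i.interval.chrom,
                    i.interval.start,
                    i.interval.end,
                    g.gene_id,
                    INTRON,
                    i.ordinal,
                    n_int - i.ordinal + 1,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "gene_id", "feature", "ordinal", "rev_ordinal"],
    )


class _ChromIndex:
    """Disjoint-segment lookup over possibly overlapping feature intervals.

    Bases covered by exactly one feature resolve to it; bases covered by two
    or more (exon-interval overlaps within a gene, or overlapping genes) are
    ambiguous and resolve to nothing. Lookup is a single searchsorted.
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray) -> None:
        bounds = np.unique(np.concatenate([starts, ends]))
        nseg = len(bounds) - 1
        cov = np.zeros(nseg + 1, dtype=np.int64)
        who = np.zeros(nseg + 1, dtype=np.int64)
        si = np.searchsorted(bounds, starts)
        ei = np.searchsorted(bounds, ends)
        np.add.at(cov, si, 1)
        np.add.at(cov, ei, -1)
        idx = np.arange(1, len(starts) + 1, dtype=np.int64)
        np.add.at(who, si, idx)
        np.add.at(who, ei, -idx)
        self.bounds = bounds
        self.coverage = np.cumsum(cov)[:nseg]
        self.owner = np.cumsum(who)[:nseg] - 1  # row index where coverage==1

    def lookup(self, pos: np.ndarray) -> np.ndarray:
        """Feature row index per position, -1 when unassigned/ambiguous."""
        seg = np.searchsorted(self.bounds, pos, side="right") - 1
        ok = (seg >= 0) & (seg < len(self.coverage))
        out = np.full(len(pos), -1, dtype=np.int64)
        segc = seg[ok]
        hit = self.coverage[segc] == 1
        res = np.where(hit, self.owner[segc], -1)
        out[np.flatnonzero(ok)] = res
        return out


def _region_of(
    mid: np.ndarray, start: np.ndarray, end: np.ndarray, minus: np.ndarray
) -> np.ndarray:
    """5'-most 25% of the gene span vs the remaining body, strand-aware."""
    length = end - start
    cut_plus = start + 0.25 * length
    cut_minus = end - 0.25 * length
    # strict/non-strict chosen so genome reflection maps the rule onto itself
    five = np.where(minus, mid > cut_minus, mid < cut_plus)
    return np.where(five, FIVE_PRIME, BODY)


def assign_tiles(
    tiles: pd.DataFrame | Sequence[GenomeInterval],
    genes: Mapping[str, GeneModel],
) -> pd.DataFrame:
    """Assign tiles (or bins) to gene features by their midpoint.

    A tile belongs to the feature containing its midpoint. Tiles whose
    midpoint falls in an excluded overlap zone, in a region claimed by more
    than one feature, or outside every gene, are absent from the result.

    Parameters
    ----------
    tiles
        DataFrame with columns ``tile_id, chrom, start, end`` (or a sequence
        of :class:`GenomeInterval`, which get positional ids).
    genes
        Mapping of gene_id to :class:`GeneModel`.

    Returns
    -------
    DataFrame indexed by tile_id with columns ``gene_id, feature, ordinal,
    rev_ordinal, region``. Deterministic and idempotent.
    """
    if not isinstance(tiles, pd.DataFrame):
        tiles = pd.DataFrame(
            {
                "tile_id": [f"tile_{i}" for i in range(len(tiles))],
                "chrom": [t.chrom for t in tiles],
                "start": [t.start for t in tiles],
                "end": [t.end for t in tiles],
            }
        )
    feats = _feature_rows(genes)
    gene_info = {
        gid: (g.span.start, g.span.end, g.span.strand == "-")
        for gid, g in genes.items()
    }

    out_frames = []
    known_chroms = set(feats["chrom"].unique())
    for chrom, sub in tiles.groupby("chrom", sort=False):
        if chrom not in known_chroms:
            warnings.warn(f"tiles on unknown chromosome {chrom!r} left unassigned")
            continue
        f = feats[feats["chrom"] == chrom].reset_index(drop=True)
        index = _ChromIndex(
            f["start"].to_numpy(np.int64), f["end"].to_numpy(np.int64)
        )
        mid = (sub["start"].to_numpy(float) + sub["end"].to_numpy(float)) / 2
        row = index.lookup(mid)
        hit = row >= 0
        if not hit.any():
            continue
        fh = f.iloc[row[hit]]
        gids = fh["gene_id"].to_numpy()
        gstart = np.array([gene_info[g][0] for g in gids], dtype=float)
        gend = np.array([gene_info[g][1] for g in gids], dtype=float)
        gminus = np.array([gene_info[g][2] for g in gids], dtype=bool)
        region = _region_of(mid[hit], gstart, gend, gminus)
        out_frames.append(
            pd.DataFrame(
                {
                    "gene_id": gids,
                    "feature": fh["feature"].to_numpy(),
                    "ordinal": fh["ordinal"].to_numpy(),
                    "rev_ordinal": fh["rev_ordinal"].to_numpy(),
                    "region": region,
                },
                index=pd.Index(sub.loc[hit, "tile_id"], name="tile_id"),
            )
        )
    if not out_frames:
        return pd.DataFrame(
            columns=ASSIGNMENT_COLUMNS, index=pd.Index([], name="tile_id")
        )
    return pd.concat(out_frames)
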