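"""Readers and writers for the standard interchange formats.

Annotation comes in as GFF3 or GTF (via gffutils) and is converted to
0-based half-open coordinates on read. Measurement tables, expression tables
and assignments are plain TSV; tracks go out as bedGraph or fixed-step
wiggle for genome-browser viewing; reads come in as BED.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import gffutils
import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel
from .preprocess import MEASUREMENT_COLUMNS, TileTrack

# --- annotation -------------------------------------------------------------


def write_gff3(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon records (1-based inclusive, per GFF3)."""
    lines = ["##gff-version 3"]
    for gid, g in genes.items():
        c, strand = g.span.chrom, g.span.strand
        lines.append(
            f"{c}\texonmark\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t{strand}\t.\tID={gid}"
        )
        for ti, tx in enumerate(g.transcripts, start=1):
            tid = f"{gid}.t{ti}"
            ts, te = tx[0][0], tx[-1][1]
            lines.append(
                f"{c}\texonmark\tmRNA\t{ts + 1}\t{te}\t.\t{strand}\t.\tID={tid};Parent={gid}"
            )
            for ei, (s, e) in enumerate(tx, start=1):
                lines.append(
                    f"{c}\texonmark\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={tid}.e{ei};Parent={tid}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> dict[str, GeneModel]:
    """Parse GFF3 or GTF into gene models (multiple transcripts per gene)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # gene -> transcript -> exon interval list, with chrom/strand per gene
    per_gene: dict[str, dict[str, list[tuple[int, int]]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    tx_parent: dict[str, str] = {}
    for f in db.all_features():
        if f.featuretype in ("mRNA", "transcript"):
            parents = f.attributes.get("Parent") or f.attributes.get("gene_id")
            if parents:
                tx_parent[f.id] = parents[0]
    for exon in db.features_of_type("exon"):
        if "transcript_id" in exon.attributes:  # GTF style
            tid = exon.attributes["transcript_id"][0]
            gid = exon.attributes.get("gene_id", [tid])[0]
        else:  # GFF3 style
            tid = exon.attributes["Parent"][0]
            gid = tx_parent.get(tid, tid)
        per_gene.setdefault(gid, {}).setdefault(tid, []).append(
            (exon.start - 1, exon.end)
        )
        meta.setdefault(gid, (exon.seqid, exon.strand))
    genes = {}
    for gid in sorted(per_gene):
        chrom, strand = meta[gid]
        txs = [sorted(ivs) for _, ivs in sorted(per_gene[gid].items())]
        genes[gid] = GeneModel.from_transcripts(gid, chrom, strand, txs)
    return genes


# --- tabular data -----------------------------------------------------------


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tiles(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tiles(tiles: pd.DataFrame, path: str | Path) -> None:
    tiles.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def write_expression(values: pd.Series, path: str | Path, status: pd.Series | None = None) -> None:
    df = pd.DataFrame({"gene_id": values.index, "expression": values.to_numpy()})
    if status is not None:
        df["status"] = status.reindex(values.index).fillna("NA").to_numpy()
    df.to_csv(path, sep="\t", index=False)


def write_track_values(track: TileTrack, path: str | Path) -> None:
    df = track.values.rename("value").rename_axis("tile_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_track_values(path: str | Path, assay_kind: str = "histone_mod", state: str = "zscore") -> TileTrack:
    df = pd.read_csv(path, sep="\t")
    return TileTrack(
        values=df.set_index("tile_id")["value"], assay_kind=assay_kind, state=state
    )


# --- reads (BED) ------------------------------------------------------------

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = [f"read_{i}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "+"
    out[_BED_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def write_assignment(assignment: pd.DataFrame, path: str | Path) -> None:
    """Assignment table as TSV (tile_id index preserved)."""
    assignment.to_csv(path, sep="\t", index=True)


def read_assignment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="tile_id")


def write_assignment_bed(
    assignment: pd.DataFrame, tiles: pd.DataFrame, path: str | Path
) -> None:
    """Assignments as BED with name 'gene|class|ordinal|region'."""
    coords = tiles.set_index("tile_id")[["chrom", "start", "end"]]
    merged = assignment.join(coords)
    name = (
        merged["gene_id"].astype(str)
        + "|"
        + merged["feature"].astype(str)
        + "|"
        + merged["ordinal"].astype(int).astype(str)
        + "|"
        + merged["region"].astype(str)
    )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "start": merged["start"],
            "end": merged["end"],
            "name": name,
            "score": 0,
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# --- browser tracks ---------------------------------------------------------


def write_bedgraph(
    track: TileTrack, tiles: pd.DataFrame, path: str | Path, name: str | None = None
) -> None:
    coords = tiles.set_index("tile_id")[["chrom", "start", "end"]]
    vals = track.values.reindex(coords.index)
    ok = vals.notna()
    header = f'track type=bedGraph name="{name or track.assay_kind}"\n'
    body = coords.loc[ok].assign(value=vals[ok]).to_csv(
        sep="\t", index=False, header=False, float_format="%.6g"
    )
    Path(path).write_text(header + body)


def write_wiggle(
    track: TileTrack, tiles: pd.DataFrame, path: str | Path, name: str | None = None
) -> None:
    """Fixed-step wiggle; one block per contiguous run of present tiles."""
    coords = tiles.set_index("tile_id")[["chrom", "start", "end"]]
    vals = track.values.reindex(coords.index)
    step = int((coords["end"] - coords["start"]).iloc[0])
    lines = [f'track type=wiggle_0 name="{name or track.assay_kind}"']
    prev_chrom, prev_start = None, None
    for (chrom, start), v in zip(
        coords[["chrom", "start"]].itertuples(index=False), vals.to_numpy()
    ):
        if not np.isfinite(v):
            prev_chrom = None
            continue
        if chrom != prev_chrom or prev_start is None or start != prev_start + step:
            lines.append(f"fixedStep chrom={chrom} start={start + 1} step={step} span={step}")
        lines.append(f"{v:.6g}")
        prev_chrom, prev_start = chrom, start
    Path(path).write_text("\n".join(lines) + "\n")


# --- configuration ----------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """YAML run configuration (JSON accepted, as a YAML subset)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
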