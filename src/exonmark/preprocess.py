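"""Two-channel tiling-array preprocessing.

The chain mirrors standard ChIP-chip practice: per replicate, background-
corrected ChIP over background-corrected input ratios, globally scaled to a
unit median; a composite median across bioreplicates; optional tile-by-tile
division by a histone-density track (mean of H2B and H3 composites, removing
nucleosome-abundance effects) and by a pre-immune IgG control; then log2,
median centring, and division by the dataset standard deviation (Z-scores).

Sequential-ChIP (two consecutive immunoprecipitations) data additionally
subtracts the matched IgG-second-round control from the ChIP channel before
the ratio is formed.

Missing values (flagged spots, non-positive ratios, zero denominators)
propagate as NaN; downstream statistics use available tiles only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MEASUREMENT_COLUMNS = [
    "tile_id",
    "chrom",
    "start",
    "end",
    "replicate",
    "chip",
    "chip_bg",
    "input",
    "input_bg",
    "flag",
]

#: track states, in chain order
STATES = ("ratio", "composite", "normalized", "log2_centred", "zscore")


@dataclass
class NormalizationRecord:
    """Append-only audit trail of preprocessing steps."""

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def append(self, name: str, **params) -> None:
        self.steps.append((name, params))

    def copy(self) -> "NormalizationRecord":
        return NormalizationRecord([(n, dict(p)) for n, p in self.steps])

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class TileTrack:
    """Per-tile values for one assay at one normalization state."""

    values: pd.Series  # index: tile_id; NaN = missing
    assay_kind: str = "histone_mod"
    state: str = "ratio"
    record: NormalizationRecord = field(default_factory=NormalizationRecord)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        self.values = self.values.astype(float)

    @property
    def n_present(self) -> int:
        return int(self.values.notna().sum())

    def _derive(self, values: pd.Series, state: str, step: str, **params) -> "TileTrack":
        rec = self.record.copy()
        rec.append(step, **params)
        return TileTrack(values=values, assay_kind=self.assay_kind, state=state, record=rec)


def _ratio_per_spot(df: pd.DataFrame) -> pd.Series:
    chip = df["chip"].to_numpy(float) - df["chip_bg"].to_numpy(float)
    inp = df["input"].to_numpy(float) - df["input_bg"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = chip / inp
    r[~np.isfinite(r)] = np.nan
    r[r <= 0] = np.nan
    if "flag" in df.columns:
        r[(df["flag"] != "ok").to_numpy()] = np.nan
    return pd.Series(r, index=df["tile_id"].to_numpy())


def enrichment_ratio(measurements: pd.DataFrame, assay_kind: str = "histone_mod") -> TileTrack:
    """Background-corrected ChIP/input ratio for one replicate.

    Ratios of duplicated spots (rows sharing a tile_id) are averaged before
    the global division by the median. Flagged spots and non-positive ratios
    are set missing.
    """
    r = _ratio_per_spot(measurements)
    per_tile = r.groupby(level=0, sort=False).mean()
    # keep first-appearance tile order
    order = pd.unique(measurements["tile_id"])
    per_tile = per_tile.reindex(order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = per_tile.median(skipna=True)
    if not np.isfinite(med) or per_tile.notna().sum() == 0:
        raise ValueError("empty track: no valid ratios")
    values = per_tile / med
    values.index.name = "tile_id"
    rec = NormalizationRecord()
    rep = measurements["replicate"].iloc[0] if "replicate" in measurements.columns else None
    rec.append("enrichment_ratio", replicate=rep, median=float(med))
    return TileTrack(values=values, assay_kind=assay_kind, state="ratio", record=rec)


def composite_median(tracks: Sequence[TileTrack]) -> TileTrack:
    """Per-tile median across replicate ratio tracks.

    Tiles missing in some replicates use the median of the available values;
    tiles missing everywhere stay missing.
    """
    if not tracks:
        raise ValueError("no replicate tracks")
    index = tracks[0].values.index
    for t in tracks[1:]:
        if not t.values.index.equals(index):
            raise ValueError("replicate tracks have mismatched tile sets")
    mat = np.vstack([t.values.to_numpy() for t in tracks])
    with np.errstate(all="ignore"):
        med = np.nanmedian(mat, axis=0)
    rec = NormalizationRecord()
    for t in tracks:
        rec.steps.extend(t.record.copy().steps)
    rec.append("composite_median", n_replicates=len(tracks))
    return TileTrack(
        values=pd.Series(med, index=index),
        assay_kind=tracks[0].assay_kind,
        state="composite",
        record=rec,
    )


def histone_density(h2b: TileTrack, h3: TileTrack) -> TileTrack:
    """Combined nucleosome-density track: mean of H2B and H3 composites."""
    if not h2b.values.index.equals(h3.values.index):
        raise ValueError("H2B/H3 tracks have mismatched tile sets")
    vals = pd.concat([h2b.values, h3.values], axis=1).mean(axis=1, skipna=True)
    rec = NormalizationRecord()
    rec.append("histone_density", components=("h2b", "h3"))
    return TileTrack(values=vals, assay_kind="histone_density", state="composite", record=rec)


def normalize_by_track(track: TileTrack, denominator: TileTrack) -> TileTrack:
    """Tile-by-tile division by a control track (histone density or IgG).

    Tiles where the denominator is missing or non-positive become missing.
    Chainable; the conventional order is histone density first, then IgG.
    """
    if not track.values.index.equals(denominator.values.index):
        raise ValueError("denominator track has a mismatched tile set")
    denom = denominator.values.to_numpy(float).copy()
    denom[denom <= 0] = np.nan
    values = pd.Series(track.values.to_numpy(float) / denom, index=track.values.index)
    return track._derive(
        values, "normalized", "normalize_by_track", denominator=denominator.assay_kind
    )


def log2_centred(track: TileTrack) -> TileTrack:
    """log2-transform and centre on the dataset median.

    Non-positive values become missing. Class-mean differences on this scale
    are in log2 enrichment units (the scale on which effects are injected by
    the synthetic generator).
    """
    v = track.values.to_numpy(float).copy()
    v[v <= 0] = np.nan
    with np.errstate(invalid="ignore"):
        lv = np.log2(v)
    med = np.nanmedian(lv)
    if not np.isfinite(med):
        raise ValueError("empty track: no positive values")
    values = pd.Series(lv - med, index=track.values.index)
    return track._derive(values, "log2_centred", "log2_centred", median=float(med))


def to_zscores(track: TileTrack) -> TileTrack:
    """log2 centred Z-scored enrichment: centred log2 values / dataset SD.

    The output has median ~0 and sample standard deviation 1 over present
    tiles. Raises on fewer than 3 usable values or zero SD.
    """
    if track.state != "log2_centred":
        track = log2_centred(track)
    v = track.values.to_numpy(float)
    n = np.isfinite(v).sum()
    if n < 3:
        raise ValueError("degenerate track: fewer than 3 usable values")
    sd = np.nanstd(v, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate track: zero standard deviation")
    values = pd.Series(v / sd, index=track.values.index)
    return track._derive(values, "zscore", "zscore", sd=float(sd))


def preprocess_chipchip(
    measurements: pd.DataFrame,
    histone: TileTrack | None = None,
    igg: TileTrack | None = None,
    assay_kind: str = "histone_mod",
) -> dict[str, TileTrack]:
    """Full standard chain for one assay: ratios -> composite -> controls -> Z.

    Parameters
    ----------
    measurements
        Long table over all replicates (``MEASUREMENT_COLUMNS``).
    histone, igg
        Optional composite control tracks to divide by (density first).

    Returns
    -------
    Dict of the retained states: ``composite``, ``normalized`` (when a
    control was applied), ``log2_centred`` and ``zscore``.
    """
    reps = [
        enrichment_ratio(sub, assay_kind=assay_kind)
        for _, sub in measurements.groupby("replicate", sort=True)
    ]
    comp = composite_median(reps)
    out: dict[str, TileTrack] = {"composite": comp}
    track = comp
    if histone is not None:
        track = normalize_by_track(track, histone)
    if igg is not None:
        track = normalize_by_track(track, igg)
    if track is not comp:
        out["normalized"] = track
    out["log2_centred"] = log2_centred(track)
    out["zscore"] = to_zscores(out["log2_centred"])
    return out


def composite_from_measurements(
    measurements: pd.DataFrame, assay_kind: str
) -> TileTrack:
    """Replicate ratio tracks -> composite median, for control assays."""
    reps = [
        enrichment_ratio(sub, assay_kind=assay_kind)
        for _, sub in measurements.groupby("replicate", sort=True)
    ]
    return composite_median(reps)


# --- sequential ChIP -------------------------------------------------------


def _bgcorr_channels(measurements: pd.DataFrame) -> pd.DataFrame:
    df = measurements.copy()
    df["chip_c"] = df["chip"].astype(float) - df["chip_bg"].astype(float)
    df["input_c"] = df["input"].astype(float) - df["input_bg"].astype(float)
    if "flag" in df.columns:
        bad = df["flag"] != "ok"
        df.loc[bad, ["chip_c", "input_c"]] = np.nan
    return df


def _replicate_average(measurements: pd.DataFrame) -> pd.DataFrame:
    """Average background-corrected channels over bioreplicates.

    Each replicate is first scaled so its median input signal matches the
    across-replicate median, putting arrays on a common intensity scale.
    """
    df = _bgcorr_channels(measurements)
    med_by_rep = df.groupby("replicate")["input_c"].median()
    target = float(med_by_rep.median())
    scale = target / med_by_rep
    df["scale"] = df["replicate"].map(scale)
    df["chip_s"] = df["chip_c"] * df["scale"]
    df["input_s"] = df["input_c"] * df["scale"]
    agg = df.groupby("tile_id", sort=False)[["chip_s", "input_s"]].mean()
    return agg.reindex(pd.unique(df["tile_id"]))


def seqchip_ratio(
    seq_exp: pd.DataFrame, seq_ctrl: pd.DataFrame
) -> TileTrack:
    """Control-subtracted sequential-ChIP ratio track (median-centred).

    Experimental and control datasets are replicate-averaged per channel,
    scaled to a common ChIP-channel median, and the control ChIP signal is
    subtracted from the experimental one. Non-positive corrected signals
    become missing. The ratio is then taken against the experimental input
    channel and centred on its median.
    """
    exp = _replicate_average(seq_exp)
    ctrl = _replicate_average(seq_ctrl)
    if not exp.index.equals(ctrl.index):
        raise ValueError("sequential ChIP experimental/control tile sets differ")
    # bring the control dataset onto the experimental scale via the input
    # channel (the invariant genomic material); scaling on the ChIP channel
    # would cancel the very signal being subtracted
    exp_med = float(np.nanmedian(exp["input_s"]))
    ctrl_med = float(np.nanmedian(ctrl["input_s"]))
    if ctrl_med > 0 and exp_med > 0:
        ctrl_chip = ctrl["chip_s"] * (exp_med / ctrl_med)
    else:
        ctrl_chip = ctrl["chip_s"]
    corrected = exp["chip_s"] - ctrl_chip
    corrected[corrected <= 0] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = corrected / exp["input_s"]
    ratio[~np.isfinite(ratio)] = np.nan
    ratio[ratio <= 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(ratio)
    if not np.isfinite(med):
        raise ValueError("empty track: no valid sequential-ChIP ratios")
    rec = NormalizationRecord()
    rec.append("seqchip_ratio", exp_median=exp_med, ctrl_median=ctrl_med, ratio_median=float(med))
    values = ratio / med
    values.index.name = "tile_id"
    return TileTrack(values=values, assay_kind="seq_chip", state="composite", record=rec)


def seqchip_normalize(
    seq_exp: pd.DataFrame,
    seq_ctrl: pd.DataFrame,
    histone: TileTrack | None = None,
    igg: TileTrack | None = None,
) -> TileTrack:
    """Full sequential-ChIP chain ending in a Z-score track."""
    track = seqchip_ratio(seq_exp, seq_ctrl)
    if histone is not None:
        track = normalize_by_track(track, histone)
    if igg is not None:
        track = normalize_by_track(track, igg)
    return to_zscores(track)


# --- audit replay ----------------------------------------------------------


def replay_record(
    record: NormalizationRecord,
    replicates: Sequence[pd.DataFrame] | None = None,
    controls: Mapping[str, TileTrack] | None = None,
    seqchip: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> TileTrack:
    """Re-run a recorded chain on the same inputs, bit for bit.

    ``controls`` maps assay kinds (e.g. ``histone_density``, ``igg_control``)
    to the denominator tracks the original run used.
    """
    controls = controls or {}
    track: TileTrack | None = None
    ratio_iter = iter(replicates or [])
    ratio_tracks: list[TileTrack] = []
    for name, params in record:
        if name == "enrichment_ratio":
            ratio_tracks.append(enrichment_ratio(next(ratio_iter)))
        elif name == "composite_median":
            track = composite_median(ratio_tracks)
        elif name == "seqchip_ratio":
            if seqchip is None:
                raise ValueError("seqchip inputs required to replay this record")
            track = seqchip_ratio(*seqchip)
        elif name == "normalize_by_track":
            track = normalize_by_track(track, controls[params["denominator"]])
        elif name == "log2_centred":
            track = log2_centred(track)
        elif name == "zscore":
            track = to_zscores(track)
        else:
            raise ValueError(f"unknown step {name!r}")
    if track is None:
        raise ValueError("record contains no track-producing step")
    return track
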