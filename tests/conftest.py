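import numpy as np
import pandas as pd
import pytest

from exonmark import GeneModel, TileTrack, simulate


def measurement_frame(tile_ids, chip, input_, chip_bg=0.0, input_bg=0.0,
                      replicate=1, flag=None, start=None, tile_length=100):
    """Build a raw measurement table from per-spot intensities."""
    n = len(tile_ids)
    start = np.arange(n) * tile_length if start is None else np.asarray(start)
    return pd.DataFrame(
        {
            "tile_id": tile_ids,
            "chrom": "chr1",
            "start": start,
            "end": start + tile_length,
            "replicate": replicate,
            "chip": np.asarray(chip, float),
            "chip_bg": np.broadcast_to(np.asarray(chip_bg, float), n).copy(),
            "input": np.asarray(input_, float),
            "input_bg": np.broadcast_to(np.asarray(input_bg, float), n).copy(),
            "flag": ["ok"] * n if flag is None else flag,
        }
    )


def track(values: dict, state="zscore", assay_kind="histone_mod") -> TileTrack:
    return TileTrack(values=pd.Series(values, dtype=float), state=state,
                     assay_kind=assay_kind)


@pytest.fixture
def three_exon_gene() -> GeneModel:
    """Plus-strand gene: exons [0,100), [200,300), [400,500)."""
    return GeneModel.from_transcripts(
        "g1", "chr1", "+", [[(0, 100), (200, 300), (400, 500)]]
    )


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study with a planted exon effect, shared read-only."""
    cfg = simulate.SimConfig(
        seed=42, n_genes=30, exon_effect=0.5, noise_sd=0.3,
        n_transcripts_range=(4, 4), p_alt=0.5,
    )
    return simulate.simulate_study(cfg)
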