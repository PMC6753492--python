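import numpy as np
import pandas as pd
import pytest

from spikecal import SimConfig, TaggedCounts, TrackShape, simulate_counts, simulate_tracks
from spikecal.tracks import CoverageTrack, GeneModel


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_target_genes=400,
        n_spike_genes=120,
        n_replicates_per_condition=3,
        frac_shifted=0.3,
        shift_log2fc=1.0,
        dispersion=0.05,
        mean_depth=5e5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_counts(small_cfg)


@pytest.fixture(scope="session")
def toy_tracks():
    cfg = SimConfig(n_target_genes=20, n_spike_genes=5, frac_shifted=0.5, seed=5)
    shape = TrackShape(contig_bp=100_000, promoter_density=10.0, body_density=2.0)
    return simulate_tracks(cfg, shape)


@pytest.fixture()
def uniform_track():
    """Constant density 1 signal unit per bp on a 10 kb contig, 10 bp bins."""
    return CoverageTrack({"chrT": np.full(1000, 10.0)}, bin_size=10)


@pytest.fixture()
def plus_gene():
    return GeneModel("gP", "chrT", "+", tss=4000, tes=6000)


@pytest.fixture()
def minus_gene():
    return GeneModel("gM", "chrT", "-", tss=6000, tes=4000)


def make_tagged(counts: dict, tags: dict, samples: pd.DataFrame | None = None):
    """Small TaggedCounts from dicts: counts[sample] = list, tags[gene] = tag."""
    df = pd.DataFrame(counts, index=list(tags))
    return TaggedCounts(df, pd.Series(tags), samples if samples is not None else pd.DataFrame())
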