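import numpy as np
import pytest

from dresnap.features import BinnedSignalTrack, MarkPanel
from dresnap.intervals import GenomeLayout, GenomicInterval
from dresnap.simulate import SyntheticConfig, generate_dataset


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout(chroms=(("chr1", 10_000), ("chr2", 5_000)), bin_size=100)


@pytest.fixture
def tiny_panel() -> MarkPanel:
    return MarkPanel(("markA", "markB"))


@pytest.fixture
def tiny_tracks(small_layout, tiny_panel):
    """Two deterministic marks over the small layout: ramp and constant."""
    tracks = {}
    for i, mark in enumerate(tiny_panel):
        data = {
            c: (np.arange(small_layout.n_bins(c), dtype=float) if i == 0
                else np.full(small_layout.n_bins(c), 2.0))
            for c in small_layout.chrom_names
        }
        tracks[mark] = BinnedSignalTrack(mark=mark, layout=small_layout, data=data)
    return tracks


@pytest.fixture(scope="session")
def default_dataset():
    """One generated genome at the default study conditions, shared per session."""
    config = SyntheticConfig(seed=20)
    examples, markers, truth = generate_dataset(config)
    return config, examples, markers, truth


def rand_interval(rng: np.random.Generator, chrom: str, span: int) -> GenomicInterval:
    start = int(rng.integers(0, span))
    length = int(rng.integers(1, 500))
    return GenomicInterval(chrom, start, start + length)
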