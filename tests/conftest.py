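import numpy as np
import pytest

from nm_atlas import simulate
from nm_atlas.simulate import NmSite, SimulationConfig, Transcript


@pytest.fixture(scope="session")
def small_transcriptome():
    return simulate.make_transcriptome(8, length_range=(300, 500), seed=11)


@pytest.fixture(scope="session")
def planted(small_transcriptome):
    sites = simulate.plant_sites(
        small_transcriptome, 8, f_values=[0.5, 1.0], seed=12, max_per_transcript=1
    )
    return small_transcriptome, sites


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def make_tx(seq: str, cut1: int = 0, cut2: int | None = None, tx_id: str = "tx") -> Transcript:
    return Transcript(tx_id, seq, cut1, len(seq) if cut2 is None else cut2)
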