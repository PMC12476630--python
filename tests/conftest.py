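import numpy as np
import pytest

from ribostall.core import PositionalCounts, SampleMeta, TranscriptModel
from ribostall.simulate import SimulationConfig


@pytest.fixture
def toy_transcripts():
    return {
        "tx1": TranscriptModel("g1", "tx1", "ATG" + "GTT" * 8 + "TAA"),
        "tx2": TranscriptModel("g2", "tx2", "ATG" + "GCTATTCCG" * 4 + "TAA"),
    }


@pytest.fixture
def samples_2x2():
    return [
        SampleMeta("Ctrl_r1", "Ctrl", 1),
        SampleMeta("Ctrl_r2", "Ctrl", 2),
        SampleMeta("Val_r1", "Val", 1),
        SampleMeta("Val_r2", "Val", 2),
    ]


def make_counts(arrays: dict[str, np.ndarray], samples: list[SampleMeta]) -> PositionalCounts:
    return PositionalCounts(samples=samples, counts={k: np.asarray(v, dtype=float) for k, v in arrays.items()})


@pytest.fixture
def small_sim_cfg():
    return SimulationConfig(
        n_genes=40,
        length_range=(60, 120),
        conditions=("Ctrl", "Val"),
        control="Ctrl",
        condition_effects={"Val": {"GTT": 4.0}},
        n_replicates=3,
        noise="none",
        seed=11,
    )
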