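import numpy as np
import pandas as pd
import pytest

from senclock import SimulationConfig
from senclock.datasets import MethylationDataset, SampleInfo, samples_to_frame


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced-scale study conditions for fast unit tests (same class mix
    and effect sizes as the defaults, fewer CpGs and samples)."""
    defaults = dict(
        n_cpgs=400,
        group_sizes={
            "sen_train_1": {
                "fibroblast_1": {"control": 30, "replicative": 10,
                                 "dna_damage": 10, "oncogene": 10}
            },
            "sen_train_2": {
                "dsf": {"control": 4, "replicative": 4, "dna_damage": 6},
                "msc_bm": {"control": 4, "replicative": 4, "dna_damage": 6},
            },
        },
        test_group_sizes={
            "sen_test_1": {"msc_1": {"control": 5, "replicative": 5,
                                     "dna_damage": 6}},
        },
        aging_n=150,
        mortality_n=400,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def tiny_dataset() -> MethylationDataset:
    """3 CpGs x 4 samples, two controls and two replicative-senescent."""
    rows = [
        SampleInfo("s1", "d1", "control", "none", "fibro"),
        SampleInfo("s2", "d1", "control", "none", "fibro"),
        SampleInfo("s3", "d1", "senescent", "replicative", "fibro"),
        SampleInfo("s4", "d1", "senescent", "replicative", "fibro"),
    ]
    betas = pd.DataFrame(
        [[0.2, 0.25, 0.6, 0.7], [0.5, 0.55, 0.4, 0.35], [0.9, 0.85, 0.9, 0.88]],
        index=["cgA", "cgB", "cgC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return MethylationDataset(betas=betas, samples=samples_to_frame(rows),
                              dataset_id="d1")
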