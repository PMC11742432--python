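import numpy as np
import pytest

from pumil.bags import InstanceFeature, SiteBag
from pumil.simulate import M6aGenConfig, MilGenConfig, gen_m6a_dataset, gen_mil_bags


@pytest.fixture(scope="session")
def mil_bags():
    """Well-separated fully-labeled MIL bags (fixed seed)."""
    return gen_mil_bags(MilGenConfig(n_bags=40, bag_size_range=(4, 10),
                                     instance_dim=8, class_separation=3.0,
                                     positive_instance_rate=0.4, seed=11))


@pytest.fixture(scope="session")
def m6a_small():
    """A small simulated nanopore dataset (a handful of transcripts)."""
    return gen_m6a_dataset(M6aGenConfig(n_transcripts=4, transcript_length=300,
                                        reads_per_site=(4, 12), seed=5))


def toy_bag(bag_id="b0", k=3, dim=4, seed=0, label=None):
    rng = np.random.default_rng(seed)
    insts = [InstanceFeature(f"{bag_id}_i{j}", rng.normal(size=dim))
             for j in range(k)]
    return SiteBag(bag_id, insts, hidden_bag_label=label)
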