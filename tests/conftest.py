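import numpy as np
import pytest

from ddisiam import (
    DrugDescriptorSet,
    DrugRoster,
    ModelConfig,
    SyntheticSpec,
    generate_dataset,
)

TINY_MODEL = ModelConfig(
    conv_channels=(4, 8, 8, 8, 16), mlp_hidden=(32, 16), n_classes=10
)


def make_drug(drug_id, sub=(), tgt=(), enz=()):
    return DrugDescriptorSet(
        drug_id=drug_id,
        modality_tokens={
            "substructure": frozenset(sub),
            "target": frozenset(tgt),
            "enzyme": frozenset(enz),
        },
    )


@pytest.fixture
def three_drug_roster():
    """Hand-listed token sets; used against the exhaustive pairwise oracle."""
    return DrugRoster(
        drugs=(
            make_drug("a", sub={"s1", "s2"}, tgt={"t1"}, enz={"e1", "e2"}),
            make_drug("b", sub={"s2", "s3"}, tgt={"t1", "t2"}, enz={"e2"}),
            make_drug("c", sub={"s4"}, tgt={"t2"}, enz={"e1", "e2", "e3"}),
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic benchmark (60 drugs, 6 clusters, 10 events)."""
    spec = SyntheticSpec(seed=0)
    roster, cluster_ids, pairs = generate_dataset(spec)
    return spec, roster, cluster_ids, pairs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
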