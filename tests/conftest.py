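import numpy as np
import pytest

from trialign.alignment import AlignmentConfig, pretrain
from trialign.encoders import desk_configs
from trialign.synthetic_data import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """60 records, 4 classes, half with structures."""
    records, manifest = generate_corpus(SyntheticSpec(n=60, K=4, structure_coverage=0.5, seed=11))
    return records, manifest


@pytest.fixture(scope="session")
def desk_cfg():
    return desk_configs(seed=0)


def study_corpus_split(seed: int = 0):
    """The desk-scale study corpus: n=600, K=8, coverage 0.5, 80:20 split."""
    records, _ = generate_corpus(SyntheticSpec(n=600, K=8, structure_coverage=0.5, seed=0))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    train = [records[i] for i in order[:480]]
    held = [records[i] for i in order[480:]]
    return train, held


def desk_align_cfg(total_steps: int, seed: int = 0, **kw) -> AlignmentConfig:
    """Desk-scale pretraining recipe (batch 32+32, lr 3e-4 cosine)."""
    kw.setdefault("batch_struct", 32)
    kw.setdefault("batch_text", 32)
    kw.setdefault("lr", 3e-4)
    return AlignmentConfig(total_steps=total_steps, seed=seed, **kw)


@pytest.fixture(scope="session")
def pretrained_study():
    """One full desk-scale pretraining run shared by the expensive tests."""
    train, held = study_corpus_split()
    result = pretrain(train, desk_align_cfg(total_steps=1500, seed=0))
    return result, train, held
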