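import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rnamod.io import Dataset, SequenceRecord
from rnamod.model import EncoderConfig, TransformerEncoder
from rnamod.tokenization import build_vocab


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_dataset():
    """12 labeled records (6 pos / 6 neg), deterministic sequences."""
    rng = np.random.default_rng(42)
    records = []
    for i in range(12):
        seq = "".join(rng.choice(list("ACGU"), size=21))
        records.append(SequenceRecord(id=f"r{i}", sequence=seq, label=i % 2))
    return Dataset(records, name="small")


@pytest.fixture(scope="session")
def tiny_encoder():
    """A tiny 2-layer encoder with the k=3 vocabulary."""
    cfg = EncoderConfig.tiny(vocab_size=len(build_vocab(3)), max_tokens=32)
    return TransformerEncoder(cfg, rng=np.random.default_rng(1))
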