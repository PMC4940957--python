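import pytest

from meiolnc.config import SynthConfig
from meiolnc.synth import generate_all


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Desk-scale study conditions used by most integration tests."""
    return SynthConfig(n_coding=30, n_noncoding=30, seed=7,
                       n_te_insertions=8, n_nat_pairs=5,
                       n_srna_reads=2000, library_size=100_000)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_all(small_cfg)


@pytest.fixture(scope="session")
def small_assignments(small_data):
    from meiolnc.identify import identify_transcripts
    return identify_transcripts(small_data.transcripts,
                                small_data.peptide_dbs)


@pytest.fixture(scope="session")
def coding_models(small_cfg):
    from meiolnc.pipeline import train_coding_models
    return train_coding_models(small_cfg, n_train=60)
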