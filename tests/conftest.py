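import numpy as np
import pytest

from readthrough import pts1_model, rtp_model, synth_data
from readthrough.core_seq import Transcript
from readthrough.synth_data import SimSpec


@pytest.fixture(scope="session")
def default_rtp():
    return rtp_model.default_model()


@pytest.fixture(scope="session")
def default_pts1():
    return pts1_model.default_model()


@pytest.fixture(scope="session")
def variant_db():
    return synth_data.default_variant_db()


def make_extension_transcript(ext_peptide: str = "LEAEVAGNSQPTKLRCRL", seed: int = 11) -> Transcript:
    """Transcript with a planted bounded extension encoding ``ext_peptide``."""
    rng = np.random.default_rng(seed)
    cds = synth_data._random_cds(20, rng)
    ext_nt = synth_data.reverse_translate(ext_peptide, rng)
    seq = cds + "UGA" + ext_nt + "UAA" + "GCAUGC"
    return Transcript(id="planted_ext", seq=seq, stop_start=len(cds) + 1)


@pytest.fixture
def extension_transcript():
    return make_extension_transcript()


@pytest.fixture
def sim_spec():
    return SimSpec(seed=123)
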