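import numpy as np
import pytest
from hypothesis import settings

from tmc_excite import Excitation, ExcitationList, Phase, TMCRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def stick(pairs, phase=Phase.GASPHASE):
    """ExcitationList from (wavelength, f) pairs, states numbered 1..n."""
    entries = tuple(Excitation(i + 1, w, f) for i, (w, f) in enumerate(pairs))
    return ExcitationList(entries, phase)


def make_record(gas_pairs, acetone_pairs, identifier="ABCDEF", metal="Fe", charge=0):
    return TMCRecord(
        identifier=identifier,
        metal_symbol=metal,
        total_charge=charge,
        gas=stick(gas_pairs, Phase.GASPHASE),
        acetone=stick(acetone_pairs, Phase.ACETONE),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
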