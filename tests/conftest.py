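import numpy as np
import pytest

from prolyquant import exchange, nativems, synthetic


@pytest.fixture
def noiseless_series():
    """13-point EXSY series at the default mixing times, no noise."""
    series, truth = synthetic.gen_exsy_series(k_ct=8.0, k_tc=4.65, R1=1.0,
                                              noise_cv=0.0, seed=0)
    return series, truth


@pytest.fixture
def pin1_species():
    """Free protein plus phospho/non-phospho peptide complexes."""
    protein = nativems.Species("P", 18243.0, "protein")
    pep = nativems.peptide_mass("SDPVTPK")
    ppep = nativems.peptide_mass("SDPVTPK", phospho_count=1)
    return [
        protein,
        nativems.make_complex(protein, "pep", pep),
        nativems.make_complex(protein, "ppep", ppep),
    ]
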