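import numpy as np
import pytest

from spectrum_effect import PeakList, gen_peak_tables, make_fingerprint_truth


@pytest.fixture
def truth():
    return make_fingerprint_truth(seed=7)


@pytest.fixture
def clean_peak_lists(truth):
    """Noiseless, dropout-free peak lists for the default truth."""
    tables = gen_peak_tables(truth, rt_jitter_sd=0.0, dropout_prob=0.0)
    return [
        PeakList(t["sample_id"].iloc[0], t["rt_min"].to_numpy(), t["area"].to_numpy())
        for t in tables
    ]


def tables_to_peak_lists(tables):
    return [
        PeakList(t["sample_id"].iloc[0], t["rt_min"].to_numpy(), t["area"].to_numpy())
        for t in tables
    ]
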