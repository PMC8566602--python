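import pandas as pd
import pytest

import ppbc


@pytest.fixture(scope="session")
def small_cohort() -> ppbc.SimOutput:
    """A compact simulated parity cohort shared across module tests."""
    cfg = ppbc.SimConfig(
        n_samples_per_group=10, n_genes=600, targets_per_regulon=20,
        n_regulons=5, seed=11,
    )
    return ppbc.simulate_cohort(cfg)


@pytest.fixture()
def clonotable() -> pd.DataFrame:
    def make(freqs, sample="s1", total=1000):
        counts = [max(1, round(f * total)) for f in freqs]
        return pd.DataFrame(
            {
                "sample_id": sample,
                "clonotype_key": [f"c{i}" for i in range(len(freqs))],
                "duplicate_count": counts,
            }
        )

    return make
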