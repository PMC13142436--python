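import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pairscan.config import SyntheticConfig
from pairscan.peptidome import PeptideTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_config():
    return SyntheticConfig(seed=11, n_samples_per_group=3, n_peptides=400,
                           n_features=200, n_de=20, n_proteins=24,
                           protein_len_lo=120, protein_len_hi=240)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_peptide_table(rng, n_peptides=60, n_samples=4, missing_rate=0.1,
                         max_charge=3):
    """Small random peptide table for brute-force oracle checks."""
    from pairscan.peptidome import AMINO_ACIDS
    aa = list(AMINO_ACIDS)
    design = pd.DataFrame({
        "treatment": ["untreated"] * (n_samples // 2)
                     + ["IFNg"] * (n_samples - n_samples // 2),
        "cell": ["H4"] * n_samples,
        "replicate": list(range(1, n_samples + 1)),
    }, index=[f"s{i}" for i in range(n_samples)])
    design.index.name = "sample_id"
    rows = []
    for i in range(n_peptides):
        length = int(rng.integers(5, 21))
        seq = "".join(rng.choice(aa, size=length))
        for charge in range(2, 2 + int(rng.integers(1, max_charge + 1))):
            inten = rng.lognormal(10, 1, size=n_samples)
            mask = rng.random(n_samples) < missing_rate
            inten[mask] = np.nan
            rows.append((seq, charge, *inten))
    data = pd.DataFrame(rows, columns=["sequence", "charge", *design.index])
    return PeptideTable(data=data, design=design).validate()
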