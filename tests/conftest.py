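import numpy as np
import pytest

from decoynet import GeneratorConfig, generate_stratum
from decoynet.psm import PSMRecord


def make_record(i: int, **overrides) -> PSMRecord:
    """A valid PSM record with deterministic filler values."""
    base = dict(
        spectrum_id=f"scan{i:05d}",
        peptide="ACDEFGHIK",
        protein=f"IPI{i:08d}",
        charge=2,
        xcorr=1.0 + 0.1 * i,
        delta_cn=min(0.01 * i, 1.0),
        delta_mass_ppm=0.5 * ((-1) ** i),
        sp_rank=1 + (i % 7),
        perc_ions=min(0.02 * i, 1.0),
        rt_observed_s=100.0 + 10.0 * i,
        rt_pvalue=None,
    )
    base.update(overrides)
    return PSMRecord(**base)


@pytest.fixture(scope="session")
def small_stratum():
    """One non-phospho charge-2 stratum with ground truth, n=400."""
    cfg = GeneratorConfig(n_per_stratum=400, seed=42)
    records, correct = generate_stratum(cfg, phospho=False, charge=2)
    return records, correct


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
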