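import numpy as np
import pytest

from xlnrdyn.kinetics import KineticParameters
from xlnrdyn.synthetic import SyntheticDesign, generate_study


@pytest.fixture(scope="session")
def default_params() -> KineticParameters:
    return KineticParameters()


@pytest.fixture(scope="session")
def small_study():
    """Paired Wt+Mt synthetic study (4/3 genes, 5 % noise), shared truth."""
    wt_d = SyntheticDesign(n_genes=4, noise_sd_frac=0.05)
    mt_d = SyntheticDesign(strain="Mt", n_genes=3, sampling_interval=1.0,
                           noise_sd_frac=0.05)
    return generate_study(wt_d, mt_d, seed=101)


def regulon_only(ds):
    """Drop the constitutive xlnR series from a synthetic dataset."""
    return [tc for tc in ds.timecourses if tc.gene != "xlnR"]
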