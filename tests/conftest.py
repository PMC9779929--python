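import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stressgain.simulate import ProgramConfig, TruthRecord, build_program

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def toy_oneway() -> pd.DataFrame:
    """Balanced one-way layout with closed-form REML components
    (sigma2_g = 15, sigma2_e = 2)."""
    return pd.DataFrame(
        {"geno": list("AABBCC"), "y": [10.0, 12, 14, 16, 18, 20]}
    )


SMALL_TENURE = {
    "DTSTR": {1: 10, 2: 6, 3: 4, 4: 3, 5: 2, 6: 1, 7: 1, 8: 1},
    "STRCOM": {8: 1},
    "CONCOM": {1: 3, 2: 2},
    "LOCAL": {8: 1},
}


def small_config(conditions=("MDS", "STRIN"), **truth_kw) -> ProgramConfig:
    """Compact two-condition program used across the suite."""
    truth = TruthRecord(low_h2_fraction={}, **truth_kw)
    return ProgramConfig(
        conditions=conditions,
        tenure_distribution={k: dict(v) for k, v in SMALL_TENURE.items()},
        truth=truth,
    )


@pytest.fixture(scope="session")
def small_program():
    """(plots, truth) of the compact MDS+STRIN program, seed 3."""
    return build_program(small_config(), seed=3)


@pytest.fixture(scope="session")
def default_program():
    """The full default eight-year, five-condition program."""
    return build_program(ProgramConfig(), seed=11)
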