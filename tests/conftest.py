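import numpy as np
import pytest

from memfret.synthetic import MixtureSpec, MoleculeSim, TcspcSpec, default_mixture_spec


@pytest.fixture(scope="session")
def two_state_spec() -> MixtureSpec:
    """The reference two-state lifetime mixture (1.3/2.7 ns, 0.35/0.67 ns)
    with four representative open-state amplitudes."""
    return MixtureSpec(
        means=[1.3, 2.7],
        widths=[0.35, 0.67],
        weights_per_condition={
            "low": [0.40, 0.60],
            "mid": [0.26, 0.74],
            "high": [0.09, 0.91],
            "top": [0.04, 0.96],
        },
    )


@pytest.fixture(scope="session")
def preset_spec() -> MixtureSpec:
    return default_mixture_spec()


@pytest.fixture(scope="session")
def tcspc() -> TcspcSpec:
    return TcspcSpec(background_fraction=0.02)


@pytest.fixture()
def mol_template() -> MoleculeSim:
    return MoleculeSim()
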