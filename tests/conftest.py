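import numpy as np
import pytest

from foldstab import SimSpec, ThreeStateParams, TransitionFit

#: wild-type Sis1 chemical-unfolding parameters (dG kcal/mol, m kcal/mol/M)
SIS1_CHEM = ThreeStateParams(dG_NI=7.2, m_NI=2.1, dG_IU=8.0, m_IU=1.7,
                             Y_N=0.0, Y_I=0.5, Y_U=1.0)

#: wild-type Sis1 calorimetric transitions (Tm °C, dH kcal/mol), dH_vH = dH_cal
SIS1_DSC = [TransitionFit(Tm_C=59.0, dH_cal=154.0, dH_vH=154.0),
            TransitionFit(Tm_C=67.7, dH_cal=29.5, dH_vH=29.5)]


@pytest.fixture
def sis1_params() -> ThreeStateParams:
    return SIS1_CHEM


@pytest.fixture
def sis1_transitions() -> list[TransitionFit]:
    return list(SIS1_DSC)


@pytest.fixture
def urea_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 6.0 + 1e-9, 0.1), 10)


@pytest.fixture
def dsc_grid() -> np.ndarray:
    return np.round(np.arange(15.0, 90.0 + 1e-9, 0.25), 10)


@pytest.fixture
def chem_spec(sis1_params) -> SimSpec:
    return SimSpec("chem_three_state", {"params": sis1_params}, noise_sd=0.01, seed=0)
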