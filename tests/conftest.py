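import numpy as np
import pytest

from chromdyn import FractalDomainModel, PowerLawFit


@pytest.fixture
def interior_fit() -> PowerLawFit:
    """The published nuclear-interior MSD fit (D_app, beta)."""
    return PowerLawFit(d_app=0.018, beta=0.44)


@pytest.fixture
def periphery_fit() -> PowerLawFit:
    """The published nuclear-periphery MSD fit."""
    return PowerLawFit(d_app=0.013, beta=0.39)


@pytest.fixture
def interior_model() -> FractalDomainModel:
    """Domain model matching the interior inversion at alpha = 0.9."""
    return FractalDomainModel(
        alpha=0.9, d_f=2.0909, n_nucleosomes=5000, r_rms=0.268, d_egfp=20.6
    )


@pytest.fixture
def rouse_model() -> FractalDomainModel:
    """Ideal-chain domain in a purely viscous medium (classical Rouse limit)."""
    return FractalDomainModel(alpha=1.0, d_f=2.0, n_nucleosomes=200, r_rms=0.3, d_egfp=20.6)


def power_law_msd_curve(d_app: float, beta: float, lags: np.ndarray):
    """Noiseless MSDCurve sampling an exact power law."""
    from chromdyn import MSDCurve

    lags = np.asarray(lags, dtype=float)
    msd = d_app * lags**beta
    return MSDCurve(lags=lags, msd=msd, sem=0.01 * msd, n_tracks=np.full(lags.size, 100))
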