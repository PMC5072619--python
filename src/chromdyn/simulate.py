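"""Mode-space simulation of single-nucleosome tracking experiments.

Trajectories are generated directly in the linearized normal-mode
representation of the fractal-domain model — never by integrating a
discretized Langevin equation — so every sampled process has *exactly* the
covariance the theory prescribes:

* the centre-of-mass mode is fractional Brownian motion with the closed-form
  subdiffusive MSD (exponent alpha);
* each internal mode ``X_p`` is a stationary zero-mean Gaussian process with
  variance ``<X_p^2>`` and Mittag-Leffler autocovariance ``C_p(t)``;
* a bead position is the deterministic inverse cosine transform
  ``R(n, t) = X_0(t) + 2 sum_p cos(p pi n / N) X_p(t)`` truncated at
  ``n_modes``.

The imaging model drops the z coordinate (2D projection, which is what makes
the 3/2 factor in the ensemble MSD estimator exact in expectation) and adds
i.i.d. Gaussian localization error per axis and frame.  All randomness flows
from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Union

import numpy as np
from scipy.linalg import cholesky, toeplitz
from scipy.special import gamma as _gamma

from .mittag_leffler import mittag_leffler, mittag_leffler_exp_approx
from .theory import FractalDomainModel
from .trajectories import TrackEnsemble

__all__ = [
    "SimulationConfig",
    "fractional_gaussian_path",
    "stationary_mode_path",
    "reconstruct_bead",
    "simulate_tracking_experiment",
]


@dataclass
class SimulationConfig:
    """Configuration of one synthetic tracking experiment.

    ``bead_sampling`` is either ``"uniform"`` (each track observes a bead at
    a position drawn uniformly along the chain — the situation the pooled
    ensemble MSD estimator assumes) or a fixed bead index in ``[0, N]``.
    ``localization_sigma`` is the per-axis Gaussian localization error in um;
    the 0.015 um default is a typical single-molecule figure and should be
    set explicitly when it matters.  ``kernel`` selects the mode relaxation:
    ``"ml"`` (exact Mittag-Leffler, the model's own dynamics) or ``"exp"``
    (the exponential surrogate under which the closed-form short-time MSD is
    exact).
    """

    model: FractalDomainModel
    n_tracks: int
    frames_per_track: int
    frame_interval: float = 0.05
    n_modes: int | None = None
    localization_sigma: float = 0.015
    bead_sampling: Union[str, float] = "uniform"
    kernel: str = "ml"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modes is None:
            self.n_modes = min(self.model.n_nucleosomes, 512)
        if self.n_modes < 0:
            raise ValueError("n_modes must be >= 0")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.frames_per_track < 2:
            raise ValueError("frames_per_track must be >= 2")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be >= 0")
        if self.kernel not in ("ml", "exp", "exp_approx"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if isinstance(self.bead_sampling, str):
            if self.bead_sampling != "uniform":
                raise ValueError("bead_sampling must be 'uniform' or a bead index")
        elif not 0 <= float(self.bead_sampling) <= self.model.n_nucleosomes:
            raise ValueError("fixed bead index must lie in [0, N]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        model_keys = ("alpha", "d_f", "n_nucleosomes", "r_rms", "d_egfp")
        missing = [k for k in model_keys if k not in d and k != "d_egfp"]
        if missing:
            raise ValueError(f"config is missing required field(s): {missing}")
        model = FractalDomainModel(**{k: d.pop(k) for k in model_keys if k in d})
        try:
            return cls(model=model, **d)
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc

    def to_dict(self) -> dict:
        m = self.model
        return {
            "alpha": m.alpha,
            "d_f": m.d_f,
            "n_nucleosomes": m.n_nucleosomes,
            "r_rms": m.r_rms,
            "d_egfp": m.d_egfp,
            "n_tracks": self.n_tracks,
            "frames_per_track": self.frames_per_track,
            "frame_interval": self.frame_interval,
            "n_modes": self.n_modes,
            "localization_sigma": self.localization_sigma,
            "bead_sampling": self.bead_sampling,
            "kernel": self.kernel,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# exact-covariance Gaussian process generation


def _check_times(times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1D array with >= 2 entries")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0) or dt[0] <= 0:
        raise ValueError("times must be equally spaced and increasing")
    return float(dt[0])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def fractional_gaussian_path(alpha: float, msd_coefficient: float, times, seed=None) -> np.ndarray:
    """One axis of fractional Brownian motion with MSD ``coef * t^alpha``.

    Exact-covariance generation: stationary fractional Gaussian noise
    increments are sampled by circulant (Davies-Harte) embedding of their
    Toeplitz covariance, falling back to a Cholesky factorization if the
    embedding is not positive semi-definite.  The returned path starts at 0
    at ``times[0]``.

    ``alpha = 1`` reduces to ordinary Brownian motion with i.i.d. Gaussian
    increments.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1]; got {alpha}")
    if msd_coefficient < 0:
        raise ValueError("msd_coefficient must be >= 0")
    times = np.asarray(times, dtype=float)
    dt = _check_times(times)
    n_inc = times.size - 1
    sigma2 = msd_coefficient * dt**alpha  # increment variance

    k = np.arange(n_inc, dtype=float)
    acf = 0.5 * sigma2 * (
        np.abs(k + 1) ** alpha - 2.0 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha
    )
    rng = _rng(seed)
    inc = _sample_stationary(acf, n_inc, 1, rng)[:, 0]
    return np.concatenate([[0.0], np.cumsum(inc)])


def _sample_stationary(acf: np.ndarray, n: int, n_paths: int, rng: np.random.Generator) -> np.ndarray:
    """Sample (n, n_paths) draws of a stationary Gaussian vector with given ACF."""
    emb = _circulant_eigenvalues(acf)
    if emb is not None:
        return _circulant_sample(emb, n, n_paths, rng)
    return _cholesky_of_acf(acf) @ rng.standard_normal((n, n_paths))


def _circulant_eigenvalues(acf: np.ndarray):
    """Eigenvalues of the circulant embedding, or None if not PSD."""
    n = acf.size
    if n < 3:
        return None
    circ = np.concatenate([acf, acf[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-12 * max(lam.max(), 1.0):
        return None
    return np.clip(lam, 0.0, None)


def _circulant_sample(lam: np.ndarray, n: int, n_paths: int, rng: np.random.Generator) -> np.ndarray:
    """Davies-Harte sampling given the circulant eigenvalues (length 2(n-1))."""
    m = 2 * (n - 1)
    w = np.empty((m, n_paths), dtype=complex)
    w[0] = np.sqrt(lam[0]) * rng.standard_normal(n_paths)
    a = rng.standard_normal((n - 2, n_paths))
    b = rng.standard_normal((n - 2, n_paths))
    w[1 : n - 1] = np.sqrt(lam[1 : n - 1, None] / 2.0) * (a + 1j * b)
    w[n - 1] = np.sqrt(lam[n - 1]) * rng.standard_normal(n_paths)
    w[n:] = np.conj(w[n - 2 : 0 : -1])
    x = np.fft.fft(w, axis=0) / np.sqrt(m)
    return x[:n].real


def _cholesky_of_acf(acf: np.ndarray) -> np.ndarray:
    cov = toeplitz(acf)
    return _jittered_cholesky(cov)


def _jittered_cholesky(cov: np.ndarray) -> np.ndarray:
    scale = float(np.max(np.diag(cov)))
    for jitter in (0.0, 1e-14, 1e-12, 1e-10):
        try:
            return cholesky(cov + jitter * scale * np.eye(cov.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance matrix is not positive definite even with jitter")


@lru_cache(maxsize=4)
def _mode_cholesky_factors(model: FractalDomainModel, n_frames: int, dt: float, n_modes: int, kernel: str):
    """Lower Cholesky factors of the per-axis mode covariances, p = 1..P.

    Cached: the factors depend only on the model and frame grid, not on the
    seed, so repeated simulations (e.g. across seeds) reuse them.
    """
    lags = dt * np.arange(n_frames)
    return [
        _cholesky_of_acf(_mode_acf(model, p, lags, kernel))
        for p in range(1, n_modes + 1)
    ]


def _mode_acf(model: FractalDomainModel, p: int, lags: np.ndarray, kernel: str) -> np.ndarray:
    """Per-axis autocovariance C_p(lag)/3 of mode p."""
    tau = model.relaxation_time()
    z = -(float(p) ** (1.0 + 2.0 / model.d_f)) * (lags / tau) ** model.alpha
    ml = mittag_leffler if kernel == "ml" else mittag_leffler_exp_approx
    return model.mode_variance(p) / 3.0 * np.asarray(ml(model.alpha, z))


def stationary_mode_path(model: FractalDomainModel, p: int, times, seed=None, kernel: str = "ml") -> np.ndarray:
    """Sample one internal mode ``X_p`` at the given times; shape (3, n).

    Stationary zero-mean Gaussian, per-axis variance ``<X_p^2>/3`` and
    autocovariance ``C_p(|t - t'|)/3``, generated with the exact covariance
    (dense Cholesky of the Toeplitz covariance, with a tiny diagonal jitter
    escalation if the Mittag-Leffler covariance is numerically semi-definite).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    times = np.asarray(times, dtype=float)
    dt = _check_times(times)
    L = _single_mode_factor(model, p, times.size, dt, kernel)
    rng = _rng(seed)
    return (L @ rng.standard_normal((times.size, 3))).T


@lru_cache(maxsize=2048)
def _single_mode_factor(model: FractalDomainModel, p: int, n: int, dt: float, kernel: str) -> np.ndarray:
    lags = dt * np.arange(n)
    return _cholesky_of_acf(_mode_acf(model, p, lags, kernel))


def reconstruct_bead(model: FractalDomainModel, com_path: np.ndarray, mode_paths, bead_index: float) -> np.ndarray:
    """Inverse cosine transform: ``R(n, t) = X_0(t) + 2 sum_p cos(p pi n/N) X_p(t)``.

    ``mode_paths`` is a sequence of (3, n) arrays for p = 1 ... P (possibly
    empty, in which case the bead path is the centre-of-mass path).
    """
    if not 0 <= bead_index <= model.n_nucleosomes:
        raise ValueError("bead_index must lie in [0, N]")
    out = np.array(com_path, dtype=float, copy=True)
    for p, path in enumerate(mode_paths, start=1):
        out += 2.0 * np.cos(p * np.pi * bead_index / model.n_nucleosomes) * np.asarray(path)
    return out


def _com_msd_coefficient(model: FractalDomainModel) -> float:
    """3D CoM MSD prefactor so that <dX0^2>(t) = coef * t^alpha."""
    tau = model.relaxation_time()
    return (
        2.0
        * model.r_sq
        / (model.scaling_constant * _gamma(1.0 + model.alpha) * tau**model.alpha)
    )


def simulate_tracking_experiment(config: SimulationConfig) -> TrackEnsemble:
    """Generate a :class:`TrackEnsemble` of noisy 2D single-nucleosome tracks.

    For each track: draw a bead index, sample the centre-of-mass FBM and all
    internal modes on the frame grid (exact covariances, shared Cholesky
    factors across tracks), reconstruct the 3D bead path, drop z, and add
    i.i.d. Gaussian localization noise per axis.  Bit-reproducible for a
    fixed config and seed.
    """
    model = config.model
    F = config.frames_per_track
    n_tr = config.n_tracks
    dt = config.frame_interval
    rng = np.random.default_rng(config.seed)

    # bead indices
    if isinstance(config.bead_sampling, str):
        beads = rng.uniform(0.0, model.n_nucleosomes, size=n_tr)
    else:
        beads = np.full(n_tr, float(config.bead_sampling))

    # centre of mass: FBM positions at t_1..t_{F-1}, zero at t_0
    coef_axis = _com_msd_coefficient(model) / 3.0
    t = dt * np.arange(1, F, dtype=float)
    fbm_cov = 0.5 * coef_axis * (
        t[:, None] ** model.alpha + t[None, :] ** model.alpha
        - np.abs(t[:, None] - t[None, :]) ** model.alpha
    )
    L_com = _jittered_cholesky(fbm_cov)
    z = rng.standard_normal(((F - 1), n_tr * 3))
    com = np.zeros((F, n_tr * 3))
    com[1:] = L_com @ z
    pos = com.T.reshape(n_tr, 3, F)  # (track, axis, frame)

    # internal modes, accumulated with per-track cosine weights
    kern = "ml" if config.kernel == "ml" else "exp"
    factors = _mode_cholesky_factors(model, F, dt, config.n_modes, kern)
    for p, L in enumerate(factors, start=1):
        z = rng.standard_normal((F, n_tr * 3))
        path = (L @ z).T.reshape(n_tr, 3, F)
        weight = 2.0 * np.cos(p * np.pi * beads / model.n_nucleosomes)
        pos += weight[:, None, None] * path

    xy = pos[:, :2, :]  # drop z: 2D imaging projection
    if config.localization_sigma > 0:
        xy = xy + rng.normal(0.0, config.localization_sigma, size=xy.shape)

    tracks = [np.ascontiguousarray(xy[j].T) for j in range(n_tr)]
    return TrackEnsemble(tracks=tracks, frame_interval=dt, track_ids=list(range(n_tr)))
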