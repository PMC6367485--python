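"""Dynamic light scattering: forward simulation of intensity autocorrelation
functions and their inversion by cumulant analysis and regularized NNLS.

The field correlation function of a dilute polydisperse suspension is a sum
of single-particle exponentials,

    g1(tau) = sum_i w_i exp(-q**2 D_i tau),

with Rayleigh intensity weights w_i ~ d_i**6 (an approximation that degrades
above roughly a tenth of the wavelength), the scattering vector
q = 4 pi n sin(theta/2) / lambda, and Stokes-Einstein diffusion
D_i = k_B T / (3 pi eta d_i).  The measured intensity correlation follows
the Siegert relation g2 = 1 + beta g1**2.

Cumulant analysis fits ln[(g2-1)/beta]/2 by a low-order polynomial in tau;
the mean decay rate gives the z-average diameter (harmonic intensity-weighted
mean) and the second cumulant the polydispersity index PDI = mu2 / Gamma**2.
The fit defaults to third order: the cubic term absorbs skewness of the
decay-rate distribution that otherwise biases mu2 downward on realistically
polydisperse samples, while Gamma is essentially unaffected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import units

__all__ = [
    "DLSConfig",
    "Correlogram",
    "CumulantResult",
    "CumulantModel",
    "scattering_vector",
    "stokes_einstein_diameter",
    "diffusion_coefficient",
    "intensity_weights",
    "simulate_g2",
    "cumulant_analysis",
    "nnls_size_distribution",
    "z_average_closed_form",
]

#: regularization ladder tried in order when the NNLS design is degenerate
LAMBDA_LADDER = (1e-4, 1e-3, 1e-2, 1e-1)


@dataclass
class DLSConfig:
    """Instrument configuration (25 °C aqueous defaults, 173° backscatter)."""

    temperature_K: float = 298.15
    viscosity_Pa_s: float = 0.00089
    wavelength_nm: float = 633.0
    scattering_angle_deg: float = 173.0
    refractive_index: float = 1.33
    beta: float = 0.9

    def __post_init__(self):
        if min(self.temperature_K, self.viscosity_Pa_s, self.wavelength_nm,
               self.refractive_index) <= 0:
            raise ValueError("config values must be positive")
        if not (0 < self.scattering_angle_deg < 180):
            raise ValueError("scattering angle must be in (0, 180) degrees")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must be in (0, 1]")


@dataclass
class Correlogram:
    """Measured or simulated g2(tau) with the instrument configuration."""

    taus_s: np.ndarray
    g2: np.ndarray
    config: DLSConfig

    def __post_init__(self):
        self.taus_s = np.asarray(self.taus_s, float)
        self.g2 = np.asarray(self.g2, float)
        if self.taus_s.ndim != 1 or self.taus_s.shape != self.g2.shape:
            raise ValueError("taus and g2 must be matching 1-D arrays")
        if np.any(np.diff(self.taus_s) <= 0):
            raise ValueError("lag times must be strictly increasing")


@dataclass
class CumulantResult:
    """Cumulant-fit outcome: z-average size, PDI and the raw cumulants."""

    z_average_nm: float
    pdi: float
    gamma_bar_per_s: float
    mu2_per_s2: float

    def summary(self) -> str:
        return ("Cumulant analysis\n"
                f"  z-average        {self.z_average_nm:10.2f} nm\n"
                f"  PDI              {self.pdi:10.4f}\n"
                f"  Gamma_bar        {self.gamma_bar_per_s:10.4g} 1/s\n"
                f"  mu2              {self.mu2_per_s2:10.4g} 1/s^2")


def scattering_vector(config: DLSConfig) -> float:
    """Scattering vector magnitude q = 4 pi n sin(theta/2) / lambda (1/nm)."""
    theta = math.radians(config.scattering_angle_deg)
    return 4.0 * math.pi * config.refractive_index * math.sin(theta / 2.0) / config.wavelength_nm


def stokes_einstein_diameter(D_t: float, config: DLSConfig) -> float:
    """Hydrodynamic diameter (nm) from a translational diffusion coefficient
    (m²/s): d = k_B T / (3 pi eta D_t)."""
    if D_t <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    d_m = units.BOLTZMANN_J_PER_K * config.temperature_K / (
        3.0 * math.pi * config.viscosity_Pa_s * D_t)
    return d_m * units.M_TO_NM


def diffusion_coefficient(d_nm, config: DLSConfig):
    """Inverse of :func:`stokes_einstein_diameter` (m²/s from nm)."""
    d_nm = np.asarray(d_nm, float)
    if np.any(d_nm <= 0):
        raise ValueError("diameter must be > 0")
    out = units.BOLTZMANN_J_PER_K * config.temperature_K / (
        3.0 * math.pi * config.viscosity_Pa_s * d_nm * units.NM_TO_M)
    return float(out) if out.ndim == 0 else out


def intensity_weights(diameters) -> np.ndarray:
    """Rayleigh scattering weights w_i ~ d_i**6, normalized to sum to 1."""
    d = np.asarray(diameters, float)
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    w = (d / d.max()) ** 6  # scale before powering to avoid overflow
    return w / w.sum()


def _g1(diameters, weights, config, taus_s):
    q_per_m = scattering_vector(config) * 1e9  # 1/nm -> 1/m
    Dt = units.BOLTZMANN_J_PER_K * config.temperature_K / (
        3.0 * math.pi * config.viscosity_Pa_s * np.asarray(diameters) * units.NM_TO_M)
    return np.exp(-q_per_m ** 2 * Dt[None, :] * np.asarray(taus_s)[:, None]) @ weights


def simulate_g2(pop, config: DLSConfig, taus_s, noise_sd: float = 0.0,
                seed: int | None = None) -> Correlogram:
    """Forward-simulate an intensity autocorrelation function.

    Accepts a population with ``diameters`` (core) or
    ``hydrodynamic_diameters``.  Additive Gaussian noise of SD ``noise_sd``
    requires an explicit seed.
    """
    taus_s = np.asarray(taus_s, float)
    if np.any(np.diff(taus_s) <= 0):
        raise ValueError("lag times must be strictly increasing")
    d = getattr(pop, "hydrodynamic_diameters", None)
    if d is None:
        d = pop.diameters
    w = intensity_weights(d)
    g1 = _g1(d, w, config, taus_s)
    g2 = 1.0 + config.beta * g1 ** 2
    if noise_sd > 0:
        if seed is None:
            raise ValueError("noisy simulation requires an explicit integer seed")
        g2 = g2 + np.random.default_rng(int(seed)).normal(0.0, noise_sd, g2.shape)
    return Correlogram(taus_s, g2, config)


class CumulantModel:
    """Cumulant analysis of a correlogram, statsmodels-style.

    Parameters
    ----------
    correlogram : Correlogram
    fit_fraction : float
        The fit spans lags up to where g2 - 1 has decayed to this fraction of
        its initial value (default 0.1).
    order : int
        Polynomial order of the fit of ln[(g2-1)/beta]/2 in tau (default 3;
        coefficients beyond mu2 are nuisance terms).
    """

    def __init__(self, correlogram: Correlogram, fit_fraction: float = 0.1,
                 order: int = 3):
        if not (0 < fit_fraction < 1):
            raise ValueError("fit_fraction must be in (0, 1)")
        if order < 2:
            raise ValueError("order must be >= 2")
        self.correlogram = correlogram
        self.fit_fraction = fit_fraction
        self.order = order

    def fit(self) -> CumulantResult:
        corr = self.correlogram
        y_raw = corr.g2 - 1.0
        if y_raw[0] <= 0:
            raise ValueError("g2 - 1 must be positive at the shortest lag")
        cutoff = self.fit_fraction * y_raw[0]
        in_range = y_raw >= cutoff
        # use the contiguous leading run
        stop = int(np.argmin(in_range)) if not in_range.all() else y_raw.size
        t = corr.taus_s[:stop]
        y = y_raw[:stop]
        if np.any(y <= 0):
            warnings.warn("non-positive g2 - 1 inside the fit range; truncating")
            stop2 = int(np.argmax(y <= 0))
            t, y = t[:stop2], y[:stop2]
        if t.size < self.order + 1:
            raise ValueError("too few usable lags for the cumulant fit")
        z = np.log(y / corr.config.beta) / 2.0
        # scale tau for conditioning
        t0 = t[-1]
        coef = np.polynomial.polynomial.polyfit(t / t0, z, self.order)
        gamma = -coef[1] / t0
        mu2 = 2.0 * coef[2] / t0 ** 2
        if gamma <= 0:
            raise ValueError("fitted mean decay rate is non-positive")
        q_per_m = scattering_vector(corr.config) * 1e9
        Dt = gamma / q_per_m ** 2
        z_avg = stokes_einstein_diameter(Dt, corr.config)
        return CumulantResult(z_average_nm=z_avg, pdi=mu2 / gamma ** 2,
                              gamma_bar_per_s=gamma, mu2_per_s2=mu2)


def cumulant_analysis(correlogram: Correlogram, fit_fraction: float = 0.1,
                      order: int = 3) -> CumulantResult:
    """Fit the cumulant expansion and return z-average, PDI and cumulants."""
    return CumulantModel(correlogram, fit_fraction, order).fit()


def default_diameter_grid(n: int = 64, lo: float = 1.0, hi: float = 1000.0) -> np.ndarray:
    return np.logspace(math.log10(lo), math.log10(hi), n)


def nnls_size_distribution(correlogram: Correlogram, diameter_grid=None,
                           regularization: float = LAMBDA_LADDER[0]) -> pd.DataFrame:
    """Invert g2 into an intensity-weighted size distribution on a grid.

    Solves nonnegative least squares on g1 with second-difference (Tikhonov)
    smoothing; amplitudes are normalized to sum to one.  Rows are weighted
    by the observed g1 (floored at 0.05 and normalized to unit RMS), the
    propagated inverse standard deviation of ``sqrt((g2-1)/beta)`` under
    additive g2 noise, which keeps the decayed tail from steering the fit;
    the penalty matrix is divided by its row count so that the ladder values
    of lambda are comparable across grid sizes.  If the solve fails at the
    requested regularization, stronger values from the documented ladder are
    tried with a warning.
    """
    grid = default_diameter_grid() if diameter_grid is None else np.asarray(diameter_grid, float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("diameter grid must be positive and increasing")
    corr = correlogram
    y = (corr.g2 - 1.0) / corr.config.beta
    if np.all(y <= 0):
        raise ValueError("no decay to fit: g2 - 1 is non-positive everywhere")
    g1_obs = np.sqrt(np.clip(y, 0.0, None))
    q_per_m = scattering_vector(corr.config) * 1e9
    Dt = units.BOLTZMANN_J_PER_K * corr.config.temperature_K / (
        3.0 * math.pi * corr.config.viscosity_Pa_s * grid * units.NM_TO_M)
    A = np.exp(-q_per_m ** 2 * Dt[None, :] * corr.taus_s[:, None])
    w = np.clip(g1_obs, 0.05, None)
    w = w / math.sqrt(float(np.mean(w ** 2)))
    Aw = A * w[:, None]
    bw = g1_obs * w
    m = grid.size
    D2 = np.diff(np.eye(m), n=2, axis=0)
    n_pen = D2.shape[0]
    ladder = [regularization] + [l for l in LAMBDA_LADDER if l > regularization]
    last_err = None
    for lam in ladder:
        Astack = np.vstack([Aw, (math.sqrt(lam) / n_pen) * D2])
        b = np.concatenate([bw, np.zeros(n_pen)])
        try:
            x, _ = optimize.nnls(Astack, b)
        except Exception as err:  # pragma: no cover - scipy failure path
            last_err = err
            warnings.warn(f"NNLS failed at lambda={lam}; trying stronger regularization")
            continue
        total = x.sum()
        if total > 0:
            if lam != regularization:
                warnings.warn(f"regularization raised to {lam}")
            return pd.DataFrame({"diameter_nm": grid, "intensity_fraction": x / total})
        last_err = ValueError("all-zero NNLS solution")
    raise ValueError(f"NNLS inversion failed on the full ladder: {last_err}")


def z_average_closed_form(pop, config: DLSConfig | None = None) -> float:
    """Exact harmonic intensity-weighted mean diameter (nm).

    d_z = sum(w_i) / sum(w_i / d_i) with Rayleigh weights w_i ~ d_i**6.
    Independent of the instrument configuration; serves as the oracle for
    :func:`cumulant_analysis`.
    """
    d = getattr(pop, "hydrodynamic_diameters", None)
    if d is None:
        d = np.asarray(pop, float) if not hasattr(pop, "diameters") else pop.diameters
    d = np.asarray(d, float)
    if d.size == 0:
        raise ValueError("population is empty")
    w = intensity_weights(d)
    return float(1.0 / np.sum(w / d))
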