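"""Fluorescence correlation spectroscopy calibration.

Implements the chain that turns photon-count fluctuation traces into absolute
protein concentrations and copy numbers: autocorrelation of an intensity
trace, a one-component 3D-diffusion model fit, the effective confocal
detection volume, a fluorescence-intensity -> concentration calibration line,
and the conversion of masked image voxel intensities into copy numbers.

Model: for N particles of diffusion time tau_D in a 3D-Gaussian focus with
axial structure parameter kappa,

    g(tau) = offset + (1/N) (1 + tau/tau_D)^-1 (1 + tau/(kappa^2 tau_D))^-1/2

and V_eff = pi^(3/2) w0^3 kappa with w0 = sqrt(4 D tau_D) for a calibration
dye of known diffusion coefficient D.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import constants, stats

__all__ = [
    "AutocorrelationCurve",
    "DiffusionFit",
    "EffectiveVolume",
    "CalibrationLine",
    "FcsFitError",
    "autocorrelate",
    "diffusion_model",
    "fit_diffusion",
    "effective_volume",
    "concentration_from_fcs",
    "build_calibration_line",
    "intensities_to_copies",
]

#: Avogadro constant (1/mol).
N_AVOGADRO = constants.Avogadro

#: nM implied by one molecule per femtoliter: 1/(N_A * 1e-15 L) in mol/L -> nM.
_NM_PER_MOLECULE_PER_FL = 1.0 / (N_AVOGADRO * 1e-15) * 1e9


class FcsFitError(RuntimeError):
    """Raised when an autocorrelation fit fails or is unphysical."""


@dataclass
class AutocorrelationCurve:
    """Autocorrelation amplitudes g(tau) on a strictly increasing lag grid."""

    lags: np.ndarray
    g: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must have equal length")
        if self.lags.size and (np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")


@dataclass(frozen=True)
class DiffusionFit:
    """Fitted one-component 3D-diffusion parameters."""

    n_particles: float
    tau_d_s: float
    kappa: float
    offset: float
    redchi: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_particles <= 0 or self.tau_d_s <= 0:
            raise ValueError("n_particles and tau_d_s must be positive")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")


@dataclass(frozen=True)
class EffectiveVolume:
    """3D-Gaussian effective detection volume."""

    w0_um: float
    kappa: float
    v_eff_fl: float


@dataclass(frozen=True)
class CalibrationLine:
    """Concentration = slope * (intensity - background) calibration."""

    slope: float          # nM per intensity unit
    intercept: float      # background intensity units (x-intercept)
    r_squared: float


def autocorrelate(
    times_s: np.ndarray, counts: np.ndarray, lag_grid_s: np.ndarray
) -> AutocorrelationCurve:
    """Normalized fluctuation autocorrelation of a uniformly sampled trace.

    g(tau) = <dF(t) dF(t+tau)> / <F>^2 evaluated at the requested lags,
    which are snapped to integer multiples of the sampling interval.
    """
    times_s = np.asarray(times_s, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if times_s.size != counts.size or times_s.size < 4:
        raise ValueError("trace must have matching time/count arrays of length >= 4")
    dt = np.diff(times_s)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("trace must be uniformly sampled")
    dt = float(dt[0])
    mean = counts.mean()
    if mean == 0:
        raise ValueError("zero-mean trace cannot be normalized")
    lag_grid_s = np.asarray(lag_grid_s, dtype=float)
    lag_samples = np.rint(lag_grid_s / dt).astype(int)
    if np.any(lag_samples < 1):
        raise ValueError("lags must be at least one sampling interval")
    if counts.size < 2 * lag_samples.max():
        raise ValueError("trace must cover at least twice the maximum lag")
    delta = counts - mean
    g = np.empty(lag_samples.size)
    for i, k in enumerate(lag_samples):
        g[i] = np.mean(delta[:-k] * delta[k:]) / mean**2
    return AutocorrelationCurve(lags=lag_samples * dt, g=g)


def diffusion_model(
    tau: np.ndarray, n_particles: float, tau_d_s: float, kappa: float, offset: float = 0.0
) -> np.ndarray:
    """One-component 3D free-diffusion autocorrelation model."""
    tau = np.asarray(tau, dtype=float)
    return offset + (1.0 / n_particles) / (
        (1.0 + tau / tau_d_s) * np.sqrt(1.0 + tau / (kappa**2 * tau_d_s))
    )


def fit_diffusion(
    acf: AutocorrelationCurve, kappa_fixed: float | None = 5.0
) -> DiffusionFit:
    """Least-squares fit of the 3D-diffusion model to an ACF.

    kappa defaults to a fixed 5 (standard confocal geometry) because it is
    poorly identifiable on noisy curves; pass ``kappa_fixed=None`` to free it
    within [1, 20]. Initialization: N0 from the first-lag amplitude, tau_D0
    from the lag where the amplitude has dropped to half.
    """
    if acf.lags.size < 8:
        raise ValueError("need >= 8 lag points to fit the diffusion model")
    g0 = acf.g[0]
    if not np.any(acf.g > 0) or g0 <= 0:
        raise FcsFitError("autocorrelation carries no positive amplitude to fit")
    n0 = 1.0 / g0
    half_idx = np.argmin(np.abs(acf.g - g0 / 2.0))
    tau0 = float(acf.lags[half_idx]) if acf.lags[half_idx] > 0 else float(np.median(acf.lags))

    params = lmfit.Parameters()
    params.add("n_particles", value=max(n0, 1e-3), min=1e-6)
    params.add("tau_d_s", value=tau0, min=acf.lags[0] * 1e-3, max=acf.lags[-1] * 1e3)
    if kappa_fixed is None:
        params.add("kappa", value=5.0, min=1.0, max=20.0)
    else:
        params.add("kappa", value=float(kappa_fixed), vary=False)
    params.add("offset", value=0.0)

    def residual(p):
        model = diffusion_model(
            acf.lags, p["n_particles"], p["tau_d_s"], p["kappa"], p["offset"]
        )
        res = acf.g - model
        if acf.weights is not None:
            res = res * acf.weights
        return res

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FcsFitError(f"diffusion fit did not converge: {result.message}")
    values = result.params.valuesdict()
    if values["n_particles"] <= 0:
        raise FcsFitError("fit returned a non-positive particle number")
    return DiffusionFit(
        n_particles=float(values["n_particles"]),
        tau_d_s=float(values["tau_d_s"]),
        kappa=float(values["kappa"]),
        offset=float(values["offset"]),
        redchi=float(result.redchi) if result.redchi is not None else float("nan"),
    )


def effective_volume(
    tau_d_s: float, dye_diffusion_um2_s: float, kappa: float = 5.0
) -> EffectiveVolume:
    """Effective detection volume from a calibration-dye diffusion fit.

    w0 = sqrt(4 D tau_D); V_eff = pi^(3/2) w0^3 kappa. With w0 in um the
    volume in um^3 equals femtoliters numerically. The dye diffusion
    coefficient is experiment configuration, not a package constant.
    """
    if tau_d_s <= 0 or dye_diffusion_um2_s <= 0 or kappa <= 0:
        raise ValueError("tau_d_s, dye diffusion coefficient and kappa must be positive")
    w0 = np.sqrt(4.0 * dye_diffusion_um2_s * tau_d_s)
    v_eff = np.pi**1.5 * w0**3 * kappa
    return EffectiveVolume(w0_um=float(w0), kappa=float(kappa), v_eff_fl=float(v_eff))


def concentration_from_fcs(fit: DiffusionFit, vol: EffectiveVolume) -> float:
    """Concentration in nM implied by N particles in the effective volume."""
    return fit.n_particles / vol.v_eff_fl * _NM_PER_MOLECULE_PER_FL


def build_calibration_line(
    intensities: np.ndarray, concentrations_nm: np.ndarray
) -> CalibrationLine:
    """OLS calibration line concentration = slope * (intensity - background).

    Fit as C = m*I + b; the background is reported in x-intercept form
    (-b/m) so that zero concentration maps to the background intensity.
    """
    intensities = np.asarray(intensities, dtype=float)
    concentrations_nm = np.asarray(concentrations_nm, dtype=float)
    if intensities.size != concentrations_nm.size or intensities.size < 3:
        raise ValueError("need >= 3 (intensity, concentration) pairs")
    if np.ptp(intensities) == 0:
        raise ValueError("degenerate calibration: intensities have zero variance")
    fit = stats.linregress(intensities, concentrations_nm)
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationLine(
        slope=float(fit.slope),
        intercept=float(-fit.intercept / fit.slope),
        r_squared=float(fit.rvalue**2),
    )


def intensities_to_copies(
    image: np.ndarray,
    mask: np.ndarray,
    line: CalibrationLine,
    voxel_volume_fl: float,
) -> tuple[np.ndarray, float, float]:
    """Convert masked voxel intensities to a concentration map and copies.

    Per voxel C = slope * max(I - background, 0) in nM (negative
    background-subtracted intensities clamp to zero); total copies integrate
    C * voxel volume * N_A over the mask. Returns (concentration map nM,
    total copies, mean concentration over the mask).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask must match image shape")
    if voxel_volume_fl <= 0:
        raise ValueError("voxel_volume_fl must be positive")
    if not mask.any():
        raise ValueError("empty mask")
    conc_map = np.zeros_like(image)
    conc_map[mask] = line.slope * np.clip(image[mask] - line.intercept, 0.0, None)
    copies_per_voxel = conc_map[mask] * 1e-9 * voxel_volume_fl * 1e-15 * N_AVOGADRO
    return conc_map, float(copies_per_voxel.sum()), float(conc_map[mask].mean())
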