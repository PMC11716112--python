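"""Ground-truth-known synthetic inputs for every pipeline stage.

Each generator emulates the measurement process of one assay with known
generative parameters so that the corresponding analysis module can be tested
end to end without any external data: exponential FRAP recovery with an
immobile fraction, 30-s spot-bleach depletion traces, one-component
3D-diffusion autocorrelation curves, random-spot STED fields, and loop-bearing
Gaussian-chain 3D polymer traces with localization noise and missing
positions. All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .fcs import AutocorrelationCurve, diffusion_model
from .frap import RecoveryCurve
from .spotbleach import BleachTrace
from .traces import ChromatinTrace, TraceEnsemble

__all__ = [
    "gen_frap_curve",
    "gen_spot_bleach_trace",
    "gen_fcs_curve",
    "gen_count_trace",
    "gen_sted_field",
    "gen_two_channel_spots",
    "gen_trace_ensemble",
    "gen_stag2_depletion_pair",
]


def gen_frap_curve(
    a: float,
    koff_per_s: float,
    t_grid_s: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RecoveryCurve:
    """Synthetic half-nucleus FRAP readout d(t) = a + (1-a) e^{-koff t}.

    Gaussian noise of sd ``noise_sd`` is added to d(t); the emitted
    bleached/unbleached intensity pair is constructed to be exactly
    consistent with the (noisy) difference readout.
    """
    if not (0.0 <= a <= 1.0):
        raise ValueError("a must lie in [0, 1]")
    if koff_per_s <= 0:
        raise ValueError("koff must be positive")
    t = np.asarray(t_grid_s, dtype=float)
    rng = np.random.default_rng(seed)
    d = a + (1.0 - a) * np.exp(-koff_per_s * t)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=t.shape)
        noise[0] = 0.0  # d(0) = 1 by construction of the normalization
        d = d + noise
    # intensity pair around a conserved total, initial contrast 0.8
    contrast0 = 0.8
    f_ub = 1.0 + 0.5 * contrast0 * d
    f_b = 1.0 - 0.5 * contrast0 * d
    return RecoveryCurve(
        t_s=t, f_unbleached=f_ub, f_bleached=f_b,
        prebleach_unbleached=1.0, prebleach_bleached=1.0,
    )


def gen_spot_bleach_trace(
    bound: float,
    bleach_rate_per_s: float = 0.2,
    duration_s: float = 30.0,
    dt_s: float = 0.01,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> BleachTrace:
    """Two-pool spot-bleach depletion trace.

    The bound pool (share ``bound``) bleaches exponentially in place; the
    soluble pool (share 1 - bound) is continuously replenished and stays
    constant. The default bleach rate (0.2/s) depletes the bound pool to
    <0.3% of its initial value over the 30-s illumination.
    """
    if not (0.0 <= bound <= 1.0):
        raise ValueError("bound must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2.0, dt_s)
    intensity = (1.0 - bound) + bound * np.exp(-bleach_rate_per_s * t)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=t.shape)
    return BleachTrace(t_s=t, intensity=intensity)


def gen_fcs_curve(
    n_particles: float,
    tau_d_s: float,
    kappa: float = 5.0,
    noise_sd: float = 0.0,
    lag_grid_s: np.ndarray | None = None,
    seed: int | None = None,
) -> AutocorrelationCurve:
    """Model 3D-diffusion autocorrelation curve with proportional noise.

    Noise is multiplicative Gaussian (sd ``noise_sd`` relative to the local
    model amplitude), so "1% noise" perturbs every lag by 1% of g(tau).
    Default lag grid: 64 log-spaced lags from tau_D/30 to 300 tau_D.
    """
    if n_particles <= 0 or tau_d_s <= 0 or kappa < 1:
        raise ValueError("n_particles, tau_d_s must be positive and kappa >= 1")
    if lag_grid_s is None:
        lag_grid_s = np.geomspace(tau_d_s / 30.0, 300.0 * tau_d_s, 64)
    lags = np.asarray(lag_grid_s, dtype=float)
    rng = np.random.default_rng(seed)
    g = diffusion_model(lags, n_particles, tau_d_s, kappa)
    if noise_sd > 0:
        g = g * (1.0 + rng.normal(0.0, noise_sd, size=lags.shape))
    return AutocorrelationCurve(lags=lags, g=g)


def gen_count_trace(
    n_mean: float,
    retention: float,
    n_samples: int,
    seed: int | None = None,
) -> np.ndarray:
    """Stationary particle-count trace with geometric autocorrelation.

    Immigration-death dynamics: each sampling step keeps Binomial(n, retention)
    particles and adds Poisson(n_mean (1 - retention)) newcomers, giving a
    Poisson(n_mean) stationary count with autocorrelation retention^k and thus
    a fluctuation autocorrelation g(k) = retention^k / n_mean - the discrete
    analogue of particles diffusing through a detection volume, used as an
    independent oracle for the correlator.
    """
    if not (0.0 < retention < 1.0):
        raise ValueError("retention must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_samples)
    n = rng.poisson(n_mean)
    for i in range(n_samples):
        counts[i] = n
        n = rng.binomial(n, retention) + rng.poisson(n_mean * (1.0 - retention))
    return counts


def gen_sted_field(
    density_per_um3: float,
    area_um2: float = 200.0,
    pixel_nm: float = 18.88,
    blur_sigma_px: float = 2.6,
    gain: float = 6.0,
    z_depth_um: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-spot STED image and its ground-truth centroid list.

    ``n = density x area x z_depth`` single-pixel spots are placed at uniform
    random pixel positions, Gaussian blurred (sigma 2.6 px) and scaled so an
    isolated spot peaks at ``gain`` times the maximum of the uniform [0, 1)
    random background added underneath. Returns (image, (n, 2) row/col
    ground-truth positions).
    """
    if density_per_um3 < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    side_px = int(round(np.sqrt(area_um2) * 1000.0 / pixel_nm))
    n_spots = int(round(density_per_um3 * area_um2 * z_depth_um))
    deltas = np.zeros((side_px, side_px))
    positions = rng.integers(0, side_px, size=(n_spots, 2))
    np.add.at(deltas, (positions[:, 0], positions[:, 1]), 1.0)
    blurred = ndimage.gaussian_filter(deltas, sigma=blur_sigma_px)
    # isolated blurred delta peaks at 1/(2 pi sigma^2); rescale peak -> gain
    spots = blurred * (2.0 * np.pi * blur_sigma_px**2) * gain
    background = rng.random((side_px, side_px))
    return spots + background, positions


def gen_two_channel_spots(
    density1_per_um3: float,
    density2_per_um3: float,
    coupled_fraction: float = 0.0,
    area_um2: float = 200.0,
    pixel_nm: float = 18.88,
    blur_sigma_px: float = 2.6,
    gain: float = 6.0,
    z_depth_um: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired spot fields where a fraction of channel-2 spots colocalize.

    Channel 2 places ``coupled_fraction`` of its spots at randomly chosen
    channel-1 positions and the remainder independently; supports Pearson
    colocalization baselines at realistic densities.
    """
    if not (0.0 <= coupled_fraction <= 1.0):
        raise ValueError("coupled_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    side_px = int(round(np.sqrt(area_um2) * 1000.0 / pixel_nm))
    n1 = int(round(density1_per_um3 * area_um2 * z_depth_um))
    n2 = int(round(density2_per_um3 * area_um2 * z_depth_um))
    pos1 = rng.integers(0, side_px, size=(n1, 2))
    n_coupled = min(int(round(coupled_fraction * n2)), n1)
    coupled = pos1[rng.choice(n1, size=n_coupled, replace=False)] if n_coupled else (
        np.empty((0, 2), dtype=int))
    free = rng.integers(0, side_px, size=(n2 - n_coupled, 2))
    pos2 = np.vstack([coupled, free])

    def render(positions: np.ndarray) -> np.ndarray:
        deltas = np.zeros((side_px, side_px))
        np.add.at(deltas, (positions[:, 0], positions[:, 1]), 1.0)
        blurred = ndimage.gaussian_filter(deltas, sigma=blur_sigma_px)
        return blurred * (2.0 * np.pi * blur_sigma_px**2) * gain + rng.random(
            (side_px, side_px))

    return render(pos1), render(pos2)


def gen_trace_ensemble(
    n_traces: int,
    n_bins: int = 100,
    step_nm: float = 100.0,
    loops: list[tuple[int, int, float, float]] | None = None,
    localization_noise_nm: float = 0.0,
    missing_fraction: float = 0.0,
    condition: str = "WT",
    seed: int | None = None,
) -> TraceEnsemble:
    """Gaussian-chain trace ensemble with planted loops.

    The backbone takes independent Gaussian steps with RMS length ``step_nm``
    (per-axis sd step_nm/sqrt(3)). Each planted loop (i, j, tightness_nm,
    fraction) pulls anchor j to distance tightness_nm from anchor i in the
    stated fraction of traces, rigidly translating the downstream chain so
    local structure is preserved; nested/stacked loops are planted by listing
    loops that share an anchor index. Isotropic Gaussian localization noise
    (per-axis sd ``localization_noise_nm``) is added last and positions are
    dropped independently at ``missing_fraction``.
    """
    loops = loops or []
    seen = set()
    for i, j, tight, frac in loops:
        if not (0 <= i < j < n_bins):
            raise ValueError(f"loop anchors ({i}, {j}) outside [0, {n_bins})")
        if (i, j) in seen:
            raise ValueError(f"duplicate loop anchors ({i}, {j})")
        if tight < 0 or not (0.0 <= frac <= 1.0):
            raise ValueError("tightness must be >= 0 and fraction in [0, 1]")
        seen.add((i, j))
    rng = np.random.default_rng(seed)
    per_axis = step_nm / np.sqrt(3.0)
    traces = []
    for t in range(n_traces):
        steps = rng.normal(0.0, per_axis, size=(n_bins - 1, 3))
        xyz = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        for i, j, tight, frac in sorted(loops):
            if rng.random() >= frac:
                continue
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            target = xyz[i] + tight * direction
            xyz[j:] += target - xyz[j]
        if localization_noise_nm > 0:
            xyz = xyz + rng.normal(0.0, localization_noise_nm, size=xyz.shape)
        if missing_fraction > 0:
            drop = rng.random(n_bins) < missing_fraction
            xyz[drop] = np.nan
        traces.append(ChromatinTrace(trace_id=f"{condition}_{t}", xyz_nm=xyz,
                                     condition=condition))
    return TraceEnsemble(traces)


#: base TAD-scale loops shared by both conditions: anchors ~600 kb apart
#: (12-kb bins), pulled to 40 nm in 70% of traces.
_BASE_LOOPS = [(10, 60, 40.0, 0.7)]
#: sub-loops sharing anchors with the base loop (nested/stacked geometry).
_NESTED_LOOPS = [(10, 35, 40.0, 0.5), (35, 60, 40.0, 0.5), (60, 85, 40.0, 0.5)]


def gen_stag2_depletion_pair(
    n_traces: int,
    n_bins: int = 100,
    step_nm: float = 100.0,
    localization_noise_nm: float = 20.0,
    missing_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[TraceEnsemble, TraceEnsemble]:
    """Matched WT / STAG2-depletion trace ensembles.

    WT carries base loops plus nested sub-loops sharing anchors; the
    depletion condition removes the nested sub-loops and decompacts the
    chain by 10% larger steps - the qualitative geometry expected when the
    abundant short-loop extruder is absent.
    """
    wt = gen_trace_ensemble(
        n_traces, n_bins, step_nm, _BASE_LOOPS + _NESTED_LOOPS,
        localization_noise_nm, missing_fraction, condition="WT", seed=seed,
    )
    depleted = gen_trace_ensemble(
        n_traces, n_bins, step_nm * 1.1, _BASE_LOOPS,
        localization_noise_nm, missing_fraction, condition="dSTAG2", seed=seed + 1,
    )
    return wt, depleted
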