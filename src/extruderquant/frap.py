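"""Half-nucleus FRAP kinetics with an immobile fraction.

Converts bleached/unbleached region intensities from half-nucleus
photobleaching series into the normalized-difference recovery readout

    d(t) = (F_ub(t) - F_b(t)) / (F_ub(0) - F_b(0))

and fits the single-exponential model with an immobile fraction

    d(t) = a + (1 - a) exp(-k_off t),

where ``a`` is the fraction of protein that does not exchange during the
observation window ("long-term bound") and 1/k_off is the mean residence
time of the dynamically bound pool. Region means are DNA-channel-weighted
1D-profile means along the major chromatin axis, with a central pixel gap
excluded to avoid bleach-boundary effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "RecoveryCurve",
    "FrapFit",
    "IdentifiabilityWarning",
    "extract_regions",
    "normalized_difference",
    "fit_recovery",
    "bound_fraction_from_unbleached",
]


class IdentifiabilityWarning(UserWarning):
    """The data do not constrain a fitted parameter (e.g. flat recovery)."""


@dataclass
class RecoveryCurve:
    """Time-indexed bleached/unbleached region intensities after a bleach."""

    t_s: np.ndarray
    f_unbleached: np.ndarray
    f_bleached: np.ndarray
    prebleach_unbleached: float | None = None
    prebleach_bleached: float | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f_unbleached = np.asarray(self.f_unbleached, dtype=float)
        self.f_bleached = np.asarray(self.f_bleached, dtype=float)
        if not (self.t_s.shape == self.f_unbleached.shape == self.f_bleached.shape):
            raise ValueError("t_s, f_unbleached and f_bleached must have equal length")
        if self.t_s.size and (self.t_s[0] < 0 or np.any(np.diff(self.t_s) <= 0)):
            raise ValueError("t_s must be non-negative and strictly increasing")

    @property
    def d(self) -> np.ndarray:
        """Normalized difference series (1 at t=0 by construction)."""
        return normalized_difference(self)


@dataclass(frozen=True)
class FrapFit:
    """Fitted immobile fraction and unbinding rate."""

    immobile_fraction: float
    koff_per_s: float
    rmse: float
    identifiable: bool = True

    @property
    def residence_time_s(self) -> float:
        return 1.0 / self.koff_per_s


def _profile_positions(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of masked pixels and their projection on the major axis."""
    coords = np.argwhere(mask)
    centered = coords - coords.mean(axis=0)
    # principal axis of the chromatin mask via SVD of pixel coordinates
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return coords, centered @ vt[0]


def extract_regions(
    image_stack: np.ndarray,
    chromatin_mask: np.ndarray,
    bleach_roi: np.ndarray,
    dna_stack: np.ndarray | None = None,
    gap_px: int = 14,
    n_prebleach: int = 1,
) -> RecoveryCurve:
    """DNA-weighted bleached/unbleached region means per frame.

    Pixel intensities inside the chromatin mask are aggregated along the
    mask's major 2D axis; the ``gap_px`` positions centered on the
    bleached/unbleached boundary are excluded from both region means.
    Weights are the DNA-channel intensities (uniform if no DNA stack is
    given). The first ``n_prebleach`` frames provide the pre-bleach means and
    t=0 is the first post-bleach frame (frame interval taken as 1 s unless
    rescaled by the caller).
    """
    image_stack = np.asarray(image_stack, dtype=float)
    if image_stack.ndim == 2:
        image_stack = image_stack[None]
    chromatin_mask = np.asarray(chromatin_mask, dtype=bool)
    bleach_roi = np.asarray(bleach_roi, dtype=bool)
    if not chromatin_mask.any():
        raise ValueError("empty chromatin mask")
    if not (chromatin_mask & bleach_roi).any():
        raise ValueError("bleach ROI does not overlap the chromatin mask")
    if image_stack.shape[0] <= n_prebleach:
        raise ValueError("need at least one pre-bleach and one post-bleach frame")

    coords, proj = _profile_positions(chromatin_mask)
    in_roi = bleach_roi[tuple(coords.T)]
    # boundary along the axis = midpoint between the two region centroids
    boundary = 0.5 * (proj[in_roi].mean() + proj[~in_roi].mean())
    keep = np.abs(proj - boundary) > gap_px / 2.0
    bleached_sel = keep & in_roi
    unbleached_sel = keep & ~in_roi
    if not bleached_sel.any() or not unbleached_sel.any():
        raise ValueError("a region is empty after excluding the central gap")

    rows, cols = coords[:, 0], coords[:, 1]
    if dna_stack is None:
        weights = np.ones((image_stack.shape[0], coords.shape[0]))
    else:
        dna_stack = np.asarray(dna_stack, dtype=float)
        if dna_stack.ndim == 2:
            dna_stack = np.broadcast_to(dna_stack[None], image_stack.shape)
        weights = dna_stack[:, rows, cols]
    values = image_stack[:, rows, cols]

    def wmean(sel: np.ndarray) -> np.ndarray:
        return (values[:, sel] * weights[:, sel]).sum(axis=1) / weights[:, sel].sum(axis=1)

    f_b, f_ub = wmean(bleached_sel), wmean(unbleached_sel)
    n_post = image_stack.shape[0] - n_prebleach
    return RecoveryCurve(
        t_s=np.arange(n_post, dtype=float),
        f_unbleached=f_ub[n_prebleach:],
        f_bleached=f_b[n_prebleach:],
        prebleach_unbleached=float(f_ub[:n_prebleach].mean()),
        prebleach_bleached=float(f_b[:n_prebleach].mean()),
    )


def normalized_difference(curve: RecoveryCurve) -> np.ndarray:
    """d(t) = (F_ub(t) - F_b(t)) / (F_ub(0) - F_b(0))."""
    diff = curve.f_unbleached - curve.f_bleached
    if diff.size == 0 or diff[0] == 0:
        raise ValueError("no bleach contrast: F_ub(0) equals F_b(0)")
    return diff / diff[0]


def fit_recovery(d: np.ndarray, t_s: np.ndarray) -> FrapFit:
    """Nonlinear least squares for (a, k_off) on the normalized difference.

    Bounds a in [0, 1], k_off > 0. A curve that stays flat at 1 leaves k_off
    unidentifiable (flagged rather than failed); an observation span shorter
    than the fitted residence time triggers an identifiability warning.
    """
    d = np.asarray(d, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if d.size != t_s.size or d.size < 5:
        raise ValueError("need >= 5 time points")
    if not np.isclose(d[0], 1.0, atol=0.2):
        raise ValueError("normalized difference must start near 1 at t=0")

    def model(t, a, koff):
        return a + (1.0 - a) * np.exp(-koff * t)

    span = t_s[-1] - t_s[0]
    if np.allclose(d, 1.0, atol=1e-9):
        warnings.warn(
            "curve is flat at 1 (a -> 1): k_off is unidentifiable",
            IdentifiabilityWarning,
        )
        return FrapFit(immobile_fraction=1.0, koff_per_s=1.0 / span, rmse=0.0,
                       identifiable=False)

    a0 = float(np.clip(d[-1], 0.0, 1.0))
    half = a0 + (1.0 - a0) / 2.0
    idx = np.argmin(np.abs(d - half))
    k0 = 1.0 / max(float(t_s[idx]), span / 100.0)
    try:
        popt, _ = optimize.curve_fit(
            model, t_s, d, p0=[a0, k0], bounds=([0.0, 1e-9], [1.0, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"FRAP fit did not converge: {err}") from err
    a, koff = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((model(t_s, a, koff) - d) ** 2)))
    identifiable = bool(span >= 1.0 / koff)
    if not identifiable:
        warnings.warn(
            f"observation span {span:.0f}s is shorter than the fitted residence "
            f"time {1.0 / koff:.0f}s; k_off is poorly constrained",
            IdentifiabilityWarning,
        )
    return FrapFit(immobile_fraction=a, koff_per_s=koff, rmse=rmse,
                   identifiable=identifiable)


def bound_fraction_from_unbleached(
    prebleach: float, post_total_bleach: float, background: float = 0.0
) -> float:
    """Total chromatin-bound fraction from the unbleached-region intensity.

    Valid once the soluble pool has been fully bleached (after the repeated
    bleach steps): the remaining unbleached-region intensity relative to the
    pre-bleach value is the bound fraction. Clamped to [0, 1].
    """
    if prebleach <= background:
        raise ValueError("prebleach intensity must exceed background")
    frac = (post_total_bleach - background) / (prebleach - background)
    return float(np.clip(frac, 0.0, 1.0))
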