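"""STED spot segmentation, densities, colocalization and intensity statistics.

Segments sub-diffraction protein spots inside nuclear masks and derives the
statistics used to benchmark detection, estimate labeling efficiency and
argue about dimerization: spots per um^3 (2D mask area x an assumed optical
depth, 0.5 um by default), Pearson colocalization between channels within
nuclei, and per-spot mean-intensity summaries.

Spot pipeline: Gaussian blur (sigma 1 px) -> Otsu threshold within the mask
-> binary erosion + small-object removal -> dilation -> local maxima ->
watershed split -> per-spot centroid and mean intensity on the unblurred
image. Nuclear masking: Gaussian blur -> global threshold (triangle by
default) -> connected components, removing small and border-touching
objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure, morphology, restoration, segmentation
from skimage.feature import peak_local_max

__all__ = [
    "NuclearMask",
    "SpotSet",
    "DensityEstimate",
    "SpotSegmentationParams",
    "segment_nuclei",
    "segment_spots",
    "spot_density",
    "labeling_efficiency",
    "pearson_colocalization",
    "spot_intensity_stats",
    "intensity_ratio",
    "detection_benchmark",
    "subtract_background",
]

#: 3x3 cross structuring element for erosion/dilation.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class NuclearMask:
    """Labeled nuclear segmentation with per-nucleus pixel areas."""

    labels: np.ndarray
    pixel_size_um: float = 0.01888

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())

    def area_um2(self, label: int | None = None) -> float:
        """Area of one nucleus, or of the whole mask when label is None."""
        sel = self.mask if label is None else self.labels == label
        return float(sel.sum()) * self.pixel_size_um**2


@dataclass
class SpotSet:
    """Labeled sub-diffraction spots with centroids and mean intensities."""

    labels: np.ndarray
    centroids: np.ndarray          # (n, 2) row/col pixel coordinates
    mean_intensity: np.ndarray     # (n,) a.u. on the measurement image
    area_px: np.ndarray            # (n,)
    channel: str = ""

    @property
    def n_spots(self) -> int:
        return int(self.centroids.shape[0])


@dataclass(frozen=True)
class DensityEstimate:
    """Detected spots per um^3 under an assumed optical section depth."""

    spots_per_um3: float
    z_depth_um: float = 0.5
    labeling_efficiency_pct: float | None = None


@dataclass(frozen=True)
class SpotSegmentationParams:
    """Tunable morphology parameters of the spot pipeline.

    Erosion/dilation use a 3x3 cross; spots smaller than ``min_size_px``
    after erosion are discarded as noise; local maxima must be at least
    ``min_peak_separation_px`` apart on the blurred image.
    """

    blur_sigma_px: float = 1.0
    min_size_px: int = 4
    min_peak_separation_px: int = 3
    erosion_iterations: int = 1
    dilation_iterations: int = 1


def subtract_background(image: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction (default radius 50 px)."""
    image = np.asarray(image, dtype=float)
    background = restoration.rolling_ball(image, radius=radius_px)
    return image - background


def segment_nuclei(
    dapi_image: np.ndarray,
    method: str = "triangle",
    blur_sigma_px: float = 2.0,
    min_size_px: int = 500,
    pixel_size_um: float = 0.01888,
    remove_border: bool = True,
) -> NuclearMask:
    """Threshold-based nuclear segmentation of a DNA-stain channel.

    Mild Gaussian blur, global threshold (``triangle`` default, ``otsu``
    optional), connected components, then removal of small objects and of
    nuclei touching the image border. An image with no surviving component
    yields an empty (all-zero) label mask.
    """
    if method not in ("triangle", "otsu"):
        raise ValueError(f"unknown threshold method {method!r}")
    dapi_image = np.asarray(dapi_image, dtype=float)
    if dapi_image.size == 0:
        raise ValueError("empty image")
    blurred = filters.gaussian(dapi_image, sigma=blur_sigma_px, preserve_range=True)
    if np.ptp(blurred) == 0:
        return NuclearMask(labels=np.zeros(dapi_image.shape, dtype=int),
                           pixel_size_um=pixel_size_um)
    if method == "triangle":
        thresh = filters.threshold_triangle(blurred)
    else:
        thresh = filters.threshold_otsu(blurred)
    binary = blurred > thresh
    binary = morphology.remove_small_objects(binary, max_size=min_size_px - 1)
    if remove_border:
        binary = segmentation.clear_border(binary)
    labels = measure.label(binary)
    return NuclearMask(labels=labels, pixel_size_um=pixel_size_um)


def segment_spots(
    sted_image: np.ndarray,
    mask: NuclearMask | np.ndarray,
    params: SpotSegmentationParams | None = None,
    intensity_image: np.ndarray | None = None,
) -> SpotSet:
    """Detect sub-diffraction spots inside a nuclear mask.

    ``intensity_image`` (default: the input image) is where per-spot mean
    intensities are measured; pass the background-subtracted, unblurred image
    when reproducing the measurement chain.
    """
    params = params or SpotSegmentationParams()
    sted_image = np.asarray(sted_image, dtype=float)
    mask_arr = mask.mask if isinstance(mask, NuclearMask) else np.asarray(mask, dtype=bool)
    if mask_arr.shape != sted_image.shape:
        raise ValueError("mask must match image shape")
    if not mask_arr.any():
        raise ValueError("empty nuclear mask")
    measure_on = sted_image if intensity_image is None else np.asarray(intensity_image, float)

    blurred = filters.gaussian(sted_image, sigma=params.blur_sigma_px, preserve_range=True)
    inside = blurred[mask_arr]
    if np.ptp(inside) == 0:
        empty = np.zeros(sted_image.shape, dtype=int)
        return SpotSet(labels=empty, centroids=np.empty((0, 2)),
                       mean_intensity=np.empty(0), area_px=np.empty(0, dtype=int))
    thresh = filters.threshold_otsu(inside)
    coarse = (blurred > thresh) & mask_arr

    eroded = coarse
    for _ in range(params.erosion_iterations):
        eroded = ndimage.binary_erosion(eroded, structure=_CROSS)
    eroded = morphology.remove_small_objects(eroded, max_size=params.min_size_px - 1)
    cleaned = eroded
    for _ in range(params.dilation_iterations):
        cleaned = ndimage.binary_dilation(cleaned, structure=_CROSS)
    cleaned &= mask_arr

    peaks = peak_local_max(
        blurred,
        min_distance=params.min_peak_separation_px,
        labels=measure.label(cleaned),
        exclude_border=False,
    )
    markers = np.zeros(sted_image.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    labels = segmentation.watershed(-blurred, markers=markers, mask=cleaned)

    props = measure.regionprops(labels, intensity_image=measure_on)
    centroids = np.array([p.centroid for p in props]).reshape(-1, 2)
    return SpotSet(
        labels=labels,
        centroids=centroids,
        mean_intensity=np.array([p.intensity_mean for p in props]),
        area_px=np.array([p.area for p in props], dtype=int),
    )


def spot_density(
    spots: SpotSet, mask: NuclearMask, z_depth_um: float = 0.5
) -> DensityEstimate:
    """Spots per um^3: count / (2D mask area in um^2 x assumed depth)."""
    if z_depth_um <= 0:
        raise ValueError("z_depth_um must be positive")
    area = mask.area_um2()
    if area <= 0:
        raise ValueError("mask area must be positive")
    return DensityEstimate(
        spots_per_um3=spots.n_spots / (area * z_depth_um), z_depth_um=z_depth_um
    )


def labeling_efficiency(
    detected_density: float,
    expected_density: float,
    undercount_correction: float = 1.67,
) -> float:
    """Labeling efficiency (%) after correcting for segmentation undercount.

    The spot pipeline underestimates true densities by ~40% in the relevant
    density regime, hence the default 1.67 correction factor.
    """
    if expected_density <= 0:
        raise ValueError("expected_density must be positive")
    return 100.0 * detected_density * undercount_correction / expected_density


def pearson_colocalization(
    ch1: np.ndarray, ch2: np.ndarray, mask: NuclearMask | np.ndarray
) -> dict[int, float | None]:
    """Per-nucleus Pearson r between two channels over masked pixels.

    Nuclei where either channel has zero variance report None.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have equal shape")
    labels = mask.labels if isinstance(mask, NuclearMask) else measure.label(
        np.asarray(mask, dtype=bool))
    out: dict[int, float | None] = {}
    for label in range(1, int(labels.max()) + 1):
        sel = labels == label
        a, b = ch1[sel], ch2[sel]
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            out[label] = None
            continue
        out[label] = float(stats.pearsonr(a, b).statistic)
    return out


def spot_intensity_stats(spots: SpotSet, bins: int = 50) -> dict:
    """Summary of per-spot mean intensities (median + histogram)."""
    if spots.n_spots == 0:
        raise ValueError("empty spot set")
    hist, edges = np.histogram(spots.mean_intensity, bins=bins)
    return {
        "n": spots.n_spots,
        "median": float(np.median(spots.mean_intensity)),
        "mean": float(np.mean(spots.mean_intensity)),
        "hist": hist,
        "bin_edges": edges,
    }


def intensity_ratio(spots_a: SpotSet, spots_b: SpotSet) -> float:
    """Ratio of median spot intensities, set A over set B."""
    return (
        spot_intensity_stats(spots_a)["median"] / spot_intensity_stats(spots_b)["median"]
    )


def detection_benchmark(
    densities_per_um3,
    area_um2: float = 50.0,
    seeds=(0, 1, 2),
    params: SpotSegmentationParams | None = None,
    **field_kwargs,
):
    """Detected/true spot fraction of the pipeline on simulated fields.

    Runs ``segment_spots`` with default parameters on random-spot fields of
    increasing density and returns a DataFrame with the mean detected
    fraction per density (averaged over seeds). The pipeline increasingly
    undercounts as spots merge at high density.
    """
    import pandas as pd

    from .synth import gen_sted_field

    rows = []
    mask = None
    for density in densities_per_um3:
        fractions = []
        for seed in seeds:
            image, truth = gen_sted_field(
                density, area_um2=area_um2, seed=seed, **field_kwargs)
            if mask is None or mask.labels.shape != image.shape:
                mask = NuclearMask(labels=np.ones(image.shape, dtype=int))
            spots = segment_spots(image, mask, params)
            fractions.append(spots.n_spots / max(len(truth), 1))
        rows.append({
            "density_per_um3": density,
            "n_true": int(round(density * area_um2 * 0.5)),
            "detected_fraction": float(np.mean(fractions)),
        })
    return pd.DataFrame(rows)
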