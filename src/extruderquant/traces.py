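"""Chromatin-trace distance and contact geometry.

Consumes fitted 3D chromatin traces (ordered genomic bins with x/y/z in nm,
possibly missing positions) and computes ensemble and per-trace statistics:
QC gating, median pairwise-distance matrices, contact maps at a distance
threshold, difference maps between conditions, distance-vs-genomic-separation
scaling curves, per-trace contact counts, k-nearest-neighbor distances and
nested-loop frequencies.

Conventions: bins are 0-based; distances in nm; "contact" uses strict
inequality below the threshold; adjacent bins (|i-j| <= 1) are excluded from
per-trace contact counts and loop calls as trivial polymer neighbors; missing
positions propagate as NaN and are never imputed. Ensemble frequencies
normalize by traces where both positions are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ChromatinTrace",
    "TraceEnsemble",
    "DistanceMatrix",
    "ContactMap",
    "qc_filter",
    "completeness",
    "median_distance_matrix",
    "contact_map",
    "difference_map",
    "scaling_curve",
    "scaling_exponent",
    "trace_contacts",
    "knn_mean_distance",
    "knn_count_within_radius",
    "nested_loop_frequency",
    "traces_from_dataframe",
]

#: default contact threshold for ensemble maps (nm)
MAP_CONTACT_THRESHOLD_NM = 120.0
#: default contact threshold for per-trace contact counts (nm)
TRACE_CONTACT_THRESHOLD_NM = 100.0


@dataclass
class ChromatinTrace:
    """One ordered 3D trace over ``n_bins`` fixed genomic bins.

    ``xyz_nm`` is (n_bins, 3) with NaN rows where a position was not
    detected or failed QC.
    """

    trace_id: str
    xyz_nm: np.ndarray
    condition: str = "WT"
    cell_stage: str = ""

    def __post_init__(self) -> None:
        self.xyz_nm = np.asarray(self.xyz_nm, dtype=float)
        if self.xyz_nm.ndim != 2 or self.xyz_nm.shape[1] != 3:
            raise ValueError("xyz_nm must be an (n_bins, 3) array")
        present = ~np.isnan(self.xyz_nm).any(axis=1)
        if not np.all(np.isfinite(self.xyz_nm[present])):
            raise ValueError("present coordinates must be finite")

    @property
    def n_bins(self) -> int:
        return self.xyz_nm.shape[0]

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.xyz_nm).any(axis=1)

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix (NaN where either bin absent)."""
        diff = self.xyz_nm[:, None, :] - self.xyz_nm[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class TraceEnsemble:
    """A collection of traces sharing a bin grid."""

    traces: list[ChromatinTrace]

    def __post_init__(self) -> None:
        if self.traces:
            n = self.traces[0].n_bins
            if any(t.n_bins != n for t in self.traces):
                raise ValueError("all traces must share the same number of bins")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    @property
    def n_bins(self) -> int:
        return self.traces[0].n_bins if self.traces else 0

    def distance_stack(self) -> np.ndarray:
        """(n_traces, n_bins, n_bins) stack of per-trace distance matrices."""
        return np.stack([t.distances() for t in self.traces])


@dataclass
class DistanceMatrix:
    """Median pairwise distances (nm) with contributing-trace counts."""

    median_nm: np.ndarray
    counts: np.ndarray


@dataclass
class ContactMap:
    """Contact frequencies in [0, 1] below a distance threshold."""

    frequency: np.ndarray
    counts: np.ndarray
    threshold_nm: float = MAP_CONTACT_THRESHOLD_NM


def qc_filter(
    ensemble: TraceEnsemble,
    min_positions: int = 20,
    qc_pass: dict[str, np.ndarray] | None = None,
) -> TraceEnsemble:
    """Mask QC-failing positions and drop traces with too few survivors.

    ``qc_pass`` optionally maps trace_id to a boolean per-bin pass vector;
    failing positions are set to NaN before counting. Traces with fewer than
    ``min_positions`` present positions are removed.
    """
    if min_positions < 1:
        raise ValueError("min_positions must be >= 1")
    kept = []
    for trace in ensemble:
        xyz = trace.xyz_nm.copy()
        if qc_pass is not None and trace.trace_id in qc_pass:
            xyz[~np.asarray(qc_pass[trace.trace_id], dtype=bool)] = np.nan
        masked = ChromatinTrace(trace.trace_id, xyz, trace.condition, trace.cell_stage)
        if masked.n_present >= min_positions:
            kept.append(masked)
    return TraceEnsemble(kept)


def completeness(trace: ChromatinTrace) -> float:
    """Fraction of bins with a present, QC-passing position."""
    return trace.n_present / trace.n_bins


def median_distance_matrix(ensemble: TraceEnsemble) -> DistanceMatrix:
    """Per-bin-pair median over traces of the per-trace 3D distance."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    stack = ensemble.distance_stack()
    counts = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(all="ignore"):
        median = np.nanmedian(stack, axis=0)
    median[counts == 0] = np.nan
    return DistanceMatrix(median_nm=median, counts=counts)


def contact_map(
    ensemble: TraceEnsemble, threshold_nm: float = MAP_CONTACT_THRESHOLD_NM
) -> ContactMap:
    """Fraction of traces with distance strictly below the threshold.

    Normalized per pair by the traces where both positions are present.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be positive")
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    stack = ensemble.distance_stack()
    present = ~np.isnan(stack)
    counts = present.sum(axis=0)
    hits = np.where(present, stack < threshold_nm, False).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    return ContactMap(frequency=freq, counts=counts, threshold_nm=threshold_nm)


def difference_map(a, b) -> np.ndarray:
    """Elementwise a - b for two DistanceMatrix or two ContactMap objects."""
    if type(a) is not type(b):
        raise ValueError("difference requires two objects of the same type")
    mat_a = a.median_nm if isinstance(a, DistanceMatrix) else a.frequency
    mat_b = b.median_nm if isinstance(b, DistanceMatrix) else b.frequency
    if mat_a.shape != mat_b.shape:
        raise ValueError("shape mismatch")
    return mat_a - mat_b


def scaling_curve(ensemble: TraceEnsemble) -> pd.DataFrame:
    """Distance summary per genomic separation.

    Collects every measured pairwise distance at each bin separation s >= 1
    across all traces and reports n, median and quartiles.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    stack = ensemble.distance_stack()
    n_bins = ensemble.n_bins
    rows = []
    for s in range(1, n_bins):
        idx = np.arange(n_bins - s)
        values = stack[:, idx, idx + s].ravel()
        values = values[~np.isnan(values)]
        if values.size == 0:
            continue
        rows.append(
            {
                "separation_bins": s,
                "n": values.size,
                "median_nm": float(np.median(values)),
                "q25_nm": float(np.percentile(values, 25)),
                "q75_nm": float(np.percentile(values, 75)),
            }
        )
    return pd.DataFrame(rows)


def scaling_exponent(curve: pd.DataFrame) -> float:
    """Log-log slope of median distance vs genomic separation."""
    valid = curve[curve["median_nm"] > 0]
    slope = np.polyfit(
        np.log(valid["separation_bins"].to_numpy(dtype=float)),
        np.log(valid["median_nm"].to_numpy(dtype=float)),
        1,
    )[0]
    return float(slope)


def _pair_mask(n_bins: int, min_separation: int = 2) -> np.ndarray:
    """Upper-triangle mask of pairs with j - i >= min_separation."""
    i, j = np.triu_indices(n_bins, k=min_separation)
    mask = np.zeros((n_bins, n_bins), dtype=bool)
    mask[i, j] = True
    return mask


def trace_contacts(
    trace: ChromatinTrace, threshold_nm: float = TRACE_CONTACT_THRESHOLD_NM
) -> int:
    """Number of non-adjacent bin pairs closer than the threshold.

    Pairs (i, j) with j > i + 1 and distance strictly below threshold;
    adjacent bins are trivial polymer contacts and excluded.
    """
    dist = trace.distances()
    mask = _pair_mask(trace.n_bins, min_separation=2)
    with np.errstate(invalid="ignore"):
        return int(np.sum(mask & (dist < threshold_nm)))


def knn_mean_distance(trace: ChromatinTrace, k: int) -> float:
    """Mean distance to the k spatially nearest other present positions.

    Averaged over all present positions. This is one concrete reading of a
    "k nearest neighbors" trace statistic; see ``knn_count_within_radius``
    for the alternative count-within-radius reading.
    """
    xyz = trace.xyz_nm[trace.present]
    n = xyz.shape[0]
    if k >= n:
        raise ValueError(f"k={k} requires more than k present positions (have {n})")
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    nearest = np.sort(dist, axis=1)[:, :k]
    return float(nearest.mean())


def knn_count_within_radius(trace: ChromatinTrace, radius_nm: float) -> float:
    """Mean number of other present positions within a radius (alternative)."""
    xyz = trace.xyz_nm[trace.present]
    if xyz.shape[0] < 2:
        raise ValueError("need >= 2 present positions")
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    return float((dist < radius_nm).sum(axis=1).mean())


def nested_loop_frequency(
    trace: ChromatinTrace, threshold_nm: float = TRACE_CONTACT_THRESHOLD_NM
) -> tuple[int, float]:
    """Count and rate of stacked-loop events in one trace.

    Base loops are contact pairs (i, j) with j > i + 2 and distance strictly
    below the threshold; a nested/stacked event is an unordered pair of base
    loops sharing exactly one anchor index. The rate normalizes the event
    count by the number of base loops (0 when there are none).
    """
    dist = trace.distances()
    mask = _pair_mask(trace.n_bins, min_separation=3)
    with np.errstate(invalid="ignore"):
        loop_i, loop_j = np.where(mask & (dist < threshold_nm))
    loops = list(zip(loop_i.tolist(), loop_j.tolist()))
    n_loops = len(loops)
    count = 0
    for a in range(n_loops):
        for b in range(a + 1, n_loops):
            shared = len(set(loops[a]) & set(loops[b]))
            if shared == 1:
                count += 1
    rate = count / n_loops if n_loops else 0.0
    return count, rate


def traces_from_dataframe(df: pd.DataFrame, n_bins: int | None = None) -> TraceEnsemble:
    """Build an ensemble from a long-format trace table.

    Expected columns: trace_id, bin_index, x_nm, y_nm, z_nm; optional
    condition, stage and a boolean qc_pass (failing rows are masked to NaN).
    """
    required = {"trace_id", "bin_index", "x_nm", "y_nm", "z_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table is missing columns: {sorted(missing)}")
    if n_bins is None:
        n_bins = int(df["bin_index"].max()) + 1
    traces = []
    for trace_id, group in df.groupby("trace_id", sort=False):
        xyz = np.full((n_bins, 3), np.nan)
        idx = group["bin_index"].to_numpy(dtype=int)
        coords = group[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        if "qc_pass" in group.columns:
            coords = np.where(
                group["qc_pass"].to_numpy(dtype=bool)[:, None], coords, np.nan
            )
        xyz[idx] = coords
        traces.append(
            ChromatinTrace(
                trace_id=str(trace_id),
                xyz_nm=xyz,
                condition=str(group["condition"].iloc[0]) if "condition" in group else "WT",
                cell_stage=str(group["stage"].iloc[0]) if "stage" in group else "",
            )
        )
    return TraceEnsemble(traces)
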