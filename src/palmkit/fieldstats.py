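"""Field-level statistics: NeNA precision, nanocluster density, colocalization.

NeNA (nearest-neighbour analysis) estimates the localization precision sigma
from the distances between localizations in *adjacent* frames: the same
molecule localized twice yields a displacement whose radial density is

    p_corr(r) = (r / (2 sigma^2)) exp(-r^2 / (4 sigma^2)),

a Rayleigh curve peaking at r = sqrt(2) sigma.  Uncorrelated neighbours add a
background that grows ~linearly in r at short range; the histogram is fitted
with a two-component mixture and sigma is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .blink import NanoCluster
from .errors import DataError, ParameterError
from .locdata import ROI, LocalizationTable

__all__ = [
    "PrecisionEstimate",
    "DensityReport",
    "nena_precision",
    "cluster_density",
    "colocalization_filter",
]


@dataclass
class PrecisionEstimate:
    """NeNA localization-precision fit."""

    sigma: float                       # nm
    correlated_weight: float           # mixture weight of the same-molecule term
    fit_range: tuple[float, float]     # nm
    bin_edges: np.ndarray = field(repr=False, default=None)
    histogram: np.ndarray = field(repr=False, default=None)
    n_pairs: int = 0


def _adjacent_frame_nn_distances(table: LocalizationTable, max_radius: float) -> np.ndarray:
    """Distance from every localization to its nearest neighbour one frame later."""
    frames = table.frames
    coords = table.coords
    dists: list[np.ndarray] = []
    for f in np.unique(frames):
        cur = coords[frames == f]
        nxt = coords[frames == f + 1]
        if not len(cur) or not len(nxt):
            continue
        d, _ = cKDTree(nxt).query(cur, k=1)
        dists.append(d[d <= max_radius])
    return np.concatenate(dists) if dists else np.empty(0)


def nena_correlated_density(r: np.ndarray, sigma: float) -> np.ndarray:
    """Radial density of the same-molecule displacement between two frames."""
    return (r / (2.0 * sigma**2)) * np.exp(-(r**2) / (4.0 * sigma**2))


def nena_precision(
    table: LocalizationTable,
    max_radius: float = 150.0,
    bin_nm: float = 1.0,
) -> PrecisionEstimate:
    """Estimate localization precision from adjacent-frame nearest neighbours.

    Fits ``A p_corr(r; sigma) + (1 - A) 2 r / r_max^2`` to the binned distance
    histogram (least squares, 1-nm bins by default) and returns sigma in nm.
    Requires >= 100 adjacent-frame neighbour pairs within `max_radius`.
    """
    if max_radius <= 0 or bin_nm <= 0:
        raise ParameterError("max_radius and bin_nm must be > 0")
    if len(np.unique(table.frames)) < 2:
        raise DataError("NeNA needs localizations spanning at least 2 frames")
    dists = _adjacent_frame_nn_distances(table, max_radius)
    if len(dists) < 100:
        raise DataError(
            f"too few adjacent-frame neighbour pairs for NeNA ({len(dists)} < 100)"
        )

    edges = np.arange(0.0, max_radius + bin_nm, bin_nm)
    counts, _ = np.histogram(dists, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (counts.sum() * bin_nm)

    def model(r, sigma, a):
        return a * nena_correlated_density(r, sigma) + (1 - a) * 2.0 * r / max_radius**2

    sigma0 = max(centers[np.argmax(counts)] / np.sqrt(2.0), 1.0)
    popt, _ = optimize.curve_fit(
        model, centers, density, p0=(sigma0, 0.9),
        bounds=((0.5, 0.0), (max_radius / 2.0, 1.0)), maxfev=20000,
    )
    return PrecisionEstimate(
        sigma=float(popt[0]), correlated_weight=float(popt[1]),
        fit_range=(0.0, max_radius), bin_edges=edges, histogram=counts,
        n_pairs=int(len(dists)),
    )


@dataclass
class DensityReport:
    """Nanocluster surface density per cell (ROI), in clusters per um^2."""

    per_cell: list[float]
    mean: float
    sd: float

    @classmethod
    def from_densities(cls, densities: Sequence[float]) -> "DensityReport":
        arr = np.asarray(densities, float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return cls(per_cell=list(map(float, arr)), mean=float(arr.mean()), sd=sd)


def cluster_density(
    clusters: Sequence[NanoCluster],
    rois: ROI | Sequence[ROI],
) -> DensityReport:
    """Clusters per um^2 inside each ROI, with mean +/- SD across ROIs (cells)."""
    roi_list = [rois] if isinstance(rois, ROI) else list(rois)
    if not roi_list:
        raise ParameterError("at least one ROI required")
    xs = np.array([c.x for c in clusters]) if clusters else np.empty(0)
    ys = np.array([c.y for c in clusters]) if clusters else np.empty(0)
    densities = []
    for roi in roi_list:
        area = roi.area_um2
        if area <= 0:
            raise ParameterError("ROI area must be > 0")
        inside = int(roi.contains(xs, ys).sum()) if len(xs) else 0
        densities.append(inside / area)
    return DensityReport.from_densities(densities)


def colocalization_filter(
    clusters: Sequence[NanoCluster],
    ligand: LocalizationTable,
    radius: float = 150.0,
) -> list[NanoCluster]:
    """Keep clusters whose centroid has a ligand localization within `radius` nm.

    Marks the ``colocalized`` flag on every input cluster and returns the
    retained subset.  Used to restrict counting to ligand-bound receptors.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if not len(ligand):
        raise DataError("ligand table is empty")
    if not clusters:
        return []
    tree = cKDTree(ligand.coords)
    pts = np.array([[c.x, c.y] for c in clusters])
    d, _ = tree.query(pts, k=1)
    retained = []
    for c, di in zip(clusters, d):
        c.colocalized = bool(di <= radius)
        if c.colocalized:
            retained.append(c)
    return retained
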