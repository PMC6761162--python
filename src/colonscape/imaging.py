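"""Quantification of FISH and histology images.

Scenes are single optical sections with a luminal side (row 0), a mucus
band delimited by two annotated polylines (the epithelial surface and the
mucus outer edge), and host tissue below.  Area fractions stand in for
biovolume fractions, distances are measured in micrometres using the pixel
scale, and the mucus boundaries are explicit annotations rather than
auto-detected structures, matching how such images are delineated
interactively in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, stats
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "segment_channel",
    "BiovolumeProfile",
    "biovolume_profile",
    "normalize_profiles",
    "enrichment_extent",
    "mean_cell_area",
    "ClusterStats",
    "cluster_stats",
    "mucus_thickness",
    "goblet_biovolume",
]


@dataclass(frozen=True)
class ImageStack:
    """Multi-channel raster with physical scale and boundary annotations.

    ``channels`` maps channel names to equally shaped 2-D arrays;
    ``boundaries`` maps annotation names (``"epithelial_surface"``,
    ``"mucus_outer_edge"``) to (N, 2) polylines in (x, y) pixel
    coordinates, with y increasing toward the tissue side.
    """

    channels: dict
    scale_um: float
    boundaries: dict

    def __post_init__(self) -> None:
        if self.scale_um <= 0:
            raise ValueError("scale must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def write_stack(stack: ImageStack, tiff_path, sidecar_path) -> None:
    names = list(stack.channels)
    tifffile.imwrite(
        tiff_path,
        np.stack([stack.channels[n].astype(np.float32) for n in names]),
        photometric="minisblack",
    )
    meta = {
        "scale_um": stack.scale_um,
        "channels": names,
        "boundaries": {k: np.asarray(v).tolist() for k, v in stack.boundaries.items()},
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh)


def read_stack(tiff_path, sidecar_path) -> ImageStack:
    data = tifffile.imread(tiff_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    channels = {n: data[i] for i, n in enumerate(meta["channels"])}
    boundaries = {k: np.asarray(v, dtype=float) for k, v in meta["boundaries"].items()}
    return ImageStack(channels=channels, scale_um=float(meta["scale_um"]), boundaries=boundaries)


def segment_channel(stack: ImageStack, channel: str, method: str = "otsu") -> np.ndarray:
    """Binary foreground mask of one channel by global Otsu thresholding."""
    if channel not in stack.channels:
        raise KeyError(f"unknown channel {channel!r}")
    if method != "otsu":
        raise ValueError(f"unknown method {method!r}")
    img = np.asarray(stack.channels[channel], dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("constant-intensity image: threshold undefined")
    return img > threshold_otsu(img)


def _edge_rows(boundary: np.ndarray, n_cols: int) -> np.ndarray:
    """Per-column y of a boundary polyline, linearly interpolated."""
    b = np.asarray(boundary, dtype=float)
    order = np.argsort(b[:, 0])
    return np.interp(np.arange(n_cols), b[order, 0], b[order, 1])


def _lumen_distance_um(stack: ImageStack) -> np.ndarray:
    """Euclidean distance (um) of each luminal pixel to the mucus outer edge.

    Pixels at or below the outer edge (mucus and tissue) get distance 0.
    """
    if "mucus_outer_edge" not in stack.boundaries:
        raise ValueError("mucus outer edge annotation missing")
    rows, cols = stack.shape
    edge = _edge_rows(stack.boundaries["mucus_outer_edge"], cols)
    rr = np.arange(rows)[:, None]
    non_lumen = rr >= edge[None, :]
    dist = ndimage.distance_transform_edt(~non_lumen) * stack.scale_um
    return dist


@dataclass(frozen=True)
class BiovolumeProfile:
    """Distance-binned area fraction of a target population.

    Bins are half-open [lo, hi) in micrometres from the mucus outer edge
    into the lumen; ``fraction`` is target-and-total area over total area
    per bin (NaN where pixel support falls below the minimum);
    ``normalization`` records the per-mouse lumen mean applied, if any.
    """

    bin_edges: np.ndarray
    fraction: np.ndarray
    support: np.ndarray
    normalization: float | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:],
             "fraction": self.fraction, "support": self.support}
        )


def biovolume_profile(
    target_mask: np.ndarray,
    total_mask: np.ndarray,
    stack: ImageStack,
    bin_width_um: float = 2.0,
    max_dist_um: float = 150.0,
    min_support: int = 50,
) -> BiovolumeProfile:
    """Target area fraction in distance bins from the mucus outer edge.

    The default geometry follows the field convention of 2-um bins covering
    0-150 um into the lumen.
    """
    if target_mask.shape != total_mask.shape or target_mask.shape != stack.shape:
        raise ValueError("masks and stack must share one shape")
    dist = _lumen_distance_um(stack)
    lumen = dist > 0
    if not total_mask[lumen].any():
        raise ValueError("total mask empty in the lumen")
    edges = np.arange(0.0, max_dist_um + bin_width_um / 2, bin_width_um)
    n_bins = len(edges) - 1
    idx = np.floor(dist / bin_width_um).astype(int)
    both = target_mask & total_mask
    frac = np.full(n_bins, np.nan)
    support = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = lumen & (idx == b)
        tot = int(total_mask[sel].sum())
        support[b] = tot
        if tot >= min_support:
            frac[b] = both[sel].sum() / tot
    return BiovolumeProfile(bin_edges=edges, fraction=frac, support=support)


def normalize_profiles(
    profiles: list[BiovolumeProfile], lumen_start_um: float = 75.0
) -> list[BiovolumeProfile]:
    """Normalise one mouse's profiles to its mean lumen fraction.

    Bins starting at or beyond ``lumen_start_um`` are treated as bulk lumen;
    their mean fraction across the mouse's profiles maps to 1.0.
    """
    vals = []
    for p in profiles:
        lumen_bins = p.bin_edges[:-1] >= lumen_start_um
        vals.append(p.fraction[lumen_bins])
    pooled = np.concatenate(vals)
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0 or pooled.mean() == 0:
        raise ValueError("no usable lumen bins for normalisation")
    norm = float(pooled.mean())
    return [
        replace(p, fraction=p.fraction / norm, normalization=norm) for p in profiles
    ]


def enrichment_extent(
    profiles: list[BiovolumeProfile], alpha: float = 0.05
) -> float:
    """Distance (um) over which the target stays enriched above bulk lumen.

    Per bin, a one-sided one-sample t-test across the normalised replicate
    profiles asks whether the mean fraction exceeds 1; the extent is the
    outer edge of the maximal contiguous run of significant bins starting at
    the mucus edge (bin 0).  Returns 0 when even the first bin shows no
    enrichment.
    """
    if len(profiles) < 3:
        raise ValueError("need at least three replicate profiles")
    edges = profiles[0].bin_edges
    mat = np.vstack([p.fraction for p in profiles])
    extent = 0.0
    for b in range(mat.shape[1]):
        vals = mat[:, b]
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            break
        if np.ptp(vals) == 0:
            significant = vals[0] > 1.0
        else:
            significant = stats.ttest_1samp(vals, 1.0, alternative="greater").pvalue <= alpha
        if not significant:
            break
        extent = float(edges[b + 1])
    return extent


def mean_cell_area(
    mask: np.ndarray,
    scale_um: float,
    min_components: int = 10,
    band_factor: float = 3.0,
) -> float:
    """Mean area (um^2) of isolated single cells in a mask.

    Connected components below ``band_factor`` times the modal component
    area form the single-cell band; the mean of that band converts cluster
    areas into cell numbers downstream.
    """
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())[1:] * scale_um**2
    if len(areas) < min_components:
        raise ValueError("fewer than the minimum number of components")
    hist, edges = np.histogram(areas, bins=20, range=(0, np.percentile(areas, 90) + 1e-9))
    modal = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    singles = areas[areas < band_factor * modal]
    if len(singles) < min_components:
        raise ValueError("fewer than the minimum number of single-cell components")
    return float(singles.mean())


@dataclass(frozen=True)
class ClusterStats:
    """Connected-component accounting of cells and clusters."""

    table: pd.DataFrame           # area_um2, cells, is_cluster per component
    fraction_in_clusters: float
    mean_cell_area_um2: float
    min_cells: int

    @property
    def cluster_areas(self) -> np.ndarray:
        return self.table.loc[self.table["is_cluster"], "area_um2"].to_numpy()


def cluster_stats(
    mask: np.ndarray,
    scale_um: float,
    mean_cell_area_um2: float,
    min_cells: int = 5,
) -> ClusterStats:
    """Estimate the fraction of cells living in clusters.

    Component areas are converted to cell numbers with the single-cell mean
    area (minimum one cell per component); components holding at least
    ``min_cells`` cells count as clusters.
    """
    if mean_cell_area_um2 <= 0:
        raise ValueError("mean cell area must be positive")
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())[1:] * scale_um**2
    cells = np.maximum(1, np.round(areas / mean_cell_area_um2).astype(int))
    is_cluster = cells >= min_cells
    total = int(cells.sum())
    frac = float(cells[is_cluster].sum() / total) if total else 0.0
    table = pd.DataFrame({"area_um2": areas, "cells": cells, "is_cluster": is_cluster})
    return ClusterStats(
        table=table, fraction_in_clusters=frac,
        mean_cell_area_um2=float(mean_cell_area_um2), min_cells=int(min_cells),
    )


def _point_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance of each point to a polyline (pixel units)."""
    p = np.asarray(points, float)[:, None, :]          # (n, 1, 2)
    a = np.asarray(polyline, float)[None, :-1, :]      # (1, m, 2)
    b = np.asarray(polyline, float)[None, 1:, :]
    ab = b - a
    denom = np.sum(ab**2, axis=2)
    denom[denom == 0] = 1e-300
    t = np.clip(np.sum((p - a) * ab, axis=2) / denom, 0.0, 1.0)
    proj = a + t[:, :, None] * ab
    d = np.sqrt(np.sum((p - proj) ** 2, axis=2))
    return d.min(axis=1)


def mucus_thickness(stack: ImageStack, n_min: int = 10, n_points: int = 20):
    """Thickness of the mucus band from its two boundary annotations.

    Measures the distance from ``n_points`` evenly spaced positions on the
    epithelial surface to the mucus outer edge, in micrometres.  Returns
    ``(measurements, mean, sd)``; raises if fewer than ``n_min`` valid
    measurements are possible or the boundaries cross.
    """
    for key in ("epithelial_surface", "mucus_outer_edge"):
        if key not in stack.boundaries:
            raise ValueError(f"boundary {key!r} missing")
    n_cols = stack.shape[1]
    epi = _edge_rows(stack.boundaries["epithelial_surface"], n_cols)
    outer = _edge_rows(stack.boundaries["mucus_outer_edge"], n_cols)
    if np.any(epi < outer):
        raise ValueError("boundaries cross: epithelium above the mucus outer edge")
    if n_points < n_min:
        raise ValueError("n_points below the minimum number of measurements")
    xs = np.linspace(0, n_cols - 1, n_points)
    points = np.column_stack([xs, np.interp(xs, np.arange(n_cols), epi)])
    dists = _point_polyline_distance(points, stack.boundaries["mucus_outer_edge"])
    dists = dists * stack.scale_um
    if len(dists) < n_min:
        raise ValueError("fewer than the minimum number of measurements")
    return dists, float(dists.mean()), float(dists.std(ddof=1))


def goblet_biovolume(stain_mask: np.ndarray, tissue_mask: np.ndarray) -> float:
    """Fraction of the tissue area occupied by mucin stain (goblet cells)."""
    tissue = int(tissue_mask.sum())
    if tissue == 0:
        raise ValueError("empty tissue mask")
    return float((stain_mask & tissue_mask).sum() / tissue)
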