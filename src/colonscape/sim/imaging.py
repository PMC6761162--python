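"""FISH-like scene generator with full ground truth.

Scenes have four channels (total bacteria, a target population, host
nuclei, mucin stain) over a vertical layout: lumen at the top (row 0), a
mucin band of known width above the epithelial surface, host tissue at the
bottom.  Bacterial cells are placed in the lumen by a homogeneous Poisson
background plus a Thomas-style cluster process (Poisson parents, offspring
spread by a Gaussian scale) in which aggregate cells are contact-packed —
touching, never overlapping, as bacterial cells in a clump are; each cell
joins the target population with probability

    p(d) = clip(p0 * (1 + amplitude * max(0, 1 - d / L)), 0, 1),

where d is its distance from the mucus outer edge, so the target is
enriched within L micrometres of the mucus.  Both boundary polylines are
emitted as annotations, and every latent (cell centres, memberships,
cluster parents, band width, L) is recorded in :class:`ImageTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk

from .._rng import substream
from ..imaging import ImageStack

__all__ = ["ImageSimParams", "ImageTruth", "simulate_fish_image"]


@dataclass(frozen=True)
class ImageSimParams:
    shape: tuple = (600, 400)             # rows, cols; row 0 is luminal
    scale_um: float = 0.5                 # um per pixel
    band_width_um: float = 50.0
    tissue_depth_um: float = 20.0
    undulation_amplitude_um: float = 1.5
    undulation_period_um: float = 50.0
    cell_radius_um: float = 1.0
    cell_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sd: float = 8.0
    cell_density: float = 0.04            # background cells per um^2 of lumen
    p0: float = 0.15                      # baseline target probability
    amplitude: float = 1.0                # enrichment amplitude at the edge
    extent_um: float = 30.0               # enrichment extent L
    kappa: float = 0.0004                 # Thomas parents per um^2
    mu_cluster: float = 10.0              # mean offspring per parent
    sigma_cluster_um: float = 1.5         # offspring spread
    nuclei_density: float = 0.01          # host nuclei per um^2 of tissue
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_width_um < 0:
            raise ValueError("band width must be non-negative")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.extent_um < 0:
            raise ValueError("enrichment extent must be non-negative")
        if self.sigma_cluster_um <= 0:
            raise ValueError("cluster spread must be positive")
        if self.amplitude < 0 or self.cell_density < 0 or self.kappa < 0:
            raise ValueError("rates must be non-negative")
        band_px = (self.band_width_um + self.tissue_depth_um) / self.scale_um
        if band_px >= self.shape[0]:
            raise ValueError("mucus band and tissue exceed the image height")


@dataclass(frozen=True)
class ImageTruth:
    cells: pd.DataFrame                   # row, col (px), distance_um, is_target, parent
    band_width_um: float
    extent_um: float
    fraction_in_clusters: float
    p0: float
    amplitude: float


def _target_probability(d_um: np.ndarray, p: ImageSimParams) -> np.ndarray:
    if p.extent_um > 0:
        boost = p.amplitude * np.maximum(0.0, 1.0 - d_um / p.extent_um)
    else:
        boost = 0.0
    return np.clip(p.p0 * (1.0 + boost), 0.0, 1.0)


def simulate_fish_image(params: ImageSimParams):
    """Generate one FISH-like scene; returns ``(ImageStack, ImageTruth)``."""
    p = params
    rows, cols = p.shape
    rng_geom = substream(p.seed, "image", "geometry")
    rng_cells = substream(p.seed, "image", "cells")
    rng_noise = substream(p.seed, "image", "noise")

    band_px = p.band_width_um / p.scale_um
    tissue_px = p.tissue_depth_um / p.scale_um
    phase = rng_geom.uniform(0, 2 * np.pi)
    x = np.arange(cols)
    undulation = (p.undulation_amplitude_um / p.scale_um) * np.sin(
        2 * np.pi * x * p.scale_um / p.undulation_period_um + phase
    )
    epi = rows - tissue_px + undulation              # epithelial surface, per column
    outer = epi - band_px                            # mucus outer edge
    r_px = max(1, int(round(p.cell_radius_um / p.scale_um)))

    # --- place cells in the lumen ---------------------------------------
    lumen_area_um2 = float(np.sum(np.maximum(outer, 0.0))) * p.scale_um**2

    def sample_positions(n: int) -> np.ndarray:
        pts = np.empty((0, 2))
        while len(pts) < n:
            cand_col = rng_cells.uniform(0, cols, 4 * n)
            cand_row = rng_cells.uniform(0, outer.max(), 4 * n)
            ok = cand_row < np.interp(cand_col, x, outer) - r_px
            pts = np.vstack([pts, np.column_stack([cand_row, cand_col])[ok]])
        return pts[:n]

    n_bg = rng_cells.poisson(p.cell_density * lumen_area_um2)
    background = sample_positions(n_bg)
    parents_n = rng_cells.poisson(p.kappa * lumen_area_um2)
    cluster_pts, parent_ids = [], []
    contact = 2.0 * p.cell_radius_um / p.scale_um     # centre distance at contact
    sigma_px = p.sigma_cluster_um / p.scale_um
    for k in range(parents_n):
        centre = sample_positions(1)[0]
        n_off = rng_cells.poisson(p.mu_cluster)
        if n_off == 0:
            continue
        # grow a contact-packed aggregate: cells touch but do not overlap,
        # with overall spread set by the Gaussian proposal scale sigma_c
        pts = [centre]
        attempts = 0
        while len(pts) < n_off and attempts < 60 * n_off:
            attempts += 1
            q = centre + rng_cells.normal(0, sigma_px, 2)
            arr = np.asarray(pts)
            base = arr[np.argmin(np.sum((arr - q) ** 2, axis=1))]
            direction = q - base
            norm = np.linalg.norm(direction)
            if norm < 1e-9:
                continue
            cand = base + 0.98 * contact * direction / norm
            if np.min(np.sum((arr - cand) ** 2, axis=1)) < (0.9 * contact) ** 2:
                continue
            if not (
                0 <= cand[1] < cols
                and 0 <= cand[0] < np.interp(cand[1], x, outer) - r_px
            ):
                continue
            pts.append(cand)
        cluster_pts.append(np.asarray(pts))
        parent_ids.extend([k] * len(pts))
    clustered = np.vstack(cluster_pts) if cluster_pts else np.empty((0, 2))
    all_pts = np.vstack([background, clustered])
    parents = np.concatenate([np.full(len(background), -1), np.asarray(parent_ids, int)])

    d_um = (np.interp(all_pts[:, 1], x, outer) - all_pts[:, 0]) * p.scale_um
    is_target = rng_cells.uniform(size=len(all_pts)) < _target_probability(d_um, p)

    # --- render channels -------------------------------------------------
    total = np.zeros((rows, cols))
    target = np.zeros((rows, cols))
    for (r, c), tgt in zip(all_pts, is_target):
        rr, cc = disk((r, c), r_px, shape=(rows, cols))
        total[rr, cc] = p.cell_intensity
        if tgt:
            target[rr, cc] = p.cell_intensity

    nuclei = np.zeros((rows, cols))
    tissue_area_um2 = tissue_px * cols * p.scale_um**2
    for _ in range(rng_cells.poisson(p.nuclei_density * tissue_area_um2)):
        c = rng_cells.uniform(0, cols)
        r = rng_cells.uniform(np.interp(c, x, epi), rows)
        rr, cc = disk((r, c), 3.0 / p.scale_um, shape=(rows, cols))
        nuclei[rr, cc] = p.cell_intensity

    rr_grid = np.arange(rows)[:, None]
    mucin = np.where(
        (rr_grid >= outer[None, :]) & (rr_grid < epi[None, :]), p.cell_intensity, 0.0
    )

    channels = {}
    for name, img in (
        ("total_bacteria", total), ("target", target),
        ("host_nuclei", nuclei), ("mucin_stain", mucin),
    ):
        channels[name] = img + p.background_intensity + rng_noise.normal(
            0.0, p.noise_sd, (rows, cols)
        )

    step = max(1, cols // 50)
    xs = np.arange(0, cols, step)
    boundaries = {
        "epithelial_surface": np.column_stack([xs, epi[xs]]),
        "mucus_outer_edge": np.column_stack([xs, outer[xs]]),
    }
    stack = ImageStack(channels=channels, scale_um=p.scale_um, boundaries=boundaries)

    cells = pd.DataFrame(
        {"row": all_pts[:, 0], "col": all_pts[:, 1], "distance_um": d_um,
         "is_target": is_target, "parent": parents, "radius_px": float(r_px)}
    )
    frac = float((parents >= 0).mean()) if len(parents) else 0.0
    truth = ImageTruth(
        cells=cells, band_width_um=p.band_width_um, extent_um=p.extent_um,
        fraction_in_clusters=frac, p0=p.p0, amplitude=p.amplitude,
    )
    return stack, truth
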