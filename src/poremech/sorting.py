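"""Lateral lipid sorting at the pore rim: cylindrical density maps.

Open pores reorganize the surrounding lipids: species with positive
intrinsic curvature (e.g. lyso-PC) enrich at the toroidal rim while rigid
or cone-shaped species (cholesterol, sphingomyelin) deplete. The analysis
bins per-species particle density on (r, z) around the pore axis —
r the minimum-image lateral distance from the axis, z the height —
normalizes it to the bulk membrane density at the same z, averages along z
into a 1D radial profile, and reads off a rim enrichment factor (>1
enriched, <1 depleted) in a window around the pore radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_coordinate import CylinderSpec
from .frames import MembraneFrame, minimum_image_dxy

__all__ = [
    "DensityMap",
    "RelativeDensityMap",
    "density_map",
    "relative_density",
    "radial_profile",
    "rim_enrichment",
]


@dataclass
class DensityMap:
    """Per-species particle density on cylindrical (r, z) bins.

    Densities are counts (or mass, if particle masses are supplied) per
    nm^3, averaged over frames; bin volumes are pi (r_{i+1}^2 - r_i^2) dz.
    ``axis_xy`` records the pore axis used for the last frame.
    """

    r_edges: np.ndarray
    z_edges: np.ndarray
    density: dict[str, np.ndarray]   # species -> (n_r, n_z) array
    n_frames: int
    axis_xy: tuple[float, float]

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[1:] + self.r_edges[:-1])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[1:] + self.z_edges[:-1])

    @property
    def bin_volumes(self) -> np.ndarray:
        dz = np.diff(self.z_edges)
        ring = np.pi * np.diff(self.r_edges ** 2)
        return ring[:, None] * dz[None, :]


@dataclass
class RelativeDensityMap:
    """Density relative to the bulk membrane at the same z.

    ``ratio`` is NaN (masked) where the bulk reference vanishes;
    ``r_bulk`` records the inner edge of the bulk region.
    """

    r_edges: np.ndarray
    z_edges: np.ndarray
    ratio: dict[str, np.ndarray]
    r_bulk: float

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[1:] + self.r_edges[:-1])

    @property
    def bin_volumes(self) -> np.ndarray:
        dz = np.diff(self.z_edges)
        ring = np.pi * np.diff(self.r_edges ** 2)
        return ring[:, None] * dz[None, :]


def density_map(
    frames,
    species: list[str],
    axis: str | tuple[float, float] = "auto",
    dr: float = 0.2,
    dz: float = 0.2,
    r_max: float | None = None,
    z_range: tuple[float, float] | None = None,
    masses: dict[str, float] | None = None,
    role: str | None = "head",
) -> DensityMap:
    """Cylindrically binned per-species density around the pore axis.

    ``axis="auto"`` locates the pore axis per frame via the reaction
    coordinate's densest-polar-column search, so drifting pores stay
    centered. By default only head-role particles are binned (one marker
    per lipid); pass ``role=None`` to bin every particle of the species.
    ``masses`` converts counts to mass density (per-particle mass in amu).
    """
    if isinstance(frames, MembraneFrame):
        frames = [frames]
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    box = frames[0].box
    if r_max is None:
        r_max = box[:2].min() / 2.0
    if r_max > box[:2].min() / 2.0:
        r_max = float(box[:2].min() / 2.0)  # truncate to the periodic half-box
    if z_range is None:
        z_range = (0.0, float(box[2]))
    r_edges = np.arange(0.0, r_max + dr * 0.5, dr)
    z_edges = np.arange(z_range[0], z_range[1] + dz * 0.5, dz)
    acc = {sp: np.zeros((len(r_edges) - 1, len(z_edges) - 1)) for sp in species}
    axis_xy = (box[0] / 2.0, box[1] / 2.0)
    for frame in frames:
        if axis == "auto":
            cyl = CylinderSpec(center_xy="auto").resolve(frame)
            axis_xy = tuple(cyl.center_xy)
        else:
            axis_xy = tuple(axis)
        for sp in species:
            m = frame.mask(species=sp)
            if role is not None:
                m &= frame.mask(role=role)
            pos = frame.positions[m]
            if len(pos) == 0:
                continue
            d = minimum_image_dxy(pos[:, :2], axis_xy, frame.box[:2])
            r = np.hypot(d[:, 0], d[:, 1])
            w = masses.get(sp, 1.0) if masses else 1.0
            hist, _, _ = np.histogram2d(r, pos[:, 2], bins=[r_edges, z_edges])
            acc[sp] += w * hist
    volumes = np.pi * np.diff(r_edges ** 2)[:, None] * np.diff(z_edges)[None, :]
    density = {sp: acc[sp] / (volumes * len(frames)) for sp in species}
    return DensityMap(
        r_edges=r_edges, z_edges=z_edges, density=density,
        n_frames=len(frames), axis_xy=axis_xy,
    )


def relative_density(dmap: DensityMap, r_bulk: float | None = None) -> RelativeDensityMap:
    """Density relative to the bulk membrane, per z row.

    Each (r, z) bin is divided by the volume-weighted mean density of the
    bulk region (r >= r_bulk) at the same z; where a z row has no bulk
    signal for a species, the species' overall (volume-weighted) bulk mean
    is used as fallback. Bins whose reference is zero are masked with NaN.
    The default bulk region is the outer quarter of the radial range.
    """
    if r_bulk is None:
        r_bulk = 0.75 * float(dmap.r_edges[-1])
    bulk_cols = dmap.r_centers >= r_bulk
    if np.sum(bulk_cols) < 2:
        raise ValueError("bulk region must contain at least 2 radial bins")
    vols = dmap.bin_volumes
    ratio = {}
    for sp, rho in dmap.density.items():
        vb = vols[bulk_cols, :]
        rb = rho[bulk_cols, :]
        row_ref = np.sum(rb * vb, axis=0) / np.sum(vb, axis=0)      # per z
        overall = float(np.sum(rb * vb) / np.sum(vb))               # fallback
        ref = np.where(row_ref > 0, row_ref, overall)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(ref[None, :] > 0, rho / ref[None, :], np.nan)
        ratio[sp] = rel
    return RelativeDensityMap(
        r_edges=dmap.r_edges, z_edges=dmap.z_edges, ratio=ratio, r_bulk=float(r_bulk)
    )


def radial_profile(rel: RelativeDensityMap, z_window: float | None = None,
                   z_center: float | None = None) -> dict[str, np.ndarray]:
    """Volume-weighted z-average of the relative density, per radial bin.

    Averages over |z - z_center| <= z_window (default: the full map around
    its midpoint). Returns species -> 1D array over r bins; bins with no
    unmasked data are NaN.
    """
    zc = z_center if z_center is not None else 0.5 * (rel.z_edges[0] + rel.z_edges[-1])
    if z_window is None:
        z_window = 0.5 * (rel.z_edges[-1] - rel.z_edges[0])
    zcenters = 0.5 * (rel.z_edges[1:] + rel.z_edges[:-1])
    sel = np.abs(zcenters - zc) <= z_window + 1e-12
    if not np.any(sel):
        raise ValueError("z window selects no rows of the map")
    vols = rel.bin_volumes[:, sel]
    out = {}
    for sp, ratio in rel.ratio.items():
        vals = ratio[:, sel]
        w = np.where(np.isnan(vals), 0.0, vols)
        num = np.nansum(vals * vols, axis=1)
        den = np.sum(w, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[sp] = np.where(den > 0, num / den, np.nan)
    return out


def rim_enrichment(
    profile: dict[str, np.ndarray],
    r_centers: np.ndarray,
    pore_radius: float,
    half_width: float = 0.5,
) -> dict[str, float]:
    """Mean relative density in the rim window per species.

    The window is r in [pore_radius - half_width, pore_radius + half_width];
    values above 1 mean rim enrichment, below 1 depletion, 0 exclusion.
    """
    lo, hi = pore_radius - half_width, pore_radius + half_width
    sel = (r_centers >= lo) & (r_centers <= hi)
    if not np.any(sel):
        raise ValueError(f"rim window [{lo}, {hi}] lies outside the profile range")
    out = {}
    for sp, vals in profile.items():
        window = vals[sel]
        window = window[~np.isnan(window)]
        out[sp] = float(np.mean(window)) if len(window) else float("nan")
    return out
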