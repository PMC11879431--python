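"""Estimation of membrane elastic parameters from fluctuations and profiles.

For a planar membrane at thermal equilibrium the quadratic tilt and splay
energies imply Gaussian fluctuation statistics, so the moduli follow from
equipartition:

* tilt modulus    kappa_theta = k_B T / (var_per_component(t) * A_l),
* bending modulus kappa       = k_B T / (var(S) * A_l),

with t the in-plane lipid tilt vector, S the splay (director divergence
along the line joining a neighbor pair) and A_l the area per lipid. The
spontaneous curvature follows from the first moment of the lateral stress
profile of one leaflet, J_s = (1/kappa) * integral (z - pivot) s(z) dz, and
the hydrophobic core thickness from the crossing points of the tail and
water density profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import MembraneFrame
from .units import KB, DEFAULT_TEMPERATURE

__all__ = [
    "DirectorField",
    "StressProfile",
    "compute_directors",
    "estimate_tilt_modulus",
    "estimate_bending_modulus",
    "spontaneous_curvature",
    "hydrophobic_thickness",
]


@dataclass
class StressProfile:
    """Tabulated lateral-minus-normal stress density s(z) in kJ mol^-1 nm^-3.

    ``leaflet_bounds`` holds the (z_lo, z_hi) interval of each leaflet,
    ordered (upper, lower), with z measured from the membrane center.
    """

    z: np.ndarray
    s: np.ndarray
    leaflet_bounds: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.z.shape != self.s.shape or self.z.ndim != 1:
            raise ValueError("z and s must be 1-D arrays of equal length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        for lo, hi in self.leaflet_bounds:
            if lo < self.z[0] - 1e-9 or hi > self.z[-1] + 1e-9:
                raise ValueError("leaflet bounds must lie inside the grid")


@dataclass
class DirectorField:
    """Per-lipid directors, reference normals and tilt vectors of one frame.

    ``leaflet`` is +1 for the upper and -1 for the lower leaflet;
    ``positions`` are the head-bead coordinates (nm), kept for neighbor-pair
    splay estimation. Lipids whose director is nearly parallel to the
    membrane plane (n . d <= 0.1) are excluded and counted in
    ``n_excluded``.
    """

    directors: np.ndarray      # (N, 3) unit vectors, head -> water orientation
    normals: np.ndarray        # (N, 3) unit reference normals
    tilts: np.ndarray          # (N, 2) in-plane tilt vectors
    leaflet: np.ndarray        # (N,) +1 / -1
    positions: np.ndarray      # (N, 3) head positions, nm
    A_l: float                 # mean area per lipid, nm^2
    n_excluded: int = 0


def compute_directors(frame: MembraneFrame) -> DirectorField:
    """Per-lipid director and tilt field of a planar membrane frame.

    The director d is the unit vector from the tail-bead centroid to the
    head bead (pointing from the core toward water); the reference normal
    is +z for the upper leaflet and -z for the lower (planar membranes
    only). The tilt vector is the in-plane part of d/(n.d) - n.
    """
    roles = frame.role.astype(str)
    z_mid = float(np.median(frame.positions[roles == "head", 2]))
    dirs, tilts, leaflets, heads = [], [], [], []
    n_excluded = 0
    for _, grp in frame.lipid_molecules().items():
        grp_roles = roles[grp]
        head = frame.positions[grp[grp_roles == "head"][0]]
        tail_centroid = frame.positions[grp[grp_roles == "tail"]].mean(axis=0)
        d = head - tail_centroid
        norm = np.linalg.norm(d)
        if norm == 0:
            n_excluded += 1
            continue
        d = d / norm
        sign = 1.0 if head[2] >= z_mid else -1.0
        n = np.array([0.0, 0.0, sign])
        nd = float(np.dot(n, d))
        if nd <= 0.1:
            n_excluded += 1
            continue
        t3 = d / nd - n
        dirs.append(d)
        tilts.append(t3[:2])
        leaflets.append(sign)
        heads.append(head)
    if not dirs:
        raise ValueError("no usable lipids in frame")
    leaflets = np.array(leaflets)
    area = frame.box[0] * frame.box[1]
    n_per_leaflet = max(np.sum(leaflets > 0), np.sum(leaflets < 0))
    return DirectorField(
        directors=np.array(dirs),
        normals=np.column_stack([np.zeros((len(dirs), 2)), leaflets]),
        tilts=np.array(tilts),
        leaflet=leaflets,
        positions=np.array(heads),
        A_l=float(area / n_per_leaflet),
        n_excluded=n_excluded,
    )


# ----------------------------------------------------------------------
# fluctuation estimators
# ----------------------------------------------------------------------

def _tilt_modulus_from_samples(tilts: np.ndarray, A_l: float, temperature: float) -> float:
    var = float(np.var(tilts, ddof=1))  # pooled per-component variance
    if var == 0:
        raise ValueError("tilt variance is zero; modulus estimate is singular")
    return KB * temperature / (var * A_l)


def estimate_tilt_modulus(
    field_or_tilts: DirectorField | np.ndarray,
    area_per_lipid: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> dict:
    """Tilt modulus from Gaussian tilt fluctuations (equipartition).

    Accepts either a :class:`DirectorField` (or a list of them, pooled over
    frames) or a raw (n, 2) array of tilt vectors with an explicit
    ``area_per_lipid``. For a field, per-leaflet estimates and their mean
    are reported; for raw samples the pooled estimate is returned in every
    slot. Requires at least 500 samples.

    Returns ``{"kappa_theta": ..., "upper": ..., "lower": ..., "n": ...}``
    in kJ mol^-1 nm^-2.
    """
    if isinstance(field_or_tilts, DirectorField):
        fields = [field_or_tilts]
    elif isinstance(field_or_tilts, (list, tuple)) and field_or_tilts and isinstance(
        field_or_tilts[0], DirectorField
    ):
        fields = list(field_or_tilts)
    else:
        tilts = np.asarray(field_or_tilts, dtype=float)
        if area_per_lipid is None:
            raise ValueError("area_per_lipid is required with raw tilt samples")
        if len(tilts) < 500:
            raise ValueError("need at least 500 tilt samples")
        k = _tilt_modulus_from_samples(tilts, area_per_lipid, temperature)
        return {"kappa_theta": k, "upper": k, "lower": k, "n": len(tilts)}

    tilts = np.concatenate([f.tilts for f in fields])
    leaf = np.concatenate([f.leaflet for f in fields])
    a_l = float(np.mean([f.A_l for f in fields]))
    if area_per_lipid is not None:
        a_l = area_per_lipid
    if len(tilts) < 500:
        raise ValueError("need at least 500 lipids x frames")
    upper = _tilt_modulus_from_samples(tilts[leaf > 0], a_l, temperature)
    lower = _tilt_modulus_from_samples(tilts[leaf < 0], a_l, temperature)
    return {
        "kappa_theta": 0.5 * (upper + lower),
        "upper": upper,
        "lower": lower,
        "n": len(tilts),
    }


def pair_splay(field: DirectorField, r_min: float = 0.5, r_max: float = 1.0,
               box_xy: tuple[float, float] | None = None) -> np.ndarray:
    """Per-neighbor-pair splay samples (d2 - d1) . r12_hat / |r12|.

    Pairs are restricted to the same leaflet and to in-plane separations in
    [r_min, r_max] nm (minimum image if ``box_xy`` is given).
    """
    out = []
    for sign in (+1.0, -1.0):
        sel = field.leaflet == sign
        pos = field.positions[sel]
        dirs = field.directors[sel]
        if len(pos) < 2:
            continue
        dxy = pos[None, :, :2] - pos[:, None, :2]
        if box_xy is not None:
            box = np.asarray(box_xy, dtype=float)
            dxy = dxy - box[None, None, :] * np.round(dxy / box[None, None, :])
        dist = np.linalg.norm(dxy, axis=-1)
        ii, jj = np.where((dist >= r_min) & (dist <= r_max))
        keep = ii < jj
        ii, jj = ii[keep], jj[keep]
        if len(ii) == 0:
            continue
        rhat = dxy[ii, jj] / dist[ii, jj, None]
        dd = dirs[jj, :2] - dirs[ii, :2]
        out.append(np.sum(dd * rhat, axis=1) / dist[ii, jj])
    if not out:
        raise ValueError("no neighbor pairs in the 0.5-1.0 nm separation band")
    return np.concatenate(out)


def estimate_bending_modulus(
    splay_or_field: np.ndarray | DirectorField,
    area_per_lipid: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    min_samples: int = 10_000,
) -> dict:
    """Monolayer bending modulus from Gaussian splay fluctuations.

    kappa = k_B T / (var(S) * A_l). Accepts raw splay samples with an
    explicit ``area_per_lipid``, or a :class:`DirectorField` from which
    neighbor-pair splay is computed. Returns
    ``{"kappa": ..., "J_s_mean": ..., "n": ...}`` with ``J_s_mean`` the
    sample mean of the splay (the spontaneous curvature for Boltzmann
    samples around J_s).
    """
    if isinstance(splay_or_field, DirectorField):
        samples = pair_splay(splay_or_field)
        a_l = area_per_lipid if area_per_lipid is not None else splay_or_field.A_l
    else:
        samples = np.asarray(splay_or_field, dtype=float)
        if area_per_lipid is None:
            raise ValueError("area_per_lipid is required with raw splay samples")
        a_l = area_per_lipid
    if len(samples) < min_samples:
        raise ValueError(f"need at least {min_samples} splay samples, got {len(samples)}")
    var = float(np.var(samples, ddof=1))
    if var == 0:
        raise ValueError("splay variance is zero; modulus estimate is singular")
    return {
        "kappa": KB * temperature / (var * a_l),
        "J_s_mean": float(np.mean(samples)),
        "n": len(samples),
    }


# ----------------------------------------------------------------------
# spontaneous curvature from a stress profile
# ----------------------------------------------------------------------

def spontaneous_curvature(
    profile: StressProfile,
    kappa: float,
    pivot: float = 0.0,
    leaflet: str = "upper",
) -> float:
    """Monolayer spontaneous curvature from the stress-profile first moment.

    J_s = (1/kappa) * integral over the leaflet of (z - pivot) * s(z) dz,
    by trapezoidal quadrature. The sign convention is positive J_s for a
    monolayer curving toward its head groups; for the lower leaflet the
    integral's sign is flipped accordingly.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    bounds = profile.leaflet_bounds[0 if leaflet == "upper" else 1]
    lo, hi = min(bounds), max(bounds)
    if not (lo - 1e-9 <= pivot <= hi + 1e-9):
        raise ValueError(f"pivot {pivot} outside leaflet bounds {bounds}")
    sel = (profile.z >= lo - 1e-12) & (profile.z <= hi + 1e-12)
    z = profile.z[sel]
    s = profile.s[sel]
    moment = float(np.trapezoid((z - pivot) * s, z))
    if leaflet != "upper":
        moment = -moment
    return moment / kappa


# ----------------------------------------------------------------------
# hydrophobic thickness
# ----------------------------------------------------------------------

def hydrophobic_thickness(frame: MembraneFrame, bin_width: float = 0.1) -> float:
    """Core thickness from the crossings of tail and water density profiles.

    Histograms tail-particle and water-particle number densities along z
    (0.1 nm bins), normalizes each profile by its own maximum, and locates
    by linear interpolation the two z positions where the normalized
    profiles cross; their distance is the hydrophobic thickness d_hc.
    """
    roles = frame.role.astype(str)
    z_tail = frame.positions[roles == "tail", 2]
    z_water = frame.positions[roles == "water", 2]
    if len(z_tail) == 0 or len(z_water) == 0:
        raise ValueError("frame must contain both tail and water particles")
    edges = np.arange(0.0, frame.box[2] + bin_width, bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    rho_t, _ = np.histogram(z_tail, bins=edges)
    rho_w, _ = np.histogram(z_water, bins=edges)
    ft = rho_t / rho_t.max()
    fw = rho_w / rho_w.max()
    diff = ft - fw
    signs = np.sign(diff)
    crossings = []
    for i in range(len(diff) - 1):
        if signs[i] == 0:
            crossings.append(centers[i])
        elif signs[i] * signs[i + 1] < 0:
            frac = diff[i] / (diff[i] - diff[i + 1])
            crossings.append(centers[i] + frac * bin_width)
    if len(crossings) < 2:
        raise ValueError("no tail/water density crossings found (degenerate frame)")
    return float(max(crossings) - min(crossings))
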