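"""Synthetic membrane configurations, fluctuation samples, PMFs and stress profiles.

This module generates every input the analysis stages consume, with known
ground truth, so the whole pipeline can be validated by parameter recovery
instead of requiring all-atom trajectories:

* toy bilayer frames — flat, thinned-by-water-wire, and open toroidal pores
  with prescribed per-species rim enrichment (coarse placeholders with one
  head bead, two tail beads and discrete water particles);
* tilt-vector and splay samples Boltzmann-drawn from the quadratic
  tilt/splay elastic energies, i.e. Gaussians whose variances are set by the
  tilt modulus kappa_theta and the monolayer bending modulus kappa;
* one-dimensional pore-formation PMFs with a nucleation rise to a known
  free energy, an optional metastable dip, and a linear large-pore tail
  whose slope encodes a known line tension;
* analytic lateral stress profiles whose leaflet first moment equals
  kappa * J_s exactly, for spontaneous-curvature recovery tests.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .frames import MembraneFrame
from .moduli import StressProfile
from .pmf import PMFProfile
from .units import KB, KJ_MOL_PER_PN_NM

__all__ = [
    "SyntheticPMFSpec",
    "DirectorSampleSpec",
    "make_flat_membrane",
    "make_pore_membrane",
    "make_water_wire",
    "sample_tilt_vectors",
    "sample_splay_values",
    "make_synthetic_pmf",
    "make_stress_profile",
]

#: Effective volume of one water particle in nm^3, used for pore-fill bookkeeping.
V_WATER = 0.030

#: Number density of water particles in the bulk slabs (per nm^3).
WATER_SLAB_DENSITY = 33.0


# ----------------------------------------------------------------------
# species bookkeeping
# ----------------------------------------------------------------------

def largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic integer species counts that sum exactly to ``n``.

    Uses the largest-remainder (Hare) rule; ties broken by species name so
    the result is independent of dict ordering.
    """
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"species fractions must sum to 1, got {total}")
    items = sorted(fractions.items())
    raw = {sp: f * n for sp, f in items}
    counts = {sp: int(math.floor(v)) for sp, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(items, key=lambda kv: (-(raw[kv[0]] - counts[kv[0]]), kv[0]))
    for sp, _ in order[:remainder]:
        counts[sp] += 1
    return counts


def _species_array(fractions: dict[str, float], n: int, rng: np.random.Generator):
    counts = largest_remainder_counts(fractions, n)
    labels = np.concatenate([np.full(c, sp, dtype=object) for sp, c in sorted(counts.items())])
    rng.shuffle(labels)
    return labels


# ----------------------------------------------------------------------
# flat membrane
# ----------------------------------------------------------------------

def _leaflet_lattice(n: int, box_xy: float, rng: np.random.Generator) -> np.ndarray:
    """Jittered square lattice of n (x, y) sites inside a box_xy x box_xy patch."""
    m = math.ceil(math.sqrt(n))
    spacing = box_xy / m
    if spacing < 0.4:
        raise ValueError(
            f"box {box_xy} nm too small for {n} lipids at >=0.4 nm spacing"
        )
    gx, gy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    sites = (np.stack([gx.ravel(), gy.ravel()], axis=1) + 0.5) * spacing
    idx = rng.choice(len(sites), size=n, replace=False)
    xy = sites[idx] + rng.uniform(-0.15, 0.15, size=(n, 2)) * spacing
    return np.mod(xy, box_xy)


def _water_slabs(box_xy: float, z_lo: float, z_hi: float, box_z: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Uniform water positions filling z < z_lo and z > z_hi."""
    vol = box_xy * box_xy * (z_lo + (box_z - z_hi))
    n = int(round(vol * WATER_SLAB_DENSITY))
    xy = rng.uniform(0.0, box_xy, size=(n, 2))
    # split particles between the two slabs proportionally to slab thickness
    u = rng.uniform(0.0, z_lo + (box_z - z_hi), size=n)
    z = np.where(u < z_lo, u, z_hi + (u - z_lo))
    return np.column_stack([xy, z])


def make_flat_membrane(
    n_lipids_per_leaflet: int,
    species_fractions: dict[str, float],
    box_xy: float = 8.0,
    d_hc: float = 2.8,
    seed: int = 0,
    water_slab: float = 1.5,
) -> MembraneFrame:
    """Build a flat toy bilayer with a dry hydrophobic core.

    Each leaflet carries ``n_lipids_per_leaflet`` lipids of one head bead at
    z = +/- d_hc/2 and two tail beads filling its half of the core, on a
    jittered square lattice. Water slabs of thickness ``water_slab`` nm lie
    above and below the membrane; the core contains no polar particles.
    """
    if n_lipids_per_leaflet < 4:
        raise ValueError("need at least 4 lipids per leaflet")
    rng = np.random.default_rng(seed)
    a = d_hc / 2.0
    box_z = d_hc + 2.0 * water_slab
    z_c = box_z / 2.0

    pos, species, role, mol = [], [], [], []
    next_mol = 0
    for sign in (+1.0, -1.0):
        xy = _leaflet_lattice(n_lipids_per_leaflet, box_xy, rng)
        sp = _species_array(species_fractions, n_lipids_per_leaflet, rng)
        # tail beads: one in the outer half of the leaflet core, one inner
        u_outer = rng.uniform(0.5, 1.0, size=n_lipids_per_leaflet)
        u_inner = rng.uniform(0.0, 0.5, size=n_lipids_per_leaflet)
        t_jit = rng.uniform(-0.05, 0.05, size=(n_lipids_per_leaflet, 2, 2))
        for i in range(n_lipids_per_leaflet):
            x, y = xy[i]
            pos.append([x, y, z_c + sign * a])
            pos.append([x + t_jit[i, 0, 0], y + t_jit[i, 0, 1], z_c + sign * a * u_outer[i]])
            pos.append([x + t_jit[i, 1, 0], y + t_jit[i, 1, 1], z_c + sign * a * u_inner[i]])
            species.extend([sp[i]] * 3)
            role.extend(["head", "tail", "tail"])
            mol.extend([next_mol] * 3)
            next_mol += 1

    waters = _water_slabs(box_xy, z_c - a, z_c + a, box_z, rng)
    for w in waters:
        pos.append(list(w))
        species.append("W")
        role.append("water")
        mol.append(next_mol)
        next_mol += 1

    return MembraneFrame(
        positions=np.array(pos, dtype=float),
        species=np.array(species, dtype=object),
        role=np.array(role, dtype=object),
        molecule_id=np.array(mol, dtype=int),
        box=np.array([box_xy, box_xy, box_z]),
    )


# ----------------------------------------------------------------------
# water wire
# ----------------------------------------------------------------------

def make_water_wire(
    n_lipids_per_leaflet: int,
    species_fractions: dict[str, float],
    box_xy: float = 8.0,
    d_hc: float = 2.8,
    seed: int = 0,
    wire_radius: float = 0.15,
    center_xy: tuple[float, float] | None = None,
    water_slab: float = 1.5,
) -> MembraneFrame:
    """Flat membrane plus a single-file water column spanning the core.

    The column is placed at ``center_xy`` (default: box center) with axial
    spacing 0.08 nm, so every 0.1 nm slab of the core contains at least one
    polar particle; the wire extends 0.3 nm beyond the core on both sides.
    The underlying flat membrane is identical to
    :func:`make_flat_membrane` called with the same arguments and seed.
    """
    if not (0.1 <= wire_radius <= 0.4):
        raise ValueError("wire_radius must lie in [0.1, 0.4] nm")
    frame = make_flat_membrane(
        n_lipids_per_leaflet, species_fractions, box_xy, d_hc, seed, water_slab
    )
    rng = np.random.default_rng([seed, 7919])  # separate stream: base frame unchanged
    z_c = frame.box[2] / 2.0
    a = d_hc / 2.0
    if center_xy is None:
        center_xy = (box_xy / 2.0, box_xy / 2.0)
    z = np.arange(z_c - a - 0.3, z_c + a + 0.3 + 1e-12, 0.08)
    n = len(z)
    r = wire_radius * np.sqrt(rng.uniform(0.0, 1.0, size=n)) * 0.9
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    wire = np.column_stack([
        center_xy[0] + r * np.cos(phi),
        center_xy[1] + r * np.sin(phi),
        z,
    ])
    next_mol = int(frame.molecule_id.max()) + 1
    return MembraneFrame(
        positions=np.vstack([frame.positions, wire]),
        species=np.concatenate([frame.species, np.full(n, "W", dtype=object)]),
        role=np.concatenate([frame.role, np.full(n, "water", dtype=object)]),
        molecule_id=np.concatenate([frame.molecule_id, next_mol + np.arange(n)]),
        box=frame.box,
    )


# ----------------------------------------------------------------------
# toroidal pore
# ----------------------------------------------------------------------

def make_pore_membrane(
    n_lipids_per_leaflet: int,
    species_fractions: dict[str, float],
    box_xy: float = 8.0,
    d_hc: float = 2.8,
    seed: int = 0,
    pore_radius: float = 0.8,
    rim_enrichment: dict[str, float] | None = None,
    water_slab: float = 1.5,
) -> MembraneFrame:
    """Toy membrane with an open toroidal pore at the box center.

    The pore rim is a half-torus of tube radius d_hc/2 around a cylinder of
    radius ``pore_radius``; head beads are distributed uniformly by area on
    the rim surface at the bulk areal lipid density, with species drawn with
    probability proportional to bulk fraction times ``rim_enrichment``
    factor (renormalized); the total rim count is scaled by the same
    normalization so the expected surface density of species *i* is
    fraction_i * factor_i / A_l. The cylinder interior is filled with water
    particles at one particle per ``V_WATER`` nm^3, so the water count
    encodes the pore radius.
    """
    rim_enrichment = dict(rim_enrichment or {})
    if pore_radius < 0.3:
        raise ValueError("pore_radius must be >= 0.3 nm")
    if any(f < 0 for f in rim_enrichment.values()):
        raise ValueError("enrichment factors must be >= 0")
    a = d_hc / 2.0
    r_ax = pore_radius + a  # torus tube axis radius
    if r_ax > box_xy / 2.0:
        raise ValueError(
            f"pore_radius + d_hc/2 = {r_ax} nm exceeds half the box {box_xy / 2} nm"
        )
    rng = np.random.default_rng(seed)
    total = sum(species_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"species fractions must sum to 1, got {total}")

    box_z = d_hc + 2.0 * water_slab
    z_c = box_z / 2.0
    cx = cy = box_xy / 2.0
    area_per_lipid = box_xy * box_xy / n_lipids_per_leaflet

    pos, species, role, mol = [], [], [], []
    next_mol = 0

    # --- bulk bilayer, excluding a disk around the pore ------------------
    r_excl = r_ax + 0.5
    for sign in (+1.0, -1.0):
        xy = _leaflet_lattice(n_lipids_per_leaflet, box_xy, rng)
        d = xy - np.array([cx, cy])
        d -= box_xy * np.round(d / box_xy)
        keep = np.hypot(d[:, 0], d[:, 1]) >= r_excl
        xy = xy[keep]
        sp = _species_array(species_fractions, len(xy), rng)
        u_outer = rng.uniform(0.5, 1.0, size=len(xy))
        u_inner = rng.uniform(0.0, 0.5, size=len(xy))
        for i in range(len(xy)):
            x, y = xy[i]
            pos.append([x, y, z_c + sign * a])
            pos.append([x, y, z_c + sign * a * u_outer[i]])
            pos.append([x, y, z_c + sign * a * u_inner[i]])
            species.extend([sp[i]] * 3)
            role.extend(["head", "tail", "tail"])
            mol.extend([next_mol] * 3)
            next_mol += 1

    # --- rim lipids on the half-torus ------------------------------------
    weights = {sp: f * rim_enrichment.get(sp, 1.0) for sp, f in species_fractions.items()}
    z_norm = sum(weights.values())
    # torus area (inner half, theta in [pi/2, 3pi/2]): 2*pi*a*(pi*r_ax - 2a)
    area_rim = 2.0 * np.pi * a * (np.pi * r_ax - 2.0 * a)
    n_rim = int(round(area_rim / area_per_lipid * z_norm))
    if n_rim > 0 and z_norm > 0:
        # sample theta with density prop. to local radius r(theta) = r_ax + a cos(theta)
        theta = np.empty(n_rim)
        filled = 0
        while filled < n_rim:
            cand = rng.uniform(np.pi / 2.0, 3.0 * np.pi / 2.0, size=2 * (n_rim - filled))
            acc = cand[rng.uniform(0, r_ax + a, size=len(cand)) < (r_ax + a * np.cos(cand))]
            take = min(len(acc), n_rim - filled)
            theta[filled:filled + take] = acc[:take]
            filled += take
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_rim)
        probs = np.array([weights[sp] / z_norm for sp in sorted(weights)])
        names = np.array(sorted(weights), dtype=object)
        sp_rim = names[rng.choice(len(names), size=n_rim, p=probs)]
        r = r_ax + a * np.cos(theta)
        head = np.column_stack([
            cx + r * np.cos(phi), cy + r * np.sin(phi), z_c + a * np.sin(theta)
        ])
        tube_center = np.column_stack([
            cx + r_ax * np.cos(phi), cy + r_ax * np.sin(phi), np.full(n_rim, z_c)
        ])
        for i in range(n_rim):
            h = head[i]
            c = tube_center[i]
            pos.append(list(h))
            pos.append(list(h + 0.35 * (c - h)))
            pos.append(list(h + 0.70 * (c - h)))
            species.extend([sp_rim[i]] * 3)
            role.extend(["head", "tail", "tail"])
            mol.extend([next_mol] * 3)
            next_mol += 1

    # --- water: pore fill + bulk slabs ------------------------------------
    n_fill = int(round(np.pi * pore_radius ** 2 * d_hc / V_WATER))
    rf = pore_radius * np.sqrt(rng.uniform(0.0, 1.0, size=n_fill))
    pf = rng.uniform(0.0, 2.0 * np.pi, size=n_fill)
    zf = rng.uniform(z_c - a, z_c + a, size=n_fill)
    fill = np.column_stack([cx + rf * np.cos(pf), cy + rf * np.sin(pf), zf])
    slabs = _water_slabs(box_xy, z_c - a, z_c + a, box_z, rng)
    for w in np.vstack([fill, slabs]):
        pos.append(list(w))
        species.append("W")
        role.append("water")
        mol.append(next_mol)
        next_mol += 1

    return MembraneFrame(
        positions=np.array(pos, dtype=float),
        species=np.array(species, dtype=object),
        role=np.array(role, dtype=object),
        molecule_id=np.array(mol, dtype=int),
        box=np.array([box_xy, box_xy, box_z]),
    )


# ----------------------------------------------------------------------
# Boltzmann fluctuation samples
# ----------------------------------------------------------------------

@dataclass
class DirectorSampleSpec:
    """Parameters of Gaussian tilt/splay fluctuation sampling.

    The quadratic tilt energy per lipid, (1/2) * kappa_theta * A_l * |t|^2,
    makes each in-plane tilt component Gaussian with variance
    k_B T / (kappa_theta * A_l); the splay energy (1/2) * kappa * A_l *
    (S - J_s)^2 makes the splay Gaussian around J_s with variance
    k_B T / (kappa * A_l).
    """

    kappa_theta_true: float = 42.53   # tilt modulus, kJ mol^-1 nm^-2
    kappa_true: float = 33.7          # monolayer bending modulus, kJ/mol
    area_per_lipid: float = 0.64      # nm^2
    n_samples: int = 100_000
    temperature: float = 310.0        # K
    J_s: float = 0.0                  # spontaneous curvature, nm^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa_theta_true <= 0 or self.kappa_true <= 0:
            raise ValueError("moduli must be positive")
        if not (0.3 < self.area_per_lipid < 1.5):
            raise ValueError("area_per_lipid must lie in (0.3, 1.5) nm^2")
        if self.n_samples < 100:
            raise ValueError("need at least 100 samples")


def sample_tilt_vectors(spec: DirectorSampleSpec) -> np.ndarray:
    """Draw n i.i.d. 2-component tilt vectors from the quadratic tilt energy."""
    rng = np.random.default_rng(spec.seed)
    var = KB * spec.temperature / (spec.kappa_theta_true * spec.area_per_lipid)
    return rng.normal(0.0, np.sqrt(var), size=(spec.n_samples, 2))


def sample_splay_values(spec: DirectorSampleSpec) -> np.ndarray:
    """Draw n i.i.d. splay samples, Gaussian around J_s."""
    rng = np.random.default_rng(spec.seed)
    var = KB * spec.temperature / (spec.kappa_true * spec.area_per_lipid)
    return rng.normal(spec.J_s, np.sqrt(var), size=spec.n_samples)


# ----------------------------------------------------------------------
# synthetic PMFs
# ----------------------------------------------------------------------

@dataclass
class SyntheticPMFSpec:
    """Ground truth for a synthetic pore-formation free-energy profile."""

    gamma_true: float = 40.0          # line tension, pN
    dG_nuc_true: float = 90.0         # nucleation free energy, kJ/mol
    R0: float = 0.4                   # nucleated-pore radius, nm
    metastable_depth: float = 0.0     # kJ/mol (0 = no metastable pore)
    noise_sd: float = 0.0             # kJ/mol
    # 0.04 spacing puts the nucleation point xi = 0.92 on the grid
    xi_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.04, 6.52, 163))
    seed: int = 0

    def __post_init__(self) -> None:
        self.xi_grid = np.asarray(self.xi_grid, dtype=float)
        if self.gamma_true < 0:
            raise ValueError("gamma_true must be >= 0")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if np.any(np.diff(self.xi_grid) <= 0):
            raise ValueError("xi_grid must be strictly increasing")
        if self.xi_grid[0] > 0.2 or self.xi_grid[-1] < 6.5:
            raise ValueError("xi_grid must span at least [0.2, 6.5]")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


#: Segment boundaries of the synthetic PMF shape (in xi units).
XI_RISE_START = 0.2
XI_NUC = 0.92
XI_LINEAR_START = 3.5
XI_META_CENTER = 2.5
META_WIDTH = 0.35


def synthetic_pmf_values(spec: SyntheticPMFSpec) -> np.ndarray:
    """Noiseless synthetic PMF G(xi) in kJ/mol on ``spec.xi_grid``.

    Shape: zero up to xi = 0.2, a smooth sigmoidal rise reaching exactly
    ``dG_nuc_true`` at xi = 0.92 (the thin-water-wire state), a plateau
    carrying an optional Gaussian metastable dip centered at xi = 2.5, and
    an exactly linear tail of slope 2*pi*gamma_true*R0 (converted to kJ/mol
    per xi unit) for xi >= 3.5.
    """
    xi = spec.xi_grid
    slope = 2.0 * np.pi * spec.gamma_true * spec.R0 * KJ_MOL_PER_PN_NM
    g = spec.dG_nuc_true * _smoothstep((xi - XI_RISE_START) / (XI_NUC - XI_RISE_START))
    mid = (xi > XI_NUC) & (xi < XI_LINEAR_START)
    dip = spec.metastable_depth * np.exp(
        -((xi - XI_META_CENTER) ** 2) / (2.0 * META_WIDTH ** 2)
    )
    g = np.where(mid, spec.dG_nuc_true - dip, g)
    tail = xi >= XI_LINEAR_START
    g = np.where(tail, spec.dG_nuc_true + slope * (xi - XI_LINEAR_START), g)
    return g


def make_synthetic_pmf(spec: SyntheticPMFSpec) -> PMFProfile:
    """Synthetic PMF with optional i.i.d. Gaussian noise, anchored at zero."""
    g = synthetic_pmf_values(spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        g = g + rng.normal(0.0, spec.noise_sd, size=len(g))
    return PMFProfile(xi=spec.xi_grid.copy(), G=g, R0=spec.R0)


# ----------------------------------------------------------------------
# analytic stress profiles
# ----------------------------------------------------------------------

def make_stress_profile(
    J_s: float,
    kappa: float,
    d_hc: float = 2.8,
    grid: np.ndarray | None = None,
    base_amplitude: float = 50.0,
) -> StressProfile:
    """Analytic lateral stress profile with exact leaflet first moment.

    The profile is symmetric in z (identical leaflets) and is built from a
    structured, moment-free base shape plus a moment-carrying component
    scaled so that the trapezoidal quadrature of z * s(z) over the upper
    leaflet equals ``kappa * J_s`` exactly on the supplied grid.
    """
    if grid is None:
        grid = np.linspace(-d_hc, d_hc, 2 * int(round(d_hc / 0.02)) + 1)
    grid = np.asarray(grid, dtype=float)
    if np.max(np.abs(grid + grid[::-1])) > 1e-9:
        raise ValueError("grid must be symmetric about z = 0")
    if np.max(np.diff(grid)) > 0.05 + 1e-12:
        raise ValueError("grid spacing must be <= 0.05 nm")
    z_max = grid[-1]
    upper = grid >= 0.0
    zu = grid[upper]
    az = np.abs(grid)

    # moment-carrying component: g1 = z * (z_max - z) on each leaflet
    g1 = az * (z_max - az)
    m1 = np.trapezoid(zu * zu * (z_max - zu), zu)
    # structured base (typical attraction/repulsion lobes), made moment-free
    g_base = np.cos(2.0 * np.pi * az / z_max) * np.exp(-((az / z_max) ** 2))
    mb = np.trapezoid(zu * g_base[upper], zu)
    g0 = g_base - (mb / m1) * g1

    s = base_amplitude * g0 + (kappa * J_s / m1) * g1
    return StressProfile(
        z=grid,
        s=s,
        leaflet_bounds=((0.0, z_max), (-z_max, 0.0)),
    )
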