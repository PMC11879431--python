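"""Continuum elastic energetics of membrane pores (Helfrich-Kozlov-Hamm).

The HKH functional assigns a monolayer patch the elastic energy

    F = integral dA [ (kappa/2) (H - J_s)^2 + (kappa_theta/2) t^2
                      + kappa_bar * K_G ],

where H is the sum of the two principal curvatures of the director field,
J_s the spontaneous curvature, t the lipid tilt magnitude and K_G the
Gaussian curvature. Without tilt and Gaussian terms it reduces to the
classical Helfrich bending energy.

Integrating the bending term over the rim of a large pore — one principal
curvature fixed at 2/d_hc by the half-toroidal rim of a membrane with
hydrophobic core thickness d_hc, the other negligible — gives the
closed-form rim line tension

    gamma_bend = kappa * d_hc * (pi/4) * (2/d_hc - J_s)^2 ,

which this module evaluates both in closed form and by direct quadrature
over a toroidal rim patch. Classical nucleation theory,
dG(R) = 2*pi*R*gamma - pi*R^2*sigma, area rescaling of nucleation free
energies between simulation and experiment, Boltzmann pore probabilities
and the correlation analysis linking pore energetics to elastic moduli
complete the continuum picture.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import DEFAULT_TEMPERATURE, KB, KJ_MOL_PER_PN_NM, PN_PER_KJ_MOL_NM

__all__ = [
    "ElasticParameters",
    "RimSurface",
    "ThermoContext",
    "hkh_energy",
    "helfrich_line_tension",
    "rim_quadrature_line_tension",
    "cnt_energy",
    "rescale_nucleation_energy",
    "pore_probability",
    "correlate",
    "load_parameter_table",
    "reference_parameter_table",
]


@dataclass
class ThermoContext:
    """Temperature and unit constants for thermodynamic conversions."""

    temperature: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self) -> None:
        if not (250.0 < self.temperature < 400.0):
            raise ValueError("temperature must lie in (250, 400) K")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in kJ/mol."""
        return KB * self.temperature


@dataclass
class ElasticParameters:
    """Per-membrane elastic parameters.

    ``kappa_theta`` is stored exactly as tabulated (a bilayer-level tilt
    modulus); :func:`hkh_energy` uses it verbatim unless a ``leaflet_factor``
    is passed there, so no hidden monolayer/bilayer factor is injected.
    """

    J_s: float                 # spontaneous curvature, nm^-1
    kappa: float               # monolayer bending modulus, kJ/mol
    kappa_theta: float         # tilt modulus, kJ mol^-1 nm^-2
    kappa_bar: float = 0.0     # Gaussian modulus, kJ/mol
    d_hc: float = 2.8          # hydrophobic core thickness, nm
    A_l: float = 0.64          # area per lipid, nm^2
    label: str = ""

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.kappa_theta <= 0:
            raise ValueError("kappa and kappa_theta must be positive")
        if not (1.5 < self.d_hc < 5.0):
            raise ValueError("d_hc must lie in (1.5, 5) nm")
        if self.A_l <= 0:
            raise ValueError("A_l must be positive")


@dataclass
class RimSurface:
    """Quadrature nodes over a parameterized monolayer patch.

    Per node: area element dA (nm^2), director mean curvature H (nm^-1,
    sum of principal curvatures), Gaussian curvature K_G (nm^-2), and tilt
    magnitude t (dimensionless).
    """

    dA: np.ndarray
    H: np.ndarray
    K_G: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.dA = np.asarray(self.dA, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.K_G = np.asarray(self.K_G, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        n = len(self.dA)
        if any(len(a) != n for a in (self.H, self.K_G, self.t)):
            raise ValueError("all node arrays must have equal length")
        if n < 16:
            raise ValueError("need at least 16 quadrature nodes")
        if np.any(self.dA <= 0):
            raise ValueError("area elements must be positive")

    @classmethod
    def flat_patch(cls, area: float, n_nodes: int = 64, tilt: float = 0.0) -> "RimSurface":
        """A flat patch of total ``area`` with uniform tilt magnitude."""
        dA = np.full(n_nodes, area / n_nodes)
        zeros = np.zeros(n_nodes)
        return cls(dA=dA, H=zeros, K_G=zeros.copy(), t=np.full(n_nodes, tilt))

    @classmethod
    def spherical_cap(cls, radius: float, area: float, n_nodes: int = 64) -> "RimSurface":
        """Patch of a sphere of given radius: H = 2/r, K_G = 1/r^2, no tilt."""
        dA = np.full(n_nodes, area / n_nodes)
        return cls(
            dA=dA,
            H=np.full(n_nodes, 2.0 / radius),
            K_G=np.full(n_nodes, 1.0 / radius ** 2),
            t=np.zeros(n_nodes),
        )

    @classmethod
    def toroidal_rim(cls, pore_radius: float, tube_radius: float,
                     n_theta: int = 256, n_phi: int = 64,
                     azimuthal_curvature: bool = True) -> "RimSurface":
        """Inner half-torus rim of an open pore.

        Tube radius a = ``tube_radius`` around an axis circle of radius
        R_ax = pore_radius + a; theta in [pi/2, 3pi/2] parameterizes the
        inner half facing the pore lumen. Principal curvatures are the tube
        curvature 1/a and the azimuthal curvature cos(theta)/r(theta) with
        r(theta) = R_ax + a*cos(theta); the latter can be switched off to
        model the large-pore limit where it is negligible.
        """
        a = tube_radius
        r_ax = pore_radius + a
        theta = np.linspace(np.pi / 2.0, 3.0 * np.pi / 2.0, n_theta + 1)
        theta = 0.5 * (theta[1:] + theta[:-1])
        dtheta = np.pi / n_theta
        dphi = 2.0 * np.pi / n_phi
        r = r_ax + a * np.cos(theta)
        c1 = 1.0 / a
        c2 = np.cos(theta) / r if azimuthal_curvature else np.zeros_like(theta)
        dA_ring = a * r * dtheta * dphi  # per phi node
        dA = np.repeat(dA_ring, n_phi)
        H = np.repeat(c1 + c2, n_phi)
        K_G = np.repeat(c1 * c2, n_phi)
        return cls(dA=dA, H=H, K_G=K_G, t=np.zeros(len(dA)))


# ----------------------------------------------------------------------
# energies
# ----------------------------------------------------------------------

def hkh_energy(
    surface: RimSurface,
    params: ElasticParameters,
    leaflet_factor: float = 1.0,
) -> float:
    """HKH elastic energy of a monolayer patch in kJ/mol.

    Quadrature of (kappa/2)(H - J_s)^2 + (kappa_theta/2) t^2 +
    kappa_bar * K_G over the patch. ``leaflet_factor`` multiplies the
    tabulated tilt modulus (pass 0.5 to read a bilayer-level value as a
    per-leaflet one).
    """
    bend = 0.5 * params.kappa * (surface.H - params.J_s) ** 2
    tilt = 0.5 * leaflet_factor * params.kappa_theta * surface.t ** 2
    gauss = params.kappa_bar * surface.K_G
    return float(np.sum(surface.dA * (bend + tilt + gauss)))


def helfrich_line_tension(params: ElasticParameters) -> float:
    """Closed-form bending line tension of a large pore's rim, in pN.

    gamma_bend = kappa * d_hc * (pi/4) * (2/d_hc - J_s)^2, from integrating
    the bending energy over a half-toroidal rim whose tube curvature is
    2/d_hc while the azimuthal curvature vanishes for a large pore.
    """
    if params.d_hc <= 0:
        raise ValueError("d_hc must be positive")
    gamma_kj = params.kappa * params.d_hc * (np.pi / 4.0) * (2.0 / params.d_hc - params.J_s) ** 2
    return float(gamma_kj * PN_PER_KJ_MOL_NM)


def rim_quadrature_line_tension(
    params: ElasticParameters,
    pore_radius: float,
    n_theta: int = 512,
    n_phi: int = 8,
    azimuthal_curvature: bool = False,
) -> float:
    """Bending line tension from direct quadrature over a toroidal rim, in pN.

    Integrates the bending energy density over the inner half-torus of tube
    radius d_hc/2 around ``pore_radius`` and divides by the rim length
    2*pi*pore_radius. By default the azimuthal (saddle) principal curvature
    is dropped, matching the large-pore assumption behind the closed form,
    so the quadrature converges to :func:`helfrich_line_tension` with only
    the O(d_hc / pore_radius) torus-area correction. With
    ``azimuthal_curvature=True`` the full toroidal director curvature is
    used; the negative saddle curvature of the inner rim then lowers the
    result by a correction that also decays as d_hc / pore_radius.
    """
    if pore_radius < params.d_hc:
        raise ValueError("pore_radius must be >= d_hc for a well-formed rim")
    surf = RimSurface.toroidal_rim(pore_radius, params.d_hc / 2.0,
                                   n_theta=n_theta, n_phi=n_phi,
                                   azimuthal_curvature=azimuthal_curvature)
    bend_only = ElasticParameters(
        J_s=params.J_s, kappa=params.kappa, kappa_theta=params.kappa_theta,
        kappa_bar=0.0, d_hc=params.d_hc, A_l=params.A_l, label=params.label,
    )
    energy = hkh_energy(surf, bend_only)  # kJ/mol
    gamma_kj = energy / (2.0 * np.pi * pore_radius)
    return float(gamma_kj * PN_PER_KJ_MOL_NM)


def cnt_energy(R: float, gamma: float, sigma: float = 0.0) -> float:
    """Classical nucleation theory pore energy dG(R) in kJ/mol.

    ``R`` in nm, line tension ``gamma`` in pN, lateral tension ``sigma`` in
    pN/nm: dG = 2*pi*R*gamma - pi*R^2*sigma, converted from pN nm to kJ/mol.
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    pn_nm = 2.0 * np.pi * R * gamma - np.pi * R ** 2 * sigma
    return float(pn_nm * KJ_MOL_PER_PN_NM)


# ----------------------------------------------------------------------
# area rescaling and pore probability
# ----------------------------------------------------------------------

def rescale_nucleation_energy(
    dG_sim: float,
    A_exp: float,
    A_sim: float,
    ctx: ThermoContext | None = None,
) -> float:
    """Nucleation free energy rescaled from simulation to experimental area.

    Because pore formation probability is proportional to membrane area,
    dG_exp = dG_sim - k_B T * ln(A_exp / A_sim). Both areas must be in the
    same units and positive.
    """
    if A_exp <= 0 or A_sim <= 0:
        raise ValueError("areas must be positive")
    ctx = ctx or ThermoContext()
    return float(dG_sim - ctx.kT * np.log(A_exp / A_sim))


def pore_probability(dG: float, ctx: ThermoContext | None = None) -> tuple[float, int]:
    """Boltzmann probability of pore formation and its decimal order.

    Returns (exp(-dG / k_B T), floor(log10) of it). The order is the
    integer n with 10^n <= p < 10^(n+1).
    """
    ctx = ctx or ThermoContext()
    log10_p = -dG / ctx.kT / np.log(10.0)
    p = float(10.0 ** log10_p)
    return p, int(np.floor(log10_p))


# ----------------------------------------------------------------------
# correlation analysis
# ----------------------------------------------------------------------

def correlate(
    x: dict[str, float] | pd.Series,
    y: dict[str, float] | pd.Series,
    exclude: list[str] | tuple[str, ...] = (),
) -> dict:
    """Pearson correlation and OLS line between two labeled vectors.

    Pairs are matched by label; labels in ``exclude`` (e.g. a sterol-rich
    membrane whose sterol is depleted from the pore rim) are dropped before
    fitting. Requires at least three retained pairs.
    """
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    labels = [l for l in xs.index if l in ys.index and l not in set(exclude)]
    if len(labels) < 3:
        raise ValueError(f"need >= 3 retained pairs, got {len(labels)}")
    xv = xs[labels].to_numpy()
    yv = ys[labels].to_numpy()
    slope, intercept = np.polyfit(xv, yv, 1)
    r = float(np.corrcoef(xv, yv)[0, 1])
    return {
        "R": r,
        "slope": float(slope),
        "intercept": float(intercept),
        "n": len(labels),
        "labels": labels,
        "excluded": [l for l in exclude if l in xs.index and l in ys.index],
    }


# ----------------------------------------------------------------------
# parameter tables
# ----------------------------------------------------------------------

_TABLE_COLUMNS = {
    "component": "label",
    "J_s": "J_s",
    "kappa": "kappa",
    "kappa_theta": "kappa_theta",
    "d_hc": "d_hc",
    "A_l": "A_l",
    "kappa_bar": "kappa_bar",
}


def load_parameter_table(path) -> list[ElasticParameters]:
    """Read a CSV of per-membrane elastic parameters.

    Expected columns: ``component``, ``J_s`` (nm^-1), ``kappa`` (kJ/mol),
    ``kappa_theta`` (kJ mol^-1 nm^-2); optional ``kappa_bar``, ``d_hc``,
    ``A_l``, and ``*_se`` columns (ignored here).
    """
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = dict(
            J_s=float(row["J_s"]),
            kappa=float(row["kappa"]),
            kappa_theta=float(row["kappa_theta"]),
            label=str(row.get("component", "")),
        )
        for col in ("kappa_bar", "d_hc", "A_l"):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        out.append(ElasticParameters(**kwargs))
    return out


def reference_parameter_table() -> pd.DataFrame:
    """Published per-membrane elastic parameters shipped with the package.

    Spontaneous curvature, monolayer bending modulus and bilayer tilt
    modulus for nine planar model membranes, with 1 SE columns and the
    bending-theory rim line tension reported alongside.
    """
    ref = importlib.resources.files("poremech").joinpath("data/elastic_parameters.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
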