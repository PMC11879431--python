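"""Free-energy profiles of pore formation and their headline quantities.

A potential of mean force (PMF) G(xi_p) along the joint pore
nucleation/expansion coordinate carries two numbers that summarize a
membrane's resistance to poration:

* the nucleation free energy, the PMF value at xi_p = 0.92 where a thin
  transmembrane water wire has just formed, and
* the line tension gamma of the open pore's rim, obtained from the slope of
  the linear large-pore regime: since the pore free energy grows as
  2*pi*R*gamma with radius R = xi_p * R0, gamma = slope / (2*pi) after
  converting kJ mol^-1 nm^-1 to pN.

The module also detects metastable open pores (local PMF minima at
xi_p > 1), quantifies hysteresis between opening and closing profiles, and
attaches bootstrap standard errors.
"""

from __future__ import annotations

import io
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .units import PN_PER_KJ_MOL_NM

__all__ = [
    "PMFProfile",
    "PoreEnergetics",
    "read_pmf",
    "nucleation_free_energy",
    "line_tension",
    "detect_metastable",
    "bootstrap_errors",
    "hysteresis",
    "XI_NUC_DEFAULT",
    "FIT_RANGE_DEFAULT",
]

#: Reaction-coordinate value defining the nucleation free energy
#: (thin-water-wire state).
XI_NUC_DEFAULT = 0.92

#: Fit range (in xi units) of the linear large-pore regime.
FIT_RANGE_DEFAULT = (4.0, 6.5)

#: The PMF is anchored to zero at its minimum below this xi (flat-membrane basin).
XI_ANCHOR_MAX = 0.5


@dataclass
class PMFProfile:
    """One-dimensional free-energy profile G(xi) in kJ/mol.

    On construction the profile is sorted by xi and anchored so that its
    minimum over xi < 0.5 (the flat-membrane basin) is zero; if the grid
    does not reach below 0.5, the global minimum is used instead.
    """

    xi: np.ndarray
    G: np.ndarray
    se: np.ndarray | None = None
    R0: float = 0.4

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.xi.shape != self.G.shape or self.xi.ndim != 1:
            raise ValueError("xi and G must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.G)) or not np.all(np.isfinite(self.xi)):
            raise ValueError("xi and G must be finite")
        order = np.argsort(self.xi, kind="stable")
        self.xi = self.xi[order]
        self.G = self.G[order]
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)[order]
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("xi values must be distinct")
        basin = self.xi < XI_ANCHOR_MAX
        ref = np.min(self.G[basin]) if np.any(basin) else np.min(self.G)
        self.G = self.G - ref

    def interpolate(self, xi: float | np.ndarray) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        if np.any(xi < self.xi[0]) or np.any(xi > self.xi[-1]):
            raise ValueError("interpolation point outside the profile range")
        return np.interp(xi, self.xi, self.G)


@dataclass
class PoreEnergetics:
    """Extracted pore energetics: nucleation free energy and rim line tension."""

    dG_nuc: float                      # kJ/mol
    gamma: float                       # pN
    dG_nuc_se: float = 0.0
    gamma_se: float = 0.0
    fit_range: tuple[float, float] = FIT_RANGE_DEFAULT
    fit_r2: float = float("nan")
    fit_intercept: float = float("nan")   # kJ/mol
    low_r2_warning: bool = False
    metastable: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dG_nuc_kJ_per_mol": self.dG_nuc,
            "dG_nuc_se": self.dG_nuc_se,
            "gamma_pN": self.gamma,
            "gamma_se": self.gamma_se,
            "fit_range": list(self.fit_range),
            "fit_r2": self.fit_r2,
            "fit_intercept_kJ_per_mol": self.fit_intercept,
            "low_r2_warning": self.low_r2_warning,
            "metastable_minima": [list(m) for m in self.metastable],
        }


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_pmf(path, R0: float = 0.4) -> PMFProfile:
    """Read a PMF from XVG-compatible or CSV two/three-column text.

    Lines starting with ``#`` or ``@`` are ignored (XVG conventions); the
    separator may be whitespace or a comma. Columns are (xi, G[, SE]) with
    G in kJ/mol. The profile is sorted and anchored on construction.
    """
    path = pathlib.Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line[0] in "#@;":
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                continue  # header line in a CSV
    if len(rows) < 10:
        raise ValueError(f"{path}: need at least 10 numeric data rows, got {len(rows)}")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ValueError(f"{path}: need at least 2 numeric columns")
    data = np.array([r[:ncol] for r in rows], dtype=float)
    xi, g = data[:, 0], data[:, 1]
    if len(np.unique(xi)) != len(xi):
        raise ValueError(f"{path}: duplicated xi values")
    se = data[:, 2] if ncol >= 3 else None
    return PMFProfile(xi=xi, G=g, se=se, R0=R0)


def write_pmf(profile: PMFProfile, path) -> None:
    """Write a profile as two/three-column XVG-compatible text."""
    cols = [profile.xi, profile.G]
    header = "# pore-formation PMF\n@ xaxis label \"xi_p\"\n@ yaxis label \"G (kJ/mol)\"\n"
    if profile.se is not None:
        cols.append(profile.se)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.column_stack(cols), fmt="%.8g")


# ----------------------------------------------------------------------
# headline quantities
# ----------------------------------------------------------------------

def nucleation_free_energy(pmf: PMFProfile, xi_nuc: float = XI_NUC_DEFAULT) -> float:
    """PMF value at the thin-water-wire state xi_nuc (linear interpolation)."""
    return float(pmf.interpolate(xi_nuc))


def line_tension(
    pmf: PMFProfile,
    fit_range: tuple[float, float] = FIT_RANGE_DEFAULT,
    slope_is_gamma: bool = False,
) -> PoreEnergetics:
    """Rim line tension from the linear large-pore regime of the PMF.

    Ordinary least squares of G against the pore radius R = xi * R0 on
    ``fit_range`` gives a slope in kJ mol^-1 nm^-1; dividing by 2*pi (the
    rim length per unit radius) and converting units yields gamma in pN.
    With ``slope_is_gamma`` the 2*pi division is skipped, for comparison
    with conventions that read the slope itself as the line tension.

    Returns a :class:`PoreEnergetics` whose ``dG_nuc`` field is also filled
    (at the default xi_nuc) for convenience; ``fit_r2`` below 0.9 sets
    ``low_r2_warning`` instead of raising.
    """
    lo, hi = fit_range
    sel = (pmf.xi >= lo) & (pmf.xi <= hi)
    if np.sum(sel) < 5:
        raise ValueError(f"need >= 5 grid points inside fit range {fit_range}")
    r = pmf.xi[sel] * pmf.R0
    g = pmf.G[sel]
    slope, intercept = np.polyfit(r, g, 1)
    resid = g - (slope * r + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    gamma_kj = slope if slope_is_gamma else slope / (2.0 * np.pi)
    gamma = gamma_kj * PN_PER_KJ_MOL_NM
    try:
        dg = nucleation_free_energy(pmf)
    except ValueError:
        dg = float("nan")
    return PoreEnergetics(
        dG_nuc=dg,
        gamma=float(gamma),
        fit_range=fit_range,
        fit_r2=float(r2),
        fit_intercept=float(intercept),
        low_r2_warning=bool(r2 < 0.9),
    )


def detect_metastable(
    pmf: PMFProfile, min_depth: float = 1.0, xi_min: float = 1.0,
    smooth_frac: float | None = None,
) -> list[tuple[float, float]]:
    """Local PMF minima at xi > xi_min deep enough to imply metastable pores.

    A grid point is a candidate if it is a strict local minimum; its depth
    is measured to the lower of the two flanking maxima. Minima shallower
    than ``max(min_depth, 2 * local SE)`` are suppressed. For profiles with
    point noise, ``smooth_frac`` applies a lowess smooth (that fraction of
    the data per local fit) before minima detection, so statistical wiggles
    are not reported as metastable pores. Returns a list of
    (xi_minimum, depth in kJ/mol).
    """
    xi = pmf.xi
    g = _lowess_smooth(xi, pmf.G, frac=smooth_frac) if smooth_frac else pmf.G
    hits: list[tuple[float, float]] = []
    idx = np.arange(1, len(xi) - 1)
    local_min = (g[idx] < g[idx - 1]) & (g[idx] <= g[idx + 1])
    for i in idx[local_min]:
        if xi[i] <= xi_min:
            continue
        left_max = np.max(g[: i + 1])
        right_max = np.max(g[i:])
        depth = min(left_max, right_max) - g[i]
        threshold = min_depth
        if pmf.se is not None:
            threshold = max(threshold, 2.0 * float(pmf.se[i]))
        if depth >= threshold:
            hits.append((float(xi[i]), float(depth)))
    return hits


# ----------------------------------------------------------------------
# bootstrap errors
# ----------------------------------------------------------------------

def _lowess_smooth(xi: np.ndarray, g: np.ndarray, frac: float = 0.12) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sm = lowess(g, xi, frac=frac, it=0, return_sorted=False)
    return np.asarray(sm, dtype=float)


def _estimate_pair(profile: PMFProfile, xi_nuc: float, fit_range) -> tuple[float, float]:
    dg = nucleation_free_energy(profile, xi_nuc)
    gam = line_tension(profile, fit_range).gamma
    return dg, gam


def bootstrap_errors(
    pmfs: PMFProfile | list[PMFProfile],
    n_boot: int = 200,
    seed: int = 0,
    xi_nuc: float = XI_NUC_DEFAULT,
    fit_range: tuple[float, float] = FIT_RANGE_DEFAULT,
) -> dict:
    """Bootstrap standard errors of the nucleation free energy and line tension.

    With three or more replicate profiles (common xi grid), a case bootstrap
    resamples whole replicates and re-estimates from the pointwise mean
    profile. With a single profile, residuals around a lowess smooth are
    resampled i.i.d. and re-added to the smooth (residual bootstrap) — a
    stand-in for resampling the underlying umbrella histograms, which are
    not modeled here.

    Returns ``{"dG_nuc_se": ..., "gamma_se": ..., "scheme": ...}``.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    rng = np.random.default_rng(seed)

    if isinstance(pmfs, PMFProfile):
        profiles = [pmfs]
    else:
        profiles = list(pmfs)

    if len(profiles) >= 3:
        xi = profiles[0].xi
        for p in profiles[1:]:
            if p.xi.shape != xi.shape or np.max(np.abs(p.xi - xi)) > 1e-9:
                raise ValueError("replicate profiles must share a common xi grid")
        gs = np.stack([p.G for p in profiles])
        m = len(profiles)
        dgs, gammas = [], []
        for _ in range(n_boot):
            pick = rng.integers(0, m, size=m)
            mean_g = gs[pick].mean(axis=0)
            prof = PMFProfile(xi=xi.copy(), G=mean_g, R0=profiles[0].R0)
            dg, gam = _estimate_pair(prof, xi_nuc, fit_range)
            dgs.append(dg)
            gammas.append(gam)
        scheme = "replicate"
    else:
        pmf = profiles[0]
        lo, hi = fit_range
        if np.sum((pmf.xi >= lo) & (pmf.xi <= hi)) < 20:
            raise ValueError("residual bootstrap needs >= 20 points in the fit range")
        smooth = _lowess_smooth(pmf.xi, pmf.G)
        resid = pmf.G - smooth
        n = len(resid)
        dgs, gammas = [], []
        for _ in range(n_boot):
            g_star = smooth + resid[rng.integers(0, n, size=n)]
            prof = PMFProfile(xi=pmf.xi.copy(), G=g_star, R0=pmf.R0)
            dg, gam = _estimate_pair(prof, xi_nuc, fit_range)
            dgs.append(dg)
            gammas.append(gam)
        scheme = "residual"

    return {
        "dG_nuc_se": float(np.std(dgs, ddof=1)),
        "gamma_se": float(np.std(gammas, ddof=1)),
        "scheme": scheme,
    }


def analyze_pmf(
    pmf: PMFProfile,
    xi_nuc: float = XI_NUC_DEFAULT,
    fit_range: tuple[float, float] = FIT_RANGE_DEFAULT,
    n_boot: int | None = None,
    seed: int = 0,
    min_depth: float = 1.0,
    smooth_frac: float | None = None,
) -> PoreEnergetics:
    """Full single-profile analysis: energies, metastability and (optionally) SEs.

    ``smooth_frac`` is forwarded to :func:`detect_metastable`; on noisy
    profiles a lowess pre-smooth (e.g. 0.1) suppresses spurious minima.
    """
    result = line_tension(pmf, fit_range)
    result.dG_nuc = nucleation_free_energy(pmf, xi_nuc)
    result.metastable = detect_metastable(pmf, min_depth=min_depth,
                                          smooth_frac=smooth_frac)
    if n_boot:
        ses = bootstrap_errors(pmf, n_boot=n_boot, seed=seed,
                               xi_nuc=xi_nuc, fit_range=fit_range)
        result.dG_nuc_se = ses["dG_nuc_se"]
        result.gamma_se = ses["gamma_se"]
    return result


# ----------------------------------------------------------------------
# hysteresis
# ----------------------------------------------------------------------

def hysteresis(pmf_open: PMFProfile, pmf_close: PMFProfile) -> float:
    """Maximum absolute difference between opening and closing profiles.

    Both profiles are anchored on construction; the comparison runs over
    their common xi range, with the closing profile linearly interpolated
    onto the opening grid.
    """
    lo = max(pmf_open.xi[0], pmf_close.xi[0])
    hi = min(pmf_open.xi[-1], pmf_close.xi[-1])
    if hi <= lo:
        raise ValueError("profiles have no overlapping xi range")
    sel = (pmf_open.xi >= lo) & (pmf_open.xi <= hi)
    xi = pmf_open.xi[sel]
    diff = pmf_open.G[sel] - pmf_close.interpolate(xi)
    return float(np.max(np.abs(diff)))
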