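"""Annotated particle configurations of membrane systems.

A :class:`MembraneFrame` is the in-memory container every geometric analysis
operates on: particle positions in nm inside an orthorhombic periodic box,
plus per-particle species labels (e.g. POPC, CHOL, W), structural roles
(head / tail / water / polar) and molecule ids. Frames round-trip through
GRO and PDB coordinate files with a side-car YAML mapping that records the
species and role of every (residue name, atom name) pair, since neither
format can carry those annotations natively.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "MembraneFrame",
    "POLAR_ROLES",
    "write_frame",
    "read_frame",
    "write_role_map",
    "read_role_map",
]

#: Roles counted as "polar" for transmembrane-defect detection.
POLAR_ROLES = ("water", "polar")

_VALID_ROLES = ("head", "tail", "water", "polar")


@dataclass
class MembraneFrame:
    """Particle configuration with species/role annotations.

    Parameters
    ----------
    positions : (N, 3) float array
        Coordinates in nm; wrapped into ``[0, box)`` on construction.
    species : (N,) str array
        Chemical species label per particle (e.g. ``POPC``, ``CHOL``, ``W``).
    role : (N,) str array
        One of ``head``, ``tail``, ``water``, ``polar``.
    molecule_id : (N,) int array
        Groups particles into molecules; each lipid molecule must contain
        exactly one head particle and at least one tail particle.
    box : (3,) float array
        Orthorhombic box edge lengths in nm, all positive.
    """

    positions: np.ndarray
    species: np.ndarray
    role: np.ndarray
    molecule_id: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.role = np.asarray(self.role, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        n = len(self.positions)
        for name, arr in (("species", self.species), ("role", self.role),
                          ("molecule_id", self.molecule_id)):
            if len(arr) != n:
                raise ValueError(f"{name} must have length {n}")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        bad = set(np.unique(self.role.astype(str))) - set(_VALID_ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        # wrap into the primary image
        self.positions = np.mod(self.positions, self.box[None, :])

    # ------------------------------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def polar_mask(self) -> np.ndarray:
        """Boolean mask of particles counted as polar for defect detection."""
        return np.isin(self.role.astype(str), POLAR_ROLES)

    def mask(self, role: str | None = None, species: str | None = None) -> np.ndarray:
        m = np.ones(self.n_particles, dtype=bool)
        if role is not None:
            m &= self.role.astype(str) == role
        if species is not None:
            m &= self.species.astype(str) == species
        return m

    def lipid_molecules(self) -> dict[int, np.ndarray]:
        """Map molecule_id -> particle indices, for molecules with a head particle."""
        roles = self.role.astype(str)
        out: dict[int, np.ndarray] = {}
        order = np.argsort(self.molecule_id, kind="stable")
        ids = self.molecule_id[order]
        bounds = np.flatnonzero(np.diff(ids)) + 1
        for grp in np.split(order, bounds):
            if np.any(roles[grp] == "head"):
                out[int(self.molecule_id[grp[0]])] = grp
        return out

    def validate_lipids(self) -> None:
        """Check the one-head / >=1-tail invariant for every lipid molecule."""
        roles = self.role.astype(str)
        for mol_id, grp in self.lipid_molecules().items():
            n_head = int(np.sum(roles[grp] == "head"))
            n_tail = int(np.sum(roles[grp] == "tail"))
            if n_head != 1 or n_tail < 1:
                raise ValueError(
                    f"molecule {mol_id}: {n_head} head / {n_tail} tail particles"
                )

    def translated(self, shift) -> "MembraneFrame":
        """Return a copy rigidly translated by ``shift`` (nm), rewrapped."""
        return MembraneFrame(
            positions=self.positions + np.asarray(shift, dtype=float)[None, :],
            species=self.species.copy(),
            role=self.role.copy(),
            molecule_id=self.molecule_id.copy(),
            box=self.box.copy(),
        )


# ----------------------------------------------------------------------
# role-map side car
# ----------------------------------------------------------------------

def write_role_map(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(mapping, fh, sort_keys=True)


def read_role_map(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ----------------------------------------------------------------------
# GRO / PDB I/O through MDAnalysis
# ----------------------------------------------------------------------

_ROLE_ATOM_NAMES = {"head": "HD", "tail": "TL", "water": "W", "polar": "PW"}


def _frame_to_universe(frame: MembraneFrame):
    import MDAnalysis as mda

    n = frame.n_particles
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(np.unique(frame.molecule_id)),
        atom_resindex=np.unique(frame.molecule_id, return_inverse=True)[1],
        trajectory=True,
    )
    roles = frame.role.astype(str)
    names = np.array([_ROLE_ATOM_NAMES[r] for r in roles], dtype=object)
    # disambiguate atoms within a residue (GRO wants distinct names for clarity)
    u.add_TopologyAttr("name", names.astype(str))
    # residue name = species of the first atom of the residue (all atoms of a
    # toy molecule share one species)
    resnames = []
    seen: dict[int, str] = {}
    for mid, sp in zip(frame.molecule_id, frame.species):
        if int(mid) not in seen:
            seen[int(mid)] = str(sp)[:5]
    for mid in np.unique(frame.molecule_id):
        resnames.append(seen[int(mid)])
    u.add_TopologyAttr("resname", resnames)
    u.add_TopologyAttr("resid", list(range(1, len(resnames) + 1)))
    u.atoms.positions = frame.positions * 10.0  # nm -> Angstrom
    u.dimensions = np.array([*(frame.box * 10.0), 90.0, 90.0, 90.0])
    return u, names


def write_frame(frame: MembraneFrame, path, role_map_path=None) -> None:
    """Write a frame as GRO (nm) or PDB (Angstrom) plus a role-map side car.

    The format is chosen from the file suffix. The side-car YAML (default:
    same stem with ``.roles.yaml``) records species and role per
    (residue name, atom name) pair so :func:`read_frame` can restore the
    annotations.
    """
    path = pathlib.Path(path)
    u, names = _frame_to_universe(frame)
    u.atoms.write(str(path))
    if role_map_path is None:
        role_map_path = path.with_suffix(path.suffix + ".roles.yaml")
    # key by residue (species) and atom name
    mapping: dict = {}
    for sp, name, role in zip(frame.species, names, frame.role):
        mapping.setdefault(str(sp)[:5], {})[str(name)] = {
            "species": str(sp),
            "role": str(role),
        }
    write_role_map(mapping, role_map_path)


def read_frame(path, role_map_path=None) -> MembraneFrame:
    """Read a GRO or PDB coordinate file back into a :class:`MembraneFrame`."""
    import MDAnalysis as mda

    path = pathlib.Path(path)
    if role_map_path is None:
        role_map_path = path.with_suffix(path.suffix + ".roles.yaml")
    mapping = read_role_map(role_map_path)
    u = mda.Universe(str(path))
    resnames = u.atoms.resnames
    names = u.atoms.names
    species = []
    roles = []
    for rn, an in zip(resnames, names):
        try:
            entry = mapping[str(rn)][str(an)]
        except KeyError as exc:
            raise KeyError(f"no role-map entry for residue {rn!r} atom {an!r}") from exc
        species.append(entry["species"])
        roles.append(entry["role"])
    box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    return MembraneFrame(
        positions=u.atoms.positions / 10.0,
        species=np.array(species, dtype=object),
        role=np.array(roles, dtype=object),
        molecule_id=u.atoms.resindices.astype(int),
        box=box,
    )


def minimum_image_dxy(xy: np.ndarray, center_xy, box_xy) -> np.ndarray:
    """Minimum-image in-plane displacement of points from a center (nm)."""
    d = xy - np.asarray(center_xy, dtype=float)[None, :]
    box = np.asarray(box_xy, dtype=float)
    return d - box[None, :] * np.round(d / box[None, :])
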