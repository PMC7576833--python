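"""Geometric observables for antibody trajectories.

The two bespoke observables of the pipeline live here:

* the **VH/VL interface angle** — a signed torsion over four centers of
  mass: COM(light-chain CDR loops), COM(VL), COM(VH), COM(heavy-chain CDR
  loops).  It summarizes the relative orientation of the two variable
  domains in a single frame-wise scalar.
* the **elbow angle** — a torsion over COM(variable module), the two
  switch-region COMs (which realize the hinge axis between the variable
  and constant modules of a Fab), and COM(constant module).

Both reduce to one shared signed-dihedral kernel using the IUPAC
convention: the angle is 0 for cis (eclipsed) arrangements and the sign is
fixed by the documented reference case
``dihedral((1,0,0), (0,0,0), (0,0,1), (0,1,1)) = -90 deg``.

Rigid-body superposition (Kabsch) and region RMSD are also provided; the
rotation solve is delegated to :class:`scipy.spatial.transform.Rotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .antibody import AntibodyRegions, RegionError, Trajectory

__all__ = [
    "DegenerateGeometryError",
    "InterfaceAngleSeries",
    "ElbowAngleSeries",
    "center_of_mass",
    "dihedral",
    "interface_angle",
    "elbow_angle",
    "superpose",
    "region_rmsd",
]

_COLLINEAR_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised for collinear/coincident points where an angle is undefined."""


def _wrap_degrees(angle: np.ndarray | float):
    """Map angles into (-180, 180]."""
    wrapped = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    return wrapped


def center_of_mass(
    coords: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Mass-weighted (or plain) mean position.

    ``coords`` has shape (..., n_atoms, 3); the COM is taken over the
    second-to-last axis, so per-frame COMs fall out of a trajectory slice
    in one call.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2] == 0:
        raise ValueError("empty atom selection has no center of mass")
    if not mass_weighted or masses is None:
        return coords.mean(axis=-2)
    masses = np.asarray(masses, dtype=float)
    return (coords * masses[..., :, None]).sum(axis=-2) / masses.sum()


def dihedral(p1, p2, p3, p4, degenerate: str = "raise"):
    """Signed dihedral angle in degrees, IUPAC convention, range (-180, 180].

    Accepts single points (shape (3,)) or stacked frames (shape (n, 3));
    scalar inputs return a float.  ``degenerate`` selects the behaviour for
    collinear bond triplets: ``"raise"`` (default) or ``"nan"``.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    scalar = p1.ndim == 1
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    bad = (
        (np.linalg.norm(n1, axis=-1) < _COLLINEAR_TOL)
        | (np.linalg.norm(n2, axis=-1) < _COLLINEAR_TOL)
        | (np.linalg.norm(b2, axis=-1) < _COLLINEAR_TOL)
    )
    if np.any(bad):
        if degenerate == "raise":
            raise DegenerateGeometryError(
                "collinear or coincident points: dihedral undefined"
            )
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    ang = _wrap_degrees(np.degrees(np.arctan2(y, x)))
    ang = np.where(bad, np.nan, ang)
    return float(ang) if scalar else ang


@dataclass
class InterfaceAngleSeries:
    """Per-frame VH/VL interface torsion with the COM definitions used."""

    values: np.ndarray  # degrees, (-180, 180]
    region_names: tuple[str, ...] = ("CDRs_L", "VL", "VH", "CDRs_H")
    mass_weighted: bool = True

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ElbowAngleSeries:
    """Per-frame Fab elbow torsion with the COM definitions used."""

    values: np.ndarray
    region_names: tuple[str, ...] = ("V", "switch_H", "switch_L", "C")
    mass_weighted: bool = True

    def __len__(self) -> int:
        return len(self.values)


def _region_com_series(
    traj: Trajectory,
    residue_set,
    name: str,
    mode: str,
) -> np.ndarray:
    if not residue_set:
        raise RegionError(f"region {name!r} is empty")
    atom_filter = ["CA"] if mode == "ca" else None
    idx = traj.topology.atoms_of_residues(residue_set, atom_filter=atom_filter)
    if len(idx) == 0:
        raise RegionError(f"region {name!r} selects no atoms")
    if mode == "geometric":
        return center_of_mass(traj.coords[:, idx], mass_weighted=False)
    return center_of_mass(
        traj.coords[:, idx], traj.topology.masses[idx], mass_weighted=True
    )


def interface_angle(
    traj: Trajectory, regions: AntibodyRegions, com_mode: str = "mass"
) -> InterfaceAngleSeries:
    """VH/VL interface angle per frame.

    The torsion is evaluated over COM(CDR-L1..L3), COM(VL), COM(VH),
    COM(CDR-H1..H3).  ``com_mode`` selects ``"mass"`` (mass-weighted over
    all atoms of the region, the default), ``"ca"`` (C-alpha only) or
    ``"geometric"`` (unweighted mean) for sensitivity checks.  DE loops are
    excluded from the CDR unions.
    """
    sets = [
        ("CDRs_L", regions.light_cdrs),
        ("VL", regions["VL"]),
        ("VH", regions["VH"]),
        ("CDRs_H", regions.heavy_cdrs),
    ]
    coms = [_region_com_series(traj, s, n, com_mode) for n, s in sets]
    values = dihedral(*coms)
    return InterfaceAngleSeries(values=np.atleast_1d(values),
                                mass_weighted=(com_mode == "mass"))


def elbow_angle(
    traj: Trajectory, regions: AntibodyRegions, com_mode: str = "mass"
) -> ElbowAngleSeries:
    """Fab elbow angle per frame.

    Realized as the torsion over COM(VH+VL), COM(switch_H), COM(switch_L),
    COM(CH1+CL): the two switch-region COMs form the hinge axis between
    the variable and constant modules.  Requires a Fab (constant domains
    and switch regions present).
    """
    for needed in ("CL", "CH1", "switch_L", "switch_H"):
        if needed not in regions:
            raise RegionError(
                "elbow angle requires constant domains and switch regions "
                f"(missing {needed!r})"
            )
    variable = regions["VL"] | regions["VH"]
    constant = regions["CL"] | regions["CH1"]
    sets = [
        ("V", variable),
        ("switch_H", regions["switch_H"]),
        ("switch_L", regions["switch_L"]),
        ("C", constant),
    ]
    coms = [_region_com_series(traj, s, n, com_mode) for n, s in sets]
    values = dihedral(*coms)
    return ElbowAngleSeries(values=np.atleast_1d(values),
                            mass_weighted=(com_mode == "mass"))


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.  The
    rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("mobile and reference must share shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    mu_m = np.average(mobile, axis=0, weights=weights)
    mu_r = np.average(reference, axis=0, weights=weights)
    rot, _ = Rotation.align_vectors(reference - mu_r, mobile - mu_m,
                                    weights=weights)
    R = rot.as_matrix()
    t = mu_r - R @ mu_m
    moved = mobile @ R.T + t
    d2 = ((moved - reference) ** 2).sum(axis=1)
    rmsd = float(np.sqrt(np.average(d2, weights=weights)))
    return R, t, rmsd


def _matched_atom_indices(
    traj_a: Trajectory,
    traj_b: Trajectory,
    region_a,
    atom_filter: Sequence[str] | None,
):
    """Pair atoms of both topologies by (residue key, atom name) within a region."""
    keys_a = {}
    top_a, top_b = traj_a.topology, traj_b.topology
    region_keys = {top_a.residues[i].key for i in region_a}
    for i in top_a.atoms_of_residues(region_a, atom_filter=atom_filter):
        keys_a[(top_a.residues[top_a.res_index[i]].key, top_a.atom_names[i])] = i
    map_b = {}
    b_region = [
        j for j, r in enumerate(top_b.residues) if r.key in region_keys
    ]
    for i in top_b.atoms_of_residues(b_region, atom_filter=atom_filter):
        map_b[(top_b.residues[top_b.res_index[i]].key, top_b.atom_names[i])] = i
    common = [k for k in keys_a if k in map_b]
    missing = sorted(
        {f"{k[0][0]}:{k[0][1]}{k[0][2]}" for k in set(keys_a) ^ set(map_b)}
    )
    if missing:
        raise RegionError(f"unmatched residues between structures: {missing}")
    ia = np.array([keys_a[k] for k in common], dtype=int)
    ib = np.array([map_b[k] for k in common], dtype=int)
    return ia, ib


def region_rmsd(
    traj_a: Trajectory,
    traj_b: Trajectory,
    fit_region,
    rmsd_region,
    atom_filter: Sequence[str] | None = ("CA",),
    frame_a: int = 0,
    frame_b: int = 0,
) -> float:
    """RMSD over ``rmsd_region`` after superposing on ``fit_region``.

    Residue correspondence between the two structures is established by
    insertion-code-aware residue id; the fit is not repeated on the RMSD
    region.  Default compares C-alpha atoms only.
    """
    fit_a, fit_b = _matched_atom_indices(traj_a, traj_b, fit_region, atom_filter)
    msd_a, msd_b = _matched_atom_indices(traj_a, traj_b, rmsd_region, atom_filter)
    a, b = traj_a.frame(frame_a), traj_b.frame(frame_b)
    R, t, _ = superpose(a[fit_a], b[fit_b])
    moved = a[msd_a] @ R.T + t
    return float(np.sqrt(((moved - b[msd_b]) ** 2).sum(axis=1).mean()))
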