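"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (explicit loops, internal-coordinate
chain building, O(n^3) linkage) so they stay independent of the library
code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import abmsm as ab

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


# ---------------------------------------------------------------------------
# Toy PDB texts
# ---------------------------------------------------------------------------

def _atom_line(serial, name, resname, chain, resid, x, y, z, occ=1.0,
               altloc=" ", element=None):
    element = element or name.strip()[0]
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} {chain}{resid:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )


@pytest.fixture
def toy_pdb_text() -> str:
    """Single ALA residue, 5 atoms, 1 frame."""
    lines = [
        _atom_line(1, " N  ", "ALA", "A", 1, 11.104, 6.134, -6.504),
        _atom_line(2, " CA ", "ALA", "A", 1, 11.639, 6.071, -5.147),
        _atom_line(3, " C  ", "ALA", "A", 1, 12.402, 7.340, -4.798),
        _atom_line(4, " O  ", "ALA", "A", 1, 12.350, 8.325, -5.534, element="O"),
        _atom_line(5, " CB ", "ALA", "A", 1, 12.540, 4.850, -5.004),
        "TER", "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_model_pdb_text(toy_pdb_text) -> str:
    body = "\n".join(
        line for line in toy_pdb_text.splitlines() if line.startswith("ATOM")
    )
    return f"MODEL        1\n{body}\nENDMDL\nMODEL        2\n{body}\nENDMDL\nEND\n"


@pytest.fixture
def altloc_pdb_text() -> str:
    """One atom with altlocs A (occ 0.6, x=1) and B (occ 0.4, x=9)."""
    lines = [
        _atom_line(1, " N  ", "ALA", "A", 1, 0.0, 0.0, 0.0),
        _atom_line(2, " CA ", "ALA", "A", 1, 1.0, 0.0, 0.0, occ=0.6, altloc="A"),
        _atom_line(3, " CA ", "ALA", "A", 1, 9.0, 0.0, 0.0, occ=0.4, altloc="B"),
        _atom_line(4, " C  ", "ALA", "A", 1, 2.0, 1.0, 0.0),
        "END",
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Internal-coordinate backbone builder (oracle for torsion recovery)
# ---------------------------------------------------------------------------

def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d with given bond length c-d, angle b-c-d and torsion
    a-b-c-d (IUPAC sign), by explicit geometric construction."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * np.cos(theta),
         bond * np.sin(theta) * np.cos(phi),
         -bond * np.sin(theta) * np.sin(phi)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phi_psi: list[tuple[float, float]], chain: str = "A",
                   omega: float = 180.0):
    """Build an N-CA-C backbone with prescribed (phi, psi) per residue.

    phi of the first residue is ignored (undefined).  Returns an
    ``ab.Trajectory`` of one frame.
    """
    n_res = len(phi_psi)
    coords = [np.array([0.0, 0.0, 0.0]), np.array([1.458, 0.0, 0.0])]
    coords.append(
        coords[1] + 1.525 * np.array([np.cos(np.radians(180 - 111)),
                                      np.sin(np.radians(180 - 111)), 0.0])
    )
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(coords[-3], coords[-2], coords[-1], 1.329, 117.0,
                         psi_prev)
        ca_i = place_atom(coords[-2], coords[-1], n_i, 1.458, 121.0, omega)
        c_i = place_atom(coords[-1], n_i, ca_i, 1.525, 111.0, phi_psi[i][0])
        coords.extend([n_i, ca_i, c_i])
    residues = [
        ab.Residue(chain, i + 1, "", "GLY") for i in range(n_res)
    ]
    names, res_index = [], []
    for i in range(n_res):
        names.extend(["N", "CA", "C"])
        res_index.extend([i, i, i])
    top = ab.Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(["N", "C", "C"] * n_res, dtype=object),
        masses=np.array([14.007, 12.011, 12.011] * n_res),
        res_index=np.array(res_index),
        residues=residues,
    )
    return ab.Trajectory(topology=top, coords=np.array(coords)[None])


# ---------------------------------------------------------------------------
# Brute-force linkage oracle
# ---------------------------------------------------------------------------

def brute_force_average_linkage(dist: np.ndarray, cutoff: float):
    """O(n^3) agglomerative average linkage; returns the partition at the
    cutoff as a set of frozensets (lowest-index merge on ties)."""
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, i, j)
        d, i, j = best
        if d > cutoff:
            break
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def partition_of(labels: np.ndarray):
    out: dict[int, set[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(int(lab), set()).add(i)
    return {frozenset(v) for v in out.values()}


# ---------------------------------------------------------------------------
# Small shared synthetic fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_hmm_result():
    """Default 6-loop fixture at reduced length for module tests."""
    spec = ab.default_hmm_spec(n_frames=20_000, seed=7)
    return ab.simulate_hmm_torsions(spec)


@pytest.fixture(scope="session")
def rigid_fab():
    """Rigid Fab mock with varying interface and elbow prescriptions."""
    n = 200
    spec = ab.RigidAntibodySpec(
        interface_angles=np.linspace(-120.0, 120.0, n),
        elbow_angles=np.linspace(100.0, 170.0, n),
    )
    return ab.simulate_rigid_antibody(spec)
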