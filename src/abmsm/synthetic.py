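"""Synthetic trajectories with known ground truth.

Every pipeline stage has a recovery test against one of three generators,
none of which requires molecular dynamics or downloads:

* :func:`simulate_hmm_torsions` — per-loop backbone torsion time series
  driven by a hidden metastable Markov chain with a known transition
  matrix (von Mises emissions per state).  Several loops may share one
  hidden chain (coupled loop motions) while others switch independently;
  this mimics the correlated CDR-loop dynamics of a real paratope with a
  timescale separation scaled down to testable trajectory lengths.
* :func:`simulate_rigid_antibody` — mock antibody coordinates built from
  rigid region templates placed so the four interface centers of mass (and
  optionally the four elbow centers of mass) realize a prescribed torsion
  series exactly before noise; the prescription is the oracle for the
  geometric observables.
* :func:`simulate_double_well` — Metropolis samples from a quartic
  double-well potential with an analytically known barrier, the oracle for
  free-energy surfaces and two-state kinetics.

All generators are bit-reproducible under a fixed seed, and ground truth
is always available from the spec object rather than from pipeline output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .antibody import AntibodyRegions, Residue, Topology, Trajectory, annotate_regions
from .featurize import TorsionSeries
from .geometry import _wrap_degrees

__all__ = [
    "LoopEmissions",
    "HMMTorsionSpec",
    "HMMTorsionResult",
    "RigidAntibodySpec",
    "RigidAntibodyResult",
    "simulate_hmm_torsions",
    "simulate_rigid_antibody",
    "simulate_double_well",
    "double_well_potential",
    "metastable_transition_matrix",
    "sample_markov_chain",
    "default_hmm_spec",
]

#: von Mises concentration equivalent to a ~20 degree circular standard
#: deviation (kappa ~ 1/sigma_rad^2); states overlap mildly, which stresses
#: the microstating realistically.
DEFAULT_KAPPA = 8.2


def metastable_transition_matrix(
    weights: Sequence[float], exchange: np.ndarray, scale: float
) -> np.ndarray:
    """Reversible row-stochastic matrix with stationary distribution ``weights``.

    Built from a symmetric exchange matrix: ``X_ij = scale * exchange_ij``
    off-diagonal, diagonal filled so row i sums to ``weights[i]``; then
    ``T = X / weights[:, None]``.  Small ``scale`` gives metastable
    (slow-switching) dynamics.
    """
    w = np.asarray(weights, dtype=float)
    e = np.asarray(exchange, dtype=float)
    if not np.allclose(e, e.T) or np.any(np.diag(e) != 0):
        raise ValueError("exchange must be symmetric with zero diagonal")
    x = scale * e
    off = x.sum(axis=1)
    if np.any(off >= w):
        raise ValueError("scale too large: diagonal would be negative")
    x = x + np.diag(w - off)
    return x / w[:, None]


def sample_markov_chain(
    t: np.ndarray, n: int, rng: np.random.Generator,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Sample a discrete Markov chain of length n from row-stochastic t."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or np.any(t < 0) or \
            not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix must be row-stochastic")
    m = t.shape[0]
    if initial is None:
        # exact stationary distribution as the initial law
        import scipy.linalg
        evals, evecs = scipy.linalg.eig(t.T)
        pi = np.abs(np.real(evecs[:, np.argmin(np.abs(evals - 1.0))]))
        initial = pi / pi.sum()
    cum = np.cumsum(t, axis=1)
    u = rng.random(n)
    path = np.empty(n, dtype=int)
    path[0] = int(np.searchsorted(np.cumsum(initial), u[0], side="right"))
    for i in range(1, n):
        path[i] = int(np.searchsorted(cum[path[i - 1]], u[i], side="right"))
    np.clip(path, 0, m - 1, out=path)
    return path


# ---------------------------------------------------------------------------
# Hidden-Markov torsion trajectories
# ---------------------------------------------------------------------------

@dataclass
class LoopEmissions:
    """Per-state circular emission parameters for one loop."""

    means: np.ndarray  # (n_states, n_torsions), degrees
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        if self.kappa <= 0:
            raise ValueError("von Mises concentration must be positive")


@dataclass
class HMMTorsionSpec:
    """Hidden-Markov switching torsions: shared chain plus optional
    independently switching loops."""

    transition_matrix: np.ndarray
    coupled: dict[str, LoopEmissions]
    decoupled: dict[str, tuple[np.ndarray, LoopEmissions]] = field(
        default_factory=dict
    )
    n_frames: int = 50_000
    frame_spacing: float = 0.1  # ns per frame
    seed: int = 0


@dataclass
class HMMTorsionResult:
    """Generated torsion series per loop plus the hidden state paths."""

    torsions: dict[str, TorsionSeries]
    hidden: dict[str, np.ndarray]  # "shared" plus one entry per decoupled loop
    spec: HMMTorsionSpec


def _emit_loop(
    name: str, emissions: LoopEmissions, path: np.ndarray,
    rng: np.random.Generator,
) -> TorsionSeries:
    m, d = emissions.means.shape
    if path.max() >= m:
        raise ValueError(f"loop {name!r}: emission means cover {m} states "
                         f"but the chain visits state {path.max()}")
    mu = np.radians(emissions.means)[path]  # (n, d)
    vals = np.degrees(rng.vonmises(mu, emissions.kappa))
    vals = _wrap_degrees(vals)
    labels = [(f"{name}:{i + 1}", "psi") for i in range(d)]
    return TorsionSeries(vals, labels)


def simulate_hmm_torsions(spec: HMMTorsionSpec) -> HMMTorsionResult:
    """Generate per-loop torsion series with metastable hidden switching.

    Loops in ``spec.coupled`` share one hidden chain sampled from
    ``spec.transition_matrix``; loops in ``spec.decoupled`` each get an
    independent chain from their own transition matrix.  Emissions are von
    Mises around per-state mean torsions.
    """
    rng = np.random.default_rng(spec.seed)
    hidden: dict[str, np.ndarray] = {
        "shared": sample_markov_chain(spec.transition_matrix, spec.n_frames, rng)
    }
    torsions: dict[str, TorsionSeries] = {}
    for name, emissions in spec.coupled.items():
        torsions[name] = _emit_loop(name, emissions, hidden["shared"], rng)
    for name, (t_own, emissions) in spec.decoupled.items():
        hidden[name] = sample_markov_chain(np.asarray(t_own, float),
                                           spec.n_frames, rng)
        torsions[name] = _emit_loop(name, emissions, hidden[name], rng)
    return HMMTorsionResult(torsions=torsions, hidden=hidden, spec=spec)


def default_hmm_spec(n_frames: int = 50_000, seed: int = 0) -> HMMTorsionSpec:
    """The default test fixture: 6 loops, 4 hidden macrostates shared by 5
    loops, and one independently switching loop (CDR-H2), 0.1 ns frame
    spacing."""
    t_shared = metastable_transition_matrix(
        weights=(0.35, 0.30, 0.20, 0.15),
        exchange=np.array(
            [[0, 6, 2, 1],
             [6, 0, 4, 2],
             [2, 4, 0, 5],
             [1, 2, 5, 0]], dtype=float
        ),
        scale=5e-4,
    )
    base = np.array([-135.0, -45.0, 45.0, 135.0])
    coupled = {}
    for j, loop in enumerate(["CDR-L1", "CDR-L2", "CDR-L3", "CDR-H1", "CDR-H3"]):
        means = np.column_stack([np.roll(base, j), np.roll(base, j + 1)])
        coupled[loop] = LoopEmissions(means=means)
    t_h2 = np.array([[0.995, 0.005], [0.007, 0.993]])
    decoupled = {
        "CDR-H2": (t_h2, LoopEmissions(means=np.array([[-100.0, 60.0],
                                                       [80.0, -120.0]])))
    }
    return HMMTorsionSpec(
        transition_matrix=t_shared, coupled=coupled, decoupled=decoupled,
        n_frames=n_frames, frame_spacing=0.1, seed=seed,
    )


# ---------------------------------------------------------------------------
# Rigid mock antibody
# ---------------------------------------------------------------------------

_TEMPLATE4 = np.array(
    [[1.2, 1.2, 1.2],
     [1.2, -1.2, -1.2],
     [-1.2, 1.2, -1.2],
     [-1.2, -1.2, 1.2]]
)  # centered tetrahedron, 4 atoms


def _template(n_atoms: int) -> np.ndarray:
    """Centered non-degenerate point cloud with n_atoms (multiple of 4)."""
    blocks = []
    for i in range(n_atoms // 4):
        blocks.append(_TEMPLATE4 + np.array([3.0 * i, 0.0, 0.0]))
    pts = np.vstack(blocks)
    return pts - pts.mean(axis=0)


@dataclass
class RigidAntibodySpec:
    """Prescription for a rigid-body mock antibody trajectory.

    The four interface centers of mass are placed on a canonical dihedral
    scaffold (arm length ``r``, axis length ``d``, Angstrom) so that the
    interface torsion equals ``interface_angles[t]`` exactly at zero noise;
    when ``elbow_angles`` is given, switch and constant-region templates are
    added the same way for the elbow torsion.
    """

    interface_angles: np.ndarray
    elbow_angles: np.ndarray | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    r: float = 10.0
    d: float = 20.0
    random_pose: bool = False
    #: optional per-loop discrete conformers: loop -> (list of centered
    #: templates, per-frame conformer labels); COM-preserving, so the
    #: interface prescription stays exact.
    loop_conformers: Mapping[str, tuple[Sequence[np.ndarray], np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.interface_angles = np.atleast_1d(
            np.asarray(self.interface_angles, dtype=float)
        )
        if self.elbow_angles is not None:
            self.elbow_angles = np.atleast_1d(
                np.asarray(self.elbow_angles, dtype=float)
            )
            if len(self.elbow_angles) != len(self.interface_angles):
                raise ValueError("interface and elbow series must share length")
        if self.r <= 1e-6 or self.d <= 1e-6:
            raise ValueError(
                "degenerate scaffold: arm and axis lengths must be positive"
            )


@dataclass
class RigidAntibodyResult:
    trajectory: Trajectory
    regions: AntibodyRegions
    spec: RigidAntibodySpec


def _dihedral_scaffold(theta_deg: np.ndarray, r: float, d: float) -> np.ndarray:
    """Four points whose signed (IUPAC) dihedral equals theta exactly.

    p1 = (r,0,0), p2 = origin, p3 = (0,0,d), p4 = p3 + r*(cos(-theta),
    sin(-theta), 0); the -theta azimuth compensates the sign convention
    (azimuth +90 deg yields a -90 deg dihedral).
    """
    n = len(theta_deg)
    th = np.radians(theta_deg)
    pts = np.zeros((n, 4, 3))
    pts[:, 0] = [r, 0.0, 0.0]
    pts[:, 2] = [0.0, 0.0, d]
    pts[:, 3, 0] = r * np.cos(-th)
    pts[:, 3, 1] = r * np.sin(-th)
    pts[:, 3, 2] = d
    return pts


_MOCK_REGION_CONFIG = {
    "VL": ("L", 1, 20),
    "CDR-L1": ("L", 9, 12), "CDR-L2": ("L", 13, 16), "CDR-L3": ("L", 17, 20),
    "switch_L": ("L", 21, 24), "CL": ("L", 25, 32),
    "VH": ("H", 1, 20),
    "CDR-H1": ("H", 9, 12), "CDR-H2": ("H", 13, 16), "CDR-H3": ("H", 17, 20),
    "switch_H": ("H", 21, 24), "CH1": ("H", 25, 32),
}


def _mock_topology(include_fab: bool) -> tuple[Topology, dict[str, slice]]:
    """CA-only mock topology; returns atom slices per placement group."""
    residues: list[Residue] = []
    res_index: list[int] = []
    groups: dict[str, slice] = {}
    cursor = 0

    def add(chain: str, first_res: int, n_res: int, tag: str):
        nonlocal cursor
        for k in range(n_res):
            residues.append(Residue(chain, first_res + k, "", "GLY"))
            res_index.append(len(residues) - 1)
        groups[tag] = slice(cursor, cursor + n_res)
        cursor += n_res

    add("L", 1, 8, "fw_L")
    add("L", 9, 4, "CDR-L1")
    add("L", 13, 4, "CDR-L2")
    add("L", 17, 4, "CDR-L3")
    if include_fab:
        add("L", 21, 4, "switch_L")
        add("L", 25, 8, "CL")
    add("H", 1, 8, "fw_H")
    add("H", 9, 4, "CDR-H1")
    add("H", 13, 4, "CDR-H2")
    add("H", 17, 4, "CDR-H3")
    if include_fab:
        add("H", 21, 4, "switch_H")
        add("H", 25, 8, "CH1")

    n = len(residues)
    top = Topology(
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        masses=np.full(n, 12.011),
        res_index=np.array(res_index),
        residues=residues,
    )
    return top, groups


def simulate_rigid_antibody(spec: RigidAntibodySpec) -> RigidAntibodyResult:
    """Build a mock antibody trajectory realizing prescribed angle series.

    Region templates (one CA-like atom per residue, equal masses) are
    translated per frame so the interface centers of mass — COM(light CDR
    union), COM(VL), COM(VH), COM(heavy CDR union) — sit exactly on the
    dihedral scaffold for the prescribed interface angle, and analogously
    for the elbow chain when an elbow series is given.  Isotropic Gaussian
    noise (``noise_sigma`` Angstrom) and an optional random rigid pose per
    frame are applied afterwards.
    """
    include_fab = spec.elbow_angles is not None
    top, groups = _mock_topology(include_fab)
    n_frames = len(spec.interface_angles)
    rng = np.random.default_rng(spec.seed)

    scaffold = _dihedral_scaffold(spec.interface_angles, spec.r, spec.d)
    p1, p2, p3, p4 = (scaffold[:, k] for k in range(4))  # (n_frames, 3)

    # zero-sum offsets distribute the three CDR loops around the union COM
    loop_offsets = np.array([[2.0, 0.0, 0.0], [-1.0, 1.5, 0.0], [-1.0, -1.5, 0.0]])

    coords = np.zeros((n_frames, top.n_atoms, 3))

    def place(tag: str, target: np.ndarray, conformer_templates=None,
              conformer_labels=None):
        sl = groups[tag]
        n_atoms = sl.stop - sl.start
        if conformer_templates is None:
            coords[:, sl] = _template(n_atoms)[None] + target[:, None, :]
        else:
            tmpl = np.stack([
                np.asarray(t, float) - np.asarray(t, float).mean(axis=0)
                for t in conformer_templates
            ])
            if tmpl.shape[1] != n_atoms:
                raise ValueError(
                    f"conformer templates for {tag!r} must have {n_atoms} atoms"
                )
            coords[:, sl] = tmpl[np.asarray(conformer_labels, int)] \
                + target[:, None, :]

    conf = spec.loop_conformers or {}
    # light-chain CDR loops around p1, heavy-chain ones around p4
    for k, loop in enumerate(("CDR-L1", "CDR-L2", "CDR-L3")):
        tgt = p1 + loop_offsets[k]
        place(loop, tgt, *(conf.get(loop) or (None, None)))
    for k, loop in enumerate(("CDR-H1", "CDR-H2", "CDR-H3")):
        tgt = p4 + loop_offsets[k]
        place(loop, tgt, *(conf.get(loop) or (None, None)))
    # frameworks compensate so the full-domain COMs land on p2 / p3
    n_cdr, n_fw, n_dom = 12.0, 8.0, 20.0
    place("fw_L", (n_dom * p2 - n_cdr * p1) / n_fw)
    place("fw_H", (n_dom * p3 - n_cdr * p4) / n_fw)

    if include_fab:
        elbow = _dihedral_scaffold(spec.elbow_angles, 1.2 * spec.r, 1.25 * spec.d)
        # COM of the variable module is fixed by the interface construction
        com_v = (n_dom * p2 + n_dom * p3) / (2 * n_dom)
        shift = com_v - elbow[:, 0]
        q2, q3, q4 = (elbow[:, k] + shift for k in (1, 2, 3))
        place("switch_H", q2)
        place("switch_L", q3)
        delta = np.array([3.0, 0.0, 0.0])
        place("CL", q4 + delta)
        place("CH1", q4 - delta)

    if spec.random_pose:
        from scipy.spatial.transform import Rotation
        rots = Rotation.random(n_frames, random_state=spec.seed + 1).as_matrix()
        trans = rng.normal(scale=50.0, size=(n_frames, 1, 3))
        coords = np.einsum("fij,faj->fai", rots, coords) + trans
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(scale=spec.noise_sigma, size=coords.shape)

    traj = Trajectory(topology=top, coords=coords)
    config = dict(_MOCK_REGION_CONFIG)
    if not include_fab:
        for key in ("switch_L", "CL", "switch_H", "CH1"):
            config.pop(key)
    regions = annotate_regions(top, config)
    return RigidAntibodyResult(trajectory=traj, regions=regions, spec=spec)


# ---------------------------------------------------------------------------
# Double-well sampler
# ---------------------------------------------------------------------------

def double_well_potential(x, barrier: float, a: float = 1.0):
    """Quartic double well U(x) = barrier * ((x/a)^2 - 1)^2, kcal/mol.

    Wells at x = +-a with U = 0; barrier height at x = 0 is ``barrier``.
    """
    x = np.asarray(x, dtype=float)
    return barrier * ((x / a) ** 2 - 1.0) ** 2


def simulate_double_well(
    barrier: float,
    kt: float = 0.596,
    n_steps: int = 100_000,
    seed: int = 0,
    a: float = 1.0,
    step_size: float = 0.6,
    dim: int = 1,
) -> np.ndarray:
    """Metropolis samples from the quartic double well.

    ``kt`` is the thermal energy in kcal/mol (0.596 at 300 K).  With
    ``dim=2`` an independent harmonic coordinate (spring constant
    2 kcal/mol/A^2) is appended, giving a 2-D surface with a known 1-D
    barrier along the first axis.  Returns shape (n_steps,) or
    (n_steps, 2).
    """
    if barrier < 0:
        raise ValueError("barrier must be non-negative")
    if kt <= 0 or n_steps < 1:
        raise ValueError("invalid sampler parameters")
    rng = np.random.default_rng(seed)
    x = a
    xs = np.empty(n_steps)
    proposals = rng.normal(scale=step_size, size=n_steps)
    accepts = rng.random(n_steps)
    u = float(double_well_potential(x, barrier, a))
    for i in range(n_steps):
        x_new = x + proposals[i]
        u_new = barrier * ((x_new / a) ** 2 - 1.0) ** 2
        if u_new <= u or accepts[i] < np.exp(-(u_new - u) / kt):
            x, u = x_new, u_new
        xs[i] = x
    if dim == 1:
        return xs
    if dim == 2:
        k_spring = 2.0
        ys = rng.normal(scale=np.sqrt(kt / k_spring), size=n_steps)
        return np.column_stack([xs, ys])
    raise ValueError("dim must be 1 or 2")
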