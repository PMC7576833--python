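"""Backbone-torsion featurization of CDR loops.

Conformational states of the hypervariable loops are encoded through the
backbone dihedrals phi and psi of the loop residues.  Because torsions are
circular, downstream linear methods (tICA, k-means) operate on the
(sin, cos) embedding of each angle, which is also the collective-variable
space used for enhanced sampling of CDR loops: a linear combination of the
sines and cosines of the loop psi torsions.

Angles are stored in degrees in (-180, 180]; radians appear only inside
the trig kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .antibody import Trajectory
from .geometry import DegenerateGeometryError, dihedral

__all__ = [
    "TorsionSeries",
    "FeatureMatrix",
    "backbone_torsions",
    "sincos_features",
    "metadynamics_cv",
    "combine_features",
]


@dataclass
class TorsionSeries:
    """Frames x angles matrix in degrees with (residue, angle-name) labels."""

    values: np.ndarray  # (n_frames, n_angles), degrees in (-180, 180]
    labels: list[tuple[str, str]]  # (residue label, "phi" | "psi")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("torsion values must be 2-D (frames x angles)")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count does not match angle columns")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() <= -180.0 - 1e-9 or finite.max() > 180.0 + 1e-9):
            raise ValueError("torsions must lie in (-180, 180] degrees")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_angles(self) -> int:
        return self.values.shape[1]

    def select(self, angle_names: Iterable[str]) -> "TorsionSeries":
        wanted = set(angle_names)
        cols = [i for i, (_, a) in enumerate(self.labels) if a in wanted]
        return TorsionSeries(self.values[:, cols], [self.labels[i] for i in cols])


@dataclass
class FeatureMatrix:
    """Frames x features of sin/cos torsion values with provenance labels."""

    values: np.ndarray  # in [-1, 1]
    labels: list[tuple[str, str, str]]  # (residue, angle name, "sin" | "cos")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count does not match feature columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _residue_label(res) -> str:
    return str(res)


def backbone_torsions(
    traj: Trajectory,
    residues: Iterable[int],
    angles: Sequence[str] = ("phi", "psi"),
    on_degenerate: str = "raise",
) -> TorsionSeries:
    """Compute phi/psi backbone torsions for the given residues.

    phi(i) is built from C(i-1), N(i), CA(i), C(i) and psi(i) from N(i),
    CA(i), C(i), N(i+1); neighbours are the adjacent residues of the same
    chain in topology order.  Chain-terminal residues simply lack the
    corresponding column.  Missing backbone atoms raise; collinear
    (degenerate) geometries raise by default, or — with
    ``on_degenerate="drop"`` — the affected column is dropped with a
    warning.
    """
    top = traj.topology
    residues = sorted(set(int(r) for r in residues))
    # Per-residue backbone atom lookup
    backbone: dict[int, dict[str, int]] = {}
    for i in range(top.n_atoms):
        name = str(top.atom_names[i])
        if name in ("N", "CA", "C"):
            backbone.setdefault(int(top.res_index[i]), {})[name] = i

    # Chain-order neighbours
    chain_members: dict[str, list[int]] = {}
    for idx, res in enumerate(top.residues):
        chain_members.setdefault(res.chain_id, []).append(idx)
    neighbour_prev: dict[int, int] = {}
    neighbour_next: dict[int, int] = {}
    for members in chain_members.values():
        for a, b in zip(members, members[1:]):
            neighbour_next[a] = b
            neighbour_prev[b] = a

    def atom(res_idx: int, name: str) -> int:
        try:
            return backbone[res_idx][name]
        except KeyError:
            raise ValueError(
                f"residue {top.residues[res_idx]} lacks backbone atom {name!r}"
            ) from None

    columns: list[np.ndarray] = []
    labels: list[tuple[str, str]] = []
    for r in residues:
        if r >= top.n_residues:
            raise ValueError(f"residue index {r} outside topology")
        quads = {}
        if "phi" in angles and r in neighbour_prev:
            p = neighbour_prev[r]
            quads["phi"] = (atom(p, "C"), atom(r, "N"), atom(r, "CA"), atom(r, "C"))
        if "psi" in angles and r in neighbour_next:
            nx = neighbour_next[r]
            quads["psi"] = (atom(r, "N"), atom(r, "CA"), atom(r, "C"), atom(nx, "N"))
        for angle_name, (i1, i2, i3, i4) in quads.items():
            vals = dihedral(
                traj.coords[:, i1], traj.coords[:, i2],
                traj.coords[:, i3], traj.coords[:, i4],
                degenerate="nan" if on_degenerate == "drop" else "raise",
            )
            vals = np.atleast_1d(vals)
            if np.isnan(vals).any():
                warnings.warn(
                    f"degenerate {angle_name} for residue {top.residues[r]}; "
                    "column dropped"
                )
                continue
            columns.append(vals)
            labels.append((_residue_label(top.residues[r]), angle_name))
    if not columns:
        raise ValueError("no torsions could be computed for the selection")
    return TorsionSeries(np.column_stack(columns), labels)


def sincos_features(
    ts: TorsionSeries, angle_subset: Sequence[str] | None = None
) -> FeatureMatrix:
    """Embed torsions as (sin, cos) pairs, ordered (sin, cos) by label order.

    ``angle_subset`` restricts to angle names (e.g. ``("psi",)`` for the
    enhanced-sampling collective-variable space).
    """
    if angle_subset is not None:
        ts = ts.select(angle_subset)
    if ts.n_angles == 0:
        raise ValueError("empty angle subset: no features to build")
    rad = np.radians(ts.values)
    out = np.empty((ts.n_frames, 2 * ts.n_angles))
    labels: list[tuple[str, str, str]] = []
    for j, (res, ang) in enumerate(ts.labels):
        out[:, 2 * j] = np.sin(rad[:, j])
        out[:, 2 * j + 1] = np.cos(rad[:, j])
        labels.append((res, ang, "sin"))
        labels.append((res, ang, "cos"))
    return FeatureMatrix(out, labels)


def metadynamics_cv(ts: TorsionSeries, weights: Sequence[float]) -> np.ndarray:
    """Linear-combination collective variable over psi sin/cos features.

    ``weights`` has length 2 x (number of retained psi torsions), matching
    the (sin, cos) column order of :func:`sincos_features`; the CV is the
    per-frame dot product of the weights with that feature vector.
    """
    fm = sincos_features(ts, angle_subset=("psi",))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (fm.n_features,):
        raise ValueError(
            f"weight length {weights.size} does not match feature count "
            f"{fm.n_features} (2 per psi torsion)"
        )
    return fm.values @ weights


def combine_features(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate feature blocks column-wise (e.g. all CDR loops combined)."""
    if not matrices:
        raise ValueError("nothing to combine")
    n = matrices[0].n_frames
    if any(m.n_frames != n for m in matrices):
        raise ValueError("feature blocks must share the frame count")
    values = np.hstack([m.values for m in matrices])
    labels = [lab for m in matrices for lab in m.labels]
    return FeatureMatrix(values, labels)
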