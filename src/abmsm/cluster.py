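"""Geometric clustering of trajectory frames and canonical-cluster assignment.

Two complementary views of loop conformation live here:

* **average-linkage hierarchical clustering** of frames under a pairwise
  RMSD metric with a distance cutoff (1.2 Angstrom is the conventional
  seeding-stage choice), used both for whole-binding-site clustering and
  for per-loop conformational states;
* **canonical-cluster assignment**, matching each frame's loop torsions
  against user-supplied median torsion vectors (PyIgClassify-style labels
  such as ``L1-11-3``) under a mean circular distance.

Linkage distances default to C-alpha RMSD after a per-frame fit on the
framework (the non-CDR Fv residues); the fit mask is recorded in the
result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .antibody import AntibodyRegions, Trajectory
from .featurize import TorsionSeries
from .geometry import superpose

__all__ = [
    "ClusterResult",
    "CanonicalAssignment",
    "pairwise_rmsd_matrix",
    "average_linkage_cluster",
    "per_loop_cluster",
    "assign_canonical",
]

UNASSIGNED = "unassigned"


@dataclass
class ClusterResult:
    """Flat clustering of frames with medoid representatives.

    Labels are dense ``0..K-1``, ordered by first frame occurrence; each
    representative is the frame closest (in mean distance) to the other
    members of its cluster.
    """

    labels: np.ndarray
    representatives: np.ndarray  # frame index per cluster
    cutoff: float
    metric: str = "ca_rmsd"
    fit_mask: str = "framework"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def populations(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class CanonicalAssignment:
    """Per-frame nearest canonical-cluster label with circular distance."""

    labels: list[str]
    distances: np.ndarray  # mean circular distance, degrees
    threshold: float

    @property
    def assigned_fraction(self) -> float:
        return float(np.mean([lab != UNASSIGNED for lab in self.labels]))


def pairwise_rmsd_matrix(
    traj: Trajectory,
    selection,
    fit_selection=None,
    atom_filter: Sequence[str] | None = ("CA",),
) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix in Angstrom.

    Every pair is superposed on ``fit_selection`` (defaults to the RMSD
    selection itself), then the RMSD is taken over ``selection`` without
    refitting.  C-alpha atoms by default.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    sel_idx = traj.topology.atoms_of_residues(selection, atom_filter=atom_filter)
    if len(sel_idx) == 0:
        raise ValueError("empty atom selection")
    if fit_selection is None:
        fit_idx = sel_idx
    else:
        fit_idx = traj.topology.atoms_of_residues(fit_selection,
                                                  atom_filter=atom_filter)
        if len(fit_idx) == 0:
            raise ValueError("empty fit selection")
    n = traj.n_frames
    sel = traj.coords[:, sel_idx]
    fit = traj.coords[:, fit_idx]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r, t, _ = superpose(fit[i], fit[j])
            moved = sel[i] @ r.T + t
            out[i, j] = out[j, i] = np.sqrt(
                ((moved - sel[j]) ** 2).sum(axis=1).mean()
            )
    return out


def average_linkage_cluster(
    dist: np.ndarray, cutoff: float, metric: str = "ca_rmsd",
    fit_mask: str = "framework",
) -> ClusterResult:
    """Agglomerative average-linkage clustering with a distance cutoff.

    Clusters are merged while the minimum average inter-cluster distance
    does not exceed ``cutoff`` (ties resolved to the lowest-index merge);
    representatives are cluster medoids.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    n = dist.shape[0]
    if n == 1:
        return ClusterResult(np.zeros(1, dtype=int), np.zeros(1, dtype=int),
                             cutoff, metric, fit_mask)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    flat = scipy.cluster.hierarchy.fcluster(z, t=cutoff, criterion="distance")
    # relabel densely by first occurrence
    labels = np.empty(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(flat):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels[i] = mapping[lab]
    k = len(mapping)
    reps = np.empty(k, dtype=int)
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        if members.size == 1:
            reps[c] = members[0]
        else:
            sub = dist[np.ix_(members, members)]
            reps[c] = members[int(np.argmin(sub.mean(axis=1)))]
    return ClusterResult(labels, reps, cutoff, metric, fit_mask)


def per_loop_cluster(
    traj: Trajectory,
    regions: AntibodyRegions,
    loop: str,
    cutoff: float = 1.2,
    atom_filter: Sequence[str] | None = ("CA",),
) -> ClusterResult:
    """Cluster one CDR loop's conformations after a framework fit.

    Frames are superposed on the non-CDR Fv framework; the linkage distance
    is the loop's C-alpha RMSD without refitting.
    """
    if loop not in regions:
        raise ValueError(f"loop {loop!r} not present in regions")
    dist = pairwise_rmsd_matrix(
        traj, regions[loop], fit_selection=regions.framework(),
        atom_filter=atom_filter,
    )
    return average_linkage_cluster(dist, cutoff, metric="ca_rmsd",
                                   fit_mask="framework")


def circular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mean over torsions of min(|da|, 360 - |da|), in degrees."""
    delta = np.abs(np.asarray(a, float) - np.asarray(b, float))
    return np.minimum(delta, 360.0 - delta).mean(axis=-1)


def assign_canonical(
    ts: TorsionSeries,
    references: Mapping[str, Sequence[float]],
    threshold: float = 40.0,
) -> CanonicalAssignment:
    """Assign each frame to the nearest canonical-cluster median.

    ``references`` maps labels (e.g. ``"L1-11-3"``) to torsion vectors of
    the same dimensionality as the series; the distance is the mean
    circular distance per torsion.  Frames farther than ``threshold``
    degrees from every median are labelled ``"unassigned"``; exact ties go
    to the lexicographically smaller label.
    """
    names = sorted(references)
    if not names:
        raise ValueError("no reference medians supplied")
    refs = np.array([np.asarray(references[n], dtype=float) for n in names])
    if refs.shape[1] != ts.n_angles:
        raise ValueError(
            f"reference dimension {refs.shape[1]} does not match series "
            f"({ts.n_angles} torsions)"
        )
    d = np.stack(
        [circular_distance(ts.values, refs[k]) for k in range(len(names))],
        axis=1,
    )  # (frames, refs)
    best = np.argmin(d, axis=1)  # argmin takes first minimum: lexicographic tie rule
    best_d = d[np.arange(len(best)), best]
    labels = [
        names[b] if bd <= threshold else UNASSIGNED
        for b, bd in zip(best, best_d)
    ]
    return CanonicalAssignment(labels=labels, distances=best_d,
                               threshold=threshold)
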