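"""Synthesis of macrostate ensembles, angle distributions and loop coupling.

Once the Markov-state model and PCCA+ macrostates are in hand, this module
ties the kinetic picture back to structure:

* frames are partitioned into **macrostate ensembles** via the crisp
  microstate-to-macrostate map, with equilibrium probabilities from the
  stationary distribution;
* each ensemble yields a **per-state distribution** of the VH/VL interface
  angle (or elbow angle) on a shared binning, with median shifts between
  states quantified with a bootstrap interval;
* macrostate representatives are **projected onto per-loop free-energy
  surfaces** to see which loops move between paratope states;
* per-loop geometric cluster labels are crossed into **co-occurrence
  matrices**, with Cramér's V as the scalar association score
  ``V = sqrt(chi^2 / (n (min(r, c) - 1)))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .cluster import ClusterResult
from .kinetics import MacrostateModel, MarkovModel, TICAModel, project

__all__ = [
    "MacrostateEnsemble",
    "PerStateAngles",
    "CooccurrenceMatrix",
    "macrostate_ensembles",
    "per_state_angle_distribution",
    "project_macrostates_on_loop_fes",
    "loop_cooccurrence",
    "cramers_v",
]


@dataclass
class MacrostateEnsemble:
    """Frames belonging to one metastable paratope state."""

    macrostate: int
    frames: np.ndarray
    probability: float
    representative: int | None = None  # frame index


def macrostate_ensembles(
    micro_labels: np.ndarray,
    model: MarkovModel,
    macro: MacrostateModel,
    coords: np.ndarray | None = None,
    centers: np.ndarray | None = None,
) -> tuple[list[MacrostateEnsemble], np.ndarray]:
    """Partition frames into macrostate ensembles.

    ``micro_labels`` are original microstate labels per frame; frames whose
    microstate fell outside the model's connected set go into the returned
    ``unassigned`` pool.  When tICA ``coords`` and k-means ``centers`` are
    given, each ensemble's representative frame is the medoid of its
    highest-probability microstate (the frame closest to that microstate's
    center).
    """
    micro_labels = np.asarray(micro_labels, dtype=int)
    active_labels = model.map_labels(micro_labels)
    unassigned = np.nonzero(active_labels < 0)[0]
    pi = model.stationary_distribution
    ensembles: list[MacrostateEnsemble] = []
    for a in range(macro.n_macrostates):
        micro_in_a = macro.microstates_of(a)
        frame_mask = np.isin(active_labels, micro_in_a)
        frames = np.nonzero(frame_mask)[0]
        rep = None
        if coords is not None and micro_in_a.size and frames.size:
            top_micro = micro_in_a[int(np.argmax(pi[micro_in_a]))]
            cand = np.nonzero(active_labels == top_micro)[0]
            if cand.size:
                if centers is not None:
                    center = centers[model.active_set[top_micro]]
                else:
                    center = coords[cand].mean(axis=0)
                rep = int(cand[np.argmin(
                    np.linalg.norm(coords[cand] - center, axis=1)
                )])
        ensembles.append(
            MacrostateEnsemble(
                macrostate=a,
                frames=frames,
                probability=float(macro.probabilities[a]),
                representative=rep,
            )
        )
    return ensembles, unassigned


@dataclass
class PerStateAngles:
    """Per-macrostate angle histograms on a shared binning."""

    edges: np.ndarray
    histograms: dict[int, np.ndarray]
    medians: dict[int, float]
    iqrs: dict[int, float]
    reference: float | None  # e.g. the crystal-structure angle
    median_shifts: dict[tuple[int, int], tuple[float, float, float]]
    empty_states: list[int]

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def per_state_angle_distribution(
    ensembles: Sequence[MacrostateEnsemble],
    angles: np.ndarray,
    bins: int = 36,
    reference: float | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> PerStateAngles:
    """Angle distribution per macrostate ensemble.

    All states share one binning over the full angle range observed.  The
    shift between two states is the difference of their medians, reported
    with a bootstrap percentile interval (2.5/97.5%).  Empty ensembles are
    flagged, not histogrammed.
    """
    angles = np.asarray(getattr(angles, "values", angles), dtype=float)
    n_total = max((e.frames.max() + 1 for e in ensembles if e.frames.size),
                  default=0)
    if len(angles) < n_total:
        raise ValueError(
            f"angle series ({len(angles)} frames) shorter than ensembles "
            f"require ({n_total})"
        )
    edges = np.histogram_bin_edges(angles, bins=bins)
    rng = np.random.default_rng(seed)
    hists: dict[int, np.ndarray] = {}
    medians: dict[int, float] = {}
    iqrs: dict[int, float] = {}
    empty: list[int] = []
    for e in ensembles:
        if e.frames.size == 0:
            empty.append(e.macrostate)
            continue
        vals = angles[e.frames]
        hists[e.macrostate], _ = np.histogram(vals, bins=edges)
        medians[e.macrostate] = float(np.median(vals))
        q1, q3 = np.percentile(vals, [25, 75])
        iqrs[e.macrostate] = float(q3 - q1)
    shifts: dict[tuple[int, int], tuple[float, float, float]] = {}
    for a, b in combinations(sorted(medians), 2):
        va = angles[next(e.frames for e in ensembles if e.macrostate == a)]
        vb = angles[next(e.frames for e in ensembles if e.macrostate == b)]
        point = medians[b] - medians[a]
        boot = np.empty(n_boot)
        for i in range(n_boot):
            boot[i] = (
                np.median(rng.choice(vb, size=vb.size, replace=True))
                - np.median(rng.choice(va, size=va.size, replace=True))
            )
        lo, hi = np.percentile(boot, [2.5, 97.5])
        shifts[(a, b)] = (point, float(lo), float(hi))
    return PerStateAngles(edges=edges, histograms=hists, medians=medians,
                          iqrs=iqrs, reference=reference,
                          median_shifts=shifts, empty_states=empty)


def project_macrostates_on_loop_fes(
    loop_model: TICAModel,
    loop_features,
    representative_frames: Sequence[int],
    n_components: int = 2,
) -> np.ndarray:
    """Project macrostate representative frames into a loop's tICA plane.

    ``loop_features`` is the loop's feature matrix over all frames; the
    representatives' rows are projected with the loop's own tICA model, so
    the points land on that loop's free-energy surface.
    """
    feats = getattr(loop_features, "values", np.asarray(loop_features, float))
    reps = np.asarray(representative_frames, dtype=int)
    if reps.size and (reps.min() < 0 or reps.max() >= feats.shape[0]):
        raise ValueError("representative frame outside the feature domain")
    return project(loop_model, feats[reps], n_components=n_components)


@dataclass
class CooccurrenceMatrix:
    """Joint cluster-occupancy counts for one loop pair."""

    loops: tuple[str, str]
    counts: np.ndarray  # (clusters of A, clusters of B)
    cramers_v: float

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def normalized(self, mode: str = "joint") -> np.ndarray:
        if mode == "joint":
            return self.counts / self.counts.sum()
        if mode == "row":
            return self.counts / self.counts.sum(axis=1, keepdims=True)
        raise ValueError(f"unknown normalization {mode!r}")


def cramers_v(counts: np.ndarray) -> float:
    """Cramér's V association score, V = sqrt(chi2 / (n (min(r,c) - 1))).

    Degenerate tables (a loop with a single cluster) carry no association
    information and return 0.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    r, c = counts.shape
    if min(r, c) < 2:
        return 0.0
    chi2 = scipy.stats.chi2_contingency(counts, correction=False)[0]
    n = counts.sum()
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def loop_cooccurrence(
    cluster_results: Mapping[str, ClusterResult | np.ndarray],
) -> dict[tuple[str, str], CooccurrenceMatrix]:
    """All pairwise joint cluster-occupancy matrices with Cramér's V.

    Every loop must be clustered over the identical frame set; marginals of
    each joint matrix equal the per-loop cluster populations by
    construction.
    """
    labels = {
        name: np.asarray(getattr(res, "labels", res), dtype=int)
        for name, res in cluster_results.items()
    }
    lengths = {name: len(lab) for name, lab in labels.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"frame-set mismatch between loops: {lengths}")
    out: dict[tuple[str, str], CooccurrenceMatrix] = {}
    for a, b in combinations(sorted(labels), 2):
        la, lb = labels[a], labels[b]
        ka, kb = la.max() + 1, lb.max() + 1
        counts = np.zeros((ka, kb))
        np.add.at(counts, (la, lb), 1.0)
        out[(a, b)] = CooccurrenceMatrix(
            loops=(a, b), counts=counts, cramers_v=cramers_v(counts)
        )
    return out
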