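"""Markov-state modelling of CDR-loop dynamics.

The kinetic stage turns sin/cos torsion features into a coarse-grained
picture of paratope states:

1. **tICA** finds the slowest linear collective coordinates by solving the
   generalized eigenproblem ``C_tau v = lambda C_0 v`` built from
   symmetrized instantaneous and time-lagged covariances.
2. **k-means** discretizes the leading tICA coordinates into microstates
   (150 by default).
3. A **Markov-state model** is estimated at a lag time tau from
   sliding-window transition counts, restricted to the largest strongly
   connected set, with a reversible maximum-likelihood transition matrix
   (detailed balance enforced); its stationary distribution gives state
   populations, its spectrum gives implied timescales ``t_i =
   -tau / ln lambda_i``.
4. The model is validated with the **Chapman-Kolmogorov test** and
   coarse-grained into metastable macrostates with **PCCA+**.
5. Populations over any two coordinates are rendered as a free-energy
   surface ``dG = -k_B T ln(p / p_max)``.

All stochastic stages take explicit seeds.  Lag times are expressed in
frames; physical units follow from the trajectory's frame spacing (ns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
from sklearn.cluster import KMeans

from .featurize import FeatureMatrix

__all__ = [
    "TICAModel",
    "MicrostateModel",
    "MarkovModel",
    "MacrostateModel",
    "FreeEnergySurface",
    "CKTestResult",
    "fit_tica",
    "project",
    "kmeans_microstates",
    "count_matrix",
    "estimate_msm",
    "stationary_distribution",
    "implied_timescales",
    "ck_test",
    "pcca",
    "macrostate_kinetics",
    "free_energy_surface",
    "KB_KCAL_PER_MOL_K",
]

KB_KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant, kcal/(mol K)


def _as_arrays(features) -> list[np.ndarray]:
    if isinstance(features, (FeatureMatrix, np.ndarray)):
        features = [features]
    out = []
    for seg in features:
        arr = seg.values if isinstance(seg, FeatureMatrix) else np.asarray(seg, float)
        if arr.ndim != 2:
            raise ValueError("each feature segment must be 2-D (frames x features)")
        out.append(arr)
    return out


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

@dataclass
class TICAModel:
    """Time-lagged independent component analysis model.

    Eigenvectors are C0-orthonormal (``v_i^T C0 v_j = delta_ij``) and sorted
    by descending eigenvalue; an eigenvalue is the autocorrelation of its
    component at the lag.
    """

    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ct: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns
    ridge: float
    frame_spacing: float | None = None

    @property
    def lag_ns(self) -> float | None:
        return None if self.frame_spacing is None else self.lag * self.frame_spacing

    def n_components_for_kinetic_variance(self, fraction: float = 0.95) -> int:
        """Smallest m whose components carry `fraction` of the kinetic
        variance sum(lambda_i^2) over positive eigenvalues."""
        lam = np.clip(self.eigenvalues, 0.0, None) ** 2
        if lam.sum() == 0:
            return 1
        cum = np.cumsum(lam) / lam.sum()
        return int(np.searchsorted(cum, fraction) + 1)


def fit_tica(features, lag: int, ridge: float = 1e-6,
             frame_spacing: float | None = None) -> TICAModel:
    """Estimate tICA from one or more trajectory segments.

    Covariances are accumulated per segment (no pairs straddle a segment
    boundary) with the symmetrized estimator: the mean and C0 average over
    both ends of each lagged pair and ``C_tau`` is symmetrized as
    ``(C_tau + C_tau^T)/2``, which keeps the spectrum real and bounded by
    one.  A small ridge on C0 regularizes redundant features.
    """
    segments = _as_arrays(features)
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    dim = segments[0].shape[1]
    s_x = np.zeros(dim)
    s_xx = np.zeros((dim, dim))
    s_xy = np.zeros((dim, dim))
    n_pairs = 0
    for i, seg in enumerate(segments):
        if seg.shape[0] <= lag:
            raise ValueError(
                f"segment {i} has {seg.shape[0]} frames, shorter than lag {lag}"
            )
        x, y = seg[:-lag], seg[lag:]
        s_x += x.sum(axis=0) + y.sum(axis=0)
        s_xx += x.T @ x + y.T @ y
        s_xy += x.T @ y + y.T @ x
        n_pairs += x.shape[0]
    mean = s_x / (2 * n_pairs)
    c0 = s_xx / (2 * n_pairs) - np.outer(mean, mean)
    ct = s_xy / (2 * n_pairs) - np.outer(mean, mean)
    c0_reg = c0 + ridge * np.eye(dim)
    # guard against truly rank-deficient input beyond what the ridge fixes
    if np.linalg.eigvalsh(c0_reg).min() <= 0:
        raise ValueError("C0 is rank-deficient beyond the ridge regularization")
    evals, evecs = scipy.linalg.eigh(ct, c0_reg)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.abs(evals).max() > 1 + 1e-8:
        warnings.warn("tICA eigenvalue outside [-1, 1]; estimate may be noisy")
    return TICAModel(lag=lag, mean=mean, c0=c0, ct=(ct + ct.T) / 2,
                     eigenvalues=evals, eigenvectors=evecs, ridge=ridge,
                     frame_spacing=frame_spacing)


def project(model: TICAModel, features, n_components: int | None = None):
    """Mean-free projection onto the leading tICA eigenvectors.

    A list of segments returns a list of projections; a single matrix
    returns one array of shape (frames, n_components).
    """
    single = isinstance(features, (FeatureMatrix, np.ndarray))
    segments = _as_arrays(features)
    m = n_components or model.eigenvectors.shape[1]
    v = model.eigenvectors[:, :m]
    out = []
    for seg in segments:
        if seg.shape[1] != model.mean.size:
            raise ValueError(
                f"feature dimension {seg.shape[1]} does not match model "
                f"({model.mean.size})"
            )
        out.append((seg - model.mean) @ v)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Microstates
# ---------------------------------------------------------------------------

@dataclass
class MicrostateModel:
    """k-means microstating of tICA space."""

    centers: np.ndarray  # (k, dim)
    dtrajs: list[np.ndarray]  # one label array per input segment
    seed: int
    inertia: float

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """All segment labels concatenated in segment order."""
        return np.concatenate(self.dtrajs)


def kmeans_microstates(coords, k: int = 150, seed: int = 0) -> MicrostateModel:
    """Discretize (lists of) coordinate segments into k microstates.

    k-means++ initialization with a fixed seed; Lloyd iterations until the
    relative inertia change falls below 1e-8 (at most 500 iterations), so a
    fixed seed gives bit-identical labels.
    """
    single = isinstance(coords, np.ndarray)
    segments = _as_arrays(coords)
    stacked = np.vstack(segments)
    if stacked.shape[0] < k:
        raise ValueError(f"{stacked.shape[0]} frames < k={k} microstates")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=500,
                tol=1e-8, random_state=seed)
    labels = km.fit_predict(stacked)
    dtrajs = []
    start = 0
    for seg in segments:
        dtrajs.append(labels[start:start + seg.shape[0]].astype(int))
        start += seg.shape[0]
    return MicrostateModel(centers=km.cluster_centers_, dtrajs=dtrajs,
                           seed=seed, inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# Markov-state model
# ---------------------------------------------------------------------------

def count_matrix(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window transition counts C_ij = #{t : s(t)=i, s(t+lag)=j}."""
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if not dtrajs or all(d.size == 0 for d in dtrajs):
        raise ValueError("empty discrete trajectories")
    if n_states is None:
        n_states = max(int(d.max()) for d in dtrajs if d.size) + 1
    c = np.zeros((n_states, n_states))
    for i, d in enumerate(dtrajs):
        if d.size <= lag:
            raise ValueError(f"discrete trajectory {i} shorter than lag {lag}")
        np.add.at(c, (d[:-lag], d[lag:]), 1.0)
    return c


@dataclass
class MarkovModel:
    """Reversible (or naive) Markov-state model over the connected set."""

    lag: int
    counts: np.ndarray          # counts restricted to the active set
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    active_set: np.ndarray      # original state ids of the active set
    fraction_states: float
    fraction_counts: float
    reversible: bool
    frame_spacing: float | None = None

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def map_labels(self, dtraj: np.ndarray) -> np.ndarray:
        """Map original microstate labels to active-set indices (-1 outside)."""
        lookup = -np.ones(int(max(self.active_set.max() + 1, dtraj.max() + 1)),
                          dtype=int)
        lookup[self.active_set] = np.arange(self.n_states)
        return lookup[np.asarray(dtraj, dtype=int)]


def _largest_connected_set(c: np.ndarray) -> np.ndarray:
    n_comp, assignment = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(c > 0), directed=True, connection="strong"
    )
    best, best_counts = 0, -1.0
    for comp in range(n_comp):
        members = np.nonzero(assignment == comp)[0]
        total = c[np.ix_(members, members)].sum()
        if total > best_counts:
            best, best_counts = comp, total
    return np.nonzero(assignment == best)[0]


def _reversible_mle(c: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000):
    """Maximum-likelihood reversible transition matrix (fixed-point update).

    Iterates ``x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)`` on the symmetric
    flux matrix x until the stationary vector stops changing; then
    ``T_ij = x_ij / x_i`` and ``pi = x_i / sum(x)``.
    """
    c_sym = c + c.T
    c_row = c.sum(axis=1)
    x = c_sym / c_sym.sum()
    x_row = x.sum(axis=1)
    for _ in range(max_iter):
        denom = c_row[:, None] / x_row[:, None] + c_row[None, :] / x_row[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new /= x_new.sum()
        x_row_new = x_new.sum(axis=1)
        delta = np.max(np.abs(x_row_new - x_row) / np.maximum(x_row_new, 1e-300))
        x, x_row = x_new, x_row_new
        if delta < tol:
            break
    t = x / x_row[:, None]
    pi = x_row / x_row.sum()
    return t, pi


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    evals, evecs = scipy.linalg.eig(t.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_msm(
    c: np.ndarray,
    lag: int = 1,
    reversible: bool = True,
    frame_spacing: float | None = None,
) -> MarkovModel:
    """Estimate a Markov-state model from a count matrix.

    The model is restricted to the largest strongly connected set of the
    count graph (states must be mutually reachable for equilibrium
    probabilities to exist).  The reversible estimate enforces detailed
    balance ``pi_i T_ij = pi_j T_ji`` via the standard fixed-point
    iteration; the naive estimate simply row-normalizes the counts.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("count matrix must be square")
    if np.any(c < 0):
        raise ValueError("count matrix must be non-negative")
    active = _largest_connected_set(c)
    if active.size == 0:
        raise ValueError("empty connected set")
    if active.size < c.shape[0]:
        warnings.warn(
            f"restricting to largest connected set: {active.size}/{c.shape[0]} states"
        )
    sub = c[np.ix_(active, active)]
    if reversible:
        t, pi = _reversible_mle(sub)
    else:
        t = sub / sub.sum(axis=1, keepdims=True)
        pi = stationary_distribution(t)
    return MarkovModel(
        lag=lag,
        counts=sub,
        transition_matrix=t,
        stationary_distribution=pi,
        active_set=active,
        fraction_states=active.size / c.shape[0],
        fraction_counts=float(sub.sum() / c.sum()) if c.sum() else 1.0,
        reversible=reversible,
        frame_spacing=frame_spacing,
    )


def _reversible_spectrum(t: np.ndarray, pi: np.ndarray):
    """Real eigendecomposition of a reversible T via symmetrization.

    Returns (eigenvalues desc, right eigenvectors as columns)."""
    d = np.sqrt(pi)
    s = (t * d[:, None]) / d[None, :]
    s = (s + s.T) / 2
    evals, u = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, u = evals[order], u[:, order]
    psi = u / d[:, None]  # right eigenvectors of T
    # normalize sign: first (stationary) eigenvector positive
    for j in range(psi.shape[1]):
        ref = psi[np.argmax(np.abs(psi[:, j])), j]
        if ref < 0:
            psi[:, j] *= -1
    return evals, psi


def implied_timescales(
    model_or_t, lag: int | None = None, n: int | None = None
) -> np.ndarray:
    """Implied timescales t_i = -lag / ln(lambda_{i+1}), in frames.

    Accepts a :class:`MarkovModel` (using its lag) or a bare transition
    matrix plus ``lag``.  Eigenvalues <= 0 are below the resolution of the
    lag and are excluded with a warning; eigenvalues numerically equal to 1
    beyond the stationary one yield ``inf`` (disconnected or periodic).
    """
    if isinstance(model_or_t, MarkovModel):
        t = model_or_t.transition_matrix
        lag = model_or_t.lag
        if model_or_t.reversible:
            evals, _ = _reversible_spectrum(t, model_or_t.stationary_distribution)
        else:
            evals = np.sort(np.real(np.linalg.eigvals(t)))[::-1]
    else:
        if lag is None:
            raise ValueError("lag required with a bare transition matrix")
        t = np.asarray(model_or_t, dtype=float)
        evals = np.sort(np.real(np.linalg.eigvals(t)))[::-1]
    evals = evals[1:]  # drop the stationary eigenvalue
    if n is not None:
        evals = evals[:n]
    keep = evals > 0
    if not np.all(keep):
        warnings.warn(
            f"{np.count_nonzero(~keep)} eigenvalue(s) <= 0: below resolution "
            "at this lag; excluded"
        )
        evals = evals[keep]
    with np.errstate(divide="ignore"):
        ts = np.where(evals >= 1.0 - 1e-12, np.inf, -lag / np.log(evals))
    return ts


# ---------------------------------------------------------------------------
# PCCA+ macrostates
# ---------------------------------------------------------------------------

@dataclass
class MacrostateModel:
    """PCCA+ metastable coarse-graining of a Markov-state model."""

    memberships: np.ndarray        # chi, (n_micro, m), rows sum to 1
    assignments: np.ndarray        # crisp macrostate per microstate
    probabilities: np.ndarray      # pi-weighted macrostate probabilities
    n_macrostates: int

    def microstates_of(self, macro: int) -> np.ndarray:
        return np.nonzero(self.assignments == macro)[0]


def _inner_simplex_vertices(x: np.ndarray, m: int) -> np.ndarray:
    """Index search for the m rows of x spanning the largest simplex."""
    vertices = np.empty(m, dtype=int)
    y = x.copy()
    vertices[0] = int(np.argmax(np.linalg.norm(y, axis=1)))
    y = y - y[vertices[0]]
    for k in range(1, m):
        norms = np.linalg.norm(y, axis=1)
        vertices[k] = int(np.argmax(norms))
        v = y[vertices[k]]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError("degenerate eigenvector geometry in PCCA+")
        y = y - np.outer(y @ v, v) / nv**2
    return vertices


def pcca(model: MarkovModel, m: int) -> MacrostateModel:
    """PCCA+ fuzzy coarse-graining into m metastable macrostates.

    The first m right eigenvectors of the reversible transition matrix map
    every microstate to a point in an (m-1)-simplex; the vertex search
    picks the m most extreme microstates as pure states, and memberships
    follow from expressing each row in the vertex basis (clipped to [0, 1]
    and renormalized).  Macrostate probabilities are
    ``P_a = sum_i pi_i chi_ia``.
    """
    if m < 2:
        raise ValueError("need at least 2 macrostates")
    t = model.transition_matrix
    pi = model.stationary_distribution
    evals, psi = _reversible_spectrum(t, pi)
    if np.count_nonzero(evals > 0) < m:
        raise ValueError(
            f"only {np.count_nonzero(evals > 0)} positive eigenvalues: "
            f"choose a smaller number of macrostates than {m}"
        )
    x = psi[:, :m].copy()
    x[:, 0] = 1.0  # stationary eigenvector is constant by construction
    vertices = _inner_simplex_vertices(x, m)
    a = np.linalg.inv(x[vertices])
    chi = x @ a
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    assignments = np.argmax(chi, axis=1)
    # relabel macrostates by descending probability for stable output
    probs = chi.T @ pi
    order = np.argsort(probs)[::-1]
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(m)
    chi = chi[:, order]
    assignments = rank[assignments]
    probs = probs[order]
    if not np.allclose(probs.sum(), 1.0, atol=1e-10):
        raise AssertionError("macrostate probabilities do not sum to 1")
    return MacrostateModel(memberships=chi, assignments=assignments,
                           probabilities=probs, n_macrostates=m)


def macrostate_kinetics(model: MarkovModel, macro: MacrostateModel):
    """Pairwise mean first-passage times between macrostates.

    MFPT(A -> B) is computed by first-step analysis on the microstate
    transition matrix: solve ``(I - T_notB) h = 1`` for the expected hitting
    time of the microstate set B, then average over A with stationary
    weights.  Times are in frames (steps x lag); multiply by the frame
    spacing for physical units.  Returns ``(mfpt_matrix, probabilities)``;
    unreachable pairs are ``inf``.
    """
    t = model.transition_matrix
    pi = model.stationary_distribution
    m = macro.n_macrostates
    n = t.shape[0]
    mfpt = np.zeros((m, m))
    for b in range(m):
        target = macro.microstates_of(b)
        if target.size == 0:
            mfpt[:, b] = np.inf
            continue
        free = np.setdiff1d(np.arange(n), target)
        h = np.zeros(n)
        if free.size:
            a_mat = np.eye(free.size) - t[np.ix_(free, free)]
            try:
                h[free] = np.linalg.solve(a_mat, np.ones(free.size))
            except np.linalg.LinAlgError:
                h[free] = np.inf
        for a in range(m):
            if a == b:
                continue
            src = macro.microstates_of(a)
            w = pi[src]
            mfpt[a, b] = float(np.average(h[src], weights=w)) * model.lag
    return mfpt, macro.probabilities


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

@dataclass
class CKTestResult:
    """Predicted vs re-estimated macrostate transition probabilities.

    ``predicted[k]`` holds the m x m set-to-set probabilities implied by
    propagating the base model to ``multiples[k]`` lags; ``estimated[k]``
    the same quantity from a model re-estimated at that longer lag, with
    multinomial standard errors.  ``passed`` applies the default agreement
    rule max deviation <= max(abs_tol, n_sigma * SE).
    """

    multiples: list[int]
    predicted: np.ndarray   # (n_multiples, m, m)
    estimated: np.ndarray
    std_err: np.ndarray
    max_deviation: np.ndarray  # per multiple
    passed: bool


def _set_transition_probs(t: np.ndarray, pi: np.ndarray,
                          sets: list[np.ndarray]) -> np.ndarray:
    m = len(sets)
    out = np.zeros((m, m))
    for a in range(m):
        wa = pi[sets[a]]
        rows = t[sets[a]]
        for b in range(m):
            out[a, b] = float(np.average(rows[:, sets[b]].sum(axis=1), weights=wa))
    return out


def ck_test(
    dtrajs,
    lag: int,
    n_macrostates: int,
    multiples: Sequence[int] = (1, 2, 3, 4, 5),
    reversible: bool = True,
    abs_tol: float = 0.01,
    n_sigma: float = 3.0,
) -> CKTestResult:
    """Chapman-Kolmogorov consistency test.

    A base model at ``lag`` is coarse-grained (PCCA+ crisp sets); for each
    multiple k the matrix power ``T(lag)^k`` is compared, set-to-set, with
    a model re-estimated at ``k * lag``.  Standard errors come from the
    multinomial counting statistics of each set's outgoing transitions,
    with an effective-count correction: sliding windows of length L overlap
    L-fold, so only about 1/L of the counted transitions are statistically
    independent.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, int) for d in dtrajs]
    n_states = max(int(d.max()) for d in dtrajs) + 1

    base = estimate_msm(count_matrix(dtrajs, lag, n_states), lag=lag,
                        reversible=reversible)
    macro = pcca(base, n_macrostates)
    sets = [macro.microstates_of(a) for a in range(n_macrostates)]
    t_base = base.transition_matrix
    pi = base.stationary_distribution

    m = n_macrostates
    predicted = np.zeros((len(multiples), m, m))
    estimated = np.zeros_like(predicted)
    std_err = np.zeros_like(predicted)
    max_dev = np.zeros(len(multiples))
    for k, mult in enumerate(multiples):
        long_lag = lag * mult
        if all(d.size <= long_lag for d in dtrajs):
            raise ValueError(f"trajectories too short for lag multiple {mult}")
        predicted[k] = _set_transition_probs(
            np.linalg.matrix_power(t_base, mult), pi, sets
        )
        c_long = count_matrix(dtrajs, long_lag, n_states)
        est = estimate_msm(c_long, lag=long_lag, reversible=reversible)
        # map base active-set sets into the long model's active set
        lookup = -np.ones(n_states, dtype=int)
        lookup[est.active_set] = np.arange(est.n_states)
        sets_long = []
        for s in sets:
            mapped = lookup[base.active_set[s]]
            sets_long.append(mapped[mapped >= 0])
        if any(s.size == 0 for s in sets_long):
            raise ValueError(
                f"macrostate lost from connected set at lag multiple {mult}"
            )
        estimated[k] = _set_transition_probs(
            est.transition_matrix, est.stationary_distribution, sets_long
        )
        # multinomial SE per origin set; effective counts correct for the
        # L-fold overlap of sliding windows at lag L
        for a in range(m):
            n_a = c_long[base.active_set[sets[a]], :].sum()
            n_eff = max(n_a / long_lag, 1.0)
            p = estimated[k, a]
            std_err[k, a] = np.sqrt(np.clip(p * (1 - p), 0, None) / n_eff)
        max_dev[k] = np.max(np.abs(predicted[k] - estimated[k]))
    tolerance = np.maximum(abs_tol, n_sigma * std_err)
    passed = bool(np.all(np.abs(predicted - estimated) <= tolerance))
    return CKTestResult(multiples=list(multiples), predicted=predicted,
                        estimated=estimated, std_err=std_err,
                        max_deviation=max_dev, passed=passed)


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """Histogram-based free-energy surface dG = -k_B T ln(p / p_max).

    ``free_energy`` holds kcal/mol with ``inf`` marking empty bins; the
    minimum over occupied bins is exactly 0.
    """

    edges: list[np.ndarray]
    free_energy: np.ndarray
    probabilities: np.ndarray
    temperature: float

    @property
    def kt(self) -> float:
        return KB_KCAL_PER_MOL_K * self.temperature

    def centers(self, axis: int = 0) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def value_at(self, point) -> float:
        """Free energy of the bin containing ``point``."""
        idx = []
        for x, e in zip(np.atleast_1d(point), self.edges):
            i = int(np.clip(np.searchsorted(e, x, side="right") - 1, 0, len(e) - 2))
            idx.append(i)
        return float(self.free_energy[tuple(idx)])


def free_energy_surface(
    coords: np.ndarray,
    weights: np.ndarray | None = None,
    bins: int | Sequence[int] = 60,
    temperature: float = 300.0,
    hist_range=None,
) -> FreeEnergySurface:
    """Histogram 1-D or 2-D coordinates into a free-energy surface.

    Optional per-frame weights (e.g. stationary reweighting) enter the
    histogram; probabilities are normalized over occupied bins before the
    Boltzmann inversion at the given temperature (default 300 K).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty input: no occupied bins")
    if coords.ndim == 1:
        hist, edges = np.histogram(coords, bins=bins, range=hist_range,
                                   weights=weights)
        edges_list = [edges]
    elif coords.ndim == 2 and coords.shape[1] == 2:
        hist, ex, ey = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins,
                                      range=hist_range, weights=weights)
        edges_list = [ex, ey]
    else:
        raise ValueError("coords must be 1-D or (n, 2)")
    total = hist.sum()
    if total <= 0:
        raise ValueError("no occupied bins")
    p = hist / total
    kt = KB_KCAL_PER_MOL_K * temperature
    with np.errstate(divide="ignore"):
        dg = np.where(p > 0, -kt * np.log(p / p.max()), np.inf)
    return FreeEnergySurface(edges=edges_list, free_energy=dg, probabilities=p,
                             temperature=temperature)
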