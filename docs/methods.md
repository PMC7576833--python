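# Methods

This note records the models implemented in `abmsm`, the assumptions they
make, the default parameters (with units and rationale), the scope of the
synthetic generators, and the numerical conventions. It states no
empirical results beyond what the test suite and `scripts/acceptance.py`
compute.

## Antibody model and region annotation

A structure is a `Topology` (atoms with names, elements, masses, and
insertion-code-aware residue identities) plus a coordinate array of one or
more frames in Å. Region annotation maps named residue ranges
(domains `VL`, `VH`, `CL`, `CH1`; CDR loops `CDR-L1..L3`, `CDR-H1..H3`;
optional DE loops) onto the topology and validates that every CDR lies
inside its domain and that domains and CDRs are pairwise disjoint. Chothia
and North CDR boundary presets are provided but never applied implicitly;
the caller always states the numbering convention used. When a variable
and a constant domain share a chain and no switch region is given, the
switch region defaults to the last two residues of the variable domain
plus the first two of the constant domain — a minimal, symmetric hinge
definition.

Altloc handling keeps the highest-occupancy alternative, so atom counts
stay constant across conformers of the same entry.

## Geometric observables

**Dihedral kernel.** All torsions use one signed-dihedral kernel with
range (−180°, 180°], cis = 0°. The sign is anchored by one documented
reference case: `dihedral((1,0,0), (0,0,0), (0,0,1), (0,1,1)) = −90°`.
Some other packages (e.g. mdtraj) adopt the opposite sign for the same
coordinates; cross-comparisons must account for that global sign. Bond
triplets collinear within 10⁻¹⁰ raise a degenerate-geometry error (or
yield NaN on request).

**Interface angle.** The V_H/V_L orientation is summarized per frame as
the torsion over four centers of mass: COM(CDR-L1∪L2∪L3), COM(VL),
COM(VH), COM(CDR-H1∪H2∪H3). COMs are mass-weighted over all atoms of the
region by default; Cα-only and unweighted modes exist for sensitivity
checks. DE loops are excluded from the CDR unions.

**Elbow angle.** The hinge between the variable and constant modules of a
Fab is realized as the torsion over COM(VH∪VL), COM(switch_H),
COM(switch_L), COM(CH1∪CL): the two switch-region COMs form the hinge
axis. A 4-point torsion is the simplest construction that uses exactly
the switch-region COMs as the axis; other conventions exist, which is why
the switch regions themselves are configurable.

**Superposition and RMSD.** Rigid superposition is a least-squares Kabsch
fit (proper rotation, det = +1, via `scipy.spatial.transform.Rotation`).
Region RMSD superposes on a fit region and evaluates the RMSD over a
separate region without refitting; atom correspondence is established by
(residue key, atom name), Cα-only by default.

## Featurization

φ(i) is the torsion over C(i−1), N(i), CA(i), C(i); ψ(i) over N(i),
CA(i), C(i), N(i+1); chain-terminal angles are absent rather than padded.
Torsions enter the kinetic analysis as (sin, cos) pairs, which removes the
±180° discontinuity and makes Euclidean distances meaningful for k-means.
A metadynamics-style collective variable is a linear combination of the
sin/cos features of the ψ torsions.

## Kinetic analysis

**tICA.** Instantaneous (C₀) and time-lagged (C_τ) covariances are
accumulated per trajectory segment — no lagged pair straddles a segment
boundary — with the symmetrized estimator (mean and C₀ over both ends of
each pair, C_τ symmetrized), which keeps the generalized eigenvalues real
and in [−1, 1]. A ridge of 10⁻⁶ on C₀ regularizes redundant features
(sin/cos pairs are nearly collinear when a torsion barely moves); the
value is small enough not to perturb well-conditioned problems. Components
can be selected by cumulative kinetic variance Σλ² (default fraction
0.95).

**Microstates.** Seeded k-means (k-means++ initialization, single
restart, tolerance 10⁻⁸) discretizes the leading tICA coordinates.
Default k = 150: enough spatial resolution to separate metastable basins
without starving the count matrix at the analysis lags.

**Markov-state model.** Sliding-window transition counts at lag τ
(frames) are restricted to the largest strongly connected set (equilibrium
probabilities require mutual reachability), then a reversible
maximum-likelihood transition matrix is obtained by the standard
fixed-point iteration on the symmetric flux matrix,
x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j), to relative tolerance 10⁻¹².
Implied timescales are t_i = −τ/ln λ_{i+1}; the spectrum of a reversible
model is computed through the π-symmetrized matrix D^{1/2} T D^{−1/2}
(exactly real). Eigenvalues ≤ 0 are below the resolution of the lag and
excluded with a warning.

**Chapman–Kolmogorov test.** Set-to-set transition probabilities
(π-weighted over PCCA+ crisp sets) of T(τ)^m are compared against a model
re-estimated at lag mτ for multiples 1–5. The agreement rule is
max(|predicted − estimated|) ≤ max(0.01, 3·SE) per entry. SE is the
multinomial standard error with an effective-count correction: sliding
windows at lag L overlap L-fold, so only about 1/L of the counted
transitions are independent, and N_eff = N/L. Without this correction the
SE is underestimated by √L and pure sampling fluctuations at long lags
are misread as model error.

**PCCA+.** The first m right eigenvectors map microstates into an
(m−1)-simplex; an index-search with Gram–Schmidt deflation picks the m
most extreme microstates as vertices, memberships follow from expressing
each row in the vertex basis (clipped to [0, 1] and renormalized), and
macrostates are relabeled by descending stationary probability for stable
output. Mean first-passage times between macrostates come from first-step
analysis on the microstate matrix, (I − T_notB) h = 1, averaged over the
source set with stationary weights, in frames (steps × lag).

**Free-energy surfaces.** 1-D or 2-D histograms are inverted as
ΔG = −k_B T ln(p/p_max) with k_B = 0.0019872041 kcal/(mol·K) and T =
300 K by default; empty bins carry ∞ rather than an arbitrary cap, and
the minimum over occupied bins is exactly 0.

## Conformational clustering and loop coupling

Frame-frame distances are Cα RMSDs over a loop after superposing each
pair on the framework (the non-CDR Fv residues). Average-linkage
agglomerative clustering with a distance cutoff (1.2 Å default, the
conventional seeding-stage choice) yields flat clusters with medoid
representatives; labels are densified in order of first frame occurrence.
Canonical-cluster assignment matches per-frame loop torsions against
reference median vectors under the mean circular distance, with a 40°
default threshold and lexicographic tie-breaking; frames beyond the
threshold are `"unassigned"`.

Loop coupling is quantified by crossing per-loop cluster labels into joint
count tables whose marginals equal the per-loop populations by
construction, scored with Cramér's V = √(χ²/(n·(min(r,c)−1))); degenerate
tables (a loop with one cluster) score 0.

## Synthetic generators (scope and parameters)

The generators provide ground truth for testing; they are not molecular
dynamics surrogates.

**Hidden-Markov torsion emitter.** The default fixture has four hidden
states with stationary weights (0.35, 0.30, 0.20, 0.15) — exact by
construction: the transition matrix is built from a symmetric exchange
matrix scaled by 5·10⁻⁴, giving eigenvalues (1, 0.98308, 0.97176,
0.95813) and a slowest relaxation of −1/ln λ₂ = 58.61 frames. Five
coupled loops emit two torsions each from von Mises distributions around
state-dependent means 90° apart, κ = 8.2 (circular standard deviation
≈ 20°, comparable to backbone torsion fluctuations within one
conformational substate); one decoupled loop (CDR-H2) switches on its own
two-state chain. Frame spacing is nominally 0.1 ns.

**Rigid mock antibody.** Region templates (one equal-mass pseudo-atom per
residue) are translated so the four interface COMs sit exactly on a
dihedral scaffold (arm 10 Å, axis 20 Å) realizing the prescribed
interface angle, and analogously for the elbow chain; prescriptions are
therefore exact to machine precision at zero noise. Optional isotropic
Gaussian coordinate noise (σ in Å), random rigid poses per frame, and
COM-preserving discrete loop conformers perturb the mock without breaking
the prescription.

**Double-well sampler.** Metropolis sampling of U(x) =
barrier·((x/a)² − 1)² with kT = 0.596 kcal/mol (300 K), wells at ±a
(a = 1 Å), proposal step 0.6 Å. `dim=2` appends an independent harmonic
coordinate (spring constant 2 kcal/mol/Å²) for 2-D surfaces with a known
1-D barrier.

## Limitations

- tICA is linear; strongly nonlinear slow coordinates are only captured
  through the microstate discretization downstream.
- The CK test uses PCCA+ crisp sets; very fuzzy macrostates would blur the
  set-to-set probabilities.
- Free-energy surfaces are raw histograms; no kernel smoothing or
  reweighting beyond optional per-frame weights.
- The mock antibody has one pseudo-atom per residue and equal masses; it
  exercises the geometry code paths, not packing or sterics.
- Pairwise RMSD matrices are O(frames²); cluster subsampled frames for
  long trajectories.
- The dihedral sign convention is anchored to the documented reference
  case and is the mirror of some other packages' convention.
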