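# abmsm

Kinetic characterization of antibody paratope states from conformational
ensembles.

Antibody binding sites are not static: the six complementarity-determining
region (CDR) loops interconvert between a handful of metastable
conformational states, and those paratope states co-vary with the relative
orientation of the heavy- and light-chain variable domains. `abmsm`
implements the full analysis pipeline for this problem:

- **Structure handling** — PDB reading/writing, multi-model trajectories,
  insertion-code-aware antibody region annotation (CDR loops, framework,
  switch regions, constant domains).
- **Featurization** — backbone φ/ψ torsions per CDR loop, sin/cos
  embedding, metadynamics-style collective variables.
- **Geometry** — a signed V<sub>H</sub>/V<sub>L</sub> interface torsion
  angle over four centers of mass, the Fab elbow angle, Kabsch
  superposition and region RMSDs.
- **Kinetics** — time-lagged independent component analysis (tICA),
  k-means microstates, reversible Markov-state models with implied
  timescales, Chapman–Kolmogorov validation, PCCA+ metastable macrostates,
  mean first-passage times, and free-energy surfaces
  ΔG = −k<sub>B</sub>T ln(p/p<sub>max</sub>).
- **Conformational clustering** — average-linkage RMSD clustering of loop
  conformations with medoid representatives, canonical-cluster assignment,
  and loop–loop co-occurrence statistics (Cramér's V).
- **Synthetic generators** — hidden-Markov torsion emitters, rigid mock
  antibodies realizing prescribed angle series exactly, and Metropolis
  double-well samplers, providing analytic ground truth for every stage.

## Worked example

Recover four metastable paratope states, their populations and kinetics
from synthetic CDR-loop torsions (ground truth: populations 0.35 / 0.30 /
0.20 / 0.15, slowest relaxation 58.6 frames):

```python
import numpy as np
import abmsm as ab

# 1. Synthetic ground truth: six CDR loops, four shared paratope states
spec = ab.default_hmm_spec(n_frames=50_000, seed=0)
sim = ab.simulate_hmm_torsions(spec)

# 2. Featurize the five coupled loops and find slow coordinates
features = ab.combine_features(
    [ab.sincos_features(sim.torsions[name]) for name in spec.coupled]
)
tica = ab.fit_tica(features, lag=5)
coords = ab.project(tica, features, n_components=3)

# 3. Microstates, Markov-state model, metastable macrostates
micro = ab.kmeans_microstates(coords, k=150, seed=0)
msm = ab.estimate_msm(ab.count_matrix(micro.dtrajs, lag=10), lag=10)
macro = ab.pcca(msm, 4)

print("macrostate probabilities:", np.round(macro.probabilities, 3))
print("slowest implied timescale: %.1f frames"
      % ab.implied_timescales(msm, n=1)[0])

# 4. Validate the model and extract kinetics
ck = ab.ck_test(micro.dtrajs, lag=10, n_macrostates=4)
print("Chapman-Kolmogorov test passed:", ck.passed)
mfpt, probs = ab.macrostate_kinetics(msm, macro)
print("MFPT state 0 -> 1: %.0f frames" % mfpt[0, 1])
```

Output:

```
macrostate probabilities: [0.331 0.293 0.216 0.16 ]
slowest implied timescale: 58.1 frames
Chapman-Kolmogorov test passed: True
MFPT state 0 -> 1: 141 frames
```

The geometric observables are exact by construction on the rigid mock
antibody:

```python
mock = ab.simulate_rigid_antibody(ab.RigidAntibodySpec(
    interface_angles=np.array([-44.5, -40.0, -36.5]),
    elbow_angles=np.array([130.0, 140.0, 150.0]),
))
print("interface:", ab.interface_angle(mock.trajectory, mock.regions).values)
print("elbow:    ", ab.elbow_angle(mock.trajectory, mock.regions).values)
```

```
interface: [-44.5 -40.  -36.5]
elbow:     [130. 140. 150.]
```

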