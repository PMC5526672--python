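# flywalk

Dynamic structure of walking behavior from body-velocity time series.

Freely walking fruit flies (and many other animals) can be tracked as a
centroid plus a body orientation on a plane. Three body-frame velocity
components — translation `vT` (cm/s), rotation `vR` (deg/s) and side-slip
`vS` (cm/s) — then describe whole-animal movement completely. `flywalk`
implements a pipeline that turns such trajectories into a quantitative
description of behavioral structure:

1. **Kinematics** — read/smooth centroid–orientation tables (CSV/HDF5) and
   derive body-frame velocities, accelerations and the heading velocity
   `vH = vR − d/dt arctan2(vS, vT)`.
2. **Phase space** — the kinematic field `E[v̇ | v⃗]` on a velocity grid, and
   the divergence statistic
   `σ̄(t) = ⟨σ_t[vT]·σ_t[vR]·σ_t[vS]⟩_NB / (σ[vT]·σ[vR]·σ[vS])`,
   the normalized spread of trajectory ensembles a time `t` after passing a
   small velocity neighborhood, with conditioning on upcoming turn peaks
   and mode identity.
3. **Segmentation** — trajectory fragments aligned on local `vR` extrema,
   sign-normalized (`c = sgn vR(0)`), standardized, whitened and decomposed
   with FastICA; whenever fragment coefficients in the independent
   components are multimodal, the data are split at the density valley and
   the procedure recurses. Leaves of the tree are *submodes*; the fitted
   tree classifies new trajectories (`FragmentSegmenter.fit/predict`).
4. **Sequence models** — history-dependence fractions
   `ρ = I(u_i; u_{i−1})/H(u)` and `ρ₂ = I(u_i; u_{i−2} | u_{i−1})/H(u_i|u_{i−1})`,
   count-based Markov chains, categorical HMMs, and *mode models* (MM):
   Markov chains over submode groups with deterministic emission support —
   `N(N−1)+N(M−1)` free parameters for an HMM versus `N(N−1)+(M−N)` for an MM.
5. **Generative validation** — the multiset match fraction
   `f = ⟨F_S:R⟩/⟨F_R:R⟩` between model-generated and real sequence samples,
   its dependence on sequence length, and the horizon `τ_P` (longest
   duration with `f ≥ 0.9`).
6. **Profiles & dwell times** — time-resolved velocity distributions per
   mode, Bhattacharyya overlap `B = Σ √(P·P′)` with a bootstrap
   significance test, and dwell-time analysis with exponential (mixture)
   fits.

A synthetic-trajectory generator (`flywalk.simulate`) renders
mode-structured velocity trajectories — a first-order Markov chain over
modes with measured default transition rates, one `vR` extremum per mode
occurrence at ~250 ms mean spacing, per-mode template curves plus noise —
so every stage can be tested against known ground truth.

## Worked example

```python
import numpy as np
import flywalk as fw
from sklearn.metrics import adjusted_rand_score

# segment 5000 planted fragments from the five default mode templates
frags, truth = fw.sample_fragments(fw.default_templates(), 5000, rng=1)
seg = fw.FragmentSegmenter(random_state=0).fit(frags)
print("submodes found:", seg.n_leaves_)
print("agreement with planted labels (ARI):",
      round(adjusted_rand_score(truth, seg.labels_), 3))

# history dependence of mode sequences under the default transition rates
seqs = fw.generate_symbol_sequences(
    fw.TABLE1_RATES, 2000, fw.simulate.geometric_lengths(8, 2), 1)
d = fw.dependence_stats(seqs, n_boot=200, rng=0)
print(f"rho = {d.rho:.3f}  rho2 = {d.rho2:.4f}")

# parameter economy of the mode model
print("free parameters, 5 states / 15 submodes:",
      fw.free_parameters(5, 15, "hmm"), "(HMM) vs",
      fw.free_parameters(5, 15, "mm"), "(MM)")

# multiset match fraction on a hand-checkable example
from flywalk.match import match_fraction_sets
frr, fsr, f = match_fraction_sets(["a","a","b"], ["a","b","b"], ["a","c","c"])
print(f"F_R:R = {frr:.3f}  F_S:R = {fsr:.3f}  f = {f:.2f}")
```

prints

```
submodes found: 5
agreement with planted labels (ARI): 1.0
rho = 0.310  rho2 = 0.0038
free parameters, 5 states / 15 submodes: 90 (HMM) vs 30 (MM)
F_R:R = 0.667  F_S:R = 0.333  f = 0.50
```

The segmentation recovers exactly the five planted movement patterns; a
first-order chain explains ~31% of the uncertainty about the next mode
while two-step history adds essentially nothing (`ρ₂ ≈ 0`), which is the
signature of limited memory between behavioral elements; and the
five-state mode model needs only a third of the parameters of the
equivalent HMM.

## Command-line pipeline

```bash
flywalk run --config pipeline.json      # stages from a JSON config
flywalk simulate --outdir out --seed 1  # or stage by stage
flywalk velocities --outdir out
flywalk segment --outdir out
```

Stages: `simulate, velocities, phasespace, diverge, segment, classify,
sequences, fit-mm, fit-hmm, match, profiles, dwell`. Every output
directory carries a `manifest.json` with the config hash and seed; reruns
with the same config and seed are bit-identical.

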