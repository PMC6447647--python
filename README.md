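# selacq

Tools for studying **selective knowledge acquisition**: why do the items we
pick up spontaneously serve later productive (even creative) use better than
items drilled into us?

The package has two coordinated halves:

1. **A mechanistic model** — a recurrent excitatory/inhibitory rate network
   (400 E / 100 I threshold-linear neurons, reciprocal E–E connectivity)
   whose E→E synapses follow the Bienenstock–Cooper–Munro (BCM) plasticity
   rule with a sliding threshold and homeostatic synaptic scaling.  New
   items are inserted as three-neuron **cell assemblies** (six zero-weight
   directed edges), and their *assimilation strength* — the mean internal
   weight after learning — is related to how correlated the assembly's
   members were with each other and with the rest of the network before
   insertion.
2. **A behavioral-statistics pipeline** for word-acquisition /
   essay-production experiments: per-subject essay-length normalization,
   recognition-confidence banding (analyzed range 50–100, lower band
   50 ≤ c ≤ 75, upper band 75 < c ≤ 100, certain = 100), Mann–Whitney /
   t comparisons with probability-of-superiority, Cohen's d and d_z effect
   sizes and percentile-bootstrap CIs, two surrogate-data tests
   (confidence–length dot product with within-subject shuffling;
   letter-reassignment among certainly-recognized words), and a
   word-embedding semantic-distance score for essays relative to the two
   component words of each novel compositional word.

Because the original subject data are not public, `selacq.synthetic`
generates behavioral datasets with controllable planted structure (or exact
nulls) and toy clustered embeddings with known geometry, so every stage of
the pipeline is testable end to end.

## Model summary

Voltages follow leaky threshold-linear rate dynamics (RK4, dt = 0.5 ms):

    τ dv_i/dt = −v_i + Σ_j w_ij F(v_j) + I_i,      F(v) = v·1[v ≥ Θ]

E→E weights follow BCM with presynaptic gating and synaptic scaling
(Euler, clamped ≥ 0, incoming sums renormalized to κ):

    τ_w dw_ij/dt = −w_ij + α φ(v_i, θ_i) σ(v_j)
    φ(v, θ) = 6.75 v²(v−θ)/θ³ + tanh(6.75(v−θ)/θ)
    θ_i ← EMA of v_i (rate γ·dt);   w_ij ← κ w_ij / Σ_k w_ik

See `docs/methods.md` for every constant, the conventions adopted where the
model statement is ambiguous, and known limitations.

## Worked example

Generate a synthetic experiment-2 dataset with a planted confidence–length
association and inflated confidence for force-presented words, then run the
full analysis:

```python
from selacq import (Experiment2Analysis, GeneratorConfig, generate_dataset)

cfg = GeneratorConfig(n_subjects=25, n_forced=2, forced_conf_boost=25.0,
                      length_effect=1.0, seed=1)
res = Experiment2Analysis(generate_dataset(cfg)).fit(n_surrogate=10_000, seed=0)
print(res.summary().to_string(index=False))
```

```
                                        analysis         test  statistic      p_value           effect     n
   certain-rating measure: forced vs spontaneous mann-whitney 560.500000 7.916263e-07         PS=0.897 25/25
     once-presented norm. length: upper vs lower mann-whitney 611.000000 3.677639e-09         PS=0.978 25/25
  norm. length upper band: spontaneous vs forced mann-whitney 451.000000 3.693443e-03         PS=0.722 25/25
norm. length certain band: spontaneous vs forced mann-whitney 280.000000 1.305841e-02         PS=0.707 18/22
             letter-reassignment (certain words)    surrogate  13.566773 9.999000e-05 null mean=11.684    23
```

Reading the table: force-presented words are recognized with certainty far
more often (PS = 0.90), yet among well-recognized words the spontaneously
memorized ones still carry longer normalized essays (PS = 0.72, one-sided
p ≈ 0.004), and the letter-reassignment statistic (13.57 of a theoretical
maximum of 23 subjects) sits in the extreme upper tail of its null
(p ≈ 1e-4) — the planted structure, recovered.

The simulation side is driven the same way:

```python
from selacq import SimParams
from selacq.assembly import AssimilationExperiment

exp = AssimilationExperiment(SimParams(), n_assemblies=100, n_topologies=1)
print(exp.run(seed=1).summary())     # Pearson r of weight vs correlations
```

A command-line interface mirrors these steps
(`selacq generate | simulate | assimilate | analyze-exp1 | analyze-exp2 |
semantic-score`); run `selacq --help`.

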