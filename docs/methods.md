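# Methods

This note documents the models, statistics and generators the package
implements, the parameter conventions it adopts where the underlying model
description is under-determined, and what the synthetic-data tests do and do
not establish.

## 1. The plastic E/I rate network

### Dynamics

The network has `n_ex` excitatory and `n_inh` inhibitory threshold-linear
rate neurons.  Voltages follow

    tau_ex  dv_ex,i/dt  = -v_ex,i + sum_j w_ee[i,j] F(v_ex,j)
                           + sum_j w_ei[i,j] F(v_inh,j) + I_ex,i
    tau_inh dv_inh,i/dt = -v_inh,i + sum_j w_ie[i,j] F(v_ex,j) + I_inh,i

with the threshold-linear activation `F(v) = v` for `v >= Θ`, else 0.
Voltages are integrated with classical fourth-order Runge-Kutta at step
`dt`; the per-neuron noise currents `I` are drawn once per step (Gaussian)
and held constant across the four RK4 stages.

E→E connectivity is reciprocal: `round(p_ee·n_ex(n_ex−1)/2)` unordered pairs
are drawn uniformly without replacement and both directed edges created, so
the adjacency matrix is symmetric (the weight matrix is not, since each
direction evolves independently).  E→I and I→E edges are independent
Bernoulli draws; their weights are fixed scalars (`w_ie_fixed = 0.2`,
`w_ei_fixed = −0.025`; inhibition enters as a negative weight on a positive
rate).

Only E→E weights are plastic.  They follow the BCM rule with a presynaptic
sigmoid gate, integrated with the Euler method (the weight timescale
`tau_w = 1000 ms` is 50× slower than the voltage timescale, which is what
justifies the cheaper integrator):

    tau_w dw[i,j]/dt = -w[i,j] + alpha * phi(v_i, theta_i) * sigma(v_j)
    phi(v, theta) = 6.75 v^2 (v - theta)/theta^3 + tanh(6.75 (v - theta)/theta)
    sigma(v) = 1 / (1 + exp(-beta (v - Θ)))        [default convention]

`phi` is the BCM curve: negative (depression) for `0 < v < theta`, positive
(potentiation) above `theta`.  The sliding threshold `theta` is a running
average of the postsynaptic voltage, updated each step as an EMA with rate
`gamma·dt`; under stationary dynamics it converges to the temporal mean
voltage.  After each Euler step weights are clamped non-negative (they are
excitatory synapses; clamping also prevents sign flips from Euler
overshoot) and synaptic scaling renormalizes each neuron's incoming plastic
weights multiplicatively to total `kappa`:

    w[i,j] <- kappa * w[i,j] / sum_k w[i,k]

Scaling is the homeostatic brake that prevents the Hebbian positive feedback
loop (potentiation → more activity → more potentiation) from diverging.
Rows whose incoming sum is non-positive are skipped that step and counted.

### Reference parameters

| parameter | value | meaning |
|---|---|---|
| n_ex, n_inh | 400, 100 | population sizes |
| p_ee, p_ei, p_ie | 0.2 | connection probabilities |
| tau_ex, tau_inh | 20 ms | voltage time constants |
| tau_w | 1000 ms | weight time constant |
| Θ | 1.0 | activation threshold |
| alpha | 0.1 | BCM gain |
| beta | 5.0 | presynaptic sigmoid slope |
| kappa | 0.5 | incoming-weight sum after scaling |
| dt | 0.5 ms | integration step |
| w_ei, w_ie | −0.025, 0.2 | fixed cross-population weights |
| I_ex | N(1.0, 0.5) | excitatory noise current, per step |
| I_inh | N(0.0, 0.5) | inhibitory noise current, per step |
| gamma | 0.001 /ms | sliding-threshold averaging rate |

### Conventions chosen where the model statement is ambiguous

These points are not fixed by the reference parameter set and are exposed in
`SimParams`; the defaults are the package's choices.

* **Sigmoid argument.**  `sigma` defaults to the standard logistic centered
  at the activation threshold, `beta·(v − Θ)`, so that `sigma(Θ) = 0.5`; a
  literal transcription variant `beta·v + Θ` is selectable
  (`sigma_convention="literal"`).
* **gamma.**  No printed value exists.  Default 0.001/ms (≈1 s averaging
  window): slow relative to the voltage dynamics, as required for the
  threshold to act as a temporal mean, and of the same order as `tau_w`.
* **Threshold bias correction.**  The EMA is used as-is by default
  (initialized at Θ); an optional startup bias correction
  `theta = theta_hat / (1 − (1 − gamma·dt)^k)` is available.  Both have the
  same stationary limit.
* **Noise integration.**  The printed sd is used per step by default; a
  white-noise scaling flag multiplies it by `sqrt(tau/dt)`.  The per-step
  reading was kept as default because the white-scaled variant drowns the
  recurrent interactions in private noise and visibly decorrelates the
  population (measured mean pairwise correlation drops by ~5×).
* **Initial conditions.**  `v = 0`, `theta_hat = Θ`, plastic weights uniform
  at `kappa/indegree` so scaling is consistent from the first step.
* **Cadence.**  Voltages, threshold, weights and scaling all update every
  `dt` step, in that order.  A `scaling_every` knob relaxes the scaling
  cadence; cadences much slower than ~0.1 s destabilize the Hebbian
  positive feedback (the run diverges), so near-continuous scaling is not
  just a convention but a stability requirement at these parameters.
* **Degenerate scaling.**  Rows with non-positive incoming sums are skipped
  and counted rather than divided.

## 2. Cell-assembly assimilation experiment

A new item is encoded as a three-neuron cell assembly: at insertion time all
six directed connections among three excitatory neurons are created with
weight zero (existing connections keep their weights; insertion is
idempotent and preserves reciprocity).  The full protocol runs the network
to 50,000 ms (stationary state), inserts 100 assemblies with uniformly
random (possibly overlapping) member triplets, and stops at 90,000 ms.

Per assembly the driver measures

* **assimilation strength** — the mean of the six internal weights averaged
  over 70,000–90,000 ms;
* **mean within-assembly correlation** — mean Pearson correlation of the
  three member pairs' activity over 30,000–50,000 ms (pre-insertion);
* **mean assembly-network correlation** — mean Pearson correlation between
  each member and every non-member excitatory neuron over the same window.

Across assemblies, Pearson r and p are reported for assimilation strength
against each correlation measure; the experiment repeats over independent
random topologies, one summary row per topology.

Choices made here: all 100 assemblies share one run per topology (the
correlation predictors are measured before insertion, so they are unaffected
by sharing; a sequential one-run-per-assembly mode exists).  Correlations
are computed on the raw voltage `v` by default (`correlate="rate"` switches
to `F(v)`).  Zero-variance traces are excluded pairwise and counted.
Within-assembly correlation uses the 3 unordered pairs; assimilation
strength uses the 6 directed weights, since weights are directional and
correlations are not.

Known limitation: at the reference parameters this network's per-pair
activity correlations are small (sd ≈ 0.03 across assemblies) and of the
same order as their estimation noise from a 20-s window, so the
across-assembly Pearson r values are substantially attenuated and vary
between topologies and seeds.  In our runs the within-assembly relationship
is reliably positive and significant (r ≈ 0.3–0.6) while the
assembly-to-network relationship is weak and seed-dependent (r ≈ −0.3 to
+0.1 at the defaults).  The alternative conventions exposed in `SimParams`
(sigma convention, noise scaling, `gamma`, scaling cadence, rate-based
correlations) change these numbers but none makes the assembly-to-network
correlation robustly positive; a much slower threshold average combined
with rate correlations can produce strongly positive values on some
topologies and negative ones on others.

## 3. Behavioral statistics

Essay lengths are normalized within subject (each subject's lengths sum
to 1), cancelling baseline-productivity differences.  Confidence bands
follow the printed boundaries exactly: analyzed range `50 ≤ c ≤ 100`
(ratings below 50 express confidence of *absence*), lower band
`50 ≤ c ≤ 75`, upper band `75 < c ≤ 100`, certain `c = 100`.  Subjects
without qualifying words for a given analysis are dropped from that analysis
only, and per-subject aggregation (mean normalized length per band) precedes
every group test, so test sample sizes are subject counts.

Group comparisons: Mann–Whitney U (one-sided unless stated) with the
probability of superiority `PS = P(A>B) + ½P(A=B)` as effect size — with the
half-tie rule PS equals `U/(n_a·n_b)` exactly; independent and paired t
with Cohen's d and d_z.  Percentile-bootstrap CIs (default 10,000
resamples, seeded) accompany each group's median (U test) or mean (t
tests).  A paired comparison with zero-variance differences is flagged
degenerate rather than given a fabricated p.

### Surrogate tests

**Dot-product test (confidence–length association).**  Per subject, the
confidence and length vectors over the analyzed words are L2-unitized
("unitized" must mean L2: only then is each subject's maximal contribution
exactly 1, making the statistic's theoretical maximum the number of
subjects).  The statistic sums the per-subject dot products; the null
shuffles each subject's length components; p is upper-tail with the
`(k+1)/(n+1)` correction.  The test is exactly calibrated whenever lengths
are exchangeable within subject given the confidences — e.g. under the
generator's `length_effect = 0` null.

**Letter-reassignment test (spontaneous vs forced among certain words).**
Only words rated exactly 100 participate.  Lengths are renormalized within
subject over those words; the statistic sums the normalized lengths of the
*spontaneously* memorized certain words.  The null redistributes each
subject's total letters uniformly (multinomial) over its certain words.
This null asserts exchangeability of individual letters, which is *much*
tighter than the variability of whole essay lengths: under a data-generating
process with independent log-normal lengths the test is strongly
anticonservative (measured rejection ≈0.5 at α=0.05).  It is exactly
calibrated under its own null model, which
`selacq.synthetic.reassign_letters_null` samples; the calibration tests use
that generator.  Users should treat small p-values from this test as
evidence against *letter-level* exchangeability only.

**Certain-proportion comparison.**  Per-subject proportions of
certain-rated words are compared between conditions (two-sided U test; a
raw-count mode exists because the corresponding published medians exceed 1,
suggesting counts).  Note the two groups aggregate over very different word
counts (2 forced vs 18 spontaneous), so the proportions differ in
granularity and variance; the U test can therefore discriminate them even
when the mean proportions are equal.  Permutation checks on this analysis
should target the mean difference, not the U p-value.

## 4. Semantic distance

Each compositional word has two component words.  An essay's semantic score
is the mean over its tokens of the larger cosine similarity to the two
components; tokens equal to a component are excluded, out-of-vocabulary
tokens skipped and counted, duplicate tokens scored per occurrence.  A lower
score means a larger creative leap away from the components.  Tokenization
is an injected dependency — essays arrive pre-tokenized; the package bundles
no morphological analyzer.  Embeddings load from word2vec text format;
cosine similarity makes any uniform vector rescaling irrelevant.

Group comparisons of scores use one-sided t tests (paired within subject
across confidence bands; independent between presentation conditions, for
the case where too few subjects have scores in both conditions).

## 5. Synthetic data generator

The generator emulates the experiments' data structure (the original subject
data are not public): per subject, `n_words = 20` words, `n_forced` of them
presented five times; latent per-word salience ~ N(0,1); confidence a
rounded clipped Gaussian `conf_mid + conf_effect·salience + noise
(+ forced_conf_boost)`; essay selection Bernoulli with logit
`logit(selection_rate) + length_effect·salience`; selected lengths
log-normal with log-location shifted by `length_effect·salience`.  With
`length_effect = 0` selection and length are independent of salience (and
hence of confidence), giving the exact null of the confidence–length tests;
with `forced_conf_boost = 0` condition labels carry no signal.

Defaults: 30 subjects, `conf_mid = 75`, `conf_effect = 15`,
`conf_noise_sd = 10` — chosen so that roughly 10–15% of once-presented words
hit the certainty rating 100, matching the published per-subject medians of
certain-rating proportions; `selection_rate = 0.4` (subjects write essays
for a minority of words); `total_letters_mean = 1000` characters per
subject.  The distribution families (truncated Gaussian confidence,
log-normal lengths) are generator choices, not claims about the original
data.

The toy embedding places cluster centroids exactly orthonormal (QR) and
token vectors at unit-normalized centroid-plus-noise with the noise scale
solved from the target intra-cluster cosine (`E[cos] ≈ 1/(1+s²) = w`).
Essays mix tokens from the word's own component cluster (probability
`1 − semantic_leap`) and other clusters, so the expected essay score
decreases strictly in `semantic_leap`.

What passing tests show — and what they do not: calibration and power
results establish that the pipeline recovers planted effects and holds its
nominal error rate *under this generator's assumptions* (independent
subjects, monotone salience→confidence link, log-normal lengths).  Real
essay data involve word-by-word dependence, subject-specific strategies and
tokenizer noise that the generator does not model; the tests validate the
statistical machinery, not the psychology.

## 6. Numerical notes

* RK4 at dt = 0.5 ms reproduces the single-neuron closed form to <1e-8 at
  100 ms and shows the expected ~dt⁴ error scaling.
* Synaptic scaling conserves incoming sums to within 1e-10 per step.
* The BCM threshold entering `phi` is floored at 1e-6 inside the simulator
  (the `1/theta³` term diverges as `theta → 0+`); the floor never binds at
  reference parameters.
* Surrogate p-values use `(k+1)/(n+1)` so p > 0 always.
* All stochastic components (topology, noise, assembly selection, bootstrap,
  surrogates, generators) are driven by seeded numpy Generators; identical
  seeds give bit-identical results.

## 7. Problem sizes used in the test suite

The test suite runs the assimilation protocol at half timeline (insertion
at 25 s, stop at 45 s, windows 15–25 s and 35–45 s) with 50 assemblies on
one topology, and the behavioral calibrations at 500 null datasets
(n_surrogate = 1000) and 200 planted-effect replicates.  The full printed
protocol (50/90 s, 100 assemblies) runs in `scripts/acceptance.py`.
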