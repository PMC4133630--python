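# dpbtn — dynamic probabilistic Boolean threshold networks

Bayesian inference of signed, weighted, possibly cyclic signaling networks
from *short* time-course measurements (two or three time points) collected
after a *large* number of perturbations — the data layout produced by
systematic RNAi knockdown or overexpression screens with protein-array
readouts.  The package is for computational biologists who want full
posterior distributions over network topologies (not a single point
estimate), including feedback loops, which steady-state methods cannot
resolve.

## Model

Each protein v_i is a Boolean variable updated synchronously in discrete
model time; the network is a weighted adjacency matrix W (w_ij > 0
activation, w_ij < 0 inhibition).  Activation is a stochastic threshold
rule,

    P(v_i(t+1) = 1 | v(t)) = σ(γ (w0_i + Σ_j w_ji v_j(t))),

with basal weights w0_i ≤ 0 and stochasticity γ.  Knockdowns clamp nodes to
0, overexpression to 1.  An integer vector τ maps the real measurement
times to model steps; unobserved intermediate steps and missing values are
marginalized in the likelihood by forward simulation.  Priors: an L_q
kernel exp(−Σ(|w_ij − μ_ij|/s)^q) on the weights (sparsity at q = 1, prior
knowledge through μ), negative-gamma on w0, binomial on τ.  The posterior
over Ω = (W, w0, τ) is sampled with an evolutionary population MCMC scheme
(mutation, crossover, migration between subpopulations, each move
Metropolis–Hastings-corrected), then summarized by per-edge posterior
medians, density-based clusters of alternative topologies, and ROC/PR
curves against a gold standard when one exists.

## Worked example

Generate the built-in 7-node knockdown benchmark (9 experiments: all single
knockdowns plus the combinations (3,4) and (4,6), two measurement times),
fit the posterior, and compare the inferred edges to the generating
network:

```python
import numpy as np
from dpbtn import simulate, ThresholdNetworkModel, SamplerConfig

rng = np.random.default_rng(1)
lab = simulate.generate_sn1_data(rng)          # dataset + gold standard
model = ThresholdNetworkModel(lab.dataset)
res = model.fit(SamplerConfig(seed=1))         # 2e4 proposal steps, 3x4 chains
print(res.summary(top=10))
ev = res.evaluate(lab.gold)
print(f"AUC_ROC = {ev.auc_roc:.3f}, AUC_PR = {ev.auc_pr:.3f}")
```

Output:

```
Dynamic probabilistic Boolean threshold network - posterior summary
====================================================================
nodes: 7    experiments: 9    time points: 2
posterior draws: 2148 (12 chains)
acceptance rate: 0.347    PSRF(log posterior): 1.007
median tau: [6.0]

top 10 edges by posterior support (median weight [IQR], support fraction):
    1 -> 3     +2.340 [+1.410, +3.154]  support 0.99  activation
    3 -> 5     +2.335 [+1.680, +2.990]  support 0.99  activation
    1 -> 7     +1.905 [+1.331, +2.830]  support 0.98  activation
    1 -> 2     +2.154 [+0.940, +2.712]  support 0.98  activation
    5 -> 6     +1.227 [+0.441, +3.330]  support 0.97  activation
    2 -> 3     +0.824 [+0.186, +1.335]  support 0.95  activation
    7 -> 2     +0.826 [+0.030, +1.854]  support 0.95  activation
    4 -> 5     +0.914 [+0.286, +1.301]  support 0.94  activation
    3 -> 6     +0.230 [-0.393, +1.046]  support 0.94  activation
    2 -> 4     +1.574 [+0.721, +2.750]  support 0.94  activation

AUC_ROC = 0.945, AUC_PR = 0.818
```

Reading it: the sampler ran 12 chains in 3 subpopulations and kept 2148
thinned post-burn-in draws; τ concentrates on the true 6 model steps
between the two measurements.  Six of the eight true edges (1→2, 1→3, 2→4,
3→5, 4→5, 5→6) appear in the top ten by posterior support with large
positive medians; ranking *all* 42 candidate edges by |median| against the
generating topology gives AUC_ROC 0.945.  A desk-scale run like this takes
roughly 15 s; posterior quantiles sharpen with more proposal steps
(`SamplerConfig(n_steps=...)`).

The same workflow is available from the shell:

```sh
dpbtn simulate --protocol sn1 --seed 3 --out data/
dpbtn infer --observations data/observations.tsv --design data/design.tsv \
    --n-nodes 7 --seed 1 --trace trace.tsv
dpbtn aggregate --trace trace.tsv --out clusters/
dpbtn evaluate --trace trace.tsv --gold data/gold.tsv --out eval/
```

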