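# netpsych

Regularized partial-correlation network analysis of ordinal mental-health
survey items — the standard network-psychometrics pipeline (Spearman
correlations → graphical lasso with EBIC selection → centrality and
predictability → bootstrap stability → permutation-based two-group
comparison → walktrap communities with bridge centrality), implemented as a
tested Python library and exercised end-to-end on synthetic data with known
ground truth.

It is written for researchers analyzing symptom-level survey data — e.g.
depression (PHQ-9), anxiety (GAD-7) and acute stress (IES-6) items together
with stressor ratings and perceived social support — who want each stage of
the pipeline as an importable, seeded, unit-tested function rather than a
monolithic script.

## The model

Item responses are modeled as discretized margins of a latent Gaussian
vector. The estimated object is a Gaussian graphical model: a sparse
precision matrix **K** whose off-diagonal entries give partial correlations

    rho_ij = -K_ij / sqrt(K_ii K_jj),

the association between two items controlling for all others. Estimation
maximizes the L1-penalized Gaussian log-likelihood over a 100-point penalty
path (diagonal unpenalized) and selects the penalty minimizing the extended
BIC,

    EBIC = -2 L + E log n + 4 E gamma log p,   gamma = 0.5,

with E the number of retained edges. Downstream inference covers:

* **expected influence** `EI_i = sum_j w_ij` and its bridge variant over
  community boundaries;
* **predictability**: the share of each node's variance explained by its
  estimated neighbors;
* **stability**: nonparametric-bootstrap edge CIs and the case-dropping
  CS-coefficient (>= 0.5 indicates good stability);
* **two-group comparison**: a permutation test of global-strength
  invariance (S) and network-structure invariance (M), with Holm-corrected
  per-edge tests;
* **communities**: walktrap over the weighted network with
  modularity-selected cut.

Because raw survey data of this kind are rarely shareable, the package
ships a first-class synthetic-data module: sparse ground-truth networks
with scale-aligned communities, ordinal discretization by thresholds, and a
two-group variant in which one group's network is uniformly stronger — so
recovery, test validity and power are all checkable against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
3,000-respondent, 28-node dataset (9 PHQ + 7 GAD + 6 IES items, four
collapsed stressor nodes, two support nodes; group 1's generating network
is 1.3x stronger):

```sh
python analysis/01_simulate_study_data.py
python analysis/02_estimate_network.py
python analysis/03_centrality_predictability.py
python analysis/04_stability.py
python analysis/05_compare_groups.py
python analysis/06_communities.py
```

Selected output:

```
selected lambda=0.0444 (118 of 378 possible edges)
10 negative edges; strongest negative:
node_i node_j  weight
  PHQ9   SSFm  -0.084
  PHQ9   SSFr  -0.042
...
CS-coefficient (expected influence) = 0.75 (good stability)
global strength: group1=9.80, group0=6.63; S=3.16 (p=0.002)
overall: 5 communities (Q=0.56, ARI vs planted scales=0.94)
```

Reading this: the EBIC-selected network keeps 118 of 378 possible edges;
the planted negative edge from family support (SSFm) to suicidal ideation
(PHQ9) is recovered as the strongest negative association; expected
influence survives dropping 75% of cases (CS = 0.75, above the 0.5 bar);
the permutation test detects the stronger group's larger global strength
(S = 3.16, p = 0.002); and walktrap recovers communities closely aligned
with the generating symptom scales (ARI = 0.94).

The same computations are available directly from the library, e.g.

```python
from netpsych import make_study_fixture, estimate_network, walktrap

table, truth = make_study_fixture(seed=7, group_sizes=(1500, 1500))
net, path = estimate_network(table.values)   # Spearman -> EBIC-glasso
part = walktrap(net)                         # deterministic communities
```

or as one call: `netpsych.run_full_analysis(AnalysisConfig(...))`, which
writes every artifact plus a manifest that reproduces the run bit-for-bit.

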