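# conect

Geometry-aware network analysis of EEG time series for dementia-subtype
classification research.

`conect` turns a single-channel EEG segment into a directed weighted
graph, summarizes that graph with 15 topological and geometric features,
selects discriminative feature subsets with an ant-colony wrapper, and
evaluates classifiers under leakage-safe, subject-grouped protocols. It
is aimed at researchers studying graph representations of
electrophysiological signals (AD / FTD / HC contrasts in particular) who
want a fully seeded, testable pipeline that runs end-to-end on synthetic
data before touching any clinical recording.

## The model

Each sample of a segment x₀ … x_{n−1} is a node. With chord angles
θ_ab = arctan((x_b − x_a)/(b − a)), an edge i → j (j > i) exists iff

  θ_ik < θ_ij  for every intermediate k,

i.e. iff every intermediate sample lies strictly below the chord from
(i, x_i) to (j, x_j). Adjacent samples always connect, so the graph is a
connected DAG oriented along time. Edges are weighted by

  w_ij = α·|x_j − x_i| + β/(j − i) + γ·|θ_ij|,  (α, β, γ) = (0.5, 0.3, 0.2),

combining amplitude difference, temporal proximity and chord angle.
From the resulting network, 13 classical descriptors (edge count,
weight-distribution moments, Gini index, global efficiency, modularity,
degrees, betweenness, node strength, path length) are joined by two
geometric indices:

* **WAII** — mean over nodes of the coefficient of variation of each
  node's *outgoing* edge weights (local irregularity; the only
  direction-sensitive feature of the set);
* **CBEFI** — mean over edges of |x_j − 2x_k + x_i| / (j − i)² with k
  the integer midpoint (local curvature along edges).

Feature subsets of size 4–8 are selected by ant-colony optimization
(pheromone-proportional sampling, evaporation 0.1, iteration-best
deposit) with cross-validated Random Forest accuracy as fitness, and
classifiers (Random Forest, AdaBoost, bagged trees, k-NN, RBF-SVM) are
evaluated with subject-grouped splits so no identity leaks across the
train/test boundary. See `docs/methods.md` for conventions and design
choices.

## Worked example

The printed 10-value series from a real EEG trace:

```python
import numpy as np
from conect import build_network, feature_vector

x = [156.20, 161.28, 160.55, 161.87, 163.43, 175.29, 169.43,
     161.67, 157.32, 162.65]
net = build_network(np.array(x))
print(net.n_edges)
fv = feature_vector(net)
print(round(fv[3], 6), round(fv[14], 6), round(fv[15], 6))
```

prints

```
19
3.695851 0.379344 2.879002
```

— the series maps to a 10-node network with 19 directed edges, mean edge
weight ≈ 3.70 (dominated by the amplitude term on this µV-scale series),
WAII ≈ 0.379 (outgoing weights vary by ~38% of their mean at a typical
node) and CBEFI ≈ 2.88 (strong local curvature around the 175.29 peak).

A full synthetic run from the shell:

```bash
conect synth --profile easy3 --subjects 10 --channels 2 \
             --samples 2000 --seed 1 --out cohort/
conect extract --data cohort/ --out features.csv
conect run --features features.csv --task AD_FTD_HC --seed 1 \
           --report report.json
```

The easy cohort's three classes (slowed-and-smoothed "AD", transient-rich
"FTD", mixed-rhythm "HC") are separable: the multiclass Random Forest
report typically shows accuracy ≥ 0.9 on the held-out subjects.

## Layout

```
src/conect/
  signal_io.py           CSV/EDF/EEGLAB-SET readers, windowing
  synthetic_data.py      labeled synthetic cohorts (easy + geometry)
  arc_network.py         edge rule, weights, network construction
  graph_features.py      the 15-feature vector
  aco_selection.py       ant-colony wrapper selection
  classification_eval.py splits, metrics, experiments, ablation, CV grid
  cli.py                 `conect` command-line interface
tests/                   pytest suite (unit, property, acceptance)
scripts/acceptance.py    end-to-end reproduction script
docs/methods.md          model conventions, cohort design, limitations
```

## Scope

The package implements the analysis pipeline and a synthetic test
harness. It does not download or bundle any clinical dataset, does not
preprocess EEG (no filtering, ICA or artifact rejection — windows are
cut from raw samples), and does not re-implement comparison feature
selectors such as ReliefF or Boruta.
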