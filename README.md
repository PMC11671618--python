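# autoppi

Process-specific protein–protein interaction (PPI) discovery by
genomic-evidence integration and consensus classification, with dense
network-module extraction — the kind of pipeline used to map, e.g., the
autophagy interactome of a tumour type from public expression and
annotation resources.

## The problem and the method

Experimental interactome maps are sparse and rarely specific to a
disease context or a biological process. `autoppi` predicts new
interactions for a chosen process (say, proteins annotated to GO terms
containing *autophagy*) from four independent genomic evidence features
computed for every protein pair (a, b):

| feature | definition | intuition |
|---|---|---|
| co-expression | Pearson r of the two genes' expression profiles | interacting proteins are co-regulated |
| minimal GO annotation | member count of the smallest GO term annotating both | sharing a *specific* term is strong evidence |
| minimal KEGG pathway | same construction on KEGG pathways | shared specific pathway membership |
| diversity of functions | \|GO(a)\| + \|GO(b)\| | functional breadth of the pair |

Training labels come from a **gold standard**: positives are merged,
de-duplicated curated interactions; negatives follow the
localization-incompatibility rule (a plasma-membrane protein and a
nuclear protein are assumed not to interact; dual-localized proteins are
excluded from the rule).

Features are discretized by equal-frequency binning with a dedicated
missing-value bin, scored by a one-way ANOVA F filter, and fed to three
classifiers — categorical naive Bayes with Laplace smoothing, a
CART/Gini decision tree, and z-standardized Euclidean k-NN — trained
under a 7:3 stratified split with 10-fold cross-validation. A model is
*accepted* only if both training and testing misclassification (at score
0.5) are ≤ 0.15. Candidate pairs are scored by every accepted model at
its max-F1 operating threshold; the **consensus** is the strict
intersection of the per-model positive sets minus already-known
interactions. The consensus network is then mined for hubs (degree
ranking) and dense modules with an MCODE-style algorithm (vertex weight
= k·density of the densest core of the closed neighborhood, seeded
expansion with node score cutoff 0.2, haircut, 2-core requirement).

Because real interaction databases cannot ship with a package, `autoppi`
includes a first-class synthetic-data generator with known ground truth
at two levels: feature tables with stated class-conditional
distributions (enabling exact Bayes-oracle tests, e.g. AUC = Φ(Δμ/σ√2)
for a Gaussian feature) and full protein universes with planted
interaction complexes whose expected co-expression follows the factor
model r = λ²/(λ²+σ²).

## Worked example

Run the packaged benchmark (synthetic universe, 500 proteins, 250
planted interactions of which 30% are hidden among the candidates):

```python
from autoppi import run_fixture

report = run_fixture(seed=1, work_dir="demo")
for name, m in report["models"].items():
    print(name, round(m["training_error"], 3), round(m["testing_error"], 3),
          round(m["auc"], 3), m["accepted"])
print(report["counts"]["novel_consensus"], report["recovery"])
```

prints

```
NB 0.057 0.085 0.991 True
DT 0.041 0.094 0.966 True
KNN 0.033 0.047 0.986 True
79 {'precision': 0.8734177215189873, 'recall': 0.92, 'n_predicted': 79, 'n_recoverable': 75}
```

All three models clear the 0.15 error ceiling; the strict consensus of
their calls recovers 92% of the hidden planted interactions at 87%
precision, and `demo/run/` contains the gold standard, feature scores,
serialized models, ROC/PR plots, the consensus pair list with per-model
scores, Cytoscape-ready SIF/GraphML/edge-list exports, a hub table and
ranked modules (`run_report.json` summarises everything).

The same workflow is scriptable from the shell:

```sh
autoppi generate --seed 1 --out-dir demo/universe
autoppi init-config --out demo/run.cfg     # edit paths, then:
autoppi run-all --config demo/run.cfg
```

with further subcommands (`build-gold`, `featurize`, `train`,
`evaluate`, `predict`, `consensus`, `network`) exposing each stage.

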