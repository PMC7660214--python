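# popgse — population-graph spectral ensembles

`popgse` classifies subjects as patients or controls from resting-state
functional connectivity (RSFC) and categorical phenotypes by combining many
*population graphs* — graphs whose nodes are subjects and whose edges
weight inter-subject similarity — through graph signal processing and a
learnable neural ensemble.  It is aimed at researchers working with
connectome cohorts (e.g. autism-spectrum classification from multi-site
resting-state fMRI) who want a systematic alternative to hand-picking one
graph definition.

## Method

Each subject's feature vector x_i is the strict lower triangle of its
r × r connectivity matrix (d = r(r−1)/2).  A family of 18 graphs is built
from one edge-weight rule and its ablations,

    W(i, j) = sim(x_i, x_j) · Σ_h 1[M_h(v_i) = M_h(v_j)],

with sim a Gaussian kernel of correlation distance and M_h ranging over
subsets of {site, sex, age group}: one connectivity-only graph, seven
phenotype-only graphs, seven combined graphs, and fully-connected /
identity / random baselines.  For each graph the combinatorial Laplacian
L = D − A is eigendecomposed (L = U Λ Uᵀ) and the features are ideally
low-pass filtered, x̃ = U_k U_kᵀ x.  Sweeping the cutoff k under
cross-validation categorizes each graph as **low-frequency** (accuracy
saturates within the first 20% of the spectrum) or high-frequency; only
low-frequency graphs are kept.  Each kept graph trains a 512/64 rectifier
*learning block* on its filtered features, and a softmax gate
α = softmax(w) fuses the 64-dim block representations,

    H = Σ_i α_i p_i ,   ŷ = sigmoid(H W + b),

trained end-to-end with cross-entropy under stratified k-fold
cross-validation.  See `docs/methods.md` for assumptions, parameter
defaults and limitations.

## Worked example

Run the whole pipeline on a built-in synthetic cohort (120 subjects,
12 regions, strong planted class signal, three sites):

```python
import popgse as pg

config = {
    "cohort": {"simulate": {
        "n_patients": 60, "n_controls": 60, "r": 12,
        "effect_size": 1.5, "signal_fraction": 0.4, "noise_sd": 0.15,
        "n_sites": 3, "sex_imbalance": 0.6, "age_range": [6, 28],
    }},
    "curves": {"epochs": 20, "n_folds": 2},
    "ensemble": {"epochs": 50},
    "evaluation": {"n_folds": 5, "seed": 0},
}
bundle = pg.run_experiment(config, out_dir="demo", seed=0)
print(bundle["selected_graphs"])
print(bundle["metrics"]["accuracy"], bundle["metrics"]["auc"])
```

This prints the eight selected low-frequency graphs and the out-of-fold
metrics:

```
['sim_RSFC', 'sim_RSFC_site', 'sim_RSFC_sex', 'sim_RSFC_age',
 'sim_RSFC_site_sex', 'sim_RSFC_site_age', 'sim_RSFC_sex_age',
 'sim_RSFC_site_sex_age']
accuracy 1.000  auc 1.000  sensitivity 1.000  specificity 1.000  f 1.000
```

Exactly the eight connectivity-bearing graphs qualify as low-frequency —
the phenotype-only and baseline graphs need the full spectrum — and on
this deliberately well-separated cohort the ensemble classifies perfectly
(per-fold accuracy 1.000 ± 0.000).  The fitted gate spreads almost
uniformly (α between 0.117 and 0.128 across the eight blocks), as expected
when every block is informative.  `demo/` receives `predictions.csv`,
`gates.csv`, `metrics.json` and a provenance manifest.  Under harder
conditions the numbers are no longer at ceiling: with noise of the full
feature scale injected into the default 300-subject cohort, the gated
ensemble reaches about 91% out-of-fold accuracy and the best filter cutoff
falls below the full spectrum (see the reproduction script below).

The same pipeline is available from the shell:

```bash
popgse run --config config.yaml --seed 0 --out-dir out/
popgse simulate / build-graphs / spectrum / curves / select / sweep-k / evaluate ...
```

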