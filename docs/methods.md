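# Methods

## Problem setting

The package targets binary disease classification (patient vs control) from
resting-state functional connectivity (RSFC) together with categorical
phenotypes.  Each subject i carries a symmetric r x r correlation matrix
between brain regions; its strict lower triangle, traversed row-major over
pairs (p, q) with p > q, is the subject's feature vector
x_i ∈ R^d, d = r(r-1)/2.  Subjects are nodes of a *population graph* whose
edge weights encode inter-subject similarity:

    W(i, j) = sim(x_i, x_j) · Σ_h 1[M_h(v_i) = M_h(v_j)]

where M_h ranges over a chosen subset of {site, sex, age group}.  Dropping
the phenotype factor gives the connectivity-only graph (`sim_RSFC`);
dropping the kernel gives seven phenotype-only graphs (integer match-count
weights); keeping both gives seven combined graphs; three baselines
(fully connected, identity/edgeless, random binary) complete the family of
18 variants.

`sim` is concretized as a Gaussian kernel of the correlation distance,
sim(x_i, x_j) = exp(-ρ²/(2σ²)) with ρ = 1 − Pearson(x_i, x_j).  σ defaults
to the mean off-diagonal correlation distance of the cohort, which keeps
weights in (0, 1] and adapts the kernel bandwidth to the observed spread;
no thresholding or sparsification is applied, so similarity graphs are
fully connected and weighted.  A constant feature vector has undefined
correlation; its similarity is defined as 0.  A missing phenotype value
matches nothing (indicator 0), which is conservative: it removes rather
than invents edges.  Age is compared after binning; default bins are
consecutive 5-year intervals spanning the observed range.

## Graph-spectral analysis

For each graph the combinatorial Laplacian L = D − A (degree matrix minus
adjacency) is eigendecomposed, L = U Λ Uᵀ, with eigenvalues sorted
non-decreasing.  Eigenvalues act as graph frequencies: the graph Fourier
transform of a node signal is x̂ = Uᵀx, and ideal low-pass filtering keeps
the first k modes, x̃ = U_k U_kᵀ x — an orthogonal projection (idempotent,
norm non-increasing, exact at k = n).  The combinatorial (unnormalized)
Laplacian is the default; a symmetric normalized variant exists behind a
flag but is never used by the pipeline.

Numerical conventions: eigenvectors within numerically tied eigenvalues
keep the solver's stable order, and each eigenvector's sign is fixed so its
largest-magnitude entry is positive, making bases reproducible.  The
edgeless identity baseline has L = 0 (self-loops carry no Laplacian
weight); its eigendecomposition degenerates to the coordinate basis with
all eigenvalues 0, which keeps filtering well-defined — and makes the graph
maximally non-smooth for any non-trivial signal, as expected of a
disconnected baseline.  A configured cutoff larger than the cohort size is
clamped to k = n.

A graph is categorized **low-frequency** for the classification task when
the best cross-validated accuracy restricted to cutoffs k ≤ 0.2 n comes
within a 0.01 margin of the best accuracy over the whole grid (which must
include k = n); otherwise **high-frequency**.  The 20% fraction mirrors
treating the leading fifth of the spectrum as "low", and the one-point
margin tolerates fold-level noise.

## Learning blocks and the gated ensemble

Each selected graph gets a *learning block*: a feed-forward network on the
low-pass-filtered features with hidden layers of width 512 and 64,
rectifier activations, dropout after both hidden layers (default rate 0.3),
and a two-class softmax head, trained full-batch with Adam at learning rate
0.01 for 200 epochs, no early stopping.  Filtering is transductive: the
eigenbasis comes from the full-cohort graph (graphs are defined over the
whole population), but labels of held-out subjects never enter training.
The 64-unit post-rectifier activation is the block representation p_i.

The ensemble fuses m block representations with a learnable softmax gate
α = softmax(w) (w initialized from a seeded normal at scale 0.01):

    H = Σ_i α_i p_i ,   ŷ = sigmoid(H W + b)

trained with cross-entropy over labelled subjects; probabilities are
clipped at 1e-12 inside the loss.  Decisions threshold ŷ at 0.5.  Two
deliberate design choices where the architecture description was open:

- **Fusion width.**  The weighted *sum* of 64-dim representations (width
  64) is the default, implementing the fusion equation literally; a
  `weighted_concat` mode (α-scaled blocks concatenated, width 64·m = 512
  for eight blocks) is provided behind a flag, since a stacked n x 512
  input is the other natural reading.
- **Training regime.**  Default is end-to-end: all block trunks, the gate
  and the head are optimized jointly per cross-validation fold, from
  scratch.  A two-stage mode (pretrain blocks with their own softmax heads,
  then fit gate + head on frozen representations) is provided for
  comparison.  The gate is re-learned per fold.

Because no GPU framework is assumed, the networks are implemented directly
in numpy with manual backpropagation and full-batch Adam; training is a
pure function of the seed, so every pipeline stage is bit-reproducible.
Weights use He-normal initialization; batch size equals the training fold
(full batch), chosen for determinism at cohort sizes in the hundreds.

## Evaluation

Model selection and reporting use seeded stratified k-fold cross-validation
(default 10 folds; class counts per fold within one of proportional).
Metrics: accuracy, sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with
the patient class positive, F1 of the positive class, and AUC computed by
the rank-statistic (Mann–Whitney) formulation with average-rank tie
correction.  Per-fold means ± standard deviations accompany pooled values.
Reference pipelines: `no_graph` (block on raw features — numerically
identical to any graph at k = n), `random_graph` and `fc_graph` (the
filtering pipeline on the corresponding baseline graph).  A sweep utility
re-runs the ensemble over a grid of cutoffs with shared folds and seeds.

## Synthetic cohorts

The generator draws lower-triangle features as
class mean + site offset + noise: a designated leading fraction of features
is shifted by ±effect_size/2 by class; each site contributes an additive
per-feature offset vector of scale `site_effect`; i.i.d. Gaussian noise of
s.d. `noise_sd` is added; values are clipped to [−1, 1], symmetrized, and
given a unit diagonal.  Sex is Bernoulli with configurable imbalance
(default matching a heavily male-skewed cohort, 727/871), site uniform over
`n_sites`, age uniform over `age_range` and independent of site.  The
generator is a pure function of its parameter record including the seed.

Defaults define the package's standard study cohort: 150 patients + 150
controls, r = 32 regions (d = 496 features), effect size 0.6 on 10% of
features, noise s.d. 0.25, 5 sites with offset scale 0.1 — a regime where
the class signal is clearly present but individual features are weak, as
in connectome-wide association settings.  `smooth_cohort_params` provides
a second preset (strong effect 1.5 on 40% of features, low noise, 3 sites,
near-balanced sexes, narrow age range) engineered so each
connectivity-bearing graph keeps its class-split eigenmodes inside the
lowest fifth of the spectrum; it is used to demonstrate the selection
analysis, whose expected outcome there is exactly the eight
connectivity-bearing graphs.  The spectral-room consideration behind it:
a phenotype-partitioned graph with c components spends its first c modes
on component indicators, so 0.2 n must comfortably exceed c plus one
class-split mode per component.

What the generator does *not* emulate: fMRI time series and the resulting
correlation-matrix geometry (features are clipped Gaussians, not true
correlations), multiplicative or covariance-level site effects, phenotype-
feature dependence beyond the site offsets, and age-site dependence.
Passing tests therefore show the pipeline's mechanics and its statistical
behavior under the assumed generative model, not performance on real
cohorts.

## Validation studies (popgse.experiments)

- **Selection study**: all 18 graphs, accuracy-vs-k curves (grid
  {0.1 n, 0.2 n, n}, 2 folds, 20 epochs) on the smooth cohort (n = 120);
  expected: exactly the 8 connectivity-bearing graphs qualify.
- **Gating recovery**: one informative block (smooth-graph-filtered
  features) vs one noise block (row-shuffled features on a random graph),
  end-to-end training at 50 epochs on the default cohort (n = 300,
  d = 496); expected: α_informative > α_noise in the large majority of
  seeds.
- **Noisy ensemble study**: i.i.d. Gaussian noise of s.d. 1.0 — roughly
  the full feature scale, and spectrally flat, hence predominantly
  high-frequency relative to the smooth class structure — is added to the
  default cohort's features; graphs are rebuilt from the noisy features.
  Measured: ensemble vs best single block at k = 0.2 n, and the ensemble
  over cutoffs {0.1 n, 0.2 n, n} (3 folds, 25 epochs).  Expected: the
  gated ensemble stays within two points of its best member, and the best
  cutoff falls below the full spectrum.
- **Controls**: label permutation (block and two-graph ensemble) and an
  effect-size-zero cohort; both must land in the 40–60% chance band
  (accuracy, AUC respectively).

Problem sizes and epoch counts in these studies are the package's chosen
desk-scale defaults; they keep each study in the seconds-to-minutes range
on a single CPU while leaving the measured effects well clear of their
decision margins.

## Known limitations

- Transductive filtering requires the full cohort (including unlabeled
  test subjects) at basis-computation time; there is no inductive variant
  for unseen subjects.
- Full eigendecomposition is O(n³); cohorts beyond a few thousand subjects
  would need partial eigensolvers or polynomial filters, which are out of
  scope.
- The identity-baseline convention (coordinate basis) makes its "filtered"
  features depend on subject order by construction; this baseline exists
  only as a non-smooth reference.
- Accuracy-based regime categorization inherits fold noise; on very small
  cohorts the one-point margin is close to the single-subject
  quantization of fold accuracy, which is why the demonstration cohort
  uses n ≥ 120.
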