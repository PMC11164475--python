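# Methods

## Preprocessing

Input tables are probes × samples; multiple probes mapping to one gene are
collapsed by the arithmetic mean, unmapped probes dropped, and the collapsed
genes ordered lexicographically so that all downstream rank tie-breaking is
reproducible. Each sample column is then z-scored across genes using the
sample standard deviation (divisor n−1, matching common statistical software
and making the [1, 2, 3] → [−1, 0, 1] contract exact). Zero-variance columns
map to all-zeros rather than raising, so degenerate fixtures pass through.
Normalization is applied after collapsing because the per-patient sequence
being standardized is the gene-level profile. Single-gene matrices are
rejected: a per-sample z-score over one gene is identically zero and carries
no ranking information.

## Classifier

The classifier is an m–3–2 network — sigmoid hidden layer, softmax output —
trained with per-sample stochastic gradient descent on cross-entropy, in a
seeded shuffled order each epoch, from uniform(−0.05, 0.05) initial weights.
Cross-entropy is the standard pairing with a softmax output and gives clean
gradient formulas; a full-batch mode exists for debugging. Training uses a
seeded stratified 80/20 split; the held-out 20% yields the reported holdout
accuracy, and stratified ten-fold cross-validation is available as a separate
validation report. When the requested fold count equals the sample count a
plain leave-one-out split is used (a stratified split is impossible there);
fold counts between the smaller class size and n are rejected.

Defaults are epochs = 100 and learning rate = 1e-4. **At the cohort sizes
used throughout the tests (m ≤ 500 genes, a few hundred samples), that
learning rate moves the weights by ~1e-3 over a whole run — the network
stays at its initialization, holdout accuracy sits at chance, and the
gradient ranking reflects initialization noise.** All experiments in the
test suite and acceptance script therefore pass an explicit
`TrainConfig(learning_rate=0.1)`; the defaults are retained for large-m
cohorts where per-update gradients are correspondingly larger. The learning
rate is deliberately a first-class configuration field for exactly this
problem-size dependence.

## Gradient sensitivity

The derivative of the case probability with respect to each input is exact:
for a two-class softmax, ∂p₁/∂aₖ = p₁p₀(w_k,1 − w_k,0), and the sigmoid
contributes aₖ(1−aₖ)Wₕ[i,k]. The per-gene score is the mean over all n
samples of |d_ij| — absolute values, since signed derivatives of genes with
class-symmetric effects cancel. Derivatives are evaluated at all samples
under the single model trained on the 80% split; cross-validation is a
validation report only, not an ensemble. Rankings break ties
lexicographically by gene id, and the top set takes the first
floor(fraction·m) genes (fraction defaults to 0.2).

## Shapley attribution

The coalition value of a gene set S at sample x is the case probability of
the hybrid vector (x on S, baseline elsewhere) under the single trained
model — the baseline-substitution semantics of Lundberg & Lee. Retraining a
model for every coalition is 2^m trainings and is not attempted; the
retraining notion survives as the explicit `network_delta` contrast for
small panels, which trains the full and reduced models under the identical
seed/epoch protocol so the difference reflects feature removal rather than
training noise.

Exact Shapley values enumerate all 2^m coalitions (auto-selected for m ≤ 12,
refused above m = 20). The sampling estimator draws seeded permutations in
antithetic pairs (a permutation and its reverse; default 200 permutations)
and averages marginal contributions; because each permutation's marginals
telescope, efficiency (Σφ = v(full) − v(empty)) holds exactly even for the
sampled estimator. One permutation costs a single vectorized forward pass
over all samples and coalition prefixes: the hidden pre-activation is
accumulated by cumulative sums of per-gene contributions, so the full m×n
attribution matrix at 200 permutations takes seconds at m = 500, n = 400.

Per-gene scores average |φ_ij| over samples, mirroring the absolute-value
averaging of the gradient track (a signed-mean flag is retained). The
default baseline is the all-zeros vector — the per-sample mean after
z-scoring — configurable to dataset gene means or an explicit vector.

## Network and gene-set statistics

Betweenness centrality follows the unordered-pair convention — each {s, t}
pair counted once, undirected unweighted shortest paths, unreachable pairs
contributing nothing — computed via networkx (unnormalized) and
cross-checked in the tests against a brute-force all-pairs shortest-path
enumerator on graphs of up to 12 nodes. Over-representation is database-free:
gene-set collections arrive as GMT files, each set is intersected with the
user-supplied universe, the one-sided hypergeometric tail P(X ≥ overlap) is
computed per set (overlap 0 gives p = 1), and Benjamini–Hochberg adjustment
is applied across sets.

## Downstream statistics

Differential expression uses Welch's unequal-variance two-sided t-test per
gene. Correlation analysis computes cosine similarity between gene vectors
restricted to each group's samples, without re-centering per group (the
matrix is already z-scored); the difference matrix is case minus control by
default, so positive entries mean the pairwise trend strengthened in cases —
orientation is configurable and recorded. Clinical regressions are ordinary
least squares of the indicator (MMSE or NFT) on single-gene expression. The
SVM biomarker panel standardizes features inside the training split
(pipeline), uses a linear kernel by default on a seeded stratified 80/20
split, reports held-out accuracy plus stratified ten-fold cross-validated
accuracies, and for 2-gene panels exports per-gene decision thresholds (the
boundary crossing with the other gene held at its training mean).

## Synthetic cohorts

The generator emulates a two-group microarray brain cohort: default 187
control / 176 case samples, background genes standard normal per sample,
informative genes shifted by `effect_size` within-group SDs in cases
(per-gene sign configurable), correlated blocks built from a shared Gaussian
latent factor (value = √ρ·factor + √(1−ρ)·noise, giving pairwise correlation
ρ exactly), `probes_per_gene` probe rows per gene with independent Gaussian
measurement noise, and clinical scores coupled to the informative-gene mean:
MMSE = 30 + slope·mean + noise clipped to [0, 30] (default slope −1.5), NFT
= max(0, slope·mean + noise) (default slope +2). Scores are driven by
expression, not group label, so regression-recovery tests have a known
planted slope. Everything is reproducible from one seed, which is recorded
in the simulation manifest.

Two consequences of this design matter for interpreting tests. First,
because the MMSE intercept sits at the ceiling of its [0, 30] range, control
samples (expression near 0) are partially clipped and a whole-cohort
regression attenuates the planted slope by ~25%; slope-recovery experiments
therefore regress within the case group, whose expression sits away from the
boundary. Second, small gene panels (2–6 genes) are constructed directly as
already-normalized matrices: per-sample z-scoring across only two genes
collapses every sample to ±1/√2 and destroys the signal, whereas real panels
are row subsets of a full z-scored matrix. "Linearly separable" 2-gene
fixtures shift both genes by the stated effect (a single-gene shift of 3 SD
caps Bayes accuracy at 0.933).

The generator does not model spatial microarray artifacts, saturation,
batch effects, or heavy-tailed noise; passing recovery tests demonstrates
that the method ranks genes correctly when its distributional assumptions
hold, not that it is robust to real microarray pathology.

## Pipeline

`run_pipeline` sequences simulate/ingest → collapse+z-score+align → train →
gradient ranking → Shapley ranking → intersection → optional ORA and
centrality → differential expression, correlation, clinical regression and
SVM on the consensus genes. One global seed is expanded into per-stage seeds
by a fixed counter scheme (stage k uses seed + k), so each stage is
independently reproducible; the manifest records the seed, the full config,
cohort dimensions and top-ranked genes, and a run can be re-executed from
its manifest alone. A stage failure aborts with the stage name after
persisting a partial manifest.

## Numerical notes and limitations

- Sigmoid and softmax are evaluated in numerically stable forms; training
  aborts with the epoch number if the loss goes non-finite.
- Rank ties break lexicographically by gene id; top sets use floor.
- Zero-variance genes: cosine similarities are set to 0 with a warning;
  constant expression is rejected in regression (the slope is undefined).
- Exact Shapley memory grows as 2^m; the m ≤ 20 cap keeps it ~100 MB.
- The m–3–2 architecture is fixed by design; no regularization, calibration
  or architecture search is provided.
- Betweenness matching any particular external tool's printed scores is out
  of scope — conventions (ordered vs unordered pairs, normalization) differ
  between tools.
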