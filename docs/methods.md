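# Methods

## Problem and model

The package predicts transcription-factor binding sites (TFBSs) on a genome
divided into fixed-width bins (default 200 bp). Each chromosome is modelled
as a linear chain: bin labels `y_j ∈ {0, 1}` (background / site), observed
feature matrix `x` with one real-valued row (per-bin maximum PWM score,
always row 1) and binary rows (histone-mark peak overlap, promoter
membership). A two-state linear-chain conditional random field assigns

    p(y | x; λ) ∝ exp( Σ_j Σ_k λ_k f_k(y_j, y_{j−1}, j, x) )

The CRF is discriminative: it models only the conditional distribution of
labels given features, so arbitrarily correlated features (e.g. H3K4me2 and
H3K4me3) can be mixed without an independence assumption — the motivation
for choosing it over a generative HMM for this problem.

### Feature template families

| family | value | role |
|---|---|---|
| PWM_STATE | `x_{1,j}·I{y_j = u}` | couples motif strength to the bin label (only real-valued family) |
| OCCURRENCE | `I{y_{j−1}=u, y_j=v, x_{i,j}=1}` | single mark / promoter present in the bin |
| COOCCURRENCE | … and `x_{i′,j}=1` | two marks in one bin (bivalent-domain-like patterns) |
| ADJ_PAIR | … with `x_{i′,j−1}=1, x_{i,j}=1` | mark pattern across adjacent bins |
| ADJ_TRIPLE | … and `x_{i″,j+1}=1` | three-bin pattern |
| TRANSITION | `I{y_{j−1}=u, y_j=v}` | label-transition prior (extension, default on) |

The pure transition family is an extension: the five x-conditioned families
cannot express baseline site sparsity in bins where every binary feature is
0, so without it the model is miscalibrated on feature-empty stretches. It
can be disabled (`include_transitions=False`).

Default instantiation over a registry with B binary rows: PWM_STATE for
u∈{0,1}; OCCURRENCE for every row × (u,v); COOCCURRENCE for every unordered
row pair × (u,v); ADJ_PAIR for both orders of every pair plus each row's
diagonal (same mark in adjacent bins) × (u,v); ADJ_TRIPLE for each row's
diagonal triple × (u,v); 4 transitions. For B = 9 this yields K = 546
features. No feature selection is performed: with L2 regularisation,
uninformative templates receive weights near zero.

Each binary condition carries a polarity flag, so negated patterns ("not in
a promoter region") are expressible; the default is positive polarity.

### Boundary and degenerate-input conventions

- A virtual background label precedes bin 1: the pair potential at j = 0
  uses only the `y_prev = 0` slice, and `y_{-1}` matches `u = 0`.
- Matrix references outside `[0, L)` (adjacent-bin templates at the chain
  ends) read 0, so ADJ_PAIR never fires at the first bin and ADJ_TRIPLE
  never fires at the last.
- Bin spans are 0-based half-open; a peak center on a bin boundary belongs
  to the right-hand bin; the final bin may be short and is treated like any
  other.
- PWM scan positions whose window contains `N`, or that would overhang the
  chromosome end, carry a −∞ sentinel; a bin with no scorable position is
  floored to the chromosome-wide minimum finite positional score so no
  infinities reach the CRF. The per-bin score is the maximum over windows
  *starting* in the bin (windows may overhang the right edge).

## Training

Weights maximise the conditional log-likelihood summed over chains
(chains = chromosomes, trained jointly) minus a single L2 penalty
`‖λ‖²/(2σ²)`. The gradient is empirical-minus-expected feature counts minus
`λ/σ²`, with expectations from exact forward–backward node and edge
marginals. Optimisation uses L-BFGS-B on the negated objective with the
analytic gradient; convergence is a projected-gradient max-norm below `tol`
(default 1e−5, `max_iter` 200, warning + best-so-far weights on
non-convergence). The objective is strictly concave for σ² < ∞, so the
deterministic zero initialisation needs no restarts.

Parameters that matter:

- `σ²` (regularisation variance, default 10.0): larger is weaker
  regularisation. The default is a conventional mid-range choice for
  hundreds of features on ~10⁴ training bins; it is exposed everywhere.
- `bin_size` (default 200 bp): matches the resolution of histone-mark peak
  calls and the typical spacing between sites.
- `promoter_half_width` (default 2000 bp): promoter = 4 kb window centred
  on the TSS, not strand-aware, clipped at chromosome ends.
- PWM scoring: log2 odds against a uniform background with pseudocount 0.01
  per cell, strand-maximum. The PWM row enters raw (no standardisation);
  the PWM_STATE weight absorbs its scale.

Inference is log-space forward–backward, linear in L; the inner recursions
are numba-compiled so whole-chromosome chains (10⁵–10⁶ bins) remain
practical. Node/edge marginals satisfy normalisation and consistency
identities to ≤1e−8, enforced by tests against exhaustive enumeration for
L ≤ 12.

## Prediction and evaluation

The score of bin j is its posterior marginal `s_j = p(y_j = 1 | x; λ)`;
calling uses a strict threshold (`s_j > t`). Evaluation sweeps thresholds
with tied scores grouped, reporting trapezoidal AUC, AUC10% (area at
FPR ≤ 0.1, maximum 0.1; computed in integer count space with rational
arithmetic so boundary cases are exact), and TPR at fixed FPR levels.
Cross-validation shuffles chromosome names with a seed, deals them
round-robin into k folds, trains out-of-fold and scores in-fold; per-fold
and pooled ROC results are both reported because fold averaging and
pooling answer slightly different questions (typical-fold performance vs
overall ranking quality). External predictors are compared like-for-like
by assigning each predicted interval to the bin containing its center
(maximum score per bin, unscored bins ranked last as ties).

## Synthetic benchmark: what it emulates and what it does not

The generator plants motif instances (sampled from the motif's column
distributions) at non-overlapping positions in i.i.d. uniform background
sequence, with a configurable fraction inside 4 kb promoter windows around
generated TSSs (default 30 %, emulating the promoter enrichment of some
factors' sites). Each histone mark covers site-containing bins with
probability `p_on|site` and other bins with `p_on|background`; one
designated pair (H3K4me3/H3K27me3, bivalent-like) is jointly forced on in
site bins with probability 0.2. Consecutive "on" bins are merged into BED
intervals so the peak-overlap round trip is exercised.

Default rates make the three H3K4 methylation marks comparably and
moderately informative (0.45/0.44/0.42 on-site vs 0.12–0.14 background),
repressive and structural marks nearly uninformative, mirroring the known
ordering of mark discriminativeness around binding sites and producing the
characteristic benchmark structure: sequence alone is mediocre, adding the
best single mark helps, and integrating all features helps most. The
default dataset is 4 chromosomes × 200 kb with 50 sites each; the
`benchmark()` variant used for the ablation and null studies is
20 chromosomes × 150 kb with 40 sites each, sized so 10-fold
chromosome-holdout CV has two chromosomes (~80 positive bins) per fold and
fold-level AUCs are stable enough to resolve the ablation ordering. On this
benchmark the ablation gaps are assessed as the mean of *paired* per-fold
AUC differences against twice their SD — models are compared on identical
folds, so pairing removes shared fold-composition noise.

Deliberate idealisations, and hence what passing benchmarks do **not**
show about real data: background sequence is i.i.d. (no repeats, GC
structure or CpG islands); marks are conditionally independent given the
label except for the one boosted pair; mark peaks align to bin boundaries;
peak calls are noise-free; positive rates (~5 %) are far higher than
genome-wide site density; and there is one motif per dataset. Real-data
performance additionally depends on peak-caller quality, motif model
fidelity and chromatin-state heterogeneity that the generator does not
simulate.

## Numerical and design choices

- Probabilities are computed in log space throughout; `log Z` from the
  forward and backward passes agrees to ≤1e−8 as a runtime invariant.
- Peak center is `floor((start + end)/2)`.
- The all-sentinel PWM bin floor, tie handling in ROC (group-wise), and the
  strict calling threshold are all stated conventions rather than silent
  behaviours, and each is covered by a test.
- Sign conventions in evaluation follow the standard definitions: FN =
  positive bins predicted negative, FP = negative bins predicted positive.
- Problem sizes in tests (8–12-bin enumeration oracles, 200×100-bin
  parameter recovery, the 20×150 kb benchmark) were chosen so the full
  suite exercises every code path at exact or tight statistical tolerances
  while remaining a desk-scale computation.

## Known limitations

- Two states only; no semi-Markov durations, no Viterbi decoding (marginals
  are the prediction, by design).
- Binary chromatin features only; continuous signal shape/intensity is not
  modelled.
- Promoter windows ignore strand; refGene-style TSS tables are reduced to
  point positions.
- Training recompiles feature activations per chain into dense K × L
  arrays; for K in the thousands on full mammalian genomes a sparse
  activation layout would be preferable.
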