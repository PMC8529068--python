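# Methods notes

This note records the models and procedures `trinetomics` implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Synthetic cohort model

Each sample draws $K$ independent standard-normal latent factors. A feature
loading on factor $j$ with loading $\lambda \in [0,1)$ takes the latent
value $z = \lambda f_j + \sqrt{1-\lambda^2}\,\sigma\,\varepsilon$ with
$\varepsilon \sim N(0,1)$; with the default noise scale $\sigma = 1$ two
features sharing a factor have correlation $\lambda^2$, and Spearman
correlations are preserved by the monotone maps onto each domain's
observation scale:

* **Microbiome** — $\exp(b_i + z)$ with per-feature baselines
  $b_i \sim N(0, 1.5^2)$, thinned by a per-entry presence Bernoulli at the
  configured prevalence (default 0.9) and renormalised per sample, giving
  compositional zero-inflated relative abundances that close to 1 within
  1e-9.
* **Metabolome** — $\exp(\mu_i + z)$, $\mu_i \sim N(3,1)$: positive
  log-normal intensities.
* **Phenotype** — $z$ rescaled by per-feature log-normal scales, plus a
  binary `disease` column from a logistic model.

Factor layout: every factor owns one metabolite module with size drawn from
`module_size_range` (default 5–20), plus round-robin up to **two MGS and two
biomarkers per factor**. Two per factor keeps every planted cross-domain
edge type (microbe–metabolite, metabolite–biomarker, microbe–biomarker)
represented without letting a single factor dominate the network; all pairs
sharing a factor are recorded as planted edges. Defaults emulate the study
conditions: 138 samples, loading 0.8, ten factors.

The disease label uses `disease_effect` $\times$ the mean of the
standardised *driver* biomarkers as the logit. Drivers are the tail
`n_biomarkers // 4` biomarkers, which are factor-free whenever
$2K + \lceil n/4 \rceil \le n$: the cohort's disease signal then lives in
the biomarkers only, and microbiome-based classification hovers near
chance — the qualitative contrast the package's classification benchmark
checks. The default effect 3.0 was chosen from the generative model itself:
with seven drivers the Bayes-optimal AUC of the logit score is ~0.84,
matching the strong blood-biomarker separation the cohort is meant to
emulate, while effect 1.0 would cap it at ~0.65.

What the generator does **not** emulate: batch effects, sequencing depth
variation, non-Gaussian copulas, heavy-tailed clinical units, overlapping
factor membership, and realistic phylogenetic or pathway correlation
structure. Passing the recovery benchmarks therefore shows the pipeline's
statistics behave as designed under their own assumptions, not that real
cohorts will yield equally clean recovery.

## Metabolite co-abundance modules

Intensities are log2 transformed with a pseudocount of half the smallest
non-zero value (scale-aware, avoids $-\infty$). The biweight
midcorrelation uses Tukey weights $w_i = (1-u_i^2)^2$ on
$u_i = (x_i - \mathrm{med})/(9\,\mathrm{MAD})$, $|u_i| < 1$; a feature with
MAD = 0 falls back to Pearson standardisation for that vector (logged).
Signed adjacency $((1+c)/2)^\beta$ uses $\beta = 13$ by default; the
scale-free scan (`pick_soft_threshold`) bins connectivities into ten
equal-width bins and reports the $R^2$ of log-frequency on
log-connectivity, choosing the smallest grid power reaching the target
$R^2$ (0.8), the argmax otherwise, and the grid maximum with a warning for
degenerate networks. Dissimilarity is topological overlap
$d_{ij} = 1 - (l_{ij} + a_{ij})/(\min(k_i,k_j) + 1 - a_{ij})$ (configurable
to $1-a$).

**Simplified dynamic cut.** The published dynamic hybrid tree-cut is
heavily parameterised; the implementation uses a deterministic
simplification: average-linkage clustering is cut statically at the
$(1-\text{deep\_split}/8)$ fraction of the dendrogram height range (deep
split 4 cuts mid-range; deeper splits cut lower and yield finer branches),
branches below `min_size` (default 3) dissolve to "unassigned", and
unassigned features are adopted by the module whose eigenprofile they
correlate with at $r \ge 0.3$. The height-*range* anchor matters: TOM
dissimilarities concentrate near their maximum at high $\beta$, so a
quantile of the merge-height distribution would land inside the
within-module merges and shatter real modules. The tie rule for a flat
dendrogram (all dissimilarities equal) is a single module. This variant
recovers planted block structure exactly in the test suite but is not
claimed to match the original algorithm branch-for-branch.

Eigenprofiles are the first principal component scores of the standardised
member submatrix, scaled to unit variance and oriented so their correlation
with the mean member profile is non-negative; variance explained is
$s_1^2/\sum s_j^2$.

## Correlation screens

Spearman $\rho$ is Pearson on mid-ranks; two-sided p-values use
$t = \rho\sqrt{(n-2)/(1-\rho^2)}$ with $n-2$ df, $p = 0$ at $|\rho| = 1$
(the $n \approx 138$ regime; an exact method would matter only below
$n \approx 10$). Phenotype missing values are handled by pairwise deletion
with `n_used` recorded; pairs with fewer than four complete observations or
a constant vector are skipped and counted. BH adjustment is applied within
each domain-pair round separately — the round is the inferential family —
and the false-discovery calibration assesses the realised FDP at that
per-family level (measured 0.10 at q < 0.1 over 200 null cohorts, matching
the BH guarantee; pooling across independently adjusted families would
mechanically inflate it). Triangular retention keeps triples whose three
legs all reach p < 0.05; the network filter instead requires q < 0.1,
$|\rho| \ge 0.3$ (boundary kept) and distinct domains.

## PERMANOVA

The screen is single-variable with continuous or binary covariates:
$G = -\tfrac12 J D^2 J$, $r^2 = (\tilde v^\top G \tilde v/\tilde v^\top
\tilde v)/\mathrm{tr}(G)$, pseudo-$F$ with $n-2$ residual df, and a
permutation p-value with the add-one rule (default 999 permutations, never
reported as 0). Binary 0/1 covariates reproduce the classical two-group
PERMANOVA (verified against the group sum-of-squares identity). The
distance defaults to Bray–Curtis on relative abundances; the metric and the
permutation count are assumptions, both configurable. Null calibration at
$n = 40$, 100 features gives a rejection rate of ~0.04–0.05 at
$\alpha = 0.05$.

## Reporter scores

Member p-values map to $z_i = \Phi^{-1}(1-p_i)$ (clipped to
$[10^{-15}, 1-10^{-15}]$), signed by the direction of change (sign of the
group-median difference in the differential-abundance context). The module
score $Z = \sum z_i/\sqrt k$ is corrected against $\mu_k, \sigma_k$
estimated from 1000 random size-$k$ draws from the background of all scored
features (sampling rather than the closed-form normal null; the closed form
is a one-line swap). $|Z_\text{corr}| \ge 1.96$ is flagged significant. A
degenerate background ($\sigma_k = 0$) is an error rather than a silent 0.

## Communities

Edge length is $1-|\rho|$ (stronger correlation, shorter path); an
unweighted option exists. Edge betweenness uses Brandes' accumulation over
Dijkstra shortest-path DAGs with fractional credit for ties, reported per
unordered pair. Girvan–Newman removes the maximum-betweenness edge, ties
broken by lexicographic edge id for determinism, recomputing betweenness
only within the component the removal touched; each component-count
increase snapshots a candidate partition, and the returned partition
maximises unweighted Newman–Girvan modularity on the original graph
(earliest wins on ties) — the canonical cut-selection companion of the
algorithm. Community summaries prune communities below 5 nodes and report
per-community domain-pair edge counts with display rounding of one decimal
at $\ge 1000$ edges and nearest integer below (both the exact fractions and
the display values are kept).

## Cross-validation

Classification uses stratified folds; down-sampling subsamples the
training-fold majority class to the minority size, never touching test
folds, and is not applied to regression (no class structure exists there).
ROC AUCs are computed per repeat on the pooled out-of-fold scores and then
averaged; per-repeat values are retained. The default learner is a
500-tree random forest with $\sqrt p$ (classification) or $p/3$
(regression) features per split; any scikit-learn style estimator can be
substituted. Feature importances (mean decrease in impurity) are averaged
over all fits. Note that out-of-fold Spearman accuracy of a no-signal
learner is not exactly zero: the train-mean predictor shows a systematic
negative leave-out bias (mean $|r| \approx 0.27$ at $k=10$, $n=100$), which
the tests treat as the correct null behaviour.

## Problem sizes used in validation

The calibration and recovery suites run at sizes chosen to exercise the
statistics meaningfully on a laptop: FDR calibration on 200 null cohorts of
50 MGS x 50 metabolites x 20 biomarkers at $n=150$; planted recovery on one
$n=300$ cohort with ten metabolite modules of size 5–20, 40 MGS and 15
biomarkers; PERMANOVA calibration on 1000 null replicates at $n=40$ with
999 permutations; reporter calibration on 500 random modules of size 8 over
a 300-feature background; classification on the 138-sample generator
defaults with 5-repeat 10-fold CV.

## Known limitations

* The simplified dynamic cut and the scale-free $R^2$ binning are faithful
  in spirit but not numerically identical to the reference R
  implementations of those procedures.
* PERMANOVA is single-variable only; no interaction terms or marginal
  (covariate-adjusted) effects.
* Spearman screens ignore compositionality; no proportionality or partial
  correlations.
* Girvan–Newman recomputes betweenness exactly each round; graphs beyond a
  few thousand edges become slow, and no approximate variant is provided.
* Publication-style displayed percentages for very small edge classes in a
  large community cannot always be reproduced under a single rounding rule;
  the summary reports computed fractions alongside the display values.
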