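# Methods

This note documents the statistical procedures the package implements, the
choices made where the methods literature leaves room, and what the synthetic
study conditions do and do not establish.

## The measurement problem

The package quantifies how the concept of artificial intelligence is
represented in natural language along social-stereotype dimensions, at three
levels of language technology:

1. **Static word embeddings** — associations between AI-related target words
   and polar attribute dictionaries (high/low competence, high/low warmth;
   advantaged/disadvantaged demographic group terms), via the
   Single-Category Word Embedding Association Test (SC-WEAT).
2. **Masked language models** — the relative probability of a target word at
   the masked slot of propositional queries whose attribute slot alternates
   between the poles of an antonym pair (Fill-Mask Association Test, FMAT).
3. **Generative models with a top-k probability readout** — per-occupation
   log-ratio scores contrasting "benefits from AI" prompts with "replaced by
   AI" prompts, related to occupational prestige.

A fourth analysis places AI and each demographic group in a 4-dimensional
competence–warmth space (two stereotype dimensions × two attribute
dictionaries) and asks whether AI lies geometrically closer to advantaged
groups. Internal meta-analysis pools effects across methods.

## Estimators

### SC-WEAT

For target word *w* and attribute poles *A* (high) and *B* (low):

    s(w) = mean_{a∈A} cos(w, a) − mean_{b∈B} cos(w, b)

Multiword lexemes are resolved to the unweighted mean of their token vectors
(standard practice for static embeddings, and deterministic). Out-of-vocabulary
handling is a hard error by default, with an explicit skip-and-log policy;
silent dropping is never the default because it changes effect sizes
invisibly. Three summaries:

* **Classic effect size** `d = mean(s)/sd(s)` over target words (sample SD),
  per model × dictionary.
* **Permutation p-value**: the pooled attribute set is re-partitioned into
  same-sized high/low sides; p is the fraction of partitions whose mean
  association is at least the observed one. Exhaustive enumeration when
  requested (p ∈ (0, 1] with the observed partition counted); otherwise
  seeded random partitions with add-one smoothing (k+1)/(n+1).
  *Calibration caveat*: the permutation null assumes the attribute labels
  are exchangeable. When the two attribute sets genuinely cluster around
  different centroids — as the synthetic generator plants even at zero
  target bias — the test is anti-conservative; the calibration test
  therefore uses an i.i.d.-attribute null, which is the assumption the test
  actually makes.
* **Pooled standardized regression**: each (target word × attribute word)
  cosine similarity is one observation, scaled to unit sample SD within its
  model × dictionary cell (scale only, no centering — embeddings differ in
  similarity scale, and centering would be absorbed by the intercept
  anyway), then regressed on the attribute polarity indicator (high = 1,
  low = 0) by OLS. Because the outcome has SD 1 the slope is a standardized
  mean difference, directly interpretable as Cohen's d, and observations
  from any number of embedding models pool into one fit.

### FMAT

Queries are templates with exactly one `[MASK]` slot (scored target) and one
`{ATTRIB}` slot; the attribute dictionaries pair up positionally as antonym
pairs, so each (template, target, pair) cell yields a high and a low variant.
The per-cell contrast is `logp_high − logp_low` in natural log. Two
summaries: the **raw mean contrast** (the natural scale of a planted shift)
and the **standardized polarity slope**, built exactly like the SC-WEAT
pooled regression with log-probabilities as the outcome and the masked LM as
the standardization cell. A constant contrast across cells is well-defined
(the base probabilities still vary); the only degenerate case is zero
variance in the log-probabilities themselves.

The masked LM is injected through an adapter contract `(context, token) → p`.
The shipped backend is a deterministic fixture table; targets the adapter
cannot score raise a tokenization error and the cell is skipped and logged.
Multi-token targets at a single mask are out of scope.

### Competence–warmth geometry

A group's point is the 4-vector of its association effects
(competence and warmth × dictionaries A and B), assembled in canonical order;
coordinates are left on each dictionary's effect scale (an optional
per-dimension z-scaling exists but is off by default — with only eight group
points, rescaling by noisy SDs adds variance without improving
comparability). Distances to the AI point use the Euclidean metric, only
within one measurement method. The status contrast is OLS of distance on a
disadvantaged indicator plus method fixed effects; the dummies absorb any
additive between-method scale offset (verified numerically), and with eight
group × method records unweighted OLS is the parsimonious choice.
Status is coded disadvantaged = 1, so a positive slope means AI sits closer
to advantaged groups.

### Occupation probe (q scores)

Per occupation *x* with benefit-prompt probabilities p₁…p_{n₁} and
replacement-prompt probabilities p₁…p_{n₂}:

    q(x) = ln( (1/n₁) Σ p(x | v_benefit)  /  (1/n₂) Σ p(x | v_replacement) )

Natural log throughout. q is exactly antisymmetric under swapping the
families and invariant to global probability rescaling. An occupation absent
from a prompt's top-k readout contributes **no observation** for that prompt
— never an imputed zero or floor, which would fabricate information; the
batching scheme compensates by repetition, scheduling seeded random batches
until every occupation has at least `min_appearances` (default 100)
appearances per family (default batch size 20).

Summary statistics: one-sample t = mean/(sd/√n) with df = n−1; Cohen's
d = mean/sd with the normal-approximation CI `d ± 1.96·√(1/n + d²/(2n))`
(this approximation reproduces published intervals of this design to three
decimals); a one-sample JZS Bayes factor computed by numerical integration
of the g-prior representation of a Cauchy prior on the effect size, default
scale √2/2 (exposed as a parameter), cross-checked against an independent
implementation; and the Pearson correlation between q and occupational
prestige.

### Meta-analysis

Inverse-variance pooling with tau² = 0 (fixed), the DerSimonian–Laird moment
estimator truncated at zero, or REML by the standard fixed-point iteration
(default, matching the convention of the widely used R implementation, which
was also used to freeze reference values for the REML tests). Input
variances for pipeline effects are the squared standard errors of the
standardized-regression slopes — the only uncertainty the pipeline itself
produces. Wald 95% CIs and two-sided normal p-values.

## Synthetic study conditions

The generators produce inputs with the statistical structure the estimators
assume, plus recorded ground truth:

* **Embeddings** (`gen_embeddings`): attribute vectors are isotropic Gaussian
  clouds (`noise_sd = 0.15` per coordinate, dimension 50) around two random
  orthonormal centroids; target directions mix toward the high centroid with
  weight `bias`. The analysis scripts use `bias = 0.10`, which yields pooled
  standardized slopes averaging ≈ 0.3 across seeds — the small-to-medium
  band that language-bias effects of this kind occupy — with 40 targets and
  25 + 25 attribute words per side.
* **Fill-mask tables** (`gen_fillmask_table`): base probabilities log-uniform
  in [0.01, 0.2]; planted contrast `delta = 0.3` with Gaussian noise 0.2 over
  24 antonym pairs (the size of the larger published attribute dictionary).
  Pairs that would exceed probability 1 are shifted down pairwise, preserving
  the contrast, with a warning.
* **Probe tables** (`gen_probe_table`): 65 occupations (the count with valid
  prestige values in the published occupation set), prestige spread uniformly
  over 20–80 (a typical prestige-scale range); true score
  `q = slope·z(prestige) + N(0, σ)` with slope 0.8, σ = 0.6 in the analysis
  scripts (implied r ≈ 0.8). Probability lists are constructed so the
  log-ratio of family means equals the true q *exactly*, which is what makes
  machine-precision recovery a meaningful test of the scoring code rather
  than of the noise realization.

All generators are pure functions of their spec (seed included).

**What passing these conditions shows — and does not.** Recovery on
synthetic data verifies the estimators' algebra, calibration and wiring; it
does not validate the linguistic claims on real corpora. Real embeddings
have anisotropic geometry, frequency-correlated vector norms, and polysemy;
real masked-LM probabilities are far from log-uniform and vary with
template phrasing; real top-k readouts truncate much more aggressively than
the mock provider. Reproducing the published coefficients from real models
(e.g. the embedding-branch competence slope or the prestige correlation
r = 0.711) requires downloading the named embedding and BERT-family models
or querying a paid, non-deterministic API, and is deliberately outside the
test surface; the published Study-4 *summary* statistics are reproduced
exactly from their printed sufficient statistics instead.

## Numerical choices

* Sample SDs use ddof = 1 throughout.
* Cosine similarity clips to [−1, 1] after the dot product (guards
  float rounding on collinear vectors); zero vectors are a hard error.
* Permutation comparisons use a 1e-12 slack on ≥ to keep ties stable under
  float noise.
* The classic SC-WEAT effect declares zero variance via the score range
  (`ptp == 0`), not the computed SD, so identical scores are rejected even
  when floating-point averaging leaves a ~1e-17 residual.
* REML iterates to |Δtau²| < 1e-12 (max 500 iterations) from the DL start;
  tau² is clamped at 0 every step.
* The Bayes-factor integral uses adaptive quadrature on (0, ∞) with the
  point-null likelihood factored out, stable for |t| ≲ 30 at the sample
  sizes involved.
* Problem sizes in the tests and the acceptance script (20 seeds × 200
  targets for the null-bias check; 100 pairs; 65 occupations; exhaustive
  permutation up to C(6,3)) keep full runs within seconds while leaving
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* No subword fallback for out-of-vocabulary tokens (FastText-style subword
  reconstruction is not implemented); OOV handling is skip-or-error only.
* FMAT supports only single-token targets per adapter; multiword targets
  must be vocabulary tokens of the backend.
* The distance contrast treats the eight group points as independent
  observations; their coordinates share attribute dictionaries, so the SE is
  optimistic on real data (the published analysis has the same structure).
* The permutation test's calibration guarantee holds only under attribute
  exchangeability (see above).
* Live model backends (embedding downloads, masked-LM inference, generative
  APIs) are intentionally not bundled; the adapter contracts are the
  extension point.
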