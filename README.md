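# stereolang

Language-based measurement of how artificial intelligence is stereotyped in
natural language: whether AI-related words associate with high or low
competence and warmth, whether AI sits closer to socially advantaged
demographic groups (men/women, young/old, rich/poor, white/non-white), and
whether a generative model links high-prestige occupations with *benefiting
from* AI and low-prestige ones with *being replaced by* it.

The package is written for computational social scientists who want these
measurements as tested, composable functions rather than one-off notebook
code. Every stage runs fully offline against seeded synthetic inputs with
planted ground truth, so the estimators are verifiable without downloading
embedding models or paying for API access; real models plug in through small
adapter contracts.

## Methods at a glance

* **SC-WEAT** (`stereolang.scweat`) — per-target association
  `s(w) = mean_a cos(w,a) − mean_b cos(w,b)` between target words and polar
  attribute dictionaries; classic effect size `d = mean(s)/sd(s)`;
  permutation inference over attribute re-partitions; and a pooled estimator
  that standardizes per-(target × attribute) similarities to unit SD within
  each embedding model and regresses them on attribute polarity, so the OLS
  slope reads directly as Cohen's *d* and pools across models.
* **FMAT** (`stereolang.fmat`) — fill-mask queries
  `"The [MASK] is {ATTRIB}"` scored by a masked-LM adapter; per-antonym-pair
  contrast `log p_high − log p_low`, summarized by the same standardized
  polarity regression.
* **Competence–warmth space** (`stereolang.stereospace`) — each group gets a
  4D coordinate vector (competence, warmth × two dictionaries); Euclidean
  distances from the AI point are regressed on advantaged/disadvantaged
  status with method fixed effects.
* **Occupation probe** (`stereolang.llmprobe`) — per-occupation score
  `q(x) = ln(mean p(x|benefit prompts) / mean p(x|replacement prompts))`
  from a top-k probability readout; one-sample *t*, Cohen's *d* with
  normal-approximation CI, JZS Bayes factor, and the prestige–q Pearson
  correlation.
* **Meta-analysis** (`stereolang.metaanalysis`) — fixed, DerSimonian–Laird,
  and REML inverse-variance pooling.
* **Synthetic data** (`stereolang.synthetic`) — seeded generators with
  planted biases/contrasts/slopes for parameter-recovery testing.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
from stereolang.llmprobe import summary_from_stats, jzs_bayes_factor
from stereolang.synthetic import ProbeSpec, gen_probe_table
from stereolang.llmprobe import q_score, prestige_correlation

# 1. published occupation-probe summary (mean q = -0.551, SD = 1.920, n = 65)
s = summary_from_stats(mean=-0.551, sd=1.920, n=65)
print(f"t({s.df}) = {s.t:.3f}, p = {s.p:.3f}, d = {s.d:.3f}, "
      f"95% CI [{s.d_ci_low:.3f}, {s.d_ci_high:.3f}]")
print(f"BF10 = {jzs_bayes_factor(s.t, s.n):.3f}")

# 2. synthetic probe table with a planted prestige slope, recovered
fx = gen_probe_table(ProbeSpec(n_occupations=65, slope=0.8, noise_sd=0.6, seed=1))
print(prestige_correlation(fx.probes))
```

prints

```
t(64) = -2.314, p = 0.024, d = -0.287, 95% CI [-0.535, -0.039]
BF10 = 1.613
{'r': 0.82410295065524, 'p': 3.3896964540490764e-17, 'n': 65}
```

The first block turns a mean/SD/n summary of occupation q scores into the
one-sample test (occupations lean toward "replaced by AI" on average, a
small effect with only weak Bayesian support). The second plants a
prestige→q slope of 0.8 SD with noise 0.6 and recovers the implied
correlation (0.8/√(0.8²+0.6²) = 0.8) within sampling error.

## The analysis chain

Numbered drivers under `analysis/` run the full study pipeline on synthetic
inputs and write tables under `results/`:

```bash
python analysis/01_simulate_inputs.py        # corpora, lexicons, mock tables
python analysis/02_embedding_associations.py # SC-WEAT per corpus + pooled
python analysis/03_fillmask_associations.py  # FMAT contrasts on the mock LM
python analysis/04_competence_warmth_space.py# 4D distances + status contrast
python analysis/05_occupation_probe.py       # q scores, t/d/BF, prestige r
python analysis/06_meta_analysis.py          # pooled effects across branches
```

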