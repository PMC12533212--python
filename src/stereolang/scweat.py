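"""Single-Category Word Embedding Association Test (SC-WEAT).

For a single target category (e.g. AI-related words) and one attribute
contrast (e.g. high vs low competence), each target word w gets an
association score

    s(w) = mean_a cos(w, a) - mean_b cos(w, b)

over the high-pole words a and low-pole words b. Three estimators summarize
the scores:

* :func:`scweat_effect` — the classic SC-WEAT effect size
  d = mean(s) / sd(s) over target words, for one model × dictionary;
* :func:`permutation_pvalue` — WEAT-style inference by re-partitioning the
  pooled attribute set into same-sized high/low sides;
* :func:`pooled_regression` — the standardized-regression estimator: every
  (target word × attribute word) cosine similarity is one observation,
  scaled to unit SD within model × dictionary and regressed on the attribute
  polarity (high = 1, low = 0), so the slope reads as Cohen's d and can pool
  across embedding models.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import EffectEstimate, polarity_ols, standardize_within
from .embeddings import EmbeddingModel, cosine, resolve_vector
from .errors import DegenerateInputError, DesignError, OOVError
from .lexicons import ContrastPair, Lexicon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationRecord:
    """One target word's association score under one contrast in one model."""

    target: str
    contrast: str
    model_id: str
    dictionary_id: str
    score: float
    n_high: int
    n_low: int

    def __post_init__(self):
        if not (-2.0 <= self.score <= 2.0):
            raise ValueError(f"association score {self.score} outside [-2, 2]")
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("attribute-set sizes must be >= 1")


def _resolve_side(model: EmbeddingModel, lexicon: Lexicon, oov: str):
    """Resolve a lexicon to vectors under the OOV policy ('error' or 'skip')."""
    vecs, kept = [], []
    for lex in lexicon.words:
        try:
            vecs.append(resolve_vector(model, lex))
            kept.append(lex)
        except OOVError:
            if oov == "error":
                raise
            logger.warning("skipping OOV lexeme '%s' in model '%s'", lex, model.id)
    return kept, vecs


def association_score(model: EmbeddingModel, target: str, pair: ContrastPair,
                      dictionary_id: str = "", oov: str = "error") -> AssociationRecord:
    """Difference of mean cosine similarities to the two attribute poles.

    ``oov='skip'`` drops unresolvable attribute words (logged) and records the
    attribute counts actually used; the target itself must always resolve.
    """
    w = resolve_vector(model, target)
    _, high_vecs = _resolve_side(model, pair.high, oov)
    _, low_vecs = _resolve_side(model, pair.low, oov)
    if not high_vecs or not low_vecs:
        raise DegenerateInputError(
            f"no resolvable attribute word on one side of contrast '{pair.label}'")
    s_high = float(np.mean([cosine(w, a) for a in high_vecs]))
    s_low = float(np.mean([cosine(w, b) for b in low_vecs]))
    return AssociationRecord(
        target=target, contrast=pair.label, model_id=model.id,
        dictionary_id=dictionary_id, score=s_high - s_low,
        n_high=len(high_vecs), n_low=len(low_vecs),
    )


def scweat_effect(records: list[AssociationRecord],
                  source: dict | None = None) -> EffectEstimate:
    """Classic SC-WEAT effect size: mean / SD of the per-target scores."""
    if len(records) < 2:
        raise DegenerateInputError("need >= 2 target-word scores")
    scores = np.array([r.score for r in records], dtype=np.float64)
    if np.ptp(scores) == 0.0:
        raise DegenerateInputError("zero variance across target scores; d undefined")
    sd = scores.std(ddof=1)
    n = len(scores)
    d = float(scores.mean() / sd)
    se = 1.0 / math.sqrt(n)  # SE of a mean of unit-SD standardized scores
    return EffectEstimate(
        estimate=d, se=se, ci_low=d - 1.96 * se, ci_high=d + 1.96 * se,
        p=float(2 * (1 - _norm_cdf(abs(d) / se))), n_obs=n,
        source=source or {"method": "scweat"},
    )


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _mean_association(target_vecs, high_vecs, low_vecs) -> float:
    scores = [
        np.mean([cosine(w, a) for a in high_vecs])
        - np.mean([cosine(w, b) for b in low_vecs])
        for w in target_vecs
    ]
    return float(np.mean(scores))


def permutation_pvalue(model: EmbeddingModel, targets: Lexicon, pair: ContrastPair,
                       n_perm: int | str = 10_000, seed: int | None = None,
                       oov: str = "error") -> float:
    """One-sided permutation p-value for the mean association score.

    The pooled attribute set is re-partitioned into high/low sides of the
    original sizes; p is the fraction of partitions whose mean association is
    >= the observed one. ``n_perm='exhaustive'`` enumerates all C(n, n_high)
    partitions (the observed partition is included, so p is in (0, 1]);
    otherwise ``n_perm`` seeded random partitions are drawn and p uses
    add-one smoothing (k + 1) / (n_perm + 1).
    """
    target_vecs = [resolve_vector(model, t) for t in targets.words]
    _, high_vecs = _resolve_side(model, pair.high, oov)
    _, low_vecs = _resolve_side(model, pair.low, oov)
    pooled = high_vecs + low_vecs
    n_high = len(high_vecs)
    if len(pooled) < 2:
        raise DegenerateInputError("pooled attribute set must have >= 2 words")
    observed = _mean_association(target_vecs, high_vecs, low_vecs)

    if n_perm == "exhaustive":
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n_high):
            hi = [pooled[i] for i in idx]
            lo = [pooled[i] for i in range(len(pooled)) if i not in idx]
            stat = _mean_association(target_vecs, hi, lo)
            count += stat >= observed - 1e-12
            total += 1
        return count / total

    if not isinstance(n_perm, int) or n_perm < 1:
        raise ValueError("n_perm must be a positive integer or 'exhaustive'")
    if seed is None:
        raise ValueError("seed is required for random permutations")
    rng = np.random.default_rng(seed)
    k = 0
    indices = np.arange(len(pooled))
    for _ in range(n_perm):
        rng.shuffle(indices)
        hi = [pooled[i] for i in indices[:n_high]]
        lo = [pooled[i] for i in indices[n_high:]]
        k += _mean_association(target_vecs, hi, lo) >= observed - 1e-12
    return (k + 1) / (n_perm + 1)


def similarity_table(model: EmbeddingModel, targets: Lexicon, pair: ContrastPair,
                     dictionary_id: str = "", oov: str = "error") -> pd.DataFrame:
    """Long-form (target word × attribute word) cosine similarities.

    Columns: ``model_id, dictionary_id, contrast, target, attribute,
    polarity`` (1 = high pole, 0 = low pole), ``similarity``. This is the
    observation unit of :func:`pooled_regression`.
    """
    rows = []
    for tgt in targets.words:
        try:
            w = resolve_vector(model, tgt)
        except OOVError:
            if oov == "error":
                raise
            logger.warning("skipping OOV target '%s' in model '%s'", tgt, model.id)
            continue
        for side, polarity in ((pair.high, 1), (pair.low, 0)):
            kept, vecs = _resolve_side(model, side, oov)
            for lex, a in zip(kept, vecs):
                rows.append({
                    "model_id": model.id, "dictionary_id": dictionary_id,
                    "contrast": pair.label, "target": tgt, "attribute": lex,
                    "polarity": polarity, "similarity": cosine(w, a),
                })
    if not rows:
        raise DegenerateInputError("no resolvable target/attribute combinations")
    return pd.DataFrame(rows)


def pooled_regression(table: pd.DataFrame, source: dict | None = None) -> EffectEstimate:
    """Standardized-regression effect pooled across embedding models.

    Similarities are scaled to unit SD within each model × dictionary cell,
    then regressed on the polarity indicator; the slope is the standardized
    mean difference between the high and low attribute poles (Cohen's d).
    ``table`` may come from one or several :func:`similarity_table` calls
    concatenated.
    """
    required = {"model_id", "dictionary_id", "polarity", "similarity"}
    missing = required - set(table.columns)
    if missing:
        raise DesignError(f"similarity table missing columns: {sorted(missing)}")
    if table["polarity"].nunique() < 2:
        raise DesignError("both polarities must be present")
    cell = table["model_id"].astype(str) + "␟" + table["dictionary_id"].astype(str)
    std = standardize_within(table["similarity"], cell)
    return polarity_ols(std.to_numpy(), table["polarity"].to_numpy(),
                        source=source or {"method": "scweat_pooled"})
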