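"""Fill-Mask Association Test (FMAT).

A masked language model is asked how probable a target word is at the masked
slot of a propositional query such as ``"The [MASK] is {ATTRIB}"``, with the
attribute slot alternating between the two poles of a word pair ("warm" vs
"cold"). The per-pair contrast

    logp_high - logp_low

measures how much more natural the model finds the target in the high-pole
context. Contrasts are summarized with the same polarity-coded standardized
regression as the embedding branch.

The masked LM is injected through a minimal adapter contract
(:class:`MaskedLMAdapter`); :class:`MockMaskedLM` serves a fixed probability
table so the whole module is deterministic and byte-reproducible offline.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Protocol

import numpy as np
import pandas as pd

from .effects import EffectEstimate, polarity_ols, standardize_within
from .errors import DegenerateInputError, TemplateError, TokenizationError
from .lexicons import ContrastPair, Lexicon

MASK_SLOT = "[MASK]"
ATTRIB_SLOT = "{ATTRIB}"


@dataclass(frozen=True)
class MaskQuery:
    """One rendered fill-mask query.

    The template must contain exactly one ``[MASK]`` slot (where the target
    word is scored) and one ``{ATTRIB}`` slot (filled by ``attrib_word``).
    ``pair_index`` and ``polarity`` tie the high/low variants of one attribute
    word pair together.
    """

    template: str
    attrib_word: str
    target_word: str
    query_id: str
    pair_index: int = 0
    polarity: int = 1  # 1 = high-pole attribute, 0 = low-pole

    def __post_init__(self):
        if self.template.count(MASK_SLOT) != 1:
            raise TemplateError(
                f"template must contain exactly one {MASK_SLOT} slot: {self.template!r}")
        if self.template.count(ATTRIB_SLOT) != 1:
            raise TemplateError(
                f"template must contain exactly one {ATTRIB_SLOT} slot: "
                f"{self.template!r}")

    @property
    def context(self) -> str:
        """The query text with the attribute filled and the mask left in place."""
        return self.template.replace(ATTRIB_SLOT, self.attrib_word)


@dataclass(frozen=True)
class FillMaskObservation:
    """The scored high/low pair for one (template, target, word-pair) cell."""

    query_id: str
    model_id: str
    target_word: str
    attrib_high_word: str
    attrib_low_word: str
    logp_high: float
    logp_low: float

    def __post_init__(self):
        if self.logp_high > 1e-12 or self.logp_low > 1e-12:
            raise ValueError("log-probabilities must be <= 0")
        if not (np.isfinite(self.logp_high) and np.isfinite(self.logp_low)):
            raise ValueError("log-probabilities must be finite")

    @property
    def contrast(self) -> float:
        return self.logp_high - self.logp_low


class MaskedLMAdapter(Protocol):
    """Anything that can report p(token at mask | context)."""

    model_id: str

    def mask_probability(self, context: str, token: str) -> float:
        """Probability in (0, 1] of ``token`` at the mask; raises
        :class:`TokenizationError` if the token cannot be scored."""
        ...


class MockMaskedLM:
    """Adapter backed by a fixed ``(query context or id, token) -> p`` table.

    Keys may be either the rendered context string or a query id; unknown
    combinations raise :class:`TokenizationError`, mirroring a target that is
    not a single vocabulary token for a real model.
    """

    def __init__(self, table: dict[tuple[str, str], float], model_id: str = "mock"):
        for (ctx, tok), p in table.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"probability for ({ctx!r}, {tok!r}) outside (0, 1]")
        self.table = dict(table)
        self.model_id = model_id

    def mask_probability(self, context: str, token: str) -> float:
        try:
            return self.table[(context, token)]
        except KeyError:
            raise TokenizationError(
                f"mock adapter has no probability for ({context!r}, {token!r})"
            ) from None


def build_queries(templates: list[str], targets: Lexicon,
                  pair: ContrastPair) -> list[MaskQuery]:
    """Cartesian product templates × targets × attribute word pairs.

    The two attribute lexicons are aligned positionally into word pairs (the
    published dictionaries come as antonym pairs), so they must have equal
    length. Each word pair yields two rendered queries (high and low variant),
    deterministically ordered.
    """
    if len(pair.high) != len(pair.low):
        raise TemplateError(
            f"contrast '{pair.label}': attribute poles must pair up one-to-one "
            f"({len(pair.high)} vs {len(pair.low)} words)")
    queries = []
    for ti, template in enumerate(templates):
        for wi, target in enumerate(targets.words):
            for pi, (hi, lo) in enumerate(zip(pair.high.words, pair.low.words)):
                for polarity, attrib in ((1, hi), (0, lo)):
                    queries.append(MaskQuery(
                        template=template, attrib_word=attrib, target_word=target,
                        query_id=f"t{ti}.w{wi}.p{pi}.{'hi' if polarity else 'lo'}",
                        pair_index=pi + 1000 * (wi + 1000 * ti), polarity=polarity,
                    ))
    return queries


def score_mask(adapter: MaskedLMAdapter, query: MaskQuery) -> float:
    """Natural-log probability of the target word at the query's mask."""
    p = adapter.mask_probability(query.context, query.target_word)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"adapter returned invalid probability {p}")
    return log(p)


def collect_observations(adapter: MaskedLMAdapter,
                         queries: list[MaskQuery]) -> list[FillMaskObservation]:
    """Score paired queries into :class:`FillMaskObservation` rows.

    Queries are grouped by (template, target, pair_index); a group missing
    either polarity, or whose target the adapter cannot tokenize, is skipped.
    """
    groups: dict[tuple, dict[int, MaskQuery]] = {}
    for q in queries:
        groups.setdefault((q.template, q.target_word, q.pair_index), {})[q.polarity] = q
    observations = []
    for (_, target, _), variants in groups.items():
        if set(variants) != {0, 1}:
            continue
        hi, lo = variants[1], variants[0]
        try:
            lp_hi = score_mask(adapter, hi)
            lp_lo = score_mask(adapter, lo)
        except TokenizationError:
            continue
        observations.append(FillMaskObservation(
            query_id=hi.query_id.rsplit(".", 1)[0], model_id=adapter.model_id,
            target_word=target, attrib_high_word=hi.attrib_word,
            attrib_low_word=lo.attrib_word, logp_high=lp_hi, logp_low=lp_lo,
        ))
    return observations


def mean_contrast(observations: list[FillMaskObservation]) -> tuple[float, float]:
    """Raw mean log-probability contrast and its standard error.

    This is the natural scale of a planted contrast delta; the standardized
    estimator below divides by the log-probability SD.
    """
    if not observations:
        raise DegenerateInputError("no observations")
    contrasts = np.array([o.contrast for o in observations])
    n = len(contrasts)
    se = float(contrasts.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(contrasts.mean()), se


def fmat_association(observations: list[FillMaskObservation],
                     source: dict | None = None) -> EffectEstimate:
    """Polarity-coded standardized regression over fill-mask log-probabilities.

    Each observation contributes two rows (logp_high with polarity 1,
    logp_low with polarity 0); log-probabilities are scaled to unit SD within
    each masked LM before the pooled OLS, so the slope reads as Cohen's d,
    mirroring the embedding-branch estimator.
    """
    if len(observations) < 2:
        raise DegenerateInputError("need >= 2 observations")
    rows = []
    for o in observations:
        rows.append({"model_id": o.model_id, "polarity": 1, "logp": o.logp_high})
        rows.append({"model_id": o.model_id, "polarity": 0, "logp": o.logp_low})
    table = pd.DataFrame(rows)
    std = standardize_within(table["logp"], table["model_id"])
    return polarity_ols(std.to_numpy(), table["polarity"].to_numpy(),
                        source=source or {"method": "fmat"})
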