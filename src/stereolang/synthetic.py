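"""Seeded synthetic-data generators with known ground truth.

Every analysis stage in this package normally consumes external artifacts
(pretrained embeddings, masked-LM probabilities, generative-LM top-k logs).
The generators here produce inputs with the same statistical structure but a
*planted*, recorded effect, so each estimator can be verified offline by
parameter recovery:

* :func:`gen_embeddings` — an embedding table whose target words lean toward
  the high-attribute centroid by a controlled mixing weight ``bias``;
* :func:`gen_fillmask_table` — a mock masked-LM table with a planted mean
  log-probability contrast ``delta`` between attribute poles;
* :func:`gen_probe_table` — an occupation/prestige table plus a mock top-k
  provider whose q scores follow a planted linear prestige relationship.

All generators are pure functions of their spec (seed included): re-running
with the same spec yields identical output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .embeddings import EmbeddingModel
from .errors import StereolangError
from .fmat import MaskQuery, MockMaskedLM, build_queries
from .lexicons import ContrastPair, Lexicon, make_contrast
from .llmprobe import MockProvider, OccupationProbe, PromptSet


@dataclass(frozen=True)
class EmbeddingSpec:
    """Geometry of a synthetic embedding table.

    ``bias`` in [0, 1] is the mixing weight of each target direction toward
    the high-attribute centroid: 0 plants no association, 1 aligns every
    target with the high pole. ``noise_sd`` is per-coordinate Gaussian noise
    added to every vector.
    """

    dimension: int = 50
    n_targets: int = 40
    n_high: int = 25
    n_low: int = 25
    bias: float = 0.2
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.dimension < 2:
            raise StereolangError("dimension must be >= 2")
        if min(self.n_targets, self.n_high, self.n_low) < 1:
            raise StereolangError("counts must be >= 1")
        if not (0.0 <= self.bias <= 1.0):
            raise StereolangError("bias must be in [0, 1]")
        if self.noise_sd <= 0:
            raise StereolangError("noise_sd must be > 0")


@dataclass(frozen=True)
class EmbeddingTruth:
    """Ground truth stored alongside a generated embedding model."""

    bias: float
    noise_sd: float
    centroid_high: np.ndarray
    centroid_low: np.ndarray


def _random_unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def gen_embeddings(spec: EmbeddingSpec) -> tuple[EmbeddingModel, Lexicon,
                                                 ContrastPair, EmbeddingTruth]:
    """Generate an embedding table with a planted target→high-pole bias.

    The two attribute centroids are a random orthonormal pair; attribute
    vectors are isotropic Gaussian clouds around them. Each target direction
    is ``bias * centroid_high + (1 - bias) * u`` for a fresh random unit
    vector u, plus noise — at bias 0 targets carry no systematic association,
    at bias 1 (and vanishing noise) every association score is positive.
    """
    rng = np.random.default_rng(spec.seed)
    c_high = _random_unit(rng, spec.dimension)
    v = rng.standard_normal(spec.dimension)
    v -= v.dot(c_high) * c_high
    c_low = v / np.linalg.norm(v)

    vectors: dict[str, np.ndarray] = {}
    high_words, low_words, target_words = [], [], []
    for i in range(spec.n_high):
        w = f"high{i:03d}"
        high_words.append(w)
        vectors[w] = c_high + rng.normal(0.0, spec.noise_sd, spec.dimension)
    for i in range(spec.n_low):
        w = f"low{i:03d}"
        low_words.append(w)
        vectors[w] = c_low + rng.normal(0.0, spec.noise_sd, spec.dimension)
    for i in range(spec.n_targets):
        w = f"target{i:03d}"
        target_words.append(w)
        direction = spec.bias * c_high + (1.0 - spec.bias) * _random_unit(
            rng, spec.dimension)
        vectors[w] = direction + rng.normal(0.0, spec.noise_sd, spec.dimension)

    model = EmbeddingModel(id=f"synthetic-seed{spec.seed}", dimension=spec.dimension,
                           vectors=vectors,
                           metadata=f"planted bias={spec.bias}, noise={spec.noise_sd}")
    targets = Lexicon("synthetic_targets", "target", tuple(target_words), "none")
    pair = make_contrast(
        Lexicon("synthetic_high", "attribute", tuple(high_words), "high", "competence"),
        Lexicon("synthetic_low", "attribute", tuple(low_words), "low", "competence"),
        label="synthetic",
    )
    truth = EmbeddingTruth(bias=spec.bias, noise_sd=spec.noise_sd,
                           centroid_high=c_high, centroid_low=c_low)
    return model, targets, pair, truth


@dataclass(frozen=True)
class FillMaskTruth:
    delta: float
    noise_sd: float
    contrasts: tuple[float, ...]  # realized logp_high - logp_low per pair


def gen_fillmask_table(delta: float, n_pairs: int, noise_sd: float = 0.0,
                       seed: int = 0,
                       template: str = "the [MASK] is {ATTRIB}.",
                       target: str = "ai") -> tuple[MockMaskedLM, list[MaskQuery],
                                                    FillMaskTruth]:
    """Mock masked-LM fixture with a planted log-probability contrast.

    Per attribute word pair i the low-pole base probability is drawn
    log-uniformly in [0.01, 0.2] and the high-pole log-probability is
    ``logp_low + delta + N(0, noise_sd)``. A draw that would exceed
    probability 1 is shifted down pairwise (preserving the contrast) with a
    warning.
    """
    if n_pairs < 2:
        raise StereolangError("n_pairs must be >= 2")
    if noise_sd < 0:
        raise StereolangError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    high_words = tuple(f"good{i:03d}" for i in range(n_pairs))
    low_words = tuple(f"bad{i:03d}" for i in range(n_pairs))
    pair = make_contrast(
        Lexicon("fm_high", "attribute", high_words, "high", "warmth"),
        Lexicon("fm_low", "attribute", low_words, "low", "warmth"),
        label="synthetic_fm",
    )
    targets = Lexicon("fm_targets", "target", (target,), "none")
    queries = build_queries([template], targets, pair)

    table: dict[tuple[str, str], float] = {}
    contrasts = []
    for hi_w, lo_w in zip(high_words, low_words):
        logp_low = float(rng.uniform(np.log(0.01), np.log(0.2)))
        logp_high = logp_low + delta + float(rng.normal(0.0, noise_sd)) if noise_sd \
            else logp_low + delta
        if logp_high > 0.0:
            shift = logp_high
            warnings.warn("planted contrast pushed a probability above 1; "
                          "pair renormalized", stacklevel=2)
            logp_high -= shift
            logp_low -= shift
        ctx_hi = template.replace("{ATTRIB}", hi_w)
        ctx_lo = template.replace("{ATTRIB}", lo_w)
        table[(ctx_hi, target)] = float(np.exp(logp_high))
        table[(ctx_lo, target)] = float(np.exp(logp_low))
        contrasts.append(logp_high - logp_low)
    adapter = MockMaskedLM(table, model_id=f"mock-seed{seed}")
    return adapter, queries, FillMaskTruth(delta=delta, noise_sd=noise_sd,
                                           contrasts=tuple(contrasts))


@dataclass(frozen=True)
class ProbeSpec:
    """Planted prestige→q relationship for the generative-LM probe.

    ``slope`` is the effect of standardized prestige on the true q score;
    ``noise_sd`` is occupation-level Gaussian noise around that line;
    ``n_obs_per_family`` probability observations are produced per occupation
    per prompt family.
    """

    n_occupations: int = 65
    prestige_range: tuple[float, float] = (20.0, 80.0)
    slope: float = 0.8
    noise_sd: float = 0.3
    n_obs_per_family: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_occupations < 3:
            raise StereolangError("n_occupations must be >= 3")
        if self.n_obs_per_family < 1:
            raise StereolangError("n_obs_per_family must be >= 1")
        if self.noise_sd < 0:
            raise StereolangError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ProbeFixture:
    """Everything needed to run the probe pipeline end to end offline."""

    occupations: tuple[str, ...]
    prestige: dict[str, float]
    q_true: dict[str, float]
    probes: list[OccupationProbe]  # lists built directly, bypassing the provider
    provider: MockProvider
    prompt_set: PromptSet


def gen_probe_table(spec: ProbeSpec) -> ProbeFixture:
    """Occupation table + mock provider with q scores linear in prestige.

    Prestige values are spread uniformly over ``prestige_range``; the true
    score is ``q_true = slope * z(prestige) + N(0, noise_sd)``. Probability
    lists are constructed so that ln(mean benefit / mean replacement) equals
    q_true *exactly*: the replacement family has a fixed mean and the benefit
    family mean is that times exp(q_true), each list spread symmetrically
    around its mean. The provider serves one template per observation index,
    so running :func:`~stereolang.llmprobe.make_batches` with the bundled
    prompt set and collecting probabilities reproduces the same lists.
    """
    rng = np.random.default_rng(spec.seed)
    occupations = tuple(f"occupation{i:03d}" for i in range(spec.n_occupations))
    lo, hi = spec.prestige_range
    prestige_vals = np.linspace(lo, hi, spec.n_occupations)
    z = (prestige_vals - prestige_vals.mean()) / prestige_vals.std(ddof=1)
    noise = rng.normal(0.0, spec.noise_sd, spec.n_occupations) if spec.noise_sd \
        else np.zeros(spec.n_occupations)
    q_true_vals = spec.slope * z + noise

    base_replacement = 0.02
    # keep every probability in (0, 1] even at the largest planted q
    max_mean = base_replacement * float(np.exp(q_true_vals.max()))
    scale = 1.0
    if max_mean * 1.2 > 1.0:
        scale = 1.0 / (max_mean * 1.2)
        warnings.warn("planted q range pushed probabilities above 1; "
                      "both families rescaled", stacklevel=2)

    n = spec.n_obs_per_family
    # symmetric multipliers with mean exactly 1 (pairs 1±eps, plus a 1 if odd)
    eps = 0.1
    mult = []
    for i in range(n // 2):
        mult += [1.0 + eps * (i + 1) / n, 1.0 - eps * (i + 1) / n]
    if n % 2:
        mult.append(1.0)
    mult = np.array(mult)

    benefit_templates = tuple(
        f"the occupation most likely to benefit from artificial intelligence "
        f"is {{MASK}} (run {i})" for i in range(n))
    replacement_templates = tuple(
        f"the job most likely to be replaced by artificial intelligence "
        f"is {{MASK}} (run {i})" for i in range(n))

    probes, q_true, prestige = [], {}, {}
    provider_table: dict[str, dict[str, float]] = {t: {} for t in
                                                   benefit_templates +
                                                   replacement_templates}
    for occ, pres, q in zip(occupations, prestige_vals, q_true_vals):
        m_rep = base_replacement * scale
        m_ben = m_rep * float(np.exp(q))
        p_ben = (m_ben * mult).tolist()
        p_rep = (m_rep * mult).tolist()
        probes.append(OccupationProbe(occupation=occ, prestige=float(pres),
                                      p_benefit=p_ben, p_replacement=p_rep))
        q_true[occ] = float(q)
        prestige[occ] = float(pres)
        for t, p in zip(benefit_templates, p_ben):
            provider_table[t][occ] = p
        for t, p in zip(replacement_templates, p_rep):
            provider_table[t][occ] = p

    provider = MockProvider(provider_table)
    prompt_set = PromptSet(
        benefit_templates=benefit_templates,
        replacement_templates=replacement_templates,
        occupations=occupations,
        batch_size=spec.n_occupations,  # full list per batch: deterministic coverage
        min_appearances=n, seed=spec.seed,
    )
    return ProbeFixture(occupations=occupations, prestige=prestige, q_true=q_true,
                        probes=probes, provider=provider, prompt_set=prompt_set)
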