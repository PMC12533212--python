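"""Log-ratio probing of a generative LM's benefit-vs-replacement associations.

A generative model is prompted with two families of cloze prompts — *benefit*
("The occupation that is more likely to benefit from Artificial Intelligence
is {MASK}") and *replacement* ("The job that is most likely to be replaced by
Artificial Intelligence is {MASK}") — while reading out the top-k token
probabilities at the mask. Batches of candidate occupations are drawn at
random until each occupation has been scheduled at least ``min_appearances``
times under both families. Each occupation x then gets a score

    q(x; v) = ln( mean_i p(x | v_benefit(t_i)) / mean_j p(x | v_replacement(t_j)) )

so q > 0 means the model associates x more with benefiting from AI than with
being replaced by it. Downstream statistics: one-sample t-test / Cohen's d
with normal-approximation CI, a JZS Bayes factor, and the Pearson correlation
between q and occupational prestige.

The provider is injected; :class:`MockProvider` serves fixed probability
tables so everything is deterministic offline.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy import integrate, stats

from .errors import DegenerateInputError, InsufficientDataError, StereolangError

MASK = "{MASK}"


@dataclass(frozen=True)
class PromptSet:
    """Configuration of the probing run.

    ``batch_size`` occupations are embedded as candidates per prompt;
    batching repeats until every occupation has at least ``min_appearances``
    scheduled appearances under each prompt family.
    """

    benefit_templates: tuple[str, ...]
    replacement_templates: tuple[str, ...]
    occupations: tuple[str, ...]
    batch_size: int = 20
    min_appearances: int = 100
    seed: int = 0

    def __post_init__(self):
        if not self.benefit_templates or not self.replacement_templates:
            raise StereolangError("both prompt families need >= 1 template")
        if self.batch_size > len(self.occupations):
            raise StereolangError("batch_size cannot exceed the occupation count")
        if self.batch_size < 1 or self.min_appearances < 1:
            raise StereolangError("batch_size and min_appearances must be >= 1")


@dataclass(frozen=True)
class ProbeTask:
    """One prompt with its candidate occupation batch."""

    family: str  # "benefit" | "replacement"
    template: str
    candidates: tuple[str, ...]


@dataclass
class OccupationProbe:
    """Per-occupation probability samples and the derived q score."""

    occupation: str
    prestige: Optional[float] = None
    p_benefit: list[float] = field(default_factory=list)
    p_replacement: list[float] = field(default_factory=list)

    @property
    def n1(self) -> int:
        return len(self.p_benefit)

    @property
    def n2(self) -> int:
        return len(self.p_replacement)

    @property
    def q(self) -> float:
        return q_score(self)


class TopKProvider(Protocol):
    """A generative-LM interface returning top-k token probabilities."""

    def top_tokens(self, prompt: str, candidates: Sequence[str],
                   k: int = 20) -> dict[str, float]:
        """Probabilities of the (up to) k most probable candidates at the
        prompt's mask; candidates outside the top-k are absent from the map."""
        ...


class MockProvider:
    """Provider backed by a fixed ``template -> {occupation: p}`` table.

    For each prompt the k most probable candidates (by the table) are
    returned, emulating a top-k readout: a candidate outside the top-k is
    missing from the result, not zero.
    """

    def __init__(self, table: dict[str, dict[str, float]]):
        for template, probs in table.items():
            for occ, p in probs.items():
                if not (0.0 < p <= 1.0):
                    raise ValueError(
                        f"probability for ({template!r}, {occ!r}) outside (0, 1]")
        self.table = {t: dict(p) for t, p in table.items()}

    def top_tokens(self, prompt: str, candidates: Sequence[str],
                   k: int = 20) -> dict[str, float]:
        probs = self.table.get(prompt, {})
        known = [(occ, probs[occ]) for occ in candidates if occ in probs]
        known.sort(key=lambda kv: (-kv[1], kv[0]))
        return dict(known[:k])


def make_batches(ps: PromptSet, max_iterations: int = 1_000_000) -> list[ProbeTask]:
    """Seeded random batching until every occupation reaches min_appearances.

    Each iteration draws one template per family (cycling) and one random
    ``batch_size``-subset of occupations per family. Deterministic for a
    fixed :class:`PromptSet` (the seed is part of the spec). Raises if the
    iteration cap is hit before coverage is reached.
    """
    rng = np.random.default_rng(ps.seed)
    occupations = np.array(ps.occupations)
    counts = {fam: {occ: 0 for occ in ps.occupations}
              for fam in ("benefit", "replacement")}
    templates = {"benefit": ps.benefit_templates,
                 "replacement": ps.replacement_templates}
    tasks: list[ProbeTask] = []
    it = 0
    while any(c < ps.min_appearances for fam in counts for c in counts[fam].values()):
        if it >= max_iterations:
            raise StereolangError(
                f"batch generation exceeded {max_iterations} iterations before "
                f"reaching min_appearances={ps.min_appearances}")
        for fam in ("benefit", "replacement"):
            template = templates[fam][it % len(templates[fam])]
            batch = rng.choice(occupations, size=ps.batch_size, replace=False)
            for occ in batch:
                counts[fam][str(occ)] += 1
            tasks.append(ProbeTask(family=fam, template=template,
                                   candidates=tuple(str(o) for o in batch)))
        it += 1
    return tasks


def collect_probabilities(provider: TopKProvider, tasks: Sequence[ProbeTask],
                          prestige: Optional[dict[str, float]] = None,
                          k: int = 20) -> list[OccupationProbe]:
    """Run tasks against a provider and assemble per-occupation probes.

    An occupation absent from a task's top-k contributes no observation for
    that task (missingness is not imputed as zero). Occupations with no
    observations at all in either family are excluded with a warning.
    """
    probes: dict[str, OccupationProbe] = {}
    for task in tasks:
        result = provider.top_tokens(task.template, task.candidates, k=k)
        for occ, p in result.items():
            probe = probes.setdefault(occ, OccupationProbe(
                occupation=occ,
                prestige=(prestige or {}).get(occ)))
            if task.family == "benefit":
                probe.p_benefit.append(p)
            else:
                probe.p_replacement.append(p)
    kept = []
    for occ, probe in probes.items():
        if probe.n1 == 0 or probe.n2 == 0:
            warnings.warn(f"occupation '{occ}' has no observations in one family; "
                          f"excluded", stacklevel=2)
            continue
        kept.append(probe)
    kept.sort(key=lambda p: p.occupation)
    return kept


def q_score(probe: OccupationProbe) -> float:
    """q(x; v) = ln(mean benefit probability / mean replacement probability).

    Positive q: the occupation is associated more with benefiting from AI;
    negative q: more with being replaced by it. Invariant to rescaling all
    probabilities by a common factor and exactly antisymmetric under swapping
    the two families.
    """
    if probe.n1 < 1 or probe.n2 < 1:
        raise InsufficientDataError(
            f"occupation '{probe.occupation}': both families need >= 1 observation")
    m1 = float(np.mean(probe.p_benefit))
    m2 = float(np.mean(probe.p_replacement))
    if m2 <= 0.0:
        raise DegenerateInputError(
            f"occupation '{probe.occupation}': mean replacement probability is 0")
    return math.log(m1 / m2)


@dataclass(frozen=True)
class OneSampleSummary:
    """One-sample t-test of the q scores against 0, with Cohen's d."""

    mean: float
    sd: float
    n: int
    t: float
    df: int
    p: float
    d: float
    d_ci_low: float
    d_ci_high: float


def summary_from_stats(mean: float, sd: float, n: int) -> OneSampleSummary:
    """One-sample summary from sufficient statistics (mean, SD, n).

    t = mean / (sd/√n) with df = n−1; d = mean/sd; the d 95% CI uses the
    normal approximation SE(d) = √(1/n + d²/(2n)).
    """
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    if sd <= 0:
        raise DegenerateInputError("zero standard deviation; t undefined")
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    d = mean / sd
    se_d = math.sqrt(1.0 / n + d * d / (2.0 * n))
    return OneSampleSummary(mean=mean, sd=sd, n=n, t=t, df=df, p=p, d=d,
                            d_ci_low=d - 1.96 * se_d, d_ci_high=d + 1.96 * se_d)


def one_sample_summary(q_scores: Sequence[float]) -> OneSampleSummary:
    """One-sample t, Cohen's d and d CI for a list of q scores."""
    q = np.asarray(q_scores, dtype=np.float64)
    if len(q) < 2:
        raise InsufficientDataError("need >= 2 q scores")
    sd = float(q.std(ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("zero variance in q scores")
    return summary_from_stats(float(q.mean()), sd, len(q))


def jzs_bayes_factor(t: float, n: int, prior_scale: float = math.sqrt(2) / 2) -> float:
    """One-sample JZS Bayes factor BF10 by numerical integration.

    The alternative places a Cauchy(0, ``prior_scale``) prior on the
    standardized effect size, equivalent to an inverse-gamma(1/2, r²/2) prior
    on the g-prior variance; the Bayes factor is the ratio of the marginal
    likelihood under that prior to the point-null likelihood.
    """
    if n < 2:
        raise InsufficientDataError("need n >= 2")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    nu = n - 1
    r2 = prior_scale * prior_scale

    def integrand(g: float) -> float:
        shrink = 1.0 + n * g * r2
        like = shrink ** -0.5 * (1.0 + t * t / (shrink * nu)) ** (-(nu + 1) / 2.0)
        prior = (2.0 * math.pi) ** -0.5 * g ** -1.5 * math.exp(-1.0 / (2.0 * g))
        return like * prior

    numerator, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    denominator = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    bf = numerator / denominator
    if not np.isfinite(bf):
        raise StereolangError("Bayes factor integration did not converge")
    return float(bf)


def prestige_correlation(probes: Sequence[OccupationProbe]) -> dict[str, float]:
    """Pearson correlation between occupational prestige and q scores.

    Occupations without a prestige value are dropped; at least 3 valid pairs
    are required.
    """
    pairs = [(p.prestige, p.q) for p in probes if p.prestige is not None]
    if len(pairs) < 3:
        raise InsufficientDataError("need >= 3 occupations with valid prestige")
    prestige = np.array([a for a, _ in pairs])
    q = np.array([b for _, b in pairs])
    if prestige.std() == 0 or q.std() == 0:
        raise DegenerateInputError("zero variance in prestige or q")
    r, p = stats.pearsonr(prestige, q)
    return {"r": float(r), "p": float(p), "n": len(pairs)}
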