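"""Internal meta-analysis: inverse-variance pooling of effect estimates.

Pools Cohen's-d-scale effects from the embedding and fill-mask branches.
Three estimators of the between-source variance tau²:

* ``fixed`` — tau² := 0, weights 1/v_i;
* ``dl_random`` — DerSimonian–Laird moment estimator
  tau² = max(0, (Q − (k−1)) / C) with C = Σw − Σw²/Σw computed at the
  fixed-effect weights;
* ``reml_random`` — restricted maximum likelihood by Fisher-scoring
  fixed-point iteration (the default of the standard R implementation).

In every case the pooled effect is the weighted mean with weights
1/(v_i + tau²), se = 1/sqrt(Σw), Wald 95% CI and two-sided normal p.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import InsufficientDataError, StereolangError

MetaModel = Literal["fixed", "dl_random", "reml_random"]


@dataclass(frozen=True)
class MetaInput:
    """Effects to pool: (estimate, variance, label) triples plus the model."""

    effects: tuple[tuple[float, float, str], ...]
    model: MetaModel = "reml_random"

    def __post_init__(self):
        if not self.effects:
            raise InsufficientDataError("no effects to pool")
        for est, var, _ in self.effects:
            if var <= 0:
                raise StereolangError(f"effect variance must be > 0, got {var}")
        if self.model not in ("fixed", "dl_random", "reml_random"):
            raise StereolangError(f"unknown meta-analysis model {self.model!r}")
        if self.model != "fixed" and len(self.effects) < 2:
            raise InsufficientDataError(
                "random-effects models need >= 2 effects to estimate tau^2")


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    q_het: float
    k: int
    model: MetaModel

    def __post_init__(self):
        if self.tau2 < 0 or self.q_het < 0:
            raise ValueError("tau2 and Q must be non-negative")


def _weighted_mean(y: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * y) / np.sum(w))


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """DerSimonian–Laird tau² and the heterogeneity statistic Q."""
    w = 1.0 / v
    mu = _weighted_mean(y, w)
    q = float(np.sum(w * (y - mu) ** 2))
    c = float(np.sum(w) - np.sum(w * w) / np.sum(w))
    tau2 = max(0.0, (q - (len(y) - 1)) / c) if c > 0 else 0.0
    return tau2, q


def _reml_tau2(y: np.ndarray, v: np.ndarray, tol: float = 1e-12,
               max_iter: int = 500) -> float:
    """REML tau² by the standard fixed-point iteration.

    tau²_{new} = Σ w²[(y − μ̂)² − v] / Σ w² + 1/Σ w with w = 1/(v + tau²),
    iterated from the DL start; clamped at 0.
    """
    tau2 = _dl_tau2(y, v)[0]
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = _weighted_mean(y, w)
        num = float(np.sum(w * w * ((y - mu) ** 2 - v)))
        new = num / float(np.sum(w * w)) + 1.0 / float(np.sum(w))
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def pool_effects(meta: MetaInput) -> MetaResult:
    """Pool the effects under the requested model; see the module docstring."""
    y = np.array([e for e, _, _ in meta.effects], dtype=np.float64)
    v = np.array([var for _, var, _ in meta.effects], dtype=np.float64)
    k = len(y)
    if k == 1:
        tau2, q = 0.0, 0.0
    elif meta.model == "fixed":
        tau2 = 0.0
        q = _dl_tau2(y, v)[1]
    elif meta.model == "dl_random":
        tau2, q = _dl_tau2(y, v)
    else:
        q = _dl_tau2(y, v)[1]
        tau2 = _reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    pooled = _weighted_mean(y, w)
    se = 1.0 / math.sqrt(float(np.sum(w)))
    z = pooled / se
    p = float(2.0 * (1.0 - _norm_cdf(abs(z))))
    return MetaResult(
        pooled=pooled, se=se, ci_low=pooled - 1.96 * se, ci_high=pooled + 1.96 * se,
        p=p, tau2=tau2, q_het=q, k=k, model=meta.model,
    )


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))
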