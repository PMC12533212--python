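"""Shared effect-size container and the polarity-coded OLS estimator.

The pipeline's central estimator standardizes an outcome to unit SD within a
grouping (one embedding model × dictionary, or one masked LM) and regresses it
on a 1/0 polarity indicator. Because the outcome has SD 1, the slope is a
standardized mean difference and reads directly as Cohen's d.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, DesignError


@dataclass
class EffectEstimate:
    """A point estimate with its uncertainty.

    ``estimate`` is on the Cohen's-d scale whenever the producing operation
    standardized its outcome; ``source`` carries method/study/dimension labels.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_obs: int
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be non-negative")


def standardize_within(values: pd.Series, groups: pd.Series) -> pd.Series:
    """Scale values to unit sample SD within each group (no centering).

    Dividing by the within-group SD puts similarity scales of different
    embedding models on a common footing without moving group means through
    zero, so polarity contrasts keep their sign and magnitude in SD units.
    """
    sds = values.groupby(groups, sort=False).transform(lambda s: s.std(ddof=1))
    if (sds == 0).any() or sds.isna().any():
        raise DegenerateInputError("zero or undefined variance within a group")
    return values / sds


def polarity_ols(outcome: np.ndarray, polarity: np.ndarray,
                 source: dict | None = None) -> EffectEstimate:
    """OLS of an outcome on a 1/0 polarity indicator; slope + 95% CI.

    Requires both polarities present (otherwise the slope is unidentified).
    """
    outcome = np.asarray(outcome, dtype=np.float64)
    polarity = np.asarray(polarity, dtype=np.float64)
    levels = np.unique(polarity)
    if len(levels) < 2:
        raise DesignError("both polarities must be present in the design")
    X = sm.add_constant(polarity)
    fit = sm.OLS(outcome, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return EffectEstimate(
        estimate=float(fit.params[1]), se=float(fit.bse[1]),
        ci_low=float(ci[1][0]), ci_high=float(ci[1][1]),
        p=float(fit.pvalues[1]), n_obs=int(len(outcome)),
        source=source or {},
    )
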