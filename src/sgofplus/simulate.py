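"""Synthetic families of one-sample two-tailed t-test p-values.

The generator emulates the mixture design used throughout the power/pFDR
experiments: each family holds S tests; a fixed fraction of them carry a
true effect.  A test draws n deviates from N(0, 1) under the null or from
N(x, 1) under the alternative (default effect size x = 0.36, chosen so a
single test at the 5% level has power about 0.10 asymptotically), then runs
the one-sample t-test of mean 0 with the p-value obtained through the
regularized incomplete beta identity

    p = I_{df/(df + t^2)}(df/2, 1/2),   df = n - 1.

Truth labels travel with every family so that TPR/FPR/pFDR are computable
exactly downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

from .metatest import PValueSet

__all__ = [
    "SimulationScenario",
    "ttest_pvalue",
    "generate_family",
    "single_test_power",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulated multiple-testing experiment.

    S tests, n observations per test, ``effect_fraction`` of the tests
    drawn from N(effect_size, 1) (the rest from N(0, 1)), adjusted at
    level ``alpha``; ``n_replicates`` independent families under root
    ``seed``.
    """

    S: int = 1000
    n: int = 20
    effect_size: float = 0.36
    effect_fraction: float = 0.2
    alpha: float = 0.05
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValueError("effect_fraction must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_effects(self) -> int:
        """Deterministic effect count round(S * effect_fraction)."""
        return int(round(self.S * self.effect_fraction))

    def with_(self, **kwargs) -> "SimulationScenario":
        return replace(self, **kwargs)


def _pvalues_from_samples(samples: np.ndarray) -> np.ndarray:
    """Two-tailed one-sample t-test p-values for each row of ``samples``."""
    n = samples.shape[-1]
    df = n - 1
    mean = samples.mean(axis=-1)
    sd = samples.std(axis=-1, ddof=1)
    if np.any(sd == 0.0):
        raise ValueError("degenerate sample: zero variance")
    t = mean / (sd / np.sqrt(n))
    return special.betainc(df / 2.0, 0.5, df / (df + t * t))


def ttest_pvalue(sample) -> float:
    """Two-tailed p-value of the one-sample t-test of mean 0.

    Computed through the incomplete-beta identity; agrees with the usual
    Student-t tail formula.  Raises on samples of length < 2 or with zero
    variance (the t statistic is undefined there).
    """
    arr = np.asarray(sample, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("t-test requires at least 2 observations")
    return float(_pvalues_from_samples(arr[None, :])[0])


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    # counter-based stream: (root seed, replicate counter) keys an
    # independent, individually reproducible generator per replicate
    return np.random.default_rng([seed, replicate_index])


def generate_family(
    scenario: SimulationScenario, replicate_index: int = 0
) -> tuple[PValueSet, np.ndarray]:
    """One replicate family of p-values plus boolean truth labels.

    Exactly ``scenario.n_effects`` tests (the first ones) carry effects —
    the fixed-percentage composition of the design, not Bernoulli
    sampling.  Deterministic given (scenario.seed, replicate_index).
    """
    rng = _replicate_rng(scenario.seed, replicate_index)
    samples = rng.standard_normal((scenario.S, scenario.n))
    k = scenario.n_effects
    labels = np.zeros(scenario.S, dtype=bool)
    labels[:k] = True
    samples[labels] += scenario.effect_size
    return PValueSet(_pvalues_from_samples(samples)), labels


def single_test_power(n: int, x: float, alpha: float = 0.05) -> float:
    """Exact power of one two-tailed one-sample t-test against mean x.

    Noncentral-t computation: noncentrality x * sqrt(n), df = n - 1,
    rejection beyond the two-tailed level-``alpha`` critical value.  With
    x = 0 this reduces to the size alpha of the test.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = x * np.sqrt(n)
    return float(1.0 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
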