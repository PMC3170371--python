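"""Sequential goodness-of-fit metatests (SGoF and SGoF+).

Both methods treat a family of S p-values as data and test, with a single
binomial (or chi-squared) goodness-of-fit "metatest", whether the number of
small p-values exceeds its expectation under the complete null (all S
hypotheses true, p-values i.i.d. Uniform(0,1)).  If the metatest rejects, the
excess of significant results over the critical count is declared: the
N smallest p-values are called discoveries.

SGoF fixes the counting threshold at gamma = alpha (conventionally 0.05).
SGoF+ instead picks the threshold gamma0 that maximizes the distance
K_gamma - gamma between the empirical p-value distribution and the uniform —
the Youden-index point of the p-value ECDF — and protects the resulting
data-driven choice with a one-sided Kolmogorov-Smirnov test so that the
family-wise error rate under the complete null stays at 100*alpha %.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("sgofplus")

__all__ = [
    "PValueSet",
    "MetatestResult",
    "empirical_exceedance",
    "select_gamma0",
    "ks_one_sided_critical",
    "gof_critical_value",
    "sgof",
    "sgof_plus",
]

# Exact one-sided KS quantiles are used up to this family size; beyond it the
# asymptotic sqrt(ln(1/alpha)/(2S)) form is accurate and much cheaper.
_KS_EXACT_MAX_S = 1000


@dataclass(frozen=True)
class PValueSet:
    """A validated family of p-values.

    Input order is preserved; every sorting needed internally works on a
    copy.  Accepts any sequence of floats in [0, 1].
    """

    values: np.ndarray
    S: int = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).ravel().copy()
        if arr.size == 0:
            raise ValueError("p-value set must contain at least one value")
        if np.any(np.isnan(arr)):
            raise ValueError("p-values must not contain NaN")
        if np.any((arr < 0.0) | (arr > 1.0)):
            raise ValueError("p-values must lie in [0, 1]")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "S", int(arr.size))

    def __len__(self) -> int:
        return self.S

    def sorted(self) -> np.ndarray:
        """Ascending copy of the p-values."""
        return np.sort(self.values)

    def order(self) -> np.ndarray:
        """Stable argsort: indices of the p-values from smallest to largest."""
        return np.argsort(self.values, kind="stable")


def as_pvalue_set(pvalues: "PValueSet | Sequence[float] | np.ndarray") -> PValueSet:
    """Coerce array-likes into a :class:`PValueSet` (validating on the way)."""
    if isinstance(pvalues, PValueSet):
        return pvalues
    return PValueSet(np.asarray(pvalues, dtype=float))


@dataclass(frozen=True)
class MetatestResult:
    """Outcome of an SGoF or SGoF+ adjustment.

    Attributes
    ----------
    gamma0:
        Counting threshold used by the binomial metatest (data-driven for
        SGoF+, fixed for SGoF).
    k_gamma0, k_alpha:
        Integer counts S*K_gamma0 (p-values <= gamma0) and S*K_alpha
        (p-values <= alpha).
    critical_value:
        b_alpha(gamma0), the metatest's critical count.
    n_discoveries:
        N_alpha(gamma0) = min(S*K_gamma0 - b_alpha(gamma0) + 1, S*K_alpha)
        when the metatest rejects, else 0.
    rejected_indices:
        Input-order indices of the n_discoveries smallest p-values (ties
        broken by input order).
    ks_guard_passed, ks_distance, ks_critical:
        One-sided KS guard state: distance K_gamma0 - gamma0 and its level-
        alpha critical value.  SGoF runs no guard and reports passed=True.
    """

    gamma0: float
    k_gamma0: int
    k_alpha: int
    critical_value: int
    n_discoveries: int
    rejected_indices: np.ndarray
    ks_guard_passed: bool
    ks_distance: float
    ks_critical: float
    method_label: str
    gof_test_used: str

    def __post_init__(self) -> None:
        idx = np.asarray(self.rejected_indices, dtype=int)
        object.__setattr__(self, "rejected_indices", idx)
        if len(idx) != self.n_discoveries:
            raise ValueError("rejected_indices length must equal n_discoveries")


def empirical_exceedance(pvalues, gamma: float) -> float:
    """Observed proportion K_gamma of p-values at or below ``gamma``.

    Uses the closed convention #{p_i <= gamma}/S, so K is the value of the
    right-continuous ECDF of the p-values at gamma; under the complete null
    E(K_gamma) = gamma.
    """
    ps = as_pvalue_set(pvalues)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return float(np.count_nonzero(ps.values <= gamma)) / ps.S


def select_gamma0(pvalues) -> float:
    """Discriminant threshold gamma0 = argmax_gamma {K_gamma - gamma}.

    Candidates are the distinct observed p-values (the ECDF only jumps
    there, so the supremum of the difference is attained at one of them
    under the closed counting convention).  The degenerate candidates 0 and
    1 are excluded — the binomial metatest is undefined there.  Ties go to
    the smallest maximizing gamma (the more conservative rejection region).
    """
    ps = as_pvalue_set(pvalues)
    candidates = np.unique(ps.values)
    candidates = candidates[(candidates > 0.0) & (candidates < 1.0)]
    if candidates.size == 0:
        raise ValueError("no admissible gamma0 candidate: all p-values are 0 or 1")
    counts = np.searchsorted(ps.sorted(), candidates, side="right")
    diffs = counts / ps.S - candidates
    return float(candidates[int(np.argmax(diffs))])  # argmax returns first max


@lru_cache(maxsize=4096)
def ks_one_sided_critical(alpha: float, S: int) -> float:
    """Level-``alpha`` critical value of the one-sided KS statistic D+.

    D+ = sup_t (F_hat(t) - t) on ``S`` observations.  Exact (scipy's ksone
    distribution) for S <= 1000; the asymptotic sqrt(ln(1/alpha)/(2S)) form
    beyond that.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if S < 1:
        raise ValueError("S must be >= 1")
    if S <= _KS_EXACT_MAX_S:
        return float(stats.ksone.ppf(1.0 - alpha, S))
    return float(np.sqrt(np.log(1.0 / alpha) / (2.0 * S)))


@lru_cache(maxsize=65536)
def gof_critical_value(
    S: int,
    gamma0: float,
    alpha: float,
    mode: str = "binomial",
    conservative: bool = False,
) -> int:
    """Critical count b_alpha(gamma0) of the goodness-of-fit metatest.

    The metatest rejects when the observed count S*K_gamma0 is >= b.

    ``mode="binomial"``: b is the 100(1-alpha)% percentile of
    Binomial(S, gamma0) — the smallest k with CDF(k) >= 1-alpha.  With
    ``conservative=True`` the strictly level-alpha rule (smallest k with
    P(X >= k) <= alpha) is used instead; for a discrete distribution the
    percentile rule can exceed level alpha slightly.

    ``mode="chi2"``: count threshold equivalent to the one-sided chi-squared
    test with 1 df on the two-cell statistic (O - E)^2 / (S*gamma0*(1-gamma0)),
    applied only in the direction O > E, i.e. the normal-approximation bound
    ceil(S*gamma0 + z_{1-alpha} * sqrt(S*gamma0*(1-gamma0))).
    """
    if not 0.0 < gamma0 < 1.0:
        raise ValueError("gamma0 must lie strictly in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if mode == "binomial":
        if conservative:
            # smallest k with survival P(X >= k) <= alpha
            k = int(stats.binom.isf(alpha, S, gamma0)) + 1
            while k > 0 and stats.binom.sf(k - 2, S, gamma0) <= alpha:
                k -= 1
            return min(k, S)
        k = int(stats.binom.ppf(1.0 - alpha, S, gamma0))
        # guard against ppf edge behaviour at CDF plateaus
        while stats.binom.cdf(k, S, gamma0) < 1.0 - alpha:
            k += 1
        while k > 0 and stats.binom.cdf(k - 1, S, gamma0) >= 1.0 - alpha:
            k -= 1
        return k
    if mode == "chi2":
        z = stats.norm.ppf(1.0 - alpha)
        mean = S * gamma0
        sd = np.sqrt(S * gamma0 * (1.0 - gamma0))
        return min(int(np.ceil(mean + z * sd)), S)
    raise ValueError(f"unknown goodness-of-fit mode: {mode!r}")


def _resolve_gof_mode(S: int, mode: str) -> str:
    if mode == "auto":
        return "chi2" if S >= 10 else "binomial"
    if mode in ("binomial", "chi2"):
        return mode
    raise ValueError(f"unknown goodness-of-fit mode: {mode!r}")


def _discoveries(ps: PValueSet, n: int) -> np.ndarray:
    """Input-order indices of the n smallest p-values (stable tie-break)."""
    return ps.order()[:n]


def sgof(
    pvalues,
    alpha: float = 0.05,
    gamma: float = 0.05,
    gof: str = "auto",
    conservative: bool = False,
) -> MetatestResult:
    """Original SGoF adjustment at a fixed counting threshold ``gamma``.

    Rejection of the metatest (S*K_gamma >= b_alpha(gamma)) declares the
    N = max(0, S*K_gamma - b_alpha(gamma) + 1) smallest p-values to be
    discoveries.  With gamma = alpha the excess never exceeds S*K_alpha, so
    no cap is needed; no KS guard applies (the threshold is not data-driven)
    and ``ks_guard_passed`` is reported True by convention.
    """
    ps = as_pvalue_set(pvalues)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie strictly in (0, 1)")
    mode = _resolve_gof_mode(ps.S, gof)
    k_gamma = int(np.count_nonzero(ps.values <= gamma))
    k_alpha = int(np.count_nonzero(ps.values <= alpha))
    b = gof_critical_value(ps.S, gamma, alpha, mode=mode, conservative=conservative)
    if k_gamma >= b:
        n = min(max(k_gamma - b + 1, 0), k_alpha)
    else:
        n = 0
    return MetatestResult(
        gamma0=gamma,
        k_gamma0=k_gamma,
        k_alpha=k_alpha,
        critical_value=b,
        n_discoveries=n,
        rejected_indices=_discoveries(ps, n),
        ks_guard_passed=True,
        ks_distance=k_gamma / ps.S - gamma,
        ks_critical=ks_one_sided_critical(alpha, ps.S),
        method_label="SGoF",
        gof_test_used=mode,
    )


def sgof_plus(
    pvalues,
    alpha: float = 0.05,
    gof: str = "auto",
    conservative: bool = False,
) -> MetatestResult:
    """SGoF+ adjustment: data-driven gamma0 with a weak-FWER KS guard.

    Steps: (1) gamma0 maximizes K_gamma - gamma over the distinct observed
    p-values; (2) if the maximal distance K_gamma0 - gamma0 falls below the
    level-alpha one-sided KS critical value, no effect is declared (this
    guard restores weak FWER control at 100*alpha % under the complete
    null); (3) otherwise the binomial/chi-squared metatest runs at gamma0
    and, on rejection, the N = min(S*K_gamma0 - b_alpha(gamma0) + 1,
    S*K_alpha) smallest p-values are declared discoveries.  The cap at
    S*K_alpha keeps p-values above alpha out of the discovery set.
    """
    ps = as_pvalue_set(pvalues)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    k_alpha = int(np.count_nonzero(ps.values <= alpha))
    ks_crit = ks_one_sided_critical(alpha, ps.S)
    try:
        gamma0 = select_gamma0(ps)
    except ValueError:
        logger.warning(
            "SGoF+: all p-values are 0 or 1; no admissible gamma0, declaring "
            "no discoveries"
        )
        return MetatestResult(
            gamma0=float("nan"),
            k_gamma0=0,
            k_alpha=k_alpha,
            critical_value=0,
            n_discoveries=0,
            rejected_indices=np.empty(0, dtype=int),
            ks_guard_passed=False,
            ks_distance=float("nan"),
            ks_critical=ks_crit,
            method_label="SGoF+",
            gof_test_used="none",
        )
    mode = _resolve_gof_mode(ps.S, gof)
    k_gamma0 = int(np.count_nonzero(ps.values <= gamma0))
    distance = k_gamma0 / ps.S - gamma0
    b = gof_critical_value(ps.S, gamma0, alpha, mode=mode, conservative=conservative)
    guard_ok = distance >= ks_crit
    if guard_ok and k_gamma0 >= b:
        n = min(max(k_gamma0 - b + 1, 0), k_alpha)
    else:
        n = 0
    return MetatestResult(
        gamma0=gamma0,
        k_gamma0=k_gamma0,
        k_alpha=k_alpha,
        critical_value=b,
        n_discoveries=n,
        rejected_indices=_discoveries(ps, n),
        ks_guard_passed=bool(guard_ok),
        ks_distance=float(distance),
        ks_critical=float(ks_crit),
        method_label="SGoF+",
        gof_test_used=mode,
    )
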