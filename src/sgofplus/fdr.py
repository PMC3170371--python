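"""pFDR estimation, q-values and baseline adjustments (BH, Holm).

The estimated positive false discovery rate at a p-value threshold p is

    epFDR(p) = min(1, pi0 * S * p / (R(p) * C)),

where R(p) = #{p_i <= p} is the number of rejections at that threshold and
C = 1 - (1 - p)^S in the robust variant (an estimate of the probability of
at least one rejection, which pFDR conditions on) or C = 1 in the standard
variant.  The q-value of a test is the minimum epFDR over all rejection
regions containing it — a running minimum over larger thresholds.

BH (step-up FDR control) and Holm / Sequential Bonferroni (step-down strong
FWER control) are the baselines the metatests are compared with; their
adjusted p-values are delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .metatest import as_pvalue_set
from .pi0 import Pi0Estimate

__all__ = [
    "QValueTable",
    "AdjustmentResult",
    "epfdr",
    "qvalues",
    "bh_adjust",
    "holm_adjust",
]


@dataclass(frozen=True)
class QValueTable:
    """Per-test epFDR and q-values plus the global settings that produced them.

    ``table`` has one row per test in input order with columns
    ``index``, ``pvalue``, ``epfdr`` (the estimated pFDR of the rejection
    region ending at that test's p-value) and ``qvalue``.
    """

    table: pd.DataFrame
    pi0: float
    robust: bool

    @property
    def qvals(self) -> np.ndarray:
        return self.table["qvalue"].to_numpy()


@dataclass(frozen=True)
class AdjustmentResult:
    """Rejection set and adjusted p-values of a baseline adjustment."""

    method: str
    alpha: float
    rejected_indices: np.ndarray
    adjusted_pvalues: np.ndarray

    @property
    def n_rejections(self) -> int:
        return int(self.rejected_indices.size)


def _coerce_pi0(pi0) -> float:
    value = float(pi0) if not isinstance(pi0, Pi0Estimate) else pi0.value
    if not 0.0 <= value <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    return value


def epfdr(pvalues, threshold: float, pi0, robust: bool = True) -> float:
    """Estimated pFDR of the rejection region {p_i <= threshold}.

    Raises if no p-value falls at or below the threshold: pFDR conditions
    on at least one rejection, so it is undefined there.
    """
    ps = as_pvalue_set(pvalues)
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    pi0_value = _coerce_pi0(pi0)
    R = int(np.count_nonzero(ps.values <= threshold))
    if R == 0:
        raise ValueError(
            f"pFDR undefined at threshold {threshold}: no p-value is rejected there"
        )
    C = 1.0 - (1.0 - threshold) ** ps.S if robust else 1.0
    return min(1.0, pi0_value * ps.S * threshold / (R * C))


def qvalues(pvalues, pi0, robust: bool = True) -> QValueTable:
    """q-values: running minimum of epFDR from the largest threshold down.

    epFDR is evaluated at the observed p-values only (R(p) changes nowhere
    else; in between, the right-continuous step convention applies);
    q(p_(i)) = min_{j >= i} epFDR(p_(j)), mapped back to input order.
    """
    ps = as_pvalue_set(pvalues)
    pi0_value = _coerce_pi0(pi0)
    order = ps.order()
    sorted_p = ps.values[order]
    S = ps.S
    ranks = np.searchsorted(sorted_p, sorted_p, side="right")  # R(p_(i)), tie-safe
    C = 1.0 - (1.0 - sorted_p) ** S if robust else np.ones(S)
    with np.errstate(divide="ignore", invalid="ignore"):
        ep = pi0_value * S * sorted_p / (ranks * C)
    ep = np.where(sorted_p == 0.0, 0.0, ep)  # threshold 0: no null can be rejected
    ep = np.minimum(ep, 1.0)
    q_sorted = np.minimum.accumulate(ep[::-1])[::-1]
    ep_input = np.empty(S)
    q_input = np.empty(S)
    ep_input[order] = ep
    q_input[order] = q_sorted
    table = pd.DataFrame(
        {
            "index": np.arange(S),
            "pvalue": ps.values,
            "epfdr": ep_input,
            "qvalue": q_input,
        }
    )
    return QValueTable(table=table, pi0=pi0_value, robust=robust)


def bh_adjust(pvalues, alpha: float = 0.05) -> AdjustmentResult:
    """Benjamini-Hochberg step-up adjustment at FDR level ``alpha``."""
    ps = as_pvalue_set(pvalues)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    reject, adjusted, _, _ = multipletests(ps.values, alpha=alpha, method="fdr_bh")
    return AdjustmentResult(
        method="BH",
        alpha=alpha,
        rejected_indices=np.flatnonzero(reject),
        adjusted_pvalues=adjusted,
    )


def holm_adjust(pvalues, alpha: float = 0.05) -> AdjustmentResult:
    """Holm (Sequential Bonferroni) step-down adjustment at FWER ``alpha``."""
    ps = as_pvalue_set(pvalues)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    reject, adjusted, _, _ = multipletests(ps.values, alpha=alpha, method="holm")
    return AdjustmentResult(
        method="Holm",
        alpha=alpha,
        rejected_indices=np.flatnonzero(reject),
        adjusted_pvalues=adjusted,
    )
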