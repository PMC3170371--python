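"""Evaluation metrics over simulation replicates.

For each replicate a method's rejection set is scored against the truth
labels (confusion counts); across replicates the scenario-level quantities
are:

* power (TPR): mean TP/(TP+FN) over replicates with effects present;
* FPR: mean FP/(FP+TN);
* pFDR: mean false-discovery proportion FP/(TP+FP), averaged only over
  replicates that made at least one discovery (the conditional definition —
  replicates without discoveries are excluded, not counted as 0);
* FWER: fraction of replicates with at least one false discovery;
* power/pFDR ratio, and the signed epFDR - pFDR estimation bias.

Monte-Carlo standard errors accompany every aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fdr import bh_adjust, epfdr, holm_adjust
from .metatest import PValueSet, sgof, sgof_plus
from .pi0 import pi0_bootstrap, pi0_lbe, pi0_sdpb, pi0_smoothing
from .simulate import SimulationScenario, generate_family

__all__ = [
    "Confusion",
    "ScenarioMetrics",
    "replicate_confusion",
    "aggregate",
    "epfdr_bias",
    "run_scenario",
    "scenario_table",
    "METHODS",
]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_discoveries(self) -> int:
        return self.tp + self.fp

    @property
    def fdp(self) -> float:
        """False discovery proportion; NaN when there are no discoveries."""
        d = self.n_discoveries
        return self.fp / d if d else float("nan")


@dataclass(frozen=True)
class ScenarioMetrics:
    """Replicate-averaged metrics of one method on one scenario.

    pFDR (and hence the power/pFDR ratio and epFDR bias) is None when no
    replicate produced a discovery — the conditional quantity is undefined,
    not zero.
    """

    method: str
    n_replicates: int
    n_discovering: int
    power: float | None
    power_se: float | None
    fpr: float
    fpr_se: float
    pfdr: float | None
    pfdr_se: float | None
    fwer: float
    fwer_se: float
    power_pfdr_ratio: float | None
    epfdr_mean: float | None = None
    epfdr_bias: float | None = None
    mean_discoveries: float = 0.0


def replicate_confusion(rejected: Sequence[int], truth: Sequence[bool]) -> Confusion:
    """Confusion counts of one replicate's rejection set."""
    truth_arr = np.asarray(truth, dtype=bool)
    rej = np.zeros(truth_arr.size, dtype=bool)
    idx = np.asarray(rejected, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= truth_arr.size):
        raise ValueError("rejected index outside the family")
    rej[idx] = True
    tp = int(np.count_nonzero(rej & truth_arr))
    fp = int(np.count_nonzero(rej & ~truth_arr))
    fn = int(np.count_nonzero(~rej & truth_arr))
    tn = int(np.count_nonzero(~rej & ~truth_arr))
    return Confusion(tp=tp, fp=fp, tn=tn, fn=fn)


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    return m, se


def aggregate(
    confusions: Sequence[Confusion],
    method: str = "",
    epfdr_values: Sequence[float] | None = None,
) -> ScenarioMetrics:
    """Scenario-level metrics from per-replicate confusion counts.

    ``epfdr_values`` are per-replicate epFDR estimates at the method's
    rejection threshold (NaN where the replicate made no discovery); their
    conditional mean is compared with the observed pFDR to give the bias.
    """
    if not confusions:
        raise ValueError("aggregate requires at least one replicate")
    tp = np.array([c.tp for c in confusions], dtype=float)
    fp = np.array([c.fp for c in confusions], dtype=float)
    tn = np.array([c.tn for c in confusions], dtype=float)
    fn = np.array([c.fn for c in confusions], dtype=float)
    n_rep = len(confusions)

    effects = tp + fn
    has_effects = effects > 0
    if np.any(has_effects):
        power, power_se = _mean_se(tp[has_effects] / effects[has_effects])
    else:
        power = power_se = None

    negatives = fp + tn
    with np.errstate(invalid="ignore"):
        fpr_vals = np.where(negatives > 0, fp / np.maximum(negatives, 1), 0.0)
    fpr, fpr_se = _mean_se(fpr_vals)

    discoveries = tp + fp
    discovering = discoveries > 0
    n_disc = int(np.count_nonzero(discovering))
    if n_disc:
        pfdr, pfdr_se = _mean_se(fp[discovering] / discoveries[discovering])
    else:
        pfdr = pfdr_se = None

    fwer_vals = (fp > 0).astype(float)
    fwer, fwer_se = _mean_se(fwer_vals)

    if power is not None and pfdr is not None and pfdr > 0:
        ratio = power / pfdr
    else:
        ratio = None

    ep_mean = ep_bias = None
    if epfdr_values is not None and n_disc:
        ev = np.asarray(epfdr_values, dtype=float)
        ev = ev[discovering]
        ev = ev[~np.isnan(ev)]
        if ev.size:
            ep_mean = float(np.mean(ev))
            if pfdr is not None:
                ep_bias = epfdr_bias(ep_mean, pfdr)

    return ScenarioMetrics(
        method=method,
        n_replicates=n_rep,
        n_discovering=n_disc,
        power=power,
        power_se=power_se,
        fpr=fpr,
        fpr_se=fpr_se,
        pfdr=pfdr,
        pfdr_se=pfdr_se,
        fwer=fwer,
        fwer_se=fwer_se,
        power_pfdr_ratio=ratio,
        epfdr_mean=ep_mean,
        epfdr_bias=ep_bias,
        mean_discoveries=float(np.mean(discoveries)),
    )


def epfdr_bias(estimated: float, observed: float) -> float:
    """Signed difference estimated - observed; positive = conservative."""
    if not (0.0 <= estimated <= 1.0 and 0.0 <= observed <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    return estimated - observed


# ---------------------------------------------------------------------------
# Simulation harness

_PI0_ESTIMATORS: dict[str, Callable] = {
    "smoothing": pi0_smoothing,
    "bootstrap": pi0_bootstrap,
    "lbe": pi0_lbe,
    "sdpb": pi0_sdpb,
}


def _method_registry(alpha: float) -> dict[str, Callable[[PValueSet], np.ndarray]]:
    return {
        "sgof": lambda ps: sgof(ps, alpha=alpha, gamma=alpha).rejected_indices,
        "sgof+": lambda ps: sgof_plus(ps, alpha=alpha).rejected_indices,
        "bh": lambda ps: bh_adjust(ps, alpha=alpha).rejected_indices,
        "holm": lambda ps: holm_adjust(ps, alpha=alpha).rejected_indices,
    }


METHODS = ("sgof", "sgof+", "bh", "holm")


def run_scenario(
    scenario: SimulationScenario,
    methods: Sequence[str] = METHODS,
    estimate_epfdr: bool = False,
    pi0_method: str = "smoothing",
    robust: bool = True,
) -> dict[str, ScenarioMetrics]:
    """Run every method over the scenario's replicates and aggregate.

    With ``estimate_epfdr`` each discovering replicate also estimates pi0
    (``pi0_method``) from its own p-values and evaluates epFDR at the
    method's rejection boundary (the largest rejected p-value), so the
    aggregate carries the estimation bias epFDR - pFDR.
    """
    registry = _method_registry(scenario.alpha)
    unknown = set(methods) - set(registry)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    estimator = _PI0_ESTIMATORS[pi0_method]

    confusions: dict[str, list[Confusion]] = {m: [] for m in methods}
    ep_values: dict[str, list[float]] = {m: [] for m in methods}
    for r in range(scenario.n_replicates):
        ps, labels = generate_family(scenario, r)
        pi0_hat = None
        for m in methods:
            rejected = registry[m](ps)
            confusions[m].append(replicate_confusion(rejected, labels))
            if estimate_epfdr:
                if rejected.size:
                    if pi0_hat is None:
                        pi0_hat = estimator(ps).value
                    threshold = float(np.max(ps.values[rejected]))
                    ep = epfdr(ps, threshold, pi0_hat, robust=robust)
                else:
                    ep = float("nan")
                ep_values[m].append(ep)

    return {
        m: aggregate(
            confusions[m],
            method=m,
            epfdr_values=ep_values[m] if estimate_epfdr else None,
        )
        for m in methods
    }


def scenario_table(results: dict[str, ScenarioMetrics], scenario: SimulationScenario) -> pd.DataFrame:
    """One row per method with all aggregates and MC standard errors."""
    rows = []
    for m, met in results.items():
        rows.append(
            {
                "method": m,
                "S": scenario.S,
                "n": scenario.n,
                "effect_size": scenario.effect_size,
                "effect_fraction": scenario.effect_fraction,
                "alpha": scenario.alpha,
                "n_replicates": met.n_replicates,
                "n_discovering": met.n_discovering,
                "mean_discoveries": met.mean_discoveries,
                "power": met.power,
                "power_se": met.power_se,
                "fpr": met.fpr,
                "fpr_se": met.fpr_se,
                "pfdr": met.pfdr,
                "pfdr_se": met.pfdr_se,
                "fwer": met.fwer,
                "fwer_se": met.fwer_se,
                "power_pfdr_ratio": met.power_pfdr_ratio,
                "epfdr_mean": met.epfdr_mean,
                "epfdr_bias": met.epfdr_bias,
            }
        )
    return pd.DataFrame(rows)
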