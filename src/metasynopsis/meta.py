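"""Inverse-variance pooling with fixed- and random-effects models.

The fixed-effect estimate weights each study by ``w_i = 1/se_i^2``;
heterogeneity is summarized by Cochran's Q, Higgins' I^2 = max(0, (Q - df)/Q)
and the DerSimonian-Laird moment estimator of the between-study variance
``tau^2 = max(0, (Q - df) / C)`` with ``C = sum(w) - sum(w^2)/sum(w)``. The
random-effects estimate reuses the same machinery with weights
``1/(se_i^2 + tau^2)``. :func:`select_and_pool` applies the model-selection
rule used throughout the synopsis: random effects when I^2 >= 50%, fixed
effects otherwise. Pooled p-values are Wald-type normal approximations and
CIs are reported on the ratio scale for log-odds data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effects import Z_95, dataset_effects
from .records import AssociationDataset


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one variant-outcome dataset.

    ``theta_hat`` and ``se_hat`` are on the analysis scale (log odds ratio
    or SMD); ``ci_low``/``ci_high`` are exponentiated for ratio scales.
    Q, df and I^2 always come from the fixed-effect weights, whichever
    model produced the estimate. ``model`` is "fixed", "random", or
    "not_pooled" for a single-record passthrough (no heterogeneity).
    """

    k: int
    theta_hat: float
    se_hat: float
    ci_low: float
    ci_high: float
    p: float
    Q: float | None
    df: int
    i2: float | None
    tau2: float
    model: str
    effect_scale: str = "log_odds"

    @property
    def effect(self) -> float:
        """Point estimate on the reporting scale (OR for log-odds data)."""
        return math.exp(self.theta_hat) if self.effect_scale == "log_odds" else self.theta_hat


def _wald(theta: float, se: float, effect_scale: str) -> tuple[float, float, float]:
    lo, hi = theta - Z_95 * se, theta + Z_95 * se
    if effect_scale == "log_odds":
        lo, hi = math.exp(lo), math.exp(hi)
    p = 2 * float(stats.norm.sf(abs(theta) / se))
    return lo, hi, p


def _heterogeneity(thetas: np.ndarray, ses: np.ndarray) -> tuple[float, int, float]:
    w = 1.0 / ses**2
    theta_fe = float((w * thetas).sum() / w.sum())
    q = float((w * (thetas - theta_fe) ** 2).sum())
    df = len(thetas) - 1
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q) * 100.0
    return q, df, i2


def pool_effects(
    thetas, ses, *, method: str = "fixed", tau2: float = 0.0, effect_scale: str = "log_odds"
) -> MetaResult:
    """Pool (theta, se) arrays directly; the array-level core of this module."""
    thetas = np.asarray(thetas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if thetas.shape != ses.shape or thetas.ndim != 1:
        raise ValueError("thetas and ses must be matching 1-d arrays")
    if not (ses > 0).all():
        raise ValueError("all standard errors must be positive")
    k = len(thetas)
    if k == 0:
        raise ValueError("nothing to pool")
    if k == 1:
        lo, hi, p = _wald(float(thetas[0]), float(ses[0]), effect_scale)
        return MetaResult(
            1, float(thetas[0]), float(ses[0]), lo, hi, p,
            Q=None, df=0, i2=None, tau2=0.0, model="not_pooled",
            effect_scale=effect_scale,
        )
    q, df, i2 = _heterogeneity(thetas, ses)
    if method == "fixed":
        w = 1.0 / ses**2
        tau2 = 0.0
    elif method == "random":
        w = 1.0 / (ses**2 + tau2)
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    theta_hat = float((w * thetas).sum() / w.sum())
    se_hat = float(1.0 / math.sqrt(w.sum()))
    lo, hi, p = _wald(theta_hat, se_hat, effect_scale)
    return MetaResult(
        k, theta_hat, se_hat, lo, hi, p, q, df, i2, tau2, method, effect_scale
    )


def fixed_effect_pool(dataset: AssociationDataset) -> MetaResult:
    """Inverse-variance fixed-effect pooling of a dataset."""
    thetas, ses = dataset_effects(dataset)
    return pool_effects(thetas, ses, method="fixed", effect_scale=dataset.effect_scale)


def dl_tau2(dataset: AssociationDataset) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance."""
    thetas, ses = dataset_effects(dataset)
    return dl_tau2_from_effects(thetas, ses)


def dl_tau2_from_effects(thetas, ses) -> float:
    thetas = np.asarray(thetas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(thetas) < 2:
        raise ValueError("tau^2 estimation needs at least two studies")
    w = 1.0 / ses**2
    q, df, _ = _heterogeneity(thetas, ses)
    c = float(w.sum() - (w**2).sum() / w.sum())
    return max(0.0, (q - df) / c)


def random_effects_pool(dataset: AssociationDataset) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of a dataset."""
    thetas, ses = dataset_effects(dataset)
    if len(thetas) == 1:
        return pool_effects(thetas, ses, effect_scale=dataset.effect_scale)
    tau2 = dl_tau2_from_effects(thetas, ses)
    return pool_effects(
        thetas, ses, method="random", tau2=tau2, effect_scale=dataset.effect_scale
    )


def select_and_pool(dataset: AssociationDataset, switch_i2: float = 50.0) -> MetaResult:
    """Pool with the heterogeneity-driven model switch.

    Fixed effects when I^2 < ``switch_i2`` percent, random effects when
    I^2 >= ``switch_i2`` (the boundary goes to the random-effects model).
    Single-record datasets pass through unpooled.
    """
    thetas, ses = dataset_effects(dataset)
    if len(thetas) == 1:
        return pool_effects(thetas, ses, effect_scale=dataset.effect_scale)
    fixed = pool_effects(thetas, ses, method="fixed", effect_scale=dataset.effect_scale)
    if fixed.i2 >= switch_i2:
        tau2 = dl_tau2_from_effects(thetas, ses)
        return pool_effects(
            thetas, ses, method="random", tau2=tau2, effect_scale=dataset.effect_scale
        )
    return fixed
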