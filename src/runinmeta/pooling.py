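"""Inverse-variance meta-analysis with heterogeneity-driven model choice.

Fixed-effect pooling weights each trial by the reciprocal of its variance;
random-effects pooling adds the DerSimonian-Laird moment estimate of the
between-trial variance tau^2 to every weight denominator.  Heterogeneity is
summarized by Cochran's Q and I^2 = max(0, (Q - df) / Q) * 100.

:func:`pool_auto` implements the selection rule used throughout this
pipeline: a fixed-effect model when I^2 is below the threshold (default
40%), otherwise random effects.  The rule is applied per analysis cell, so
different strata of the same table may use different models; results carry
the model actually used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from scipy import stats

from .effect_sizes import EffectEstimate, EffectSet

Effects = Union[Sequence[tuple[float, float]], Sequence[EffectEstimate], EffectSet]


class PoolingError(ValueError):
    """Pooling not possible for the given inputs."""


@dataclass
class PoolingConfig:
    """Model-selection threshold (I^2 percent) and CI level."""

    i2_threshold: float = 40.0
    ci_level: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.i2_threshold <= 100.0:
            raise ValueError("i2_threshold must be in [0, 100]")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class PooledResult:
    """A pooled estimate with heterogeneity diagnostics.

    ``estimate``/``se``/CI are on the pooling scale (``smd`` or
    ``log_or``); ``k`` trials were pooled with ``df = k - 1``; ``i2`` is
    in percent; ``model`` records whether fixed or random-effects weights
    produced the estimate (``tau2`` is reported either way but enters the
    weights only under ``random``).
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    k: int
    Q: float
    df: int
    i2: float
    tau2: float
    model: str
    scale: str = "smd"

    @property
    def variance(self) -> float:
        return self.se * self.se


def _as_pairs(effects: Effects) -> tuple[list[tuple[float, float]], str]:
    if isinstance(effects, EffectSet):
        effects = effects.effects
    pairs = []
    scale = "smd"
    for e in effects:
        if isinstance(e, EffectEstimate):
            pairs.append((e.estimate, e.variance))
            scale = e.scale
        else:
            est, var = e
            pairs.append((float(est), float(var)))
    if not pairs:
        raise PoolingError("no effects to pool")
    if any(v <= 0 for _, v in pairs):
        raise PoolingError("all variances must be positive")
    return pairs, scale


def q_statistic(effects: Effects) -> tuple[float, int]:
    """Cochran's Q and its degrees of freedom (k - 1)."""
    pairs, _ = _as_pairs(effects)
    w = [1.0 / v for _, v in pairs]
    sw = sum(w)
    theta_f = sum(wi * th for wi, (th, _) in zip(w, pairs)) / sw
    q = sum(wi * (th - theta_f) ** 2 for wi, (th, _) in zip(w, pairs))
    return q, len(pairs) - 1


def i_squared(Q: float, df: int) -> float:
    """I^2 in percent: the share of variability beyond chance, clamped at 0."""
    if df < 0:
        raise ValueError("df must be >= 0")
    if df == 0 or Q <= df or Q == 0:
        return 0.0
    return 100.0 * (Q - df) / Q


def tau2_dl(effects: Effects) -> float:
    """DerSimonian-Laird moment estimate of the between-trial variance."""
    pairs, _ = _as_pairs(effects)
    if len(pairs) < 2:
        raise PoolingError("tau^2 needs at least 2 trials")
    w = [1.0 / v for _, v in pairs]
    sw = sum(w)
    c = sw - sum(wi * wi for wi in w) / sw
    q, df = q_statistic(pairs)
    return max(0.0, (q - df) / c)


def _pool(pairs: list[tuple[float, float]], tau2: float, scale: str,
          model: str, cfg: PoolingConfig) -> PooledResult:
    w = [1.0 / (v + tau2) for _, v in pairs]
    sw = sum(w)
    est = sum(wi * th for wi, (th, _) in zip(w, pairs)) / sw
    se = 1.0 / math.sqrt(sw)
    z = stats.norm.ppf(0.5 + cfg.ci_level / 2.0)
    q, df = q_statistic(pairs)
    tau2_info = tau2_dl(pairs) if len(pairs) >= 2 else 0.0
    return PooledResult(estimate=est, se=se, ci_low=est - z * se,
                        ci_high=est + z * se, k=len(pairs), Q=q, df=df,
                        i2=i_squared(q, df), tau2=tau2_info, model=model,
                        scale=scale)


def pool_fixed(effects: Effects,
               cfg: Optional[PoolingConfig] = None) -> PooledResult:
    """Fixed-effect (inverse-variance) pooled estimate."""
    cfg = cfg or PoolingConfig()
    pairs, scale = _as_pairs(effects)
    return _pool(pairs, 0.0, scale, "fixed", cfg)


def pool_random(effects: Effects,
                cfg: Optional[PoolingConfig] = None) -> PooledResult:
    """DerSimonian-Laird random-effects pooled estimate."""
    cfg = cfg or PoolingConfig()
    pairs, scale = _as_pairs(effects)
    if len(pairs) < 2:
        raise PoolingError("random-effects pooling needs at least 2 trials")
    return _pool(pairs, tau2_dl(pairs), scale, "random", cfg)


def pool_auto(effects: Effects,
              cfg: Optional[PoolingConfig] = None) -> PooledResult:
    """Pool with the I^2 rule: fixed when I^2 < threshold, else random.

    A single trial is always 'pooled' fixed (its own estimate and SE).
    """
    cfg = cfg or PoolingConfig()
    pairs, scale = _as_pairs(effects)
    if len(pairs) == 1:
        return _pool(pairs, 0.0, scale, "fixed", cfg)
    q, df = q_statistic(pairs)
    if i_squared(q, df) < cfg.i2_threshold:
        return _pool(pairs, 0.0, scale, "fixed", cfg)
    return _pool(pairs, tau2_dl(pairs), scale, "random", cfg)


def format_pooled(result: PooledResult) -> str:
    """Render a pooled result the way meta-analytic tables print them.

    Odds ratios are exponentiated and shown to 1 decimal; SMDs to 3
    decimals.  A trailing ``*`` marks cells where a random-effects model
    was used.
    """
    flag = "*" if result.model == "random" else ""
    if result.scale == "log_or":
        return (f"{math.exp(result.estimate):.1f} "
                f"({math.exp(result.ci_low):.1f}-"
                f"{math.exp(result.ci_high):.1f}){flag}")
    return (f"{result.estimate:.3f} "
            f"({result.ci_low:.3f} to {result.ci_high:.3f}){flag}")
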