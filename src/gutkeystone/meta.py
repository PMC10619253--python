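"""Random-effects meta-analysis (DerSimonian-Laird) of per-cohort estimates.

Given k >= 2 effect estimates b_i with standard errors se_i:

    w_i   = 1 / se_i^2                      (fixed-effect weights)
    b_F   = sum(w b) / sum(w)
    Q     = sum w (b - b_F)^2
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i  = 1 / (se_i^2 + tau^2)            (random-effects weights)
    b_R   = sum(w* b) / sum(w*),  var(b_R) = 1 / sum(w*)
    I^2   = max(0, (Q - (k-1)) / Q)

Log-odds estimates are pooled on the log scale; the pooled odds ratio and its
CI are exponentiated for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gutkeystone.associations import EffectEstimate

__all__ = ["MetaResult", "pool_random_effects"]

_Z = 1.959963984540054


@dataclass
class MetaResult:
    pooled_beta: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    k: int
    kind: str = "linear"

    @property
    def pooled_odds_ratio(self) -> float:
        if self.kind != "logistic":
            raise ValueError("pooled OR defined only for logistic estimates")
        return float(np.exp(self.pooled_beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        d = {
            "pooled_beta": self.pooled_beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "Q": self.Q,
            "I2": self.I2,
            "k": self.k,
            "kind": self.kind,
        }
        if self.kind == "logistic":
            d["pooled_odds_ratio"] = self.pooled_odds_ratio
            d["or_ci_low"], d["or_ci_high"] = self.or_ci
        return d


def pool_random_effects(estimates: list[EffectEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-cohort estimates.

    All estimates must be on the same scale (all linear, or all logistic on
    the log-odds scale). Pooled variance equals 1 / sum of random-effects
    weights exactly.
    """
    if len(estimates) < 2:
        raise ValueError("need >= 2 estimates to pool")
    kinds = {e.kind for e in estimates}
    if len(kinds) > 1:
        raise ValueError(f"mixed estimate scales: {kinds}")
    b = np.array([e.beta for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    k = len(b)
    w = 1.0 / se**2
    b_fixed = (w * b).sum() / w.sum()
    q = (w * (b - b_fixed) ** 2).sum()
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = (w_star * b).sum() / w_star.sum()
    pooled_se = np.sqrt(1.0 / w_star.sum())
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return MetaResult(
        pooled_beta=float(pooled),
        se=float(pooled_se),
        ci_low=float(pooled - _Z * pooled_se),
        ci_high=float(pooled + _Z * pooled_se),
        tau2=float(tau2),
        Q=float(q),
        I2=float(i2),
        k=k,
        kind=kinds.pop(),
    )
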