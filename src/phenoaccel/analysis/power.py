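"""Hanley–McNeil sample-size calculation for detecting an AUROC above 0.5.

Uses the Hanley & McNeil (1982) variance approximation

    V(theta) = [theta(1-theta) + (n+ - 1)(Q1 - theta^2)
                               + (n- - 1)(Q2 - theta^2)] / (n+ n-),
    Q1 = theta / (2 - theta),   Q2 = 2 theta^2 / (1 + theta),

and finds the smallest number of positives (with negatives at a fixed
ratio) such that a two-sided level-alpha test of AUC = 0.5 has the
requested power at the alternative AUC theta:

    z_{1-alpha/2} sqrt(V(0.5)) + z_{power} sqrt(V(theta)) <= theta - 0.5.
"""

from __future__ import annotations

import math

from scipy.stats import norm

__all__ = ["hanley_mcneil_variance", "auroc_sample_size"]


def hanley_mcneil_variance(theta: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil approximation to Var(AUC-hat)."""
    q1 = theta / (2.0 - theta)
    q2 = 2.0 * theta**2 / (1.0 + theta)
    return (
        theta * (1.0 - theta)
        + (n_pos - 1) * (q1 - theta**2)
        + (n_neg - 1) * (q2 - theta**2)
    ) / (n_pos * n_neg)


def auroc_sample_size(
    theta: float,
    alpha: float = 0.05,
    power: float = 0.80,
    neg_pos_ratio: float = 10.0,
    max_n_pos: int = 1_000_000,
) -> tuple[int, int]:
    """Smallest (n_pos, n_total) detecting AUC ``theta`` versus 0.5.

    Negatives are allocated as ``round(neg_pos_ratio * n_pos)``. Raises for
    theta <= 0.5 (no finite sample size separates the hypotheses).
    """
    if not 0.5 < theta < 1.0:
        raise ValueError("target AUC must be strictly between 0.5 and 1")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    if neg_pos_ratio <= 0:
        raise ValueError("neg_pos_ratio must be positive")
    z_alpha = norm.ppf(1.0 - alpha / 2.0)
    z_power = norm.ppf(power)
    for n_pos in range(2, max_n_pos):
        n_neg = round(neg_pos_ratio * n_pos)
        if n_neg < 1:
            continue
        v0 = hanley_mcneil_variance(0.5, n_pos, n_neg)
        v1 = hanley_mcneil_variance(theta, n_pos, n_neg)
        if z_alpha * math.sqrt(v0) + z_power * math.sqrt(v1) <= theta - 0.5:
            return n_pos, n_pos + n_neg
    raise RuntimeError("no sample size found below the search cap")
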