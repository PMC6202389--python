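"""Storey q-values with smoother-based pi0 estimation.

pi0 (the proportion of true null hypotheses) is estimated on a lambda grid
as pi0(lambda) = #{p > lambda} / (m (1 - lambda)), a cubic polynomial is fit
to the grid values and evaluated at the largest lambda, and the result is
clamped to (0, 1].  q-values are then the pi0-scaled step-up quantities
q_i = min_{p_(j) >= p_(i)} pi0 * m * p_(j) / j, which makes them at most the
Benjamini-Hochberg adjusted p-values.  For small families (m < 100) the grid
estimate is too noisy and pi0 falls back to 1 (plain BH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))


@dataclass
class QvalueModel:
    pi0: float
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    method: str = "smoother"

    def __post_init__(self) -> None:
        if not 0.0 < self.pi0 <= 1.0:
            raise ValueError("pi0 must be in (0, 1]")


def estimate_pi0(pvalues: np.ndarray,
                 lambda_grid=DEFAULT_LAMBDA_GRID) -> QvalueModel:
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m < 100:
        log.info("m=%d < 100: falling back to pi0=1 (plain BH)", m)
        return QvalueModel(pi0=1.0, lambda_grid=tuple(lambda_grid), method="fixed")
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([(p > L).sum() / (m * (1.0 - L)) for L in lam])
    coef = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, lam.max()))
    pi0 = min(max(pi0, 1.0 / m), 1.0)  # clamp to (0, 1]
    return QvalueModel(pi0=pi0, lambda_grid=tuple(lambda_grid), method="smoother")


def storey_qvalues(pvalues, lambda_grid=DEFAULT_LAMBDA_GRID):
    """Return (qvalues, QvalueModel) for a vector of p-values in [0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    model = estimate_pi0(p, lambda_grid)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * model.pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, model
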