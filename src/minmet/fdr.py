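"""Positive-FDR (q-value) control and Benjamini-Hochberg adjustment.

The q-value of a test is the minimum positive false discovery rate at which
it would be called significant.  The null proportion ``pi0`` is estimated
from the flat right tail of the p-value histogram on a grid of tuning
points and smoothed with a cubic fit; with ``pi0 = 1`` the q-values reduce
exactly to Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ValidationError

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass
class FdrResult:
    p_raw: np.ndarray
    pi0_hat: float
    q: np.ndarray
    lambda_grid: np.ndarray


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be a 1-D vector")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values outside [0, 1]")
    return p


def estimate_pi0(p, lambda_grid=None) -> float:
    """Estimate the proportion of true nulls from the p-value tail.

    ``pi0_hat(lambda) = #{p_i > lambda} / (m (1 - lambda))`` on the grid; the
    final estimate is the cubic-polynomial smoother evaluated at the largest
    lambda, clipped to ``[1/m, 1]`` so q-values can never be zero.
    """
    p = _validate_p(p)
    m = p.size
    if m < 10:
        warnings.warn("fewer than 10 p-values; falling back to pi0 = 1",
                      stacklevel=2)
        return 1.0
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None \
        else np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or grid.min() <= 0 or grid.max() >= 1:
        raise ValidationError("lambda grid must lie in (0, 1)")
    grid = np.sort(grid)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if grid.size >= 4:
        coeffs = np.polyfit(grid, pi0_lambda, 3)
        pi0 = float(np.polyval(coeffs, grid.max()))
    else:
        pi0 = float(pi0_lambda[-1])
    return float(np.clip(pi0, 1.0 / m, 1.0))


def compute_qvalues(p, pi0: float | None = None, lambda_grid=None) -> FdrResult:
    """q-values ``q_i = min_{t >= p_i} pi0 m t / #{p_j <= t}``, monotone in p.

    With ``pi0 = 1`` this is exactly the BH step-up adjustment.
    """
    p = _validate_p(p)
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None \
        else np.asarray(lambda_grid, dtype=float)
    if pi0 is None:
        pi0 = estimate_pi0(p, grid)
    if not 0.0 < pi0 <= 1.0:
        raise ValidationError("pi0 must be in (0, 1]")
    m = p.size
    q = np.empty(m)
    if m:
        order = np.argsort(p, kind="mergesort")
        ranked = pi0 * m * p[order] / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        q[order] = np.minimum(ranked, 1.0)
    return FdrResult(p_raw=p, pi0_hat=float(pi0), q=q,
                     lambda_grid=np.asarray(grid, dtype=float))


def bh_adjust(p) -> np.ndarray:
    """Standard Benjamini-Hochberg step-up adjusted p-values."""
    return compute_qvalues(p, pi0=1.0).q
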