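"""Hypergeometric overlap and compound-set enrichment statistics.

For two sets of sizes ``y`` and ``L`` drawn from a universe of ``N``
compounds, the probability of observing exactly ``x`` in common under the
null of unrelated sets is the hypergeometric point mass

    P(X = x | y, N, L) = C(y, x) C(N - y, L - x) / C(N, L),

evaluated via log-gamma so it neither overflows nor underflows anywhere in
double range.  The overlap/intersection p-value is this point mass; pathway
enrichment uses the right tail (one-sided Fisher exact test for
over-representation).  Network scores are the negative log10 p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import fdr as _fdr
from .io import CompoundSet, ValidationError


def _validate_support(x: int, y: int, L: int, N: int) -> None:
    for name, value in (("x", x), ("y", y), ("L", L), ("N", N)):
        if int(value) != value or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer")
    if y > N or L > N:
        raise ValidationError("set sizes cannot exceed the universe size")
    lo, hi = max(0, y + L - N), min(y, L)
    if not lo <= x <= hi:
        raise ValidationError(
            f"overlap x={x} outside the feasible support [{lo}, {hi}] "
            f"for y={y}, L={L}, N={N}"
        )


def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def log_hypergeometric_overlap(x: int, y: int, L: int, N: int,
                               mode: str = "point") -> float:
    """Natural-log hypergeometric overlap probability (point or right tail)."""
    _validate_support(x, y, L, N)
    if mode == "point":
        ks = np.array([x])
    elif mode == "tail":
        ks = np.arange(x, min(y, L) + 1)
    else:
        raise ValidationError(f"mode must be 'point' or 'tail', got {mode!r}")
    log_pmf = (_log_binom(y, ks) + _log_binom(N - y, L - ks)
               - _log_binom(N, L))
    return float(min(logsumexp(log_pmf), 0.0))


def hypergeometric_overlap(x: int, y: int, L: int, N: int,
                           mode: str = "point") -> float:
    """Hypergeometric overlap probability; see module docstring."""
    return float(np.exp(log_hypergeometric_overlap(x, y, L, N, mode)))


def overlap_ratio(x: int, L: int) -> float:
    """IPA-style ratio: overlap count over second-set size."""
    if L <= 0:
        raise ValidationError("second set must be non-empty")
    return x / L


def network_score(p: float) -> float:
    """Negative log10 of an enrichment p-value (network score)."""
    if p == 0:
        raise ValidationError(
            "p = 0: use log_hypergeometric_overlap for log-space input"
        )
    if not 0.0 < p <= 1.0:
        raise ValidationError("p must lie in (0, 1]")
    return float(-np.log10(p))


def enrich_compound_sets(hits: CompoundSet, sets: list[CompoundSet],
                         universe: CompoundSet) -> pd.DataFrame:
    """Right-tailed hypergeometric enrichment of ``hits`` against each set.

    Every set is intersected with the universe before testing; hits must be
    a subset of the universe.  Returns a frame with columns
    ``set, x, y, L, N, ratio, p, p_adj, score`` sorted by adjusted p
    (BH across the tested sets).
    """
    if not universe.members:
        raise ValidationError("empty universe")
    stray = hits.members - universe.members
    if stray:
        raise ValidationError(
            f"hits outside the universe: {sorted(stray)[:5]}"
        )
    N = len(universe.members)
    y = len(hits.members)
    rows = []
    for cs in sets:
        members = cs.members & universe.members
        L = len(members)
        if L == 0:
            continue
        x = len(hits.members & members)
        p = hypergeometric_overlap(x, y, L, N, mode="tail")
        rows.append({"set": cs.name, "x": x, "y": y, "L": L, "N": N,
                     "ratio": overlap_ratio(x, L), "p": p})
    frame = pd.DataFrame(rows,
                         columns=["set", "x", "y", "L", "N", "ratio", "p"])
    if len(frame):
        frame["p_adj"] = _fdr.bh_adjust(frame["p"].to_numpy())
        frame["score"] = [network_score(p) if p > 0 else np.inf
                          for p in frame["p"]]
        frame = frame.sort_values(["p_adj", "p"]).reset_index(drop=True)
    else:
        frame["p_adj"] = []
        frame["score"] = []
    return frame
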