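"""PCA diagnostics of samples: scores, explained variance, loading ranks.

Covariance PCA by default (metabolite-wise centering, no scaling) via
singular-value decomposition of the sample x metabolite matrix.  Component
signs are fixed by making the largest-magnitude loading positive so plots
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IntensityMatrix, ValidationError


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    pev: np.ndarray               # % explained variance, all components
    cumulative_pev: np.ndarray
    loadings: pd.DataFrame        # metabolites x components
    loading_ranks: dict[str, list[str]]  # component -> metabolite ids by |corr|
    singular_values: np.ndarray


def run_pca(matrix: IntensityMatrix, n_components: int | None = None,
            scale: bool = False) -> PcaResult:
    """PCA of samples in metabolite space.

    Requires a complete (imputed) matrix.  ``pev`` covers *all* components
    and sums to 100; ``scores``/``loadings`` are truncated to
    ``n_components``.  Loadings are additionally ranked per component by
    absolute correlation of each metabolite with the component scores.
    """
    if matrix.missing_mask.any():
        raise ValidationError("PCA requires an imputed matrix; impute first")
    x = matrix.values.T.astype(float)            # samples x metabolites
    n, p = x.shape
    max_rank = min(n - 1, p) if n > 1 else 1
    if n_components is None:
        n_components = min(max_rank, 10)
    if n_components > min(n, p):
        raise ValidationError("n_components exceeds min(n_samples, n_metabolites)")

    centered = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = centered.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        centered = centered / sd
    u, s, vt = np.linalg.svd(centered, full_matrices=False)

    # deterministic sign: largest-magnitude loading positive per component
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    var = s ** 2
    total = var.sum()
    pev = 100.0 * var / total if total > 0 else np.zeros_like(var)
    scores = u * s
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    scores_df = pd.DataFrame(scores[:, :n_components], index=matrix.sample_ids,
                             columns=comp_names)
    loadings_df = pd.DataFrame(vt[:n_components].T,
                               index=matrix.metabolite_ids, columns=comp_names)

    ranks: dict[str, list[str]] = {}
    mids = np.array(matrix.metabolite_ids)
    for k, name in enumerate(comp_names):
        score = scores[:, k]
        if np.ptp(score) == 0:
            ranks[name] = list(mids)
            continue
        centered_score = score - score.mean()
        num = centered.T @ centered_score
        denom = (np.linalg.norm(centered, axis=0)
                 * np.linalg.norm(centered_score))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, num / denom, 0.0)
        order = np.argsort(-np.abs(corr), kind="mergesort")
        ranks[name] = mids[order].tolist()

    return PcaResult(scores=scores_df, pev=pev,
                     cumulative_pev=np.cumsum(pev), loadings=loadings_df,
                     loading_ranks=ranks, singular_values=s)
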