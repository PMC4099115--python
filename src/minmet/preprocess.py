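"""Preprocessing chain for the intensity matrix.

Stages, in pipeline order:

1. :func:`select_missingness_threshold` — drop metabolites with too many
   missing cells, choosing the per-metabolite threshold ``nu`` that maximises
   (number of retained metabolites) - (missing cells among them) subject to
   ``nu < n - min_g(n_g)/2``.
2. :func:`log2_transform` — log2 of the strictly positive raw intensities.
3. :func:`impute_missing` — two-stage censoring-aware imputation on the log
   scale: artifactual missing cells get the truncated-normal conditional mean
   below the metabolite's detection limit, estimated from observed samples in
   the same experimental group; whole-group absences fall back to a
   background level (half the global minimum on raw scale).
4. :func:`log_transform_regularize` — variance stabilisation: standardise
   each metabolite's centred values by a sliding-window-median trend of the
   per-metabolite standard deviation against the mean (a surrogate for joint
   adaptive mean-variance regularization).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

from .io import IntensityMatrix, StudyDesign, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MissFilterResult:
    """Outcome of the missingness-threshold selection."""

    nu: int
    retained_ids: list[str]
    #: nu -> (retained count R, retained missing total M, J = R - M)
    objective_trace: dict[int, tuple[int, int, int]]


def feasible_nu_bound(n: int, min_group_size: int) -> int:
    """Largest feasible integer threshold: ``nu < n - min_g(n_g)/2``."""
    bound = n - min_group_size / 2.0
    return int(math.ceil(bound)) - 1


def select_missingness_threshold(matrix: IntensityMatrix,
                                 design: StudyDesign) -> MissFilterResult:
    """Choose the missing-count threshold and the retained metabolite set.

    For every feasible ``nu``, ``R(nu)`` counts metabolites with at most
    ``nu`` missing cells and ``M(nu)`` the missing cells among those
    retained; the selected ``nu`` is the largest feasible maximiser of
    ``J(nu) = R(nu) - M(nu)``.
    """
    if matrix.n_metabolites == 0 or matrix.n_samples == 0:
        raise ValidationError("empty intensity matrix")
    n = matrix.n_samples
    sizes = design.group_sizes()
    if not sizes:
        raise ValidationError("design defines no groups")
    nu_hi = feasible_nu_bound(n, min(sizes.values()))
    if nu_hi < 0:
        raise ValidationError("no feasible missingness threshold for this design")

    miss = matrix.missing_mask.sum(axis=1)
    trace: dict[int, tuple[int, int, int]] = {}
    for nu in range(0, nu_hi + 1):
        keep = miss <= nu
        trace[nu] = (int(keep.sum()), int(miss[keep].sum()),
                     int(keep.sum()) - int(miss[keep].sum()))
    # nu is the "nearest upper integer" among the observed per-metabolite
    # missing counts (0 always eligible); when no observed count is feasible
    # the bound itself is reported and nothing is retained.
    observed_feasible = {int(c) for c in np.unique(miss) if c <= nu_hi}
    candidates = sorted({0} | observed_feasible) if observed_feasible \
        else [0, nu_hi]
    best_j = max(trace[nu][2] for nu in candidates)
    best_nu = max(nu for nu in candidates if trace[nu][2] == best_j)
    retained = [mid for mid, k in zip(matrix.metabolite_ids, miss <= best_nu) if k]
    return MissFilterResult(best_nu, retained, trace)


def apply_missingness_filter(matrix: IntensityMatrix,
                             result: MissFilterResult) -> IntensityMatrix:
    return matrix.subset_metabolites(result.retained_ids)


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2 of the raw intensities (observed cells must be positive)."""
    if matrix.scale_tag != "raw":
        raise ValidationError("log2_transform expects a raw-scale matrix")
    observed = matrix.values[~matrix.missing_mask]
    if observed.size and observed.min() <= 0:
        raise ValidationError("non-positive raw intensity")
    values = np.where(matrix.missing_mask, 0.0, np.log2(
        np.where(matrix.missing_mask, 1.0, matrix.values)))
    return IntensityMatrix(values, matrix.missing_mask.copy(),
                           list(matrix.metabolite_ids), list(matrix.sample_ids),
                           matrix.annotations, scale_tag="log2")


def _truncated_normal_mean(mu: float, sd: float, cut: float) -> float:
    """E[Y | Y < cut] for Y ~ Normal(mu, sd^2), computed stably in log space."""
    alpha = (cut - mu) / sd
    # phi(alpha) / Phi(alpha) via log densities; safe far into the tail
    log_phi = -0.5 * alpha * alpha - 0.5 * math.log(2.0 * math.pi)
    ratio = math.exp(log_phi - log_ndtr(alpha))
    return mu - sd * ratio


def impute_missing(matrix: IntensityMatrix, design: StudyDesign,
                   k_neighbors: int = 2) -> IntensityMatrix:
    """Two-stage imputation of the masked cells (log-scale input).

    Stage 1 treats a missing cell as a left-censored draw: if the metabolite
    is observed in at least ``k_neighbors`` samples of the same experimental
    group, the cell is replaced by ``E[Y | Y < c_j]`` under
    ``Y ~ Normal(mu_hat, sd_hat^2)`` with the group mean/sd of those
    neighbours, where ``c_j`` is the metabolite's minimum observed intensity
    over all samples (detection-limit proxy).  Remaining cells (stage 2,
    whole-group absences) get the background level: global minimum observed
    intensity minus 1 on the log2 scale.  The output mask is all False;
    observed cells are never altered.
    """
    if matrix.scale_tag == "raw":
        raise ValidationError("impute_missing expects a log-scale matrix")
    if k_neighbors < 2:
        raise ValidationError("k_neighbors must be >= 2")
    if not matrix.missing_mask.any():
        return IntensityMatrix(matrix.values.copy(),
                               np.zeros_like(matrix.missing_mask),
                               list(matrix.metabolite_ids),
                               list(matrix.sample_ids), matrix.annotations,
                               matrix.scale_tag)
    if matrix.missing_mask.all():
        raise ValidationError("matrix has no observed values")

    sample_groups = np.array([
        f"{g}-{d}-{t}" for g, d, t in
        zip(design.genotype, design.diet, design.tissue)
    ])
    if list(design.sample_ids) != list(matrix.sample_ids):
        index = {s: i for i, s in enumerate(design.sample_ids)}
        try:
            order = [index[s] for s in matrix.sample_ids]
        except KeyError as exc:
            raise ValidationError(f"sample {exc} missing from design") from exc
        sample_groups = sample_groups[order]

    values = matrix.values.copy()
    mask = matrix.missing_mask
    observed_vals = values[~mask]
    background = observed_vals.min() - 1.0  # half the minimum on raw scale

    n_stage1 = n_stage2 = 0
    for j in range(matrix.n_metabolites):
        row_mask = mask[j]
        if not row_mask.any():
            continue
        row = values[j]
        if (~row_mask).any():
            c_j = row[~row_mask].min()
        else:
            c_j = None
        for i in np.nonzero(row_mask)[0]:
            neighbors = (~row_mask) & (sample_groups == sample_groups[i])
            vals = row[neighbors]
            if c_j is not None and vals.size >= k_neighbors:
                sd = vals.std(ddof=1)
                if sd > 0:
                    values[j, i] = _truncated_normal_mean(vals.mean(), sd, c_j)
                    n_stage1 += 1
                    continue
                logger.debug(
                    "metabolite %s sample %s: degenerate neighbour spread, "
                    "stage-2 fallback", matrix.metabolite_ids[j],
                    matrix.sample_ids[i])
            values[j, i] = background
            n_stage2 += 1
    logger.info("imputed %d cells (stage 1: %d, stage 2 background: %d)",
                n_stage1 + n_stage2, n_stage1, n_stage2)
    return IntensityMatrix(values, np.zeros_like(mask),
                           list(matrix.metabolite_ids), list(matrix.sample_ids),
                           matrix.annotations, matrix.scale_tag)


def _sliding_median_trend(means: np.ndarray, sds: np.ndarray,
                          ids: list[str], window: int) -> np.ndarray:
    """Sliding-window median of sd against mean, evaluated at each metabolite.

    Metabolites are ordered by (mean, id) — the id tie-break makes the trend
    invariant to row permutations.
    """
    p = len(means)
    order = sorted(range(p), key=lambda j: (means[j], ids[j]))
    sds_sorted = sds[np.array(order)]
    half = window // 2
    trend_sorted = np.empty(p)
    for rank in range(p):
        lo = max(0, rank - half)
        hi = min(p, lo + window)
        lo = max(0, hi - window)
        trend_sorted[rank] = np.median(sds_sorted[lo:hi])
    trend = np.empty(p)
    trend[np.array(order)] = trend_sorted
    return trend


def log_transform_regularize(matrix: IntensityMatrix,
                             design: StudyDesign | None = None) -> IntensityMatrix:
    """Log2 transform (if needed) followed by mean-variance regularization.

    The regularization is a trend-standardisation surrogate for joint
    adaptive mean-variance regularization: per-metabolite means ``m_j`` and
    standard deviations ``s_j`` are computed, a smooth trend ``s_hat(m)`` is
    fitted by a sliding-window median over metabolites ordered by mean
    (window = max(20, p/10)), and each row is replaced by its centred values
    divided by ``s_hat(m_j)`` with the mean re-added.  Output values live on
    the whole real line.
    """
    if matrix.missing_mask.any():
        raise ValidationError("regularization requires an imputed (complete) matrix")
    if matrix.scale_tag == "raw":
        matrix = log2_transform(matrix)
    values = matrix.values
    p = matrix.n_metabolites
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    window = max(20, p // 10)
    window = min(window, p)
    trend = _sliding_median_trend(means, sds, matrix.metabolite_ids, window)
    # Guard degenerate all-constant windows.
    positive = trend[trend > 0]
    floor = positive.min() if positive.size else 1.0
    trend = np.where(trend > 0, trend, floor)
    out = (values - means[:, None]) / trend[:, None] + means[:, None]
    logger.info("mean-variance regularization (surrogate trend standardisation), "
                "window=%d metabolites", window)
    return IntensityMatrix(out, matrix.missing_mask.copy(),
                           list(matrix.metabolite_ids), list(matrix.sample_ids),
                           matrix.annotations, scale_tag="regularized")


def preprocess_tissue(matrix: IntensityMatrix, design: StudyDesign,
                      k_neighbors: int = 2):
    """Full chain: filter -> log2 -> impute -> regularize.

    Returns ``(regularized_matrix, MissFilterResult)``.
    """
    filt = select_missingness_threshold(matrix, design)
    kept = apply_missingness_filter(matrix, filt)
    logged = log2_transform(kept)
    imputed = impute_missing(logged, design, k_neighbors=k_neighbors)
    regularized = log_transform_regularize(imputed, design)
    return regularized, filt
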