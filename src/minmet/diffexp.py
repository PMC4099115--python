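"""Per-metabolite moderated two-way ANOVA.

Each metabolite j is fitted with the fixed-effects model

    y_ij = mu_j + beta_G G_i + beta_D D_i + beta_GD G_i D_i + eps_ij,

with sum-to-zero (+-1) coding of the genotype and diet factors, so the
reported contrasts are classical marginal-mean differences on log2 scale:
genotype logFC = 2 beta_G, diet logFC = 2 beta_D, and the interaction logFC
is the difference-of-differences 4 beta_GD.

Residual variances are shrunk across metabolites by empirical Bayes: the
ensemble of s_j^2 is modelled as scaled-F around a prior (d0, s0^2)
estimated by moment matching of log s_j^2 (digamma/trigamma equations with
Newton inversion of the trigamma), giving posterior variances

    s~_j^2 = (d0 s0^2 + d_j s_j^2) / (d0 + d_j)

and moderated t statistics with d0 + d_j degrees of freedom.  The B
statistic is the log (base 2 by default) posterior odds of differential
concentration under a two-component normal model with prior probability
``p_prior`` and an effect-variance v0 estimated from the top-|t| tail.

Usage follows the Model/Results convention::

    res = ModeratedANOVA(matrix, design).fit()
    res.tables["genotype"].significant(0.05)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from . import fdr as _fdr
from .io import EffectTable, IntensityMatrix, StudyDesign, ValidationError

CONTRASTS = ("genotype", "diet", "interaction")
#: contrast vectors on (mu, beta_G, beta_D, beta_GD)
_CONTRAST_VECTORS = {
    "genotype": np.array([0.0, 2.0, 0.0, 0.0]),
    "diet": np.array([0.0, 0.0, 2.0, 0.0]),
    "interaction": np.array([0.0, 0.0, 0.0, 4.0]),
}


@dataclass
class LinearFit:
    """Per-metabolite OLS results on the 2x2 factorial."""

    metabolite_ids: list[str]
    coefficients: np.ndarray        # (p, 4): mu, beta_G, beta_D, beta_GD
    s2: np.ndarray                  # residual variances
    df_residual: int                # n - 4 for the full-rank design
    contrast_estimates: dict[str, np.ndarray]
    contrast_unscaled_var: dict[str, float]
    annotations: pd.DataFrame | None = None


@dataclass
class EBayesPrior:
    """Empirical-Bayes moderation hyperparameters."""

    d0: float                       # prior df (may be inf)
    s02: float                      # prior variance
    v0: dict[str, float]            # unscaled prior effect variance per contrast
    p_prior: float                  # prior probability of differential concentration


def design_matrix(design: StudyDesign) -> np.ndarray:
    """Sum-to-zero (+-1) coded design: columns 1, G, D, G*D."""
    g = np.where(np.array(design.genotype) == "MU", 1.0, -1.0)
    d = np.where(np.array(design.diet) == "HF", 1.0, -1.0)
    return np.column_stack([np.ones_like(g), g, d, g * d])


def fit_anova_models(matrix: IntensityMatrix, design: StudyDesign) -> LinearFit:
    """Ordinary least squares per metabolite on the 2x2 factorial design."""
    if matrix.missing_mask.any():
        raise ValidationError("fit_anova_models requires a complete matrix")
    cells = set(zip(design.genotype, design.diet))
    if len(cells) < 4:
        raise ValidationError(
            "rank-deficient design: empty genotype x diet cell"
        )
    if list(matrix.sample_ids) != list(design.sample_ids):
        raise ValidationError("matrix and design sample order differ")
    x = design_matrix(design)
    n = x.shape[0]
    if n <= 4:
        raise ValidationError("need more than 4 samples for residual df")
    y = matrix.values.T                      # (n, p)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = (xtx_inv @ x.T @ y).T             # (p, 4)
    resid = y - x @ beta.T
    df = n - 4
    s2 = (resid ** 2).sum(axis=0) / df
    estimates = {c: beta @ v for c, v in _CONTRAST_VECTORS.items()}
    unscaled = {c: float(v @ xtx_inv @ v) for c, v in _CONTRAST_VECTORS.items()}
    return LinearFit(list(matrix.metabolite_ids), beta, s2, df, estimates,
                     unscaled, matrix.annotation_frame())


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from the log residual variances."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    m = positive.size
    if m < 2:
        raise ValidationError(
            "moderation degenerate: residual variances are all zero; "
            "add jitter or use unmoderated t statistics"
        )
    z = np.log(positive)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = ((e - e_mean) ** 2).sum() / (m - 1)
    excess = e_var - polygamma(1, df / 2.0)
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(float(excess))
        s02 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(e_mean))
    return float(d0), s02


def squeeze_variances(s2: np.ndarray, df: int, d0: float,
                      s02: float) -> np.ndarray:
    """Posterior variances s~^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s02)
    if d0 == 0:
        return np.asarray(s2, dtype=float).copy()
    return (d0 * s02 + df * s2) / (d0 + df)


def _estimate_v0(t_mod: np.ndarray, unscaled_var: float, df_total: float,
                 p_prior: float) -> float:
    """Effect-variance estimate targeting the top-``p_prior`` tail of |t|.

    For the ceil(p_prior/2 * m) largest |t| values, each is equated to the
    quantile it should occupy under the two-component model, yielding a
    per-metabolite v0 whose mean is returned (floored at 0).
    """
    m = t_mod.size
    n_target = int(np.ceil(p_prior / 2.0 * m))
    if n_target < 1:
        return 0.0
    prop = max(n_target / m, p_prior)
    abs_t = np.sort(np.abs(t_mod))[::-1][:n_target]
    df_eff = df_total if np.isfinite(df_total) else 1e6
    p0 = 2.0 * t_dist.sf(abs_t, df_eff)
    r = np.arange(1, n_target + 1)
    p_target = ((r - 0.5) / m - (1.0 - prop) * p0) / prop
    v0 = np.zeros(n_target)
    pos = p_target > p0
    if pos.any():
        q_target = t_dist.isf(np.clip(p_target[pos], 1e-300, 1.0) / 2.0, df_eff)
        v0[pos] = unscaled_var * ((abs_t[pos] / q_target) ** 2 - 1.0)
    return float(max(v0.mean(), 0.0))


def _log_odds(t_mod: np.ndarray, df_total: float, unscaled_var: float,
              v0: float, p_prior: float, base2: bool = True) -> np.ndarray:
    """B statistic: log posterior odds of differential concentration."""
    r = (unscaled_var + v0) / unscaled_var
    t2 = t_mod ** 2
    if np.isfinite(df_total):
        kernel = (1.0 + df_total) / 2.0 * np.log(
            (t2 + df_total) / (t2 / r + df_total)
        )
    else:
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    lods = np.log(p_prior / (1.0 - p_prior)) - 0.5 * np.log(r) + kernel
    return lods / np.log(2.0) if base2 else lods


def moderate_statistics(fit: LinearFit, p_prior: float = 0.01,
                        d0_override: float | None = None,
                        b_base2: bool = True,
                        adjust: str = "qvalue"):
    """Empirical-Bayes moderation of the per-metabolite ANOVA fits.

    Returns ``(EBayesPrior, {contrast: EffectTable})``.  ``d0_override``
    forces the prior df (0 recovers classical per-metabolite t tests,
    ``inf`` gives complete shrinkage to the prior variance).  ``adjust``
    selects q-values (positive FDR) or plain BH for the adjusted p column.
    """
    if len(fit.metabolite_ids) < 10:
        raise ValidationError("moderation needs an ensemble of >= 10 metabolites")
    if not 0.0 < p_prior < 1.0:
        raise ValidationError("p_prior must be in (0, 1)")
    if d0_override is None:
        d0, s02 = estimate_prior(fit.s2, fit.df_residual)
    else:
        d0 = float(d0_override)
        _, s02 = estimate_prior(fit.s2, fit.df_residual) if d0 != 0 else (0.0, 1.0)
    s2_post = squeeze_variances(fit.s2, fit.df_residual, d0, s02)
    df_total = d0 + fit.df_residual

    v0_by_contrast: dict[str, float] = {}
    tables: dict[str, EffectTable] = {}
    for contrast in CONTRASTS:
        est = fit.contrast_estimates[contrast]
        v_c = fit.contrast_unscaled_var[contrast]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = est / np.sqrt(s2_post * v_c)
        t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
        df_eff = df_total if np.isfinite(df_total) else 1e6
        p_raw = 2.0 * t_dist.sf(np.abs(t_mod), df_eff)
        v0 = _estimate_v0(t_mod, v_c, df_total, p_prior)
        v0_by_contrast[contrast] = v0
        b = _log_odds(t_mod, df_total, v_c, v0, p_prior, base2=b_base2)
        if adjust == "qvalue":
            p_adj = _fdr.compute_qvalues(p_raw).q
        elif adjust == "bh":
            p_adj = _fdr.bh_adjust(p_raw)
        else:
            raise ValidationError(f"unknown adjust method {adjust!r}")
        frame = pd.DataFrame({
            "metabolite_id": fit.metabolite_ids,
            "logFC": est,
            "t": t_mod,
            "B": b,
            "p_raw": p_raw,
            "p_adj": p_adj,
        })
        if fit.annotations is not None:
            frame = frame.join(fit.annotations.reset_index(drop=True))
        tables[contrast] = EffectTable(frame, contrast=contrast)
    prior = EBayesPrior(d0=d0, s02=s02, v0=v0_by_contrast, p_prior=p_prior)
    return prior, tables


def effect_tables(tables: dict[str, EffectTable],
                  threshold: float = 0.05) -> dict:
    """Report bundle: per-contrast significant calls split by sign of logFC
    plus Venn-style intersection counts across the three contrasts."""
    report: dict = {"threshold": threshold, "contrasts": {}}
    sig_sets: dict[str, set] = {}
    for name, table in tables.items():
        sig = table.significant(threshold)
        up = sig[sig["logFC"] > 0]
        down = sig[sig["logFC"] < 0]
        sig_sets[name] = set(sig["metabolite_id"])
        report["contrasts"][name] = {
            "n_significant": len(sig),
            "n_up": len(up),
            "n_down": len(down),
            "up_ids": up["metabolite_id"].tolist(),
            "down_ids": down["metabolite_id"].tolist(),
        }
    names = list(tables)
    venn: dict[str, int] = {}
    for mask in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if mask >> i & 1]
        inter = set.intersection(*(sig_sets[m] for m in members)) \
            if members else set()
        venn["&".join(members)] = len(inter)
    report["venn"] = venn
    return report


class ModeratedANOVA:
    """Two-way factorial ANOVA with empirical-Bayes moderation.

    Parameters
    ----------
    matrix
        Complete (imputed) intensity matrix on the regularized scale.
    design
        Matching study design; must contain a single tissue.
    """

    def __init__(self, matrix: IntensityMatrix, design: StudyDesign):
        tissues = set(design.tissue)
        if len(tissues) > 1:
            raise ValidationError(
                f"one tissue at a time, got {sorted(tissues)}"
            )
        self.matrix = matrix
        self.design = design

    def fit(self, p_prior: float = 0.01, d0_override: float | None = None,
            b_base2: bool = True, adjust: str = "qvalue",
            fdr_threshold: float = 0.05) -> "ModeratedANOVAResults":
        linear = fit_anova_models(self.matrix, self.design)
        prior, tables = moderate_statistics(
            linear, p_prior=p_prior, d0_override=d0_override,
            b_base2=b_base2, adjust=adjust,
        )
        return ModeratedANOVAResults(self, linear, prior, tables,
                                     fdr_threshold)


class ModeratedANOVAResults:
    """Fitted moderated ANOVA: effect tables, prior, and report helpers."""

    def __init__(self, model: ModeratedANOVA, linear: LinearFit,
                 prior: EBayesPrior, tables: dict[str, EffectTable],
                 fdr_threshold: float):
        self.model = model
        self.linear = linear
        self.prior = prior
        self.tables = tables
        self.fdr_threshold = fdr_threshold

    def report(self, threshold: float | None = None) -> dict:
        return effect_tables(self.tables,
                             threshold or self.fdr_threshold)

    def summary(self) -> str:
        rep = self.report()
        lines = [
            "Moderated two-way ANOVA (genotype x diet)",
            f"  metabolites: {len(self.linear.metabolite_ids)}, "
            f"residual df: {self.linear.df_residual}",
            f"  prior df d0: {self.prior.d0:.4g}, prior variance s0^2: "
            f"{self.prior.s02:.4g}, p_prior: {self.prior.p_prior}",
            f"  significance threshold (adjusted p): {self.fdr_threshold}",
        ]
        for name, info in rep["contrasts"].items():
            lines.append(
                f"  {name:<12s} significant: {info['n_significant']:>4d} "
                f"(up {info['n_up']}, down {info['n_down']})"
            )
        return "\n".join(lines)
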