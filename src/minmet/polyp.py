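"""Zero-inflated negative-binomial (ZINB) regression of polyp counts.

The count outcome C_i per mouse is modelled as the two-component mixture

    Pr(C = c | x, z) = pi * I0(c) + (1 - pi) * f(c | x),

where ``f`` is negative binomial with mean ``exp(x' beta)`` and dispersion
``theta``, and the zero-inflation probability ``pi`` has an intercept-only
logit model.  The count covariates are ``[1, G, D, G*D*Y]`` with 0/1 factor
coding (reference WT, LF) and Y the metabolite level of one plasma
metabolite, so the three-way term is literally zero outside the
mutant/high-fat cell.  Inference on the three-way coefficient is by Wald
tests from the observed-information covariance.

The module also provides per-group correlation/regression summaries (with
the degenerate constant-count contract: r^2 = 0, Pearson rho undefined) and
the Pearson chi-square test of independence for 2x2 count tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import norm, t as t_dist

from . import fdr as _fdr
from .io import (
    EffectTable,
    IntensityMatrix,
    PolypCounts,
    StudyDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

COEF_NAMES = ("beta0", "beta_G", "beta_D", "beta_GDY")
COEF_CLAMP = 20.0
NEG_INF = -np.inf


class DegenerateMarginError(ValueError):
    """A 2x2 table has a zero row or column margin."""


@dataclass
class ZinbModel:
    """Fitted ZINB parameters and diagnostics."""

    beta: np.ndarray                  # count coefficients (beta0, G, D, GDY)
    theta: float                      # NB dispersion (> 0)
    gamma0: float                     # zero-component intercept (logit link)
    cov: np.ndarray                   # covariance of (beta, theta, gamma0)
    loglik: float
    converged: bool
    boundary_flag: bool
    n_obs: int
    df_resid: int = 0
    start_loglik: float = np.nan

    @property
    def pi(self) -> float:
        return float(expit(self.gamma0))

    def wald(self, index: int = 3) -> tuple[float, float]:
        """Wald statistic and two-sided p for a count coefficient.

        The reference distribution is t with the residual degrees of freedom
        (n minus the number of model parameters) rather than normal — at the
        cohort's n = 20 the normal reference is visibly anticonservative.
        """
        se = np.sqrt(self.cov[index, index]) if self.cov[index, index] > 0 \
            else np.nan
        if not np.isfinite(se) or se == 0:
            return np.nan, np.nan
        z = self.beta[index] / se
        if self.df_resid > 0:
            p = 2.0 * t_dist.sf(abs(z), self.df_resid)
        else:
            p = 2.0 * norm.sf(abs(z))
        return float(z), float(p)

    def conf_int(self, index: int = 3, level: float = 0.95):
        se = np.sqrt(max(self.cov[index, index], 0.0))
        half = norm.ppf(0.5 + level / 2.0) * se
        return self.beta[index] - half, self.beta[index] + half

    def summary(self) -> str:
        lines = ["Zero-inflated negative-binomial fit",
                 f"  n = {self.n_obs}, loglik = {self.loglik:.4f}, "
                 f"converged = {self.converged}, boundary = {self.boundary_flag}"]
        for i, name in enumerate(COEF_NAMES):
            z, p = self.wald(i)
            se = np.sqrt(self.cov[i, i]) if self.cov[i, i] > 0 else np.nan
            lines.append(f"  {name:<9s} {self.beta[i]:>10.4f}  se {se:>8.4f}"
                         f"  z {z:>8.3f}  p {p:.3g}")
        lines.append(f"  theta     {self.theta:>10.4f}")
        lines.append(f"  pi (zero) {self.pi:>10.4f}  (gamma0 {self.gamma0:.4f})")
        return "\n".join(lines)


def _nb_logpmf(counts: np.ndarray, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial log pmf with mean/dispersion parameterisation."""
    log_theta_frac = np.log(theta) - np.log(theta + mean)
    log_mean_frac = np.where(mean > 0, np.log(mean) - np.log(theta + mean),
                             -np.inf)
    out = (gammaln(counts + theta) - gammaln(theta) - gammaln(counts + 1)
           + theta * log_theta_frac
           + np.where(counts > 0, counts * log_mean_frac, 0.0))
    return out


def zinb_loglik(counts, exog, beta, gamma0: float, theta: float) -> float:
    """Log-likelihood of the ZINB mixture, computed in log space.

    ``counts`` are non-negative integers, ``exog`` the count-model design
    matrix, ``gamma0`` the intercept of the logit zero model.  ``pi = 1``
    with any positive count present returns ``-inf`` (impossible event).
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        as_float = np.asarray(counts, dtype=float)
        if not np.all(as_float == np.round(as_float)):
            raise ValidationError("counts must be integers")
        counts = as_float.astype(int)
    if np.any(counts < 0):
        raise ValidationError("counts must be >= 0")
    if theta <= 0:
        raise ValidationError("theta must be > 0")
    exog = np.asarray(exog, dtype=float)
    beta = np.asarray(beta, dtype=float)

    eta = exog @ beta
    mean = np.exp(eta)
    log_pi = -np.logaddexp(0.0, -gamma0)        # log expit(gamma0)
    log_1mpi = -np.logaddexp(0.0, gamma0)       # log (1 - pi)
    lp = _nb_logpmf(counts, mean, theta)
    zero = counts == 0
    ll = np.empty(counts.shape[0])
    ll[zero] = np.logaddexp(log_pi, log_1mpi + lp[zero])
    ll[~zero] = log_1mpi + lp[~zero]
    total = float(ll.sum())
    return total if np.isfinite(total) else NEG_INF


def build_count_design(design: StudyDesign, y: np.ndarray,
                       center: bool = True) -> np.ndarray:
    """Count-model design ``[1, G, D, G*D*Y]`` with 0/1 factor coding.

    ``y`` is mean-centred by default: because the mutant/high-fat cell has
    its own effective intercept (beta0 + beta_G + beta_D), centring is a
    pure reparametrisation of the same model, but it keeps the maximiser
    away from the coefficient clamp that would otherwise absorb
    ``-slope * mean(y)`` into beta_D.
    """
    g = np.where(np.array(design.genotype) == "MU", 1.0, 0.0)
    d = np.where(np.array(design.diet) == "HF", 1.0, 0.0)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != g.shape[0]:
        raise ValidationError("metabolite values do not match design length")
    if center:
        y = y - y.mean()
    return np.column_stack([np.ones_like(g), g, d, g * d * y])


def _negll_and_grad(counts: np.ndarray, exog: np.ndarray,
                    params: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its analytic gradient.

    ``params`` is (beta, gamma0, log theta); the gradient is checked against
    finite differences in the test suite.
    """
    from scipy.special import digamma

    k = exog.shape[1]
    beta, gamma0, log_theta = params[:k], params[k], params[k + 1]
    theta = float(np.exp(log_theta))
    eta = exog @ beta
    with np.errstate(over="ignore"):
        mu = np.exp(eta)
    if not np.all(np.isfinite(mu)):
        return 1e12, np.zeros(k + 2)
    pi = float(expit(gamma0))
    log_pi = -np.logaddexp(0.0, -gamma0)
    log_1mpi = -np.logaddexp(0.0, gamma0)
    lp = _nb_logpmf(counts, mu, theta)
    zero = counts == 0
    ll = np.empty(counts.shape[0])
    ll[zero] = np.logaddexp(log_pi, log_1mpi + lp[zero])
    ll[~zero] = log_1mpi + lp[~zero]
    total = ll.sum()
    if not np.isfinite(total):
        return 1e12, np.zeros(k + 2)

    grad = np.zeros(k + 2)
    tm = theta + mu
    # positive counts
    pos = ~zero
    if pos.any():
        c = counts[pos]
        mu_p, tm_p = mu[pos], tm[pos]
        dmu = c - mu_p * (c + theta) / tm_p          # d ll / d eta
        grad[:k] += exog[pos].T @ dmu
        grad[k] += -pi * pos.sum()
        dtheta = (digamma(c + theta) - digamma(theta) + np.log(theta) + 1.0
                  - np.log(tm_p) - (theta + c) / tm_p)
        grad[k + 1] += theta * dtheta.sum()
    # zeros: A = pi + (1 - pi) f0 with log f0 = lp at c = 0
    if zero.any():
        mu_z, tm_z = mu[zero], tm[zero]
        log_a = ll[zero]
        w = np.exp(log_1mpi + lp[zero] - log_a)      # (1 - pi) f0 / A
        dmu0 = -theta * mu_z / tm_z
        grad[:k] += exog[zero].T @ (w * dmu0)
        grad[k] += float(np.sum(pi * (1.0 - pi) * (1.0 - np.exp(lp[zero]))
                                / np.exp(log_a)))
        dtheta0 = np.log(theta) + 1.0 - np.log(tm_z) - theta / tm_z
        grad[k + 1] += theta * float(np.sum(w * dtheta0))
    return float(-total), -grad


def _hessian_from_grad(grad, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient (symmetrised)."""
    k = x.size
    h = np.empty((k, k))
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        h[i] = (grad(x + ei) - grad(x - ei)) / (2 * steps[i])
    return 0.5 * (h + h.T)


def fit_zinb_design(counts: np.ndarray, exog: np.ndarray,
                    max_iter: int = 300,
                    fixed_theta: float | None = None) -> ZinbModel:
    """Maximum-likelihood ZINB fit for an arbitrary count design matrix.

    Optimises (beta, gamma0, log theta) by L-BFGS-B from data-driven starting
    values; count coefficients and gamma0 are clamped to |.| <= 20, with
    ``boundary_flag`` set when a clamp binds or the zero proportion is at the
    boundary.  Non-convergence is reported via ``converged``; never raises.
    """
    counts = np.asarray(counts)
    exog = np.asarray(exog, dtype=float)
    n, k = exog.shape
    positives = counts > 0

    beta_start = np.zeros(k)
    if positives.any():
        beta_start[0] = np.log(counts[positives].mean())
    zero_frac = float((~positives).mean())
    excess = np.clip(zero_frac, 0.02, 0.98)
    gamma0_start = float(np.log(excess / (1.0 - excess)))
    x0 = np.concatenate([beta_start, [gamma0_start, 0.0]])  # log theta = 0

    def unpack(params):
        return params[:k], params[k], float(np.exp(params[k + 1]))

    def neg_ll(params):
        beta, gamma0, theta = unpack(params)
        ll = zinb_loglik(counts, exog, beta, gamma0, theta)
        return -ll if np.isfinite(ll) else 1e12

    def neg_ll_and_grad(params):
        return _negll_and_grad(counts, exog, params)

    if fixed_theta is not None:
        log_theta_bounds = (np.log(fixed_theta), np.log(fixed_theta))
        x0[k + 1] = np.log(fixed_theta)
    else:
        log_theta_bounds = (np.log(1e-3), np.log(1e6))
    bounds = [(-COEF_CLAMP, COEF_CLAMP)] * k + \
             [(-COEF_CLAMP, COEF_CLAMP), log_theta_bounds]
    start_ll = -neg_ll(x0)
    result = minimize(neg_ll_and_grad, x0, jac=True, method="L-BFGS-B",
                      bounds=bounds,
                      options={"maxiter": max_iter, "maxfun": 4 * max_iter})
    beta, gamma0, theta = unpack(result.x)

    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])
    at_bound = (result.x <= lower + 1e-6) | (result.x >= upper - 1e-6)
    pi_hat = float(expit(gamma0))
    boundary = bool(at_bound.any() or pi_hat > 0.999 or pi_hat < 0.001)

    # Covariance of (beta, theta, gamma0) from the observed information,
    # delta-mapped for theta = exp(u).  Parameters stuck at the clamp
    # (separation from all-zero cells) are held fixed: the Hessian is taken
    # over the interior block only, which keeps Wald tests for interior
    # coefficients well defined.
    kk = k + 2
    cov_full = np.full((kk, kk), np.nan)
    free = np.nonzero(~at_bound)[0]
    if free.size:
        def grad_free(sub):
            params = result.x.copy()
            params[free] = sub
            return _negll_and_grad(counts, exog, params)[1][free]

        hess = _hessian_from_grad(grad_free, result.x[free])
        cov_free = np.linalg.pinv(hess)
        cov_full[np.ix_(free, free)] = cov_free
    jac = np.eye(kk)
    jac[k + 1, k + 1] = theta            # d theta / d log theta
    cov_full = jac @ np.nan_to_num(cov_full, nan=0.0) @ jac.T
    nan_rows = np.asarray(at_bound)
    cov_full[nan_rows, :] = np.nan
    cov_full[:, nan_rows] = np.nan
    # reorder from (beta, gamma0, theta) -> (beta, theta, gamma0)
    order = list(range(k)) + [k + 1, k]
    cov = cov_full[np.ix_(order, order)]

    converged = bool(result.success)
    if not converged:
        # L-BFGS-B can stall in the line search on the separation ridge while
        # the interior gradient has effectively vanished; accept those fits.
        grad = _projected_gradient(neg_ll, result.x, lower, upper)
        converged = bool(np.max(np.abs(grad)) < 1e-2 * (1.0 + abs(result.fun)))

    return ZinbModel(
        beta=beta.copy(), theta=theta, gamma0=float(gamma0), cov=cov,
        loglik=float(-result.fun), converged=converged,
        boundary_flag=boundary, n_obs=n, df_resid=max(n - kk, 0),
        start_loglik=start_ll,
    )


def _projected_gradient(fun, x: np.ndarray, lower: np.ndarray,
                        upper: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    grad = np.empty(x.size)
    f0 = fun(x)
    for i in range(x.size):
        step = eps * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] = min(x[i] + step, upper[i])
        xm = x.copy()
        xm[i] = max(x[i] - step, lower[i])
        denom = xp[i] - xm[i]
        grad[i] = (fun(xp) - fun(xm)) / denom if denom > 0 else 0.0
    g = grad.copy()
    g[(x <= lower + 1e-9) & (grad > 0)] = 0.0
    g[(x >= upper - 1e-9) & (grad < 0)] = 0.0
    return g


def fit_zinb(counts: PolypCounts, design: StudyDesign,
             y: np.ndarray) -> ZinbModel:
    """Fit the polyp-count ZINB for one metabolite's per-mouse values."""
    mouse_design = _mouse_level_design(design)
    c = counts.aligned_to(mouse_design.sample_ids)
    exog = build_count_design(mouse_design, y)
    return fit_zinb_design(c, exog)


def _mouse_level_design(design: StudyDesign) -> StudyDesign:
    """Collapse a (possibly multi-tissue) design to one record per mouse.

    The returned design uses mouse ids as sample ids so count vectors align.
    """
    seen: dict[str, int] = {}
    idx = []
    for i, m in enumerate(design.mouse_id):
        if m not in seen:
            seen[m] = i
            idx.append(i)
    return StudyDesign(
        [design.mouse_id[i] for i in idx],
        [design.mouse_id[i] for i in idx],
        [design.genotype[i] for i in idx],
        [design.diet[i] for i in idx],
        [design.tissue[i] for i in idx],
    )


class ZeroInflatedNB:
    """Model object for the polyp-count ZINB regression.

    ``ZeroInflatedNB.from_cohort(counts, design, y)`` builds the canonical
    ``[1, G, D, G*D*Y]`` design from a study design and per-mouse metabolite
    values; the plain constructor accepts an arbitrary design matrix.
    """

    def __init__(self, counts, exog):
        self.counts = np.asarray(counts)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.shape[0] != self.counts.shape[0]:
            raise ValidationError("counts and design matrix lengths differ")

    @classmethod
    def from_cohort(cls, counts: PolypCounts, design: StudyDesign,
                    y: np.ndarray) -> "ZeroInflatedNB":
        mouse_design = _mouse_level_design(design)
        c = counts.aligned_to(mouse_design.sample_ids)
        return cls(c, build_count_design(mouse_design, y))

    def loglike(self, beta, gamma0: float, theta: float) -> float:
        return zinb_loglik(self.counts, self.exog, beta, gamma0, theta)

    def fit(self, max_iter: int = 300) -> ZinbModel:
        return fit_zinb_design(self.counts, self.exog, max_iter=max_iter)


def associate_metabolites(counts: PolypCounts, design: StudyDesign,
                          matrix: IntensityMatrix,
                          adjust: str = "qvalue") -> tuple[EffectTable, dict]:
    """Per-metabolite ZINB association of polyp counts with plasma levels.

    Fits the ZINB for every metabolite, collects the Wald p of the three-way
    G*D*Y coefficient, and adjusts across metabolites (q-values by default).
    Returns ``(EffectTable, diagnostics)``; non-converged fits are flagged
    and excluded from significance calls (their adjusted p is set to NaN).
    """
    mouse_design = _mouse_level_design(
        design.subset_tissue("PLA") if "PLA" in design.tissue else design
    )
    c = counts.aligned_to(mouse_design.sample_ids)
    if matrix.missing_mask.any():
        raise ValidationError("association requires an imputed matrix")
    col_index = {s: i for i, s in enumerate(matrix.sample_ids)}
    # matrix columns are per-sample; map mouse -> its plasma sample column
    sample_for_mouse = {}
    for sid, mid in zip(design.sample_ids, design.mouse_id):
        if sid in col_index and mid not in sample_for_mouse:
            if design.tissue[design.sample_ids.index(sid)] == "PLA" \
               or "PLA" not in design.tissue:
                sample_for_mouse[mid] = sid
    try:
        cols = [col_index[sample_for_mouse[m]] for m in mouse_design.sample_ids]
    except KeyError as exc:
        raise ValidationError(f"no plasma sample for mouse {exc}") from exc

    rows = []
    n_fail = 0
    for j, mid in enumerate(matrix.metabolite_ids):
        y = matrix.values[j, cols]
        model = fit_zinb_design(c, build_count_design(mouse_design, y))
        z, p = model.wald(3)
        ok = model.converged and np.isfinite(p)
        if not ok:
            n_fail += 1
        rows.append({"metabolite_id": mid, "logFC": model.beta[3],
                     "t": z, "B": np.nan, "p_raw": p if ok else np.nan,
                     "converged": ok})
    frame = pd.DataFrame(rows)
    frac_fail = n_fail / max(len(frame), 1)
    if frac_fail > 0.5:
        raise ValidationError(
            f"{n_fail}/{len(frame)} ZINB fits failed to converge; "
            "review model parameters"
        )
    ok_mask = frame["converged"].to_numpy()
    p_ok = frame.loc[ok_mask, "p_raw"].to_numpy()
    if adjust == "qvalue":
        q_ok = _fdr.compute_qvalues(p_ok).q
    else:
        q_ok = _fdr.bh_adjust(p_ok)
    frame["p_adj"] = np.nan
    frame.loc[ok_mask, "p_adj"] = q_ok
    frame.loc[~ok_mask, "p_raw"] = np.nan
    # EffectTable requires p in [0,1]; NaN rows sort last
    ann = matrix.annotation_frame()
    frame = frame.join(ann.reset_index(drop=True))
    table = EffectTable(frame.drop(columns=["converged"]),
                        contrast="polyp_association")
    diagnostics = {"n_nonconverged": n_fail,
                   "nonconverged_ids": frame.loc[~ok_mask,
                                                 "metabolite_id"].tolist()}
    return table, diagnostics


UNDEFINED = float("nan")


def group_correlations(counts: PolypCounts, y: np.ndarray,
                       design: StudyDesign) -> dict[str, dict[str, float]]:
    """Least-squares line, r^2 and Pearson rho of counts on y per 2x2 group.

    Constant count vectors (e.g. all-zero wild-type groups) give r^2 = 0
    with an undefined (NaN) correlation rather than an exception, and groups
    of size < 2 give undefined sentinels throughout.
    """
    mouse_design = _mouse_level_design(design)
    c = counts.aligned_to(mouse_design.sample_ids).astype(float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(mouse_design):
        raise ValidationError("y does not match the number of mice")
    out: dict[str, dict[str, float]] = {}
    labels = np.array(mouse_design.group_labels())
    for group in sorted(set(labels)):
        sel = labels == group
        cc, yy = c[sel], y[sel]
        entry = {"n": int(sel.sum()), "rho": UNDEFINED, "r2": UNDEFINED,
                 "slope": UNDEFINED, "intercept": UNDEFINED}
        if sel.sum() >= 2:
            if np.ptp(cc) == 0 or np.ptp(yy) == 0:
                # vertical/horizontal alignment: no variance to explain
                entry["r2"] = 0.0
                if np.ptp(yy) > 0:
                    entry["slope"] = 0.0
                    entry["intercept"] = float(cc.mean())
            else:
                slope, intercept = np.polyfit(yy, cc, 1)
                rho = float(np.corrcoef(yy, cc)[0, 1])
                entry.update(rho=rho, r2=rho ** 2, slope=float(slope),
                             intercept=float(intercept))
        out[group] = entry
    return out


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence for a 2x2 count table.

    No continuity correction; df = 1.  A zero row or column margin makes the
    expected counts undefined and raises :class:`DegenerateMarginError`.
    """
    from scipy.stats import chi2

    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if np.any(t < 0) or not np.all(t == np.round(t)):
        raise ValidationError("table entries must be non-negative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0):
        raise DegenerateMarginError(
            f"zero row margin (row {int(np.argmax(rows == 0))})"
        )
    if np.any(cols == 0):
        raise DegenerateMarginError(
            f"zero column margin (column {int(np.argmax(cols == 0))})"
        )
    n = t.sum()
    expected = np.outer(rows, cols) / n
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, 1, float(chi2.sf(stat, 1))


def mutant_polyp_share(table) -> float:
    """Percentage of all polyps occurring in mutant animals.

    ``table`` is the 2x2 genotype (rows WT, MU) by diet (columns LF, HF)
    table of total polyp counts.
    """
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total == 0:
        raise ValidationError("no polyps counted")
    return float(100.0 * t[1].sum() / total)
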