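"""Optical-vs-electrical calibration and the study's statistical tests.

Origin-constrained regression with a distance-to-identity summary for
comparing normalized readouts of the same release train; the Wilcoxon
rank-sum test (exact for small samples); Bonferroni-adjusted significance
levels; a Gaussian random-intercept mixed model for clustered per-cell
measurements; and first-order Gaussian error propagation for derived
quantities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


@dataclass
class RegressionResult:
    """Origin-constrained linear fit y = slope * x."""

    slope: float
    r_squared: float
    p_value: float
    d_identity: float     # mean squared distance of (x, y) to the identity
    n_points: int
    se_slope: float
    negative_r2: bool = False


def regress_through_origin(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line through the origin with identity-distance summary.

    slope = sum(xy)/sum(x^2); R^2 = 1 - SS_res/SS_tot with SS_tot about the
    mean of y (this convention can go negative for a poor constrained fit;
    such values are reported as-is and flagged); p from the t statistic of
    the slope with n - 1 degrees of freedom; d = mean((y - x)^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all-zero x: slope undefined")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    n = x.size
    if ss_res == 0:
        se, p = 0.0, 0.0
    else:
        se = math.sqrt(ss_res / (n - 1) / sxx)
        t = slope / se
        p = 2.0 * sps.t.sf(abs(t), n - 1)
    d = float(np.mean((y - x) ** 2))
    return RegressionResult(slope=slope, r_squared=float(r2), p_value=float(p),
                            d_identity=d, n_points=int(n), se_slope=float(se),
                            negative_r2=bool(r2 < 0))


def compare_readouts(
    optical: Sequence[float],
    electrical: Sequence[float],
    normalize: bool = False,
) -> Tuple[RegressionResult, pd.DataFrame]:
    """Origin-constrained regression of the optical on the electrical readout.

    With ``normalize`` each sequence is divided by its first element, so
    readouts in different units can be compared; a slope near 1 with small
    distance-to-identity d indicates that the two readouts are linearly
    related measures of the same underlying release. Note that per-train
    normalization pins the first point to (1, 1): a compressive (saturating)
    optical readout then lies above the identity (slope > 1), whereas on a
    common absolute calibration (normalize=False, both readouts scaled to
    their small-signal gain) saturation compresses the optical values below
    the identity (slope < 1).
    """
    opt = np.asarray(optical, dtype=float)
    ele = np.asarray(electrical, dtype=float)
    if opt.size != ele.size:
        raise ValueError("readouts must have equal train lengths")
    if normalize:
        if opt[0] == 0 or ele[0] == 0:
            raise ValueError("cannot normalize: zero first element")
        opt = opt / opt[0]
        ele = ele / ele[0]
    res = regress_through_origin(ele, opt)
    table = pd.DataFrame({
        "stimulus": np.arange(1, opt.size + 1),
        "electrical": ele,
        "optical": opt,
        "fitted": res.slope * ele,
    })
    return res, table


# --------------------------------------------------------------------------
# rank-sum test
# --------------------------------------------------------------------------

_EXACT_MAX_N = 12


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration of all rank assignments for combined n <= 12 (ties
    handled through midranks), normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    n, m = a.size, b.size
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2.0
    if n + m <= _EXACT_MAX_N:
        dev_obs = abs(w_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            w = float(ranks[list(combo)].sum())
            if abs(w - mu) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var == 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / math.sqrt(var)  # continuity correction
    return float(2.0 * sps.norm.sf(max(z, 0.0)))


def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted significance level alpha/m."""
    if m < 1:
        raise ValueError("number of comparisons must be at least 1")
    return alpha / m


# --------------------------------------------------------------------------
# random-intercept mixed model
# --------------------------------------------------------------------------

@dataclass
class MixedEffectResult:
    effect: float          # fixed condition effect (second level - first)
    se: float
    p: float               # Wald, two-sided
    intercept: float
    sigma_cell: float      # random-intercept SD
    sigma_resid: float
    loglik: float
    levels: Tuple[str, str]


def random_intercept_effect(
    values: Sequence[float],
    cell_ids: Sequence,
    condition_labels: Sequence,
    reml: bool = True,
) -> MixedEffectResult:
    """Fixed condition effect under a Gaussian random cell intercept.

    Model: y_ij = b0 + b1 * cond_j + u_j + e_ij with u_j ~ N(0, tau^2) per
    cell and e_ij ~ N(0, sigma^2). The marginal likelihood factorizes over
    cells (V_j = sigma^2 I + tau^2 J), so the profile log-likelihood over
    the two variance components is maximized directly; the fixed effects
    are the (maximum-likelihood) GLS estimates at the optimum. Variance
    components use REML by default (``reml=False`` for plain ML, whose
    downward-biased tau^2 makes the test anticonservative). The two-sided
    Wald p uses a t reference with (number of cells - 2) degrees of
    freedom — the effect is a between-cell contrast, and a normal
    reference is anticonservative at the cell counts typical of slice
    experiments.
    """
    y = np.asarray(values, dtype=float)
    cells = np.asarray(cell_ids)
    cond = np.asarray(condition_labels)
    if not (y.size == cells.size == cond.size):
        raise ValueError("values, cell_ids and condition_labels must align")
    unique_cells = np.unique(cells)
    if unique_cells.size < 2:
        raise ValueError("condition effect unidentifiable with a single cell")
    levels = np.unique(cond)
    if levels.size != 2:
        raise ValueError("exactly two condition levels required")
    for lev in levels:
        if np.unique(cells[cond == lev]).size < 2:
            raise ValueError(f"condition {lev!r} needs at least 2 cells")

    X = np.column_stack([np.ones(y.size), (cond == levels[1]).astype(float)])
    groups = [np.flatnonzero(cells == c) for c in unique_cells]

    def gls(sig2: float, tau2: float):
        """GLS fixed effects and profile quantities for given variances."""
        xtvx = np.zeros((2, 2))
        xtvy = np.zeros(2)
        logdet = 0.0
        quad_parts = []
        for idx in groups:
            nj = idx.size
            Xj, yj = X[idx], y[idx]
            denom = sig2 + nj * tau2
            # V^-1 = (I - (tau2/denom) J) / sig2
            w = tau2 / denom
            Xs = (Xj - w * Xj.sum(axis=0)) / sig2
            xtvx += Xj.T @ Xs
            xtvy += Xs.T @ yj
            logdet += (nj - 1) * math.log(sig2) + math.log(denom)
            quad_parts.append((idx, w))
        beta = np.linalg.solve(xtvx, xtvy)
        quad = 0.0
        for idx, w in quad_parts:
            rj = y[idx] - X[idx] @ beta
            quad += (rj @ rj - w * rj.sum() ** 2) / sig2
        return beta, xtvx, logdet, quad

    def nll(params: np.ndarray) -> float:
        sig2, tau2 = np.exp(params)
        try:
            _, xtvx, logdet, quad = gls(sig2, tau2)
        except np.linalg.LinAlgError:
            return 1e12
        out = 0.5 * (y.size * math.log(2 * math.pi) + logdet + quad)
        if reml:
            out += 0.5 * math.log(max(np.linalg.det(xtvx), 1e-300))
        return out

    var0 = float(np.var(y)) or 1.0
    best = None
    for tau_frac in (0.5, 0.05):
        start = np.log([var0 * (1 - tau_frac), var0 * tau_frac])
        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    sig2, tau2 = np.exp(best.x)
    beta, xtvx, _, _ = gls(sig2, tau2)
    cov = np.linalg.inv(xtvx)
    se = math.sqrt(cov[1, 1])
    z = beta[1] / se if se > 0 else math.inf
    df = max(unique_cells.size - 2, 1)
    p = 2.0 * sps.t.sf(abs(z), df)
    return MixedEffectResult(
        effect=float(beta[1]), se=float(se), p=float(p),
        intercept=float(beta[0]),
        sigma_cell=math.sqrt(tau2), sigma_resid=math.sqrt(sig2),
        loglik=float(-best.fun),
        levels=(str(levels[0]), str(levels[1])),
    )


def propagate_se(sigmas: Sequence[float], gradient: Sequence[float]) -> float:
    """First-order Gaussian error propagation, independent inputs.

    se = sqrt(sum_i (df/dx_i)^2 sigma_i^2) for a derived quantity
    f(x_1, ..., x_k) with the partial derivatives supplied analytically.
    """
    s = np.asarray(sigmas, dtype=float)
    g = np.asarray(gradient, dtype=float)
    if s.shape != g.shape:
        raise ValueError("sigmas and gradient must align")
    return float(np.sqrt(np.sum((g * s) ** 2)))
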