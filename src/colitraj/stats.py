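"""Shared statistical machinery for the expression/splicing pipeline.

Implements the mean-variance-weighted log-CPM transform, per-feature weighted
least squares, empirical-Bayes variance moderation (moderated t), and the
Benjamini-Hochberg and Simes multiplicity procedures.  These primitives are
the common substrate of the fixed-day and trajectory analyses and of the
exon-usage statistics, so they are written once here and validated against
independent oracles in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix

logger = logging.getLogger("colitraj")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class WeightedExpression:
    """log2-CPM matrix with positive observation-level precision weights."""

    E: pd.DataFrame          # features x samples, log2-CPM
    weights: np.ndarray      # same shape, > 0
    design_labels: pd.DataFrame | None = None  # per-sample covariates

    def __post_init__(self) -> None:
        if self.weights.shape != self.E.shape:
            raise ValueError("weights must match E in shape")
        if not np.all(self.weights > 0):
            raise ValueError("weights must be strictly positive")
        if not np.all(np.isfinite(self.E.to_numpy())):
            raise ValueError("E must be finite")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.E.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.E.columns)

    def subset_samples(self, sample_ids) -> "WeightedExpression":
        idx = [self.E.columns.get_loc(s) for s in sample_ids]
        labels = None
        if self.design_labels is not None:
            labels = self.design_labels.loc[list(sample_ids)]
        return WeightedExpression(self.E.iloc[:, idx], self.weights[:, idx], labels)


@dataclass
class LinearFit:
    """Per-feature WLS fit: coefficients, unscaled SEs, residual sd and df."""

    coefficients: pd.DataFrame     # features x design columns, log2 scale
    stdev_unscaled: pd.DataFrame   # same shape; SE = stdev_unscaled * sigma
    sigma: pd.Series               # residual sd per feature
    df_residual: pd.Series         # residual degrees of freedom
    design: pd.DataFrame           # samples x columns
    cov_unscaled: np.ndarray       # (features, p, p) unscaled coefficient covariance


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics for one tested coefficient set."""

    df_prior: float
    var_prior: float
    var_post: pd.Series            # posterior residual variances
    t: pd.DataFrame                # moderated t per coefficient
    p: pd.DataFrame                # two-sided p per coefficient
    df_total: pd.Series            # d0 + d_g


# ---------------------------------------------------------------------------
# log-CPM with precision weights
# ---------------------------------------------------------------------------


def logcpm(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """log2((count + 0.5) / (library + 1) * 1e6)."""
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def logcpm_transform(
    counts: CountMatrix,
    design: pd.DataFrame | None = None,
    span: float = 0.5,
    min_features: int = 50,
) -> WeightedExpression:
    """Transform counts to log2-CPM with mean-variance precision weights.

    A linear model (``design``, or an intercept when omitted) is fitted to
    each feature's log2-CPM; the square-root residual standard deviations are
    smoothed against average log2 count with lowess, and each observation's
    weight is the predicted standard deviation at its fitted log2 count raised
    to the power -4.  With fewer than ``min_features`` features there is not
    enough data to fit the trend, and unit weights are used with a warning.
    """
    y = counts.counts.to_numpy(dtype=float)
    lib = counts.library_sizes.to_numpy(dtype=float)
    n_feat, n_samp = y.shape
    E = logcpm(y, lib)

    if design is None:
        X = np.ones((n_samp, 1))
    else:
        X = np.asarray(design, dtype=float)

    if n_feat < min_features or n_samp <= X.shape[1]:
        warnings.warn(
            f"{n_feat} features: too few to fit a mean-variance trend; "
            "using unit weights"
        )
        W = np.ones_like(E)
        return WeightedExpression(pd.DataFrame(E, index=counts.counts.index,
                                               columns=counts.counts.columns), W)

    # unweighted per-feature linear fit
    beta, *_ = np.linalg.lstsq(X, E.T, rcond=None)   # (p, features)
    fitted = (X @ beta).T                            # features x samples
    resid = E - fitted
    df_res = n_samp - X.shape[1]
    s = np.sqrt((resid ** 2).sum(axis=1) / df_res)
    sqrt_s = np.sqrt(s)

    # mean-variance trend in average log2-count space
    log2_lib_bar = np.mean(np.log2(lib + 1.0))
    mean_logcount = E.mean(axis=1) + log2_lib_bar - np.log2(1e6)
    trend = lowess(sqrt_s, mean_logcount, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    # predicted sqrt-sd at each observation's fitted log2 count
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, tx, ty)
    pred = np.clip(pred, max(ty.min(), 1e-4), None)
    W = pred ** -4.0
    return WeightedExpression(
        pd.DataFrame(E, index=counts.counts.index, columns=counts.counts.columns), W
    )


# ---------------------------------------------------------------------------
# weighted least squares, batched over features
# ---------------------------------------------------------------------------


def _check_full_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by rank-revealing QR on the pivoted matrix
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [str(columns[j]) for j in range(len(diag))
                   if diag[j] < 1e-10 * max(diag.max(), 1.0)]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")


def fit_weighted_lm(we: WeightedExpression, design: pd.DataFrame) -> LinearFit:
    """Per-feature weighted least squares of E on the design matrix.

    Coefficients solve (X'WX) b = X'Wy per feature; the residual variance is
    the weighted RSS over n - p, and ``stdev_unscaled`` is the square root of
    the diagonal of (X'WX)^-1 so that SE = stdev_unscaled * sigma.
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if p > n:
        raise ValueError("more design columns than samples")
    _check_full_rank(X, design.columns)

    Y = we.E.to_numpy()
    W = we.weights
    # batched normal equations
    XtWX = np.einsum("gn,np,nq->gpq", W, X, X, optimize=True)
    XtWy = np.einsum("gn,np,gn->gp", W, X, Y, optimize=True)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    cov = np.linalg.inv(XtWX)
    resid = Y - beta @ X.T
    df_res = n - p
    if df_res >= 1:
        sigma2 = np.einsum("gn,gn->g", W * resid, resid) / df_res
    else:
        sigma2 = np.full(Y.shape[0], np.nan)
    su = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))

    idx = we.E.index
    cols = list(design.columns)
    return LinearFit(
        coefficients=pd.DataFrame(beta, index=idx, columns=cols),
        stdev_unscaled=pd.DataFrame(su, index=idx, columns=cols),
        sigma=pd.Series(np.sqrt(np.maximum(sigma2, 0.0)), index=idx),
        df_residual=pd.Series(np.full(len(idx), float(df_res)), index=idx),
        design=design,
        cov_unscaled=cov,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of a scaled F prior to sample variances.

    Matches moments of log(s^2): if s^2 ~ s0^2 F(df, d0) then
    E log s^2 = log s0^2 + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    and Var log s^2 = trigamma(df/2) + trigamma(d0/2); the second equation
    yields d0 by trigamma inversion, the first yields s0^2.
    """
    ok = (df > 0) & np.isfinite(s2) & (s2 > 0)
    s2 = s2[ok]
    df = df[ok]
    if s2.size < 2:
        raise ValueError("need >= 2 positive finite variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = (e - e_mean) @ (e - e_mean) / (e.size - 1)
    # subtract the sampling component of the variance of log s^2
    excess = e_var - np.mean(special.polygamma(1, df / 2.0))
    if excess <= 0:
        df_prior = np.inf
        var_prior = float(np.exp(e_mean))
    else:
        df_prior = 2.0 * _trigamma_inverse(float(excess))
        var_prior = float(np.exp(
            e_mean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        ))
    return df_prior, var_prior


def squeeze_var(s2: np.ndarray, df: np.ndarray,
                df_prior: float, var_prior: float) -> np.ndarray:
    """Posterior variances (d0*s0^2 + d*s^2) / (d0 + d)."""
    if np.isinf(df_prior):
        return np.full_like(np.asarray(s2, dtype=float), var_prior)
    return (df_prior * var_prior + df * s2) / (df_prior + df)


def moderate(fit: LinearFit, coefficients: list[str] | None = None) -> ModeratedStats:
    """Empirical-Bayes moderated t statistics for the requested coefficients.

    The prior (d0, s0^2) is estimated by method of moments on the log residual
    variances; posterior variances shrink each feature's s_g^2 toward s0^2 and
    the moderated t is referred to a t distribution on d0 + d_g df.  When all
    residual variances coincide the prior df is infinite and the posterior is
    exactly s0^2 for every feature.
    """
    cols = coefficients if coefficients is not None else list(fit.coefficients.columns)
    s2 = fit.sigma.to_numpy() ** 2
    df = fit.df_residual.to_numpy()
    testable = df >= 1
    if testable.sum() < 2:
        raise ValueError("need >= 2 features with residual df >= 1")
    if np.ptp(s2[testable]) < 1e-300:
        df_prior, var_prior = np.inf, float(s2[testable][0])
    else:
        df_prior, var_prior = fit_f_dist(s2[testable], df[testable])
    var_post = squeeze_var(s2, df, df_prior, var_prior)
    df_total = df + (df_prior if np.isfinite(df_prior) else 1e30)

    coef = fit.coefficients[cols].to_numpy()
    su = fit.stdev_unscaled[cols].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (su * np.sqrt(var_post)[:, None])
    p = 2.0 * sps.t.sf(np.abs(t), df_total[:, None])
    p[~testable] = np.nan
    t[~testable] = np.nan

    idx = fit.coefficients.index
    return ModeratedStats(
        df_prior=df_prior,
        var_prior=var_prior,
        var_post=pd.Series(var_post, index=idx),
        t=pd.DataFrame(t, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        df_total=pd.Series(df_total, index=idx),
    )


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN inputs propagate as NaN (with a warning) and do not count toward m.
    Ties are handled by a stable sort so the result is deterministic.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() < p.size:
        warnings.warn("bh_adjust: NaN p-values propagated as NaN")
    pv = p[ok]
    if pv.size == 0:
        return q
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def simes_combine(p) -> float:
    """Simes combined p-value: min_i p_(i) * m / i."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("simes_combine: empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    ps = np.sort(p)
    m = ps.size
    return float(min(np.min(ps * m / np.arange(1, m + 1)), 1.0))


# ---------------------------------------------------------------------------
# rank statistics used across modules
# ---------------------------------------------------------------------------


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with exact p for n <= 9.

    For n <= 9 the p-value enumerates all permutations of one rank vector
    (two-sided, P(|rho| >= |rho_obs|)); for larger n the normal approximation
    z = rho * sqrt(n - 1) is used.  Returns (nan, nan) when either vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
    rho = float(rx_c @ ry_c / denom)
    if n <= 9:
        from itertools import permutations

        perms = np.array(list(permutations(range(n))))
        ry_perm = ry_c[perms]                       # (n!, n)
        rhos = ry_perm @ rx_c / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        z = rho * np.sqrt(n - 1.0)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return rho, min(p, 1.0)


def hypergeom_overlap_p(overlap: int, set_a: int, set_b: int, universe: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap) for two sets in a universe."""
    if overlap > min(set_a, set_b):
        raise ValueError("overlap cannot exceed either set size")
    if max(set_a, set_b) > universe:
        raise ValueError("universe smaller than a set")
    return float(sps.hypergeom.sf(overlap - 1, universe, set_a, set_b))
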