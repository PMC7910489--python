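"""Negative-binomial quasi-likelihood testing engine.

The shared statistical machinery of the differential-interaction,
differentially-interacting-promoter, differential-TAD-boundary and
differential-expression stages: batched IRLS fitting of NB generalized linear
models with log link and offsets, Cox-Reid adjusted-profile-likelihood
dispersion estimation (common and abundance-trended), empirical-Bayes
squeezing of quasi-likelihood dispersions toward a mean-dependent trend,
quasi-likelihood F-tests, fold-change-threshold (TREAT) tests,
Benjamini-Hochberg adjustment and cross-transition pattern classification.

Counts for F features across n libraries are modelled as
``y_fi ~ NB(mu_fi, phi_f)`` with ``log mu_fi = x_i' beta_f + o_fi`` where the
offsets ``o`` absorb library size and normalization.  Deviations of the
per-feature deviance from the NB model are captured by a quasi-dispersion
which is moderated across features before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.linalg import null_space

from .normalize import loess_fit

__all__ = [
    "oneway_design",
    "transition_contrasts",
    "NBGLMFit",
    "QLDispersion",
    "fit_nb_glm",
    "nb_deviance",
    "estimate_common_dispersion",
    "estimate_trended_dispersion",
    "squeeze_ql_dispersions",
    "ql_f_test",
    "treat_test",
    "bh_adjust",
    "classify_patterns",
]

LN2 = np.log(2.0)
_ETA_LOW, _ETA_HIGH = -30.0, 30.0
_MAX_ITER = 50
_DEV_TOL = 1e-8


def oneway_design(groups, levels=None):
    """One-way layout: one indicator column per condition group.

    Returns ``(X, levels)`` where each row of X sums to 1.
    """
    groups = list(groups)
    if levels is None:
        levels = list(dict.fromkeys(groups))
    X = np.zeros((len(groups), len(levels)))
    for i, g in enumerate(groups):
        X[i, levels.index(g)] = 1.0
    if np.linalg.matrix_rank(X) < len(levels):
        raise ValueError("design matrix is not of full column rank")
    return X, list(levels)


def transition_contrasts(levels) -> dict[str, np.ndarray]:
    """Contrast vectors for each consecutive stage transition (later - earlier)."""
    out = {}
    for a, b in zip(levels[:-1], levels[1:]):
        c = np.zeros(len(levels))
        c[levels.index(b)] = 1.0
        c[levels.index(a)] = -1.0
        out[f"{a}->{b}"] = c
    return out


def nb_deviance(y, mu, dispersion) -> np.ndarray:
    """Unit NB deviances (Poisson limit at dispersion 0); 0*log0 taken as 0."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, None)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        yl = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    phi_safe = np.where(phi > 0, phi, 1.0)
    nb_term = (y + 1.0 / phi_safe) * np.log1p(phi_safe * y) - (
        y + 1.0 / phi_safe
    ) * np.log1p(phi_safe * mu)
    pois_term = y - mu
    return 2.0 * np.where(phi > 0, yl - nb_term, yl - pois_term)


def _nb_loglik(y, mu, phi) -> np.ndarray:
    """Per-observation NB log-likelihood (Poisson limit at phi=0)."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, None)
    if phi <= 0:
        return y * np.log(mu) - mu - special.gammaln(y + 1)
    r = 1.0 / phi
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + y * np.log(phi * mu / (1 + phi * mu))
        - r * np.log1p(phi * mu)
    )


@dataclass
class NBGLMFit:
    """A fitted per-feature NB GLM (log link, shared design, given offsets)."""

    coefficients: np.ndarray  # (F, p), natural-log scale
    fitted_means: np.ndarray  # (F, n)
    deviance: np.ndarray  # (F,)
    residual_df: int
    offsets: np.ndarray  # (F, n), natural-log scale
    dispersion: np.ndarray  # (F,) NB dispersions used for fitting
    design: np.ndarray  # (n, p)
    counts: np.ndarray  # (F, n)
    feature_ids: np.ndarray
    converged: np.ndarray  # (F,) bool


def _as_offsets(offsets, shape):
    if offsets is None:
        return np.zeros(shape)
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    return np.broadcast_to(offsets, shape).copy()


def fit_nb_glm(counts, design, offsets=None, dispersion=0.0, feature_ids=None) -> NBGLMFit:
    """Fit NB GLMs with log link to every feature by batched IRLS.

    ``dispersion`` may be a scalar or a per-feature vector; 0 degenerates to
    Poisson.  Non-converged features keep their last iterate and are flagged
    in ``converged``.  All-zero features are reported at the linear-predictor
    lower bound with zero deviance.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2:
        raise ValueError("counts must be 2-D (features x libraries)")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    X = np.asarray(design, dtype=float)
    nf, n = y.shape
    p = X.shape[1]
    if X.shape[0] != n:
        raise ValueError("design rows must match count columns")
    O = _as_offsets(offsets, y.shape)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float).reshape(-1), (nf,)) \
        if np.ndim(dispersion) else np.full(nf, float(dispersion))
    if np.any(phi < 0):
        raise ValueError("dispersion must be non-negative")
    phi_col = phi[:, None]

    eye = np.eye(p) * 1e-10

    def solve_beta(w, z):
        xtwx = np.einsum("fn,np,nq->fpq", w, X, X) + eye
        xtwz = np.einsum("fn,np->fp", w * z, X)
        return np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0]

    mu = np.maximum(y, 1.0 / 6.0)
    eta = np.log(mu)
    w = mu / (1.0 + phi_col * mu)
    beta = solve_beta(w, eta - O)

    def dev_of(beta_):
        eta_ = np.clip(O + beta_ @ X.T, _ETA_LOW, _ETA_HIGH)
        mu_ = np.exp(eta_)
        return mu_, nb_deviance(y, mu_, phi_col).sum(axis=1)

    mu, dev = dev_of(beta)
    converged = np.zeros(nf, dtype=bool)
    for _ in range(_MAX_ITER):
        active = ~converged
        if not active.any():
            break
        eta_a = np.clip(O[active] + beta[active] @ X.T, _ETA_LOW, _ETA_HIGH)
        mu_a = np.exp(eta_a)
        w_a = mu_a / (1.0 + phi_col[active] * mu_a)
        z_a = (eta_a - O[active]) + (y[active] - mu_a) / mu_a
        beta_new = solve_beta(w_a, z_a)

        full_new = beta.copy()
        full_new[active] = beta_new
        mu_new, dev_new = dev_of(full_new)
        # step-halving where the deviance increased
        for _half in range(10):
            worse = dev_new > dev + 1e-10
            if not worse.any():
                break
            full_new[worse] = 0.5 * (full_new[worse] + beta[worse])
            mu_new, dev_new = dev_of(full_new)
        done = np.abs(dev - dev_new) < _DEV_TOL * (np.abs(dev_new) + 0.1)
        beta, mu, dev = full_new, mu_new, dev_new
        converged |= done

    # degenerate all-zero features: pin at the lower bound, deviance 0
    allzero = y.sum(axis=1) == 0
    if allzero.any():
        pinv = np.linalg.pinv(X)
        beta[allzero] = (pinv @ (_ETA_LOW - O[allzero]).T).T
        mu[allzero] = np.exp(np.clip(O[allzero] + beta[allzero] @ X.T, _ETA_LOW, _ETA_HIGH))
        dev[allzero] = 0.0
        converged[allzero] = True

    if feature_ids is None:
        feature_ids = np.arange(nf)
    return NBGLMFit(
        coefficients=beta,
        fitted_means=mu,
        deviance=np.maximum(dev, 0.0),
        residual_df=n - p,
        offsets=O,
        dispersion=phi,
        design=X,
        counts=y,
        feature_ids=np.asarray(feature_ids),
        converged=converged,
    )


def _adjusted_profile_loglik(y, X, O, phi) -> np.ndarray:
    """Per-feature Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    fit = fit_nb_glm(y, X, O, phi)
    mu = fit.fitted_means
    ll = _nb_loglik(y, mu, phi).sum(axis=1)
    w = mu / (1.0 + phi * mu)
    xtwx = np.einsum("fn,np,nq->fpq", w, X, X) + np.eye(X.shape[1]) * 1e-10
    _, logdet = np.linalg.slogdet(xtwx)
    return ll - 0.5 * logdet


_DISP_GRID = np.logspace(-6, 1, 15)


def estimate_common_dispersion(
    counts, design, offsets=None, max_features: int = 1000
) -> float:
    """Common NB dispersion maximizing the summed adjusted profile likelihood.

    A fixed log-spaced dispersion grid is scanned, then refined locally with a
    bounded scalar optimizer.  Features are deterministically thinned (evenly
    across the abundance ordering) when there are more than ``max_features``.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    if y.shape[1] - X.shape[1] < 1:
        raise ValueError(
            "no residual degrees of freedom: dispersion is unidentifiable "
            "without replication"
        )
    O = _as_offsets(offsets, y.shape)
    if y.shape[0] > max_features:
        order = np.argsort(y.sum(axis=1), kind="stable")
        keep = order[np.linspace(0, len(order) - 1, max_features).round().astype(int)]
        y, O = y[keep], O[keep]

    def neg_apl(log_phi):
        return -_adjusted_profile_loglik(y, X, O, float(np.exp(log_phi))).sum()

    grid_vals = [neg_apl(np.log(g)) for g in _DISP_GRID]
    best = int(np.argmin(grid_vals))
    lo = np.log(_DISP_GRID[max(best - 1, 0)])
    hi = np.log(_DISP_GRID[min(best + 1, len(_DISP_GRID) - 1)])
    if lo == hi:
        return float(_DISP_GRID[best])
    res = optimize.minimize_scalar(
        neg_apl, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
    )
    return float(np.exp(res.x))


def estimate_trended_dispersion(
    counts, design, offsets=None, abundance=None, span: float = 0.5
) -> np.ndarray:
    """Abundance-dependent NB dispersion trend.

    Per-feature adjusted profile likelihoods are evaluated on the dispersion
    grid, smoothed across features as a function of abundance (loess), and the
    per-feature maximizer of the smoothed likelihood is interpolated
    quadratically on the log-dispersion scale.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    O = _as_offsets(offsets, y.shape)
    if abundance is None:
        abundance = np.log2(y.mean(axis=1) + 0.5)
    apl = np.column_stack(
        [_adjusted_profile_loglik(y, X, O, g) for g in _DISP_GRID]
    )
    sm = np.column_stack(
        [loess_fit(abundance, apl[:, k], span=span, grid=100) for k in range(apl.shape[1])]
    )
    log_grid = np.log(_DISP_GRID)
    best = np.argmax(sm, axis=1)
    out = log_grid[best]
    # quadratic interpolation around the grid maximum
    interior = (best > 0) & (best < len(_DISP_GRID) - 1)
    b = best[interior]
    f0, f1, f2 = (
        sm[interior, b - 1],
        sm[interior, b],
        sm[interior, b + 1],
    )
    denom = f0 - 2 * f1 + f2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (f0 - f2) / denom, 0.0)
    step = log_grid[1] - log_grid[0]
    out[interior] = log_grid[b] + np.clip(shift, -1, 1) * step
    return np.exp(out)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class QLDispersion:
    """Raw, trended and EB-squeezed quasi-likelihood dispersions."""

    raw: np.ndarray
    trend: np.ndarray
    squeezed: np.ndarray
    prior_df: float
    residual_df: int


def squeeze_ql_dispersions(
    fit: NBGLMFit,
    abundance=None,
    trend: str = "loess",
    span: float = 0.4,
    robust: bool = False,
    prior_df: float | None = None,
) -> QLDispersion:
    """Empirical-Bayes moderation of quasi-likelihood dispersions.

    Raw dispersions (deviance / residual df) are shrunk toward a
    mean-dependent trend (loess of raw vs abundance; a constant when
    ``trend='none'``).  The prior degrees of freedom and scale come from the
    scaled-F moment equations on ``log(raw / trend)``; ``robust=True``
    winsorizes the moment inputs at the 5%/95% quantiles.  The squeezed value
    is the ``(prior_df, residual_df)``-weighted combination of trend and raw.
    """
    d1 = fit.residual_df
    if d1 < 1:
        raise ValueError("residual df must be >= 1 to estimate QL dispersions")
    raw = fit.deviance / d1
    nf = len(raw)

    if trend == "none" or abundance is None:
        trend_vec = np.full(nf, max(np.mean(raw), 1e-10))
    elif trend == "loess":
        trend_vec = np.clip(
            loess_fit(np.asarray(abundance, float), raw, span=span, grid=200),
            1e-10,
            None,
        )
    else:
        raise ValueError(f"unknown trend method {trend!r}")

    usable = raw > 0
    if usable.sum() >= 2:
        z = np.log(raw[usable] / trend_vec[usable])
        if z.var(ddof=1) < 1e-12:
            # no between-feature variance: the raw values are not F-scattered,
            # so no log-F bias correction applies
            emean, evar = z.mean(), -1.0
        else:
            e = z - special.digamma(d1 / 2.0) + np.log(d1 / 2.0)
            if robust:
                lo, hi = np.quantile(e, [0.05, 0.95])
                e = np.clip(e, lo, hi)
            emean = e.mean()
            evar = e.var(ddof=1) - special.polygamma(1, d1 / 2.0)
    else:
        emean, evar = 0.0, -1.0

    if prior_df is None:
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            scale = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        else:
            d0 = np.inf
            scale = np.exp(emean)
    else:
        d0 = float(prior_df)
        scale = 1.0

    prior = trend_vec * scale
    if np.isinf(d0):
        squeezed = prior.copy()
    elif d0 == 0:
        squeezed = raw.copy()
    else:
        squeezed = (d0 * prior + d1 * raw) / (d0 + d1)
    return QLDispersion(raw=raw, trend=prior, squeezed=squeezed, prior_df=d0, residual_df=d1)


def _contrast_internals(fit: NBGLMFit, ql: QLDispersion, contrast):
    """Shared LRT machinery: per-feature logFC, F statistic, se and df2."""
    c = np.asarray(contrast, dtype=float).reshape(-1)
    X = fit.design
    if len(c) != X.shape[1]:
        raise ValueError("contrast length must match the number of coefficients")
    N = null_space(c[None, :])
    fit_red = fit_nb_glm(
        fit.counts, X @ N, offsets=fit.offsets, dispersion=fit.dispersion
    )
    dev_diff = np.maximum(fit_red.deviance - fit.deviance, 0.0)
    s2 = np.clip(ql.squeezed, 1e-12, None)
    fstat = dev_diff / s2  # contrast df = 1
    logfc = (fit.coefficients @ c) / LN2

    # Wald-style unscaled variance of the contrast, for se when the LRT is flat
    mu = fit.fitted_means
    w = mu / (1.0 + fit.dispersion[:, None] * mu)
    xtwx = np.einsum("fn,np,nq->fpq", w, X, X) + np.eye(X.shape[1]) * 1e-10
    u = np.einsum("p,fpq,q->f", c, np.linalg.inv(xtwx), c)
    se_wald = np.sqrt(np.clip(s2 * u, 1e-300, None)) / LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        se_lrt = np.abs(logfc) / np.sqrt(fstat)
    se = np.where(np.isfinite(se_lrt) & (se_lrt > 0), se_lrt, se_wald)

    df2 = ql.prior_df + ql.residual_df
    return logfc, fstat, se, df2


def _f_pvalue(fstat, df2):
    if np.isinf(df2):
        return stats.chi2.sf(fstat, 1)
    return stats.f.sf(fstat, 1, df2)


def ql_f_test(fit: NBGLMFit, ql: QLDispersion, contrast, feature_ids=None) -> pd.DataFrame:
    """Quasi-likelihood F-test of a single contrast for every feature.

    The numerator is the likelihood-ratio deviance of the contrast (df 1); the
    denominator the squeezed QL dispersion; the reference distribution is
    ``F(1, prior_df + residual_df)`` (chi-square limit at infinite prior df).
    """
    logfc, fstat, _, df2 = _contrast_internals(fit, ql, contrast)
    p = np.clip(_f_pvalue(fstat, df2), 0.0, 1.0)
    ids = fit.feature_ids if feature_ids is None else feature_ids
    return pd.DataFrame(
        {"feature_id": ids, "logFC": logfc, "statistic": fstat, "p": p,
         "fdr": bh_adjust(p)}
    )


def treat_test(
    fit: NBGLMFit, ql: QLDispersion, contrast, fc_threshold: float = 1.0,
    feature_ids=None,
) -> pd.DataFrame:
    """Test against H0: |true log2FC| <= log2(fc_threshold) (TREAT).

    The two one-sided tests shifted by the threshold are combined: with
    ``tau = log2(fc_threshold)`` and the moderated t statistic on
    ``prior_df + residual_df`` degrees of freedom,
    ``p = P(T > (|logFC| - tau)/se) + P(T > (|logFC| + tau)/se)`` capped at 1.
    At threshold 1 this reduces exactly to the QL F-test.
    """
    if fc_threshold < 1.0:
        raise ValueError("fc_threshold is a fold change and must be >= 1")
    tau = np.log2(fc_threshold)
    logfc, fstat, se, df2 = _contrast_internals(fit, ql, contrast)
    t_obs = np.sqrt(np.maximum(fstat, 0.0))
    if tau == 0:
        shift = np.zeros_like(t_obs)
    else:
        # zero-variance features cannot reject beyond a positive threshold
        shift = np.where(se > 0, tau / se, np.inf)
    tr = t_obs - shift
    tl = t_obs + shift
    if np.isinf(df2):
        p = stats.norm.sf(tr) + stats.norm.sf(tl)
    else:
        p = stats.t.sf(tr, df2) + stats.t.sf(tl, df2)
    p = np.clip(p, 0.0, 1.0)
    ids = fit.feature_ids if feature_ids is None else feature_ids
    return pd.DataFrame(
        {"feature_id": ids, "logFC": logfc,
         "statistic": np.sign(logfc) * np.where(np.isfinite(tr), tr, 0.0),
         "p": p, "fdr": bh_adjust(p)}
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def classify_patterns(results: dict[str, pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature {-1, 0, +1} pattern across transitions.

    The entry for a transition is ``sign(logFC)`` when its FDR is strictly
    below ``alpha``, else 0.  All transitions must cover the same feature
    universe.
    """
    if not results:
        raise ValueError("no per-transition results supplied")
    names = list(results)
    base = results[names[0]]["feature_id"].to_numpy()
    cols = {}
    for name in names:
        df = results[name].set_index("feature_id")
        missing = set(base) - set(df.index)
        if missing or len(df) != len(base):
            raise ValueError(
                f"transition {name!r} does not cover the shared feature universe"
            )
        df = df.loc[base]
        sig = df["fdr"].to_numpy() < alpha
        cols[name] = (np.sign(df["logFC"].to_numpy()) * sig).astype(int)
    out = pd.DataFrame(cols, index=pd.Index(base, name="feature_id"))
    return out
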