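"""Causal-effect estimators for two-sample Mendelian randomisation.

All estimators consume a harmonized instrument set and return an
:class:`~mrkit.types.MRFit`.  The suite comprises inverse-variance
weighted (IVW) with multiplicative random effects, MR-Egger, the
weighted median and weighted mode (pleiotropy-robust under the
majority- and plurality-valid assumptions respectively), MR-PRESSO
outlier detection, and a generalised-least-squares IVW for correlated
instruments.  p-values are two-sided from the normal distribution
throughout (summary-data asymptotics).
"""
from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import DataError, HarmonizedInstrument, MRFit

Z95 = stats.norm.ppf(0.975)

MIN_IVS = {"ivw": 2, "egger": 3, "weighted_median": 3, "weighted_mode": 3, "mr_presso": 4}


def _arrays(h: Iterable[HarmonizedInstrument]):
    use = [x for x in h if x.usable]
    bx = np.array([x.beta_exp for x in use], dtype=float)
    sx = np.array([x.se_exp for x in use], dtype=float)
    by = np.array([x.beta_out for x in use], dtype=float)
    sy = np.array([x.se_out for x in use], dtype=float)
    ids = [x.snp_id for x in use]
    if np.any(sx < 0) or np.any(sy <= 0):
        raise DataError("usable instruments require se_exp >= 0 and se_out > 0")
    return ids, bx, sx, by, sy


def _fit(method: str, beta: float, se: float, k: int, extra: Optional[dict] = None) -> MRFit:
    pvalue = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float("nan")
    return MRFit(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(pvalue),
        k_used=int(k),
        extra=extra or {},
    )


def ratio_estimates(
    h: Iterable[HarmonizedInstrument],
) -> list[tuple[str, float, float]]:
    """Per-instrument Wald ratios with second-order delta-method SEs.

    ratio_j = beta_out_j / beta_exp_j;
    se_j^2  = se_out_j^2/beta_exp_j^2
            + beta_out_j^2 se_exp_j^2 / beta_exp_j^4.
    Instruments with a zero exposure effect are excluded with a
    warning (the ratio is undefined).
    """
    out: list[tuple[str, float, float]] = []
    for x in h:
        if not x.usable:
            continue
        if x.beta_exp == 0.0:
            warnings.warn(
                f"instrument {x.snp_id} has beta_exp = 0; excluded from ratio estimates",
                stacklevel=2,
            )
            continue
        ratio = x.beta_out / x.beta_exp
        var = x.se_out**2 / x.beta_exp**2 + x.beta_out**2 * x.se_exp**2 / x.beta_exp**4
        out.append((x.snp_id, float(ratio), float(np.sqrt(var))))
    return out


def ivw(
    h: Sequence[HarmonizedInstrument], random_effects: str = "multiplicative"
) -> MRFit:
    """Inverse-variance weighted estimate of the causal effect.

    Weighted mean of the Wald ratios with first-order weights
    w_j = beta_exp_j^2 / se_out_j^2.  Under multiplicative random
    effects the fixed-effects SE is inflated by
    max(1, sqrt(Q/(k-1))), never deflated below it.
    """
    if random_effects not in ("multiplicative", "fixed"):
        raise DataError(f"unknown random_effects model {random_effects!r}")
    ids, bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < MIN_IVS["ivw"]:
        raise DataError(f"ivw requires at least {MIN_IVS['ivw']} usable instruments, got {k}")
    if np.any(bx == 0):
        keep = bx != 0
        ids = [i for i, m in zip(ids, keep) if m]
        bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
        k = len(bx)
        if k < MIN_IVS["ivw"]:
            raise DataError("too few instruments with nonzero exposure effect")
    w = bx**2 / sy**2
    r = by / bx
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - beta) ** 2))
    if random_effects == "multiplicative" and k > 1:
        infl = max(1.0, np.sqrt(q / (k - 1)))
    else:
        infl = 1.0
    return _fit(
        "ivw", beta, se_fixed * infl, k,
        {"Q": q, "se_fixed": se_fixed, "random_effects": random_effects},
    )


def _orient(bx, sx, by, sy):
    """Flip instruments so every exposure effect is non-negative."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, sx, by * sign, sy


def egger(h: Sequence[HarmonizedInstrument]) -> MRFit:
    """MR-Egger regression: slope = causal effect, intercept = mean pleiotropy.

    Weighted regression of beta_out on beta_exp (weights 1/se_out^2)
    after orienting all instruments to non-negative exposure effects,
    which is required for the intercept to represent average
    directional pleiotropy.  SEs use the same multiplicative
    random-effects floor as IVW with k-2 degrees of freedom.
    """
    ids, bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < MIN_IVS["egger"]:
        raise DataError(f"egger requires at least {MIN_IVS['egger']} usable instruments, got {k}")
    bx, sx, by, sy = _orient(bx, sx, by, sy)
    X = sm.add_constant(bx)
    res = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    # statsmodels scales the covariance by Q/(k-2); re-apply with a floor of 1
    scale = max(1.0, float(res.scale))
    cov = np.asarray(res.normalized_cov_params) * scale
    intercept, slope = float(res.params[0]), float(res.params[1])
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    p_int = 2.0 * stats.norm.sf(abs(intercept) / se_int) if se_int > 0 else float("nan")
    return _fit(
        "egger", slope, se_slope, k,
        {
            "intercept": intercept,
            "intercept_se": se_int,
            "intercept_p": float(p_int),
            "Q": float(res.scale * (k - 2)),
        },
    )


def i2_gx(h: Sequence[HarmonizedInstrument]) -> float:
    """I-squared for the instrument-exposure effects (NOME diagnostic).

    Quantifies relative measurement error in the exposure effects;
    values above 0.9 conventionally deem a set suitable for MR-Egger.
    """
    ids, bx, sx, by, sy = _arrays(h)
    if len(bx) < 2:
        raise DataError("i2_gx requires at least 2 instruments")
    if np.any(sx <= 0):
        raise DataError("i2_gx requires se_exp > 0 for every instrument")
    bx = np.abs(bx)  # oriented as in egger
    w = 1.0 / sx**2
    mu = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum((bx - mu) ** 2 * w))
    if q_gx <= 0:
        return 0.0
    return float(max(0.0, (q_gx - (len(bx) - 1)) / q_gx))


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile by linear interpolation of cumulative weights."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _boot_se(point_fn, bx, sx, by, sy, n_boot: int, seed) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        est[b] = point_fn(bxs, bys)
    return float(np.std(est, ddof=1))


def weighted_median(
    h: Sequence[HarmonizedInstrument], n_boot: int = 1000, seed: Optional[int] = None
) -> MRFit:
    """Weighted median of the Wald ratios (majority-valid assumption).

    Weights are inverse squared second-order delta-method SEs of the
    ratios; the SE comes from a seeded parametric bootstrap resampling
    both effect estimates from their sampling distributions.
    """
    ids, bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < MIN_IVS["weighted_median"]:
        raise DataError(
            f"weighted_median requires at least {MIN_IVS['weighted_median']} usable instruments, got {k}"
        )

    def point(bxs, bys):
        ok = bxs != 0
        r = bys[ok] / bxs[ok]
        var = sy[ok] ** 2 / bxs[ok] ** 2 + bys[ok] ** 2 * sx[ok] ** 2 / bxs[ok] ** 4
        return _weighted_median_point(r, 1.0 / var)

    beta = point(bx, by)
    se = _boot_se(point, bx, sx, by, sy, n_boot, seed)
    return _fit("weighted_median", beta, se, k, {"n_boot": n_boot})


def _silverman_bandwidth(r: np.ndarray) -> float:
    k = len(r)
    s = np.std(r, ddof=1) if k > 1 else 0.0
    mad = np.median(np.abs(r - np.median(r))) * 1.4826
    spread = min(s, mad) if mad > 0 else s
    return 0.9 * spread * k ** (-1 / 5)


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float
) -> float:
    bw = bandwidth_factor * _silverman_bandwidth(ratios)
    if bw <= 0:
        # degenerate spread: heaviest point mass
        vals, inv = np.unique(ratios, return_inverse=True)
        mass = np.bincount(inv, weights=weights)
        return float(vals[np.argmax(mass)])
    lo, hi = ratios.min() - 3 * bw, ratios.max() + 3 * bw
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / bw) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    h: Sequence[HarmonizedInstrument],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MRFit:
    """Weighted mode of the Wald ratios (plurality-valid assumption).

    The estimate maximises a Gaussian-kernel weighted density over the
    ratio estimates, bandwidth from the modified Silverman rule scaled
    by ``bandwidth_factor``; weights 1/ratio_se^2; SE by seeded
    parametric bootstrap.
    """
    ids, bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < MIN_IVS["weighted_mode"]:
        raise DataError(
            f"weighted_mode requires at least {MIN_IVS['weighted_mode']} usable instruments, got {k}"
        )

    def point(bxs, bys):
        ok = bxs != 0
        r = bys[ok] / bxs[ok]
        var = sy[ok] ** 2 / bxs[ok] ** 2 + bys[ok] ** 2 * sx[ok] ** 2 / bxs[ok] ** 4
        return _weighted_mode_point(r, 1.0 / var, bandwidth_factor)

    beta = point(bx, by)
    se = _boot_se(point, bx, sx, by, sy, n_boot, seed)
    return _fit(
        "weighted_mode", beta, se, k, {"n_boot": n_boot, "bandwidth_factor": bandwidth_factor}
    )


def _loo_betas(bx, by, sy):
    """IVW estimate leaving each instrument out, vectorised.

    Accepts 1-d arrays or (n_sim, k) matrices; returns the same shape.
    """
    w = bx**2 / sy**2
    r = by / bx
    num = np.sum(w * r, axis=-1, keepdims=True)
    den = np.sum(w, axis=-1, keepdims=True)
    return (num - w * r) / (den - w)


def mr_presso(
    h: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: Optional[int] = None,
) -> MRFit:
    """MR-PRESSO: residual-sum-of-squares outlier and global pleiotropy test.

    The observed global RSS sums weighted squared residuals of each
    instrument's outcome effect about its leave-one-out IVW
    prediction (weights 1/se_out^2).  A parametric null distribution
    is simulated by redrawing both effect sides from their sampling
    distributions; the global p is the empirical exceedance fraction
    and per-instrument outlier p-values (Bonferroni-corrected over k)
    come from each instrument's simulated residual distribution.
    Returns the outlier-corrected IVW fit with test results in
    ``extra``.  The distortion test is not implemented.
    """
    ids, bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < MIN_IVS["mr_presso"]:
        raise DataError(
            f"mr_presso requires at least {MIN_IVS['mr_presso']} usable instruments, got {k}"
        )
    if n_sim < 100:
        raise DataError("mr_presso requires n_sim >= 100")
    if n_sim < k / outlier_alpha:
        raise DataError(
            f"n_sim={n_sim} cannot resolve outlier_alpha={outlier_alpha} over k={k} "
            f"instruments (need n_sim >= {int(np.ceil(k / outlier_alpha))})"
        )
    rng = np.random.default_rng(seed)
    beta_loo = _loo_betas(bx, by, sy)
    d_obs = ((by - bx * beta_loo) / sy) ** 2
    rss_obs = float(np.sum(d_obs))

    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(bx * beta_loo, sy, size=(n_sim, k))
    # guard against zero simulated exposure effects
    bx_s = np.where(bx_s == 0, np.finfo(float).tiny, bx_s)
    beta_loo_s = _loo_betas(bx_s, by_s, sy)
    d_s = ((by_s - bx_s * beta_loo_s) / sy) ** 2
    rss_s = np.sum(d_s, axis=1)
    global_p = float((np.sum(rss_s >= rss_obs) + 1) / (n_sim + 1))
    p_raw = (np.sum(d_s >= d_obs, axis=0) + 1) / (n_sim + 1)
    p_corr = np.minimum(1.0, p_raw * k)
    outlier_idx = np.nonzero(p_corr < outlier_alpha)[0]
    outlier_ids = [ids[i] for i in outlier_idx]

    keep = np.ones(k, dtype=bool)
    keep[outlier_idx] = False
    if np.sum(keep) < MIN_IVS["ivw"]:
        raise DataError("mr_presso flagged too many outliers to refit IVW")
    sub = [x for x, m in zip([x for x in h if x.usable], keep) if m]
    fit = ivw(sub, random_effects="multiplicative")
    return MRFit(
        method="mr_presso",
        beta=fit.beta,
        se=fit.se,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
        pvalue=fit.pvalue,
        k_used=fit.k_used,
        extra={
            "global_p": global_p,
            "rss_obs": rss_obs,
            "outlier_indices": outlier_idx.tolist(),
            "outlier_snps": outlier_ids,
            "outlier_p_raw": p_raw.tolist(),
            "n_sim": n_sim,
        },
    )


def ivw_correlated(
    h: Sequence[HarmonizedInstrument], ld: np.ndarray | "object"
) -> MRFit:
    """Generalised least squares IVW accounting for instrument correlation.

    ``ld`` is the instrument correlation matrix (signed r, not r^2) in
    the order of the usable instruments, or a labelled DataFrame.
    With identity LD this reduces exactly to fixed-effects IVW.
    Positive semi-definite matrices are accepted via pseudo-inverse
    (perfectly correlated duplicates collapse to a single instrument);
    indefinite matrices are a hard error.
    """
    ids, bx, sx, by, sy = _arrays(h)
    k = len(bx)
    if k < 2:
        raise DataError("ivw_correlated requires at least 2 usable instruments")
    if hasattr(ld, "loc"):
        ld = ld.loc[ids, ids].to_numpy(dtype=float)
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (k, k):
        raise DataError(f"LD matrix shape {ld.shape} does not match {k} instruments")
    omega = ld * np.outer(sy, sy)
    eigvals = np.linalg.eigvalsh(omega)
    if eigvals[0] < -1e-8 * max(1.0, eigvals[-1]):
        raise DataError("LD-derived covariance matrix is not positive semi-definite")
    if eigvals[0] > 1e-10 * max(1.0, eigvals[-1]):
        omega_inv = np.linalg.inv(omega)
    else:
        omega_inv = np.linalg.pinv(omega, rcond=1e-10)
    xtw = bx @ omega_inv
    denom = float(xtw @ bx)
    beta = float(xtw @ by) / denom
    se = denom**-0.5
    return _fit("ivw_correlated", beta, se, k, {})
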