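"""Heterogeneity, pleiotropy, directionality, and scale-conversion procedures.

Applied to each fitted exposure-outcome model: Cochran's Q across the
Wald ratios, the MR-Egger intercept, MR-PRESSO's global test,
leave-one-out refits, the Steiger directionality test (with
liability-scale variance for binary outcomes), liability-scale effect
conversions, odds-ratio intervals, and multiple-testing correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import estimators
from .instruments import r2_from_pn
from .types import (
    DataError,
    HarmonizedInstrument,
    MRFit,
    SensitivityReport,
    SteigerResult,
    StudyMeta,
)


def cochran_q(
    h: Sequence[HarmonizedInstrument], beta_hat: float
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of the Wald ratios about ``beta_hat``.

    Q = sum_j w_j (r_j - beta_hat)^2 with first-order IVW weights
    w_j = beta_exp_j^2/se_out_j^2; p from chi-square with k-1 df.
    """
    use = [x for x in h if x.usable and x.beta_exp != 0]
    if len(use) < 2:
        raise DataError("cochran_q requires at least 2 usable instruments")
    bx = np.array([x.beta_exp for x in use])
    by = np.array([x.beta_out for x in use])
    sy = np.array([x.se_out for x in use])
    w = bx**2 / sy**2
    r = by / bx
    q = float(np.sum(w * (r - beta_hat) ** 2))
    df = len(use) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def leave_one_out(
    h: Sequence[HarmonizedInstrument],
) -> list[tuple[str, MRFit, bool]]:
    """IVW refits omitting each instrument in turn.

    The flag marks omissions that move the estimate outside the
    full-set 95% CI or change its sign — evidence the full estimate
    leans on a single instrument.
    """
    use = [x for x in h if x.usable]
    if len(use) < 3:
        raise DataError("leave_one_out requires at least 3 usable instruments")
    full = estimators.ivw(use)
    out: list[tuple[str, MRFit, bool]] = []
    for j, x in enumerate(use):
        sub = use[:j] + use[j + 1 :]
        fit = estimators.ivw(sub)
        flagged = (
            fit.beta < full.ci_low
            or fit.beta > full.ci_high
            or (fit.beta * full.beta < 0)
        )
        out.append((x.snp_id, fit, flagged))
    return out


def liability_r2(r2_observed: float, prevalence: float, case_proportion: float) -> float:
    """Convert observed-scale variance explained to the liability scale.

    Lee-style transformation for an ascertained case-control sample:
    r2_liab = r2_obs * K^2 (1-K)^2 / (z^2 P (1-P)) with K the
    population prevalence, P the sample case proportion and z the
    standard-normal density at the liability threshold.
    """
    if not (0.0 < prevalence < 1.0) or not (0.0 < case_proportion < 1.0):
        raise DataError("prevalence and case_proportion must lie in (0,1)")
    if r2_observed < 0:
        raise DataError("r2_observed must be >= 0")
    z = stats.norm.pdf(stats.norm.isf(prevalence))
    k = prevalence
    p = case_proportion
    return float(r2_observed * k**2 * (1 - k) ** 2 / (z**2 * p * (1 - p)))


def liability_beta(beta_observed: float, prevalence: float) -> float:
    """Rescale a binary-exposure effect to per-SD-of-liability units.

    Multiplies the observed-scale (log-odds-unit) beta by
    z/(K(1-K)) with z the standard-normal density at the liability
    threshold for prevalence K.
    """
    if not (0.0 < prevalence < 1.0):
        raise DataError("prevalence must lie in (0,1)")
    z = stats.norm.pdf(stats.norm.isf(prevalence))
    return float(beta_observed * z / (prevalence * (1.0 - prevalence)))


def steiger(
    h: Sequence[HarmonizedInstrument],
    exposure_meta: StudyMeta,
    outcome_meta: StudyMeta,
    prevalence: Optional[float] = None,
) -> SteigerResult:
    """Directionality test: do the instruments explain more exposure than outcome?

    Sums per-SNP variance explained (from p and n) on both sides;
    binary-outcome r2 is converted to the liability scale at the given
    prevalence.  The p-value compares the implied correlations via the
    independent-samples Fisher-z test (the two GWAS do not overlap).
    """
    use = [x for x in h if x.usable]
    if not use:
        raise DataError("steiger requires at least one usable instrument")
    r2_exp = 0.0
    r2_out = 0.0
    n_exp_vals, n_out_vals = [], []
    for x in use:
        p_exp = x.pvalue_exp
        if p_exp is None:
            p_exp = 2.0 * stats.norm.sf(abs(x.beta_exp) / x.se_exp)
        p_out = x.pvalue_out
        if p_out is None:
            p_out = 2.0 * stats.norm.sf(abs(x.beta_out) / x.se_out)
        if x.n_exp is None or x.n_out is None:
            raise DataError(f"steiger requires per-IV n on both sides (snp {x.snp_id})")
        r2_exp += r2_from_pn(max(p_exp, 1e-300), x.n_exp)
        r2_out += r2_from_pn(max(p_out, 1e-300), x.n_out)
        n_exp_vals.append(x.n_exp)
        n_out_vals.append(x.n_out)
    prevalence_used = None
    if outcome_meta.trait_type == "binary":
        if prevalence is None:
            prevalence = outcome_meta.prevalence
        if prevalence is None:
            raise DataError("binary outcome requires a prevalence for the Steiger test")
        cp = outcome_meta.case_proportion
        if cp is None:
            raise DataError("binary outcome requires n_cases for the Steiger test")
        r2_out = liability_r2(r2_out, prevalence, cp)
        prevalence_used = prevalence
    n1 = float(np.mean(n_exp_vals))
    n2 = float(np.mean(n_out_vals))
    z1 = np.arctanh(min(math.sqrt(r2_exp), 1 - 1e-12))
    z2 = np.arctanh(min(math.sqrt(max(r2_out, 0.0)), 1 - 1e-12))
    denom = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    zstat = (z1 - z2) / denom
    p_direction = float(2.0 * stats.norm.sf(abs(zstat)))
    return SteigerResult(
        r2_exposure=float(r2_exp),
        r2_outcome=float(r2_out),
        correct_direction=bool(r2_exp > r2_out),
        p_direction=p_direction,
        prevalence_used=prevalence_used,
        undetermined=bool(r2_exp == r2_out),
    )


def or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio and confidence interval from a log-odds beta and SE."""
    if se <= 0:
        raise DataError("se must be > 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        float(math.exp(beta)),
        float(math.exp(beta - z * se)),
        float(math.exp(beta + z * se)),
    )


def unit_context(concentration: float) -> float:
    """Concentration after a one-natural-log-unit increase (i.e. times e).

    Contextualises effects expressed per ln-unit of a concentration:
    exp(ln(c) + 1) = c * e.
    """
    if concentration <= 0:
        raise DataError("concentration must be > 0")
    return float(concentration * math.e)


@dataclass(frozen=True)
class MultipleTestingResult:
    method: str
    threshold: Optional[float]  # bonferroni only
    adjusted: Optional[tuple]  # bh only
    significant: tuple


def multiple_testing(
    pvalues: Sequence[float], method: str = "bonferroni", alpha: float = 0.05
) -> MultipleTestingResult:
    """Bonferroni threshold or Benjamini-Hochberg step-up flags.

    ``bonferroni`` returns the per-test threshold alpha/m and flags
    p < threshold; ``bh`` returns step-up adjusted p-values and flags
    at ``alpha``.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise DataError("multiple_testing requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0,1]")
    if method == "bonferroni":
        thr = alpha / p.size
        return MultipleTestingResult(
            method="bonferroni",
            threshold=float(thr),
            adjusted=None,
            significant=tuple(bool(x) for x in (p < thr)),
        )
    if method == "bh":
        rej, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        return MultipleTestingResult(
            method="bh",
            threshold=None,
            adjusted=tuple(float(x) for x in adj),
            significant=tuple(bool(x) for x in rej),
        )
    raise DataError(f"unknown correction method {method!r}")


def build_report(
    h: Sequence[HarmonizedInstrument],
    exposure_meta: StudyMeta,
    outcome_meta: StudyMeta,
    prevalence: Optional[float] = None,
    presso_n_sim: int = 1000,
    seed: Optional[int] = None,
) -> SensitivityReport:
    """Run the full sensitivity suite for one exposure-outcome model."""
    use = [x for x in h if x.usable]
    ivw_fit = estimators.ivw(use)
    q, df, qp = cochran_q(use, ivw_fit.beta)
    egger_fit = estimators.egger(use)
    presso = estimators.mr_presso(use, n_sim=presso_n_sim, seed=seed)
    loo = leave_one_out(use)
    st = steiger(use, exposure_meta, outcome_meta, prevalence=prevalence)
    return SensitivityReport(
        q_stat=q,
        q_df=df,
        q_p=qp,
        egger_intercept=egger_fit.extra["intercept"],
        egger_intercept_se=egger_fit.extra["intercept_se"],
        egger_intercept_p=egger_fit.extra["intercept_p"],
        presso_global_p=presso.extra["global_p"],
        loo_estimates=tuple(loo),
        steiger=st,
        i2_gx=estimators.i2_gx(use),
    )
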