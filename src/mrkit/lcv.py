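"""Latent causal variable model: the genetic causality proportion (GCP).

The model assumes a latent factor mediates the genetic correlation
between two traits and asks whether that factor is closer to trait 1
or trait 2.  Writing normalized per-SNP effects as
alpha_t = q_t * pi + gamma_t (pi the latent factor, gamma_t
trait-specific), the genetic correlation is rho = q1*q2 and the GCP
is defined through q1 = |rho|^{(1-gcp)/2}, q2 = |rho|^{(1+gcp)/2}.
Because the latent factor's effect distribution is heavy-tailed, the
mixed fourth-moment cumulants

    k41 = E[z1^3 z2] - 3 E[z1^2] E[z1 z2]
    k42 = E[z1 z2^3] - 3 E[z2^2] E[z1 z2]

satisfy k41/k42 = (q1/q2)^2 = |rho|^{-2 gcp} after normalization, so
the statistic T(x) = sign(rho) (K41 |rho|^x - K42 |rho|^{-x}) crosses
zero at the true GCP.  The estimator evaluates T over the grid
x in [-1, 1] (step 0.01), attaches a block-jackknife standard error
to each T(x), and returns the posterior mean over the grid weighted
by the t-likelihood of T(x)/SE(x), plus two-sided t-tests of
GCP = 0, 1 and -1 on the jackknife statistics.  The subtraction of
3*E[..]*E[..] cancels the unit sampling noise of the z-scores, so no
noise-variance correction is needed beyond it.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import COMPLEMENT, DataError, LCVResult, VariantAssociation

GRID = np.round(np.linspace(-1.0, 1.0, 201), 2)


def _align_traits(
    t1: Sequence[VariantAssociation], t2: Sequence[VariantAssociation]
) -> tuple[np.ndarray, np.ndarray, list[str], float, float]:
    """Intersect on snp_id, align trait-2 z-scores to trait-1 alleles.

    Strand complements are accepted; palindromic or mismatched allele
    pairs are dropped (munging normally removes palindromes upstream).
    Output order follows trait 1's (chrom, pos) so jackknife blocks
    are genomically contiguous.
    """
    idx2 = {r.snp_id: r for r in t2}
    z1, z2, ids = [], [], []
    recs = sorted(t1, key=lambda r: (r.chrom, r.pos, r.snp_id))
    for r1 in recs:
        r2 = idx2.get(r1.snp_id)
        if r2 is None:
            continue
        e1, o1 = r1.effect_allele, r1.other_allele
        e2, o2 = r2.effect_allele, r2.other_allele
        if {e1, o1} in ({"A", "T"}, {"C", "G"}):
            continue
        sign = None
        if (e2, o2) == (e1, o1) or (COMPLEMENT[e2], COMPLEMENT[o2]) == (e1, o1):
            sign = 1.0
        elif (o2, e2) == (e1, o1) or (COMPLEMENT[o2], COMPLEMENT[e2]) == (e1, o1):
            sign = -1.0
        if sign is None:
            continue
        z1.append(r1.beta / r1.se)
        z2.append(sign * r2.beta / r2.se)
        ids.append(r1.snp_id)
    n1 = float(np.median([r.n for r in t1]))
    n2 = float(np.median([r.n for r in t2]))
    return np.asarray(z1), np.asarray(z2), ids, n1, n2


def _stats_from_sums(s: np.ndarray):
    """(rho, K41, K42, v1, v2) from weighted moment sums.

    ``s`` rows: [sum w, w z1 z2, w z1^2, w z2^2, w z1^3 z2, w z1 z2^3];
    works on a single vector or an array of leave-block-out sums.
    """
    s = np.atleast_2d(s)
    m11 = s[:, 1] / s[:, 0]
    m20 = s[:, 2] / s[:, 0]
    m02 = s[:, 3] / s[:, 0]
    m31 = s[:, 4] / s[:, 0]
    m13 = s[:, 5] / s[:, 0]
    v1 = np.maximum(m20 - 1.0, 1e-8)
    v2 = np.maximum(m02 - 1.0, 1e-8)
    k41 = m31 - 3.0 * m20 * m11
    k42 = m13 - 3.0 * m02 * m11
    rho = m11 / np.sqrt(v1 * v2)
    K41 = k41 / (v1**1.5 * np.sqrt(v2))
    K42 = k42 / (np.sqrt(v1) * v2**1.5)
    return rho, K41, K42, m20 - 1.0, m02 - 1.0


def _t_grid(rho: np.ndarray, K41: np.ndarray, K42: np.ndarray) -> np.ndarray:
    """T(x) over the GCP grid; rows follow the input vectors."""
    a = np.clip(np.abs(rho), 0.01, 0.99)[:, None]
    s = np.sign(rho)[:, None]
    x = GRID[None, :]
    return s * (K41[:, None] * a**x - K42[:, None] * a ** (-x))


def estimate_lcv(
    munged_trait1: Sequence[VariantAssociation],
    munged_trait2: Sequence[VariantAssociation],
    ld_scores: Union[pd.DataFrame, Mapping[str, float]],
    n_blocks: int = 100,
    seed: Optional[int] = None,
) -> LCVResult:
    """Estimate the genetic causality proportion of trait 1 on trait 2.

    Inputs are munged genome-wide summary statistics for the two
    traits and per-SNP LD scores (DataFrame with snp_id/ldscore
    columns or a mapping).  SNPs are intersected and allele-aligned;
    weighted moments use LDSC-style weights 1/max(1, ldscore).  The
    estimator is deterministic; ``seed`` is accepted for interface
    stability and unused.  Standard errors come from a delete-one
    block jackknife over ``n_blocks`` contiguous SNP blocks.

    Raises :class:`DataError` when fewer than 10 * n_blocks SNPs
    survive alignment or when either trait's heritability estimate is
    degenerate (<= 0).
    """
    z1, z2, ids, n1, n2 = _align_traits(munged_trait1, munged_trait2)
    m = len(ids)
    if m < 10 * n_blocks:
        raise DataError(
            f"estimate_lcv requires at least {10 * n_blocks} aligned SNPs, got {m}"
        )
    if isinstance(ld_scores, pd.DataFrame):
        ell_map = dict(zip(ld_scores["snp_id"].astype(str), ld_scores["ldscore"]))
    else:
        ell_map = dict(ld_scores)
    try:
        ell = np.array([float(ell_map[s]) for s in ids])
    except KeyError as exc:
        raise DataError(f"LD score missing for SNP {exc.args[0]}")

    w = 1.0 / np.maximum(1.0, ell)
    terms = np.stack(
        [w, w * z1 * z2, w * z1**2, w * z2**2, w * z1**3 * z2, w * z1 * z2**3],
        axis=1,
    )
    blocks = (np.arange(m) * n_blocks) // m
    block_sums = np.zeros((n_blocks, terms.shape[1]))
    np.add.at(block_sums, blocks, terms)
    total = block_sums.sum(axis=0)

    rho_f, K41_f, K42_f, v1_f, v2_f = _stats_from_sums(total)
    if v1_f[0] <= 0:
        raise DataError("degenerate heritability estimate (<= 0) for trait 1")
    if v2_f[0] <= 0:
        raise DataError("degenerate heritability estimate (<= 0) for trait 2")
    mean_ell = float(np.sum(w * ell) / np.sum(w))
    h2_1 = float(v1_f[0]) * m / (n1 * mean_ell)
    h2_2 = float(v2_f[0]) * m / (n2 * mean_ell)

    t_full = _t_grid(rho_f, K41_f, K42_f)[0]
    loo_sums = total[None, :] - block_sums
    rho_l, K41_l, K42_l, _, _ = _stats_from_sums(loo_sums)
    t_loo = _t_grid(rho_l, K41_l, K42_l)  # (n_blocks, grid)
    mean_loo = t_loo.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * np.sum((t_loo - mean_loo) ** 2, axis=0))
    se = np.maximum(se, 1e-300)
    df = n_blocks - 1
    tstat = t_full / se

    def p_at(x: float) -> float:
        i = int(np.argmin(np.abs(GRID - x)))
        return float(max(2.0 * stats.t.sf(abs(tstat[i]), df), 1e-300))

    # posterior over the grid from the t-likelihood of T(x)/SE(x)
    logl = stats.t.logpdf(tstat, df)
    logl -= logl.max()
    wpost = np.exp(logl)
    wpost /= wpost.sum()
    gcp = float(np.sum(GRID * wpost))
    gcp_se = float(np.sqrt(max(np.sum(GRID**2 * wpost) - gcp**2, 0.0)))

    return LCVResult(
        gcp=float(np.clip(gcp, -1.0, 1.0)),
        gcp_se=gcp_se,
        p_gcp_zero=p_at(0.0),
        p_full_causal_fwd=p_at(1.0),
        p_full_causal_rev=p_at(-1.0),
        rho_g=float(rho_f[0]),
        h2_z1=h2_1,
        h2_z2=h2_2,
    )


def read_ld_scores(path) -> pd.DataFrame:
    """Read a tab-delimited (snp_id, ldscore) file."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if not {"snp_id", "ldscore"} <= set(df.columns):
        raise DataError("LD-score file must have columns snp_id and ldscore")
    return df
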