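"""Synthetic GWAS summary statistics with known causal ground truth.

Emulates the statistical structure of the real inputs to a two-sample
MR study: a handful of genome-wide-significant instruments for a
continuous exposure (default design mirrors a fasting-insulin-like
trait: 14 instruments jointly explaining 0.64% of variance in a study
of ~108,600 people), an outcome study on an independent sample,
standard errors scaling as 1/sqrt(2 maf (1-maf) n), configurable
causal effect, configurable horizontal pleiotropy (balanced,
directional, or InSIDE-violating), optional LD blocks, and
allele-bookkeeping corruptions (palindromic SNPs, swapped allele
labels) to exercise harmonization.  Identical configuration and seed
regenerate bit-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfigError, VariantAssociation

#: two-sided genome-wide significance on the z scale
Z_GW = float(stats.norm.isf(5e-8 / 2))

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters of one synthetic exposure/outcome pair.

    Defaults mirror the fasting-insulin -> anorexia design: 14
    instruments explaining 0.64% of exposure variance at n_exp =
    108,557, an outcome study of n_out = 72,515, and a true causal
    effect of -0.72 outcome units per exposure unit.
    """

    beta_causal: float = -0.72
    pleiotropy_model: str = "none"  # none | balanced | directional | correlated
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0  # fraction of IVs carrying direct effects
    n_iv: int = 14
    n_exp: float = 108_557
    n_out: float = 72_515
    r2_total: float = 0.0064
    maf_range: tuple = (0.05, 0.5)
    ld_block_spec: Optional[tuple] = None  # tuple of (block_size, r)
    n_null: int = 50
    palindromic_rate: float = 0.1
    flip_rate: float = 0.1
    snp_prefix: str = "rs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pleiotropy_model not in ("none", "balanced", "directional", "correlated"):
            raise ConfigError(f"unknown pleiotropy model {self.pleiotropy_model!r}")
        if self.n_iv < 1:
            raise ConfigError("n_iv must be >= 1")
        if not (0 < self.r2_total < 1):
            raise ConfigError("r2_total must lie in (0,1)")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ConfigError("pleiotropy_fraction must lie in [0,1]")


@dataclass
class IVDataset:
    exposure: list
    outcome: list
    ld: pd.DataFrame
    truth: SimTruth
    iv_ids: list = field(default_factory=list)


def _check_feasible(truth: SimTruth) -> None:
    mean_chi = truth.r2_total / truth.n_iv * truth.n_exp
    if math.sqrt(mean_chi) < Z_GW:
        min_r2 = truth.n_iv * Z_GW**2 / truth.n_exp
        raise ConfigError(
            f"genome-wide significance unreachable: mean per-IV noncentrality "
            f"{math.sqrt(mean_chi):.2f} < {Z_GW:.2f}; minimal feasible r2_total "
            f"at this design is {min_r2:.4g}"
        )


def _block_correlation(m: int, spec: Optional[tuple]) -> tuple[np.ndarray, np.ndarray]:
    """Signed correlation matrix (r) and membership from an LD block spec."""
    corr = np.eye(m)
    if spec:
        start = 0
        for size, r in spec:
            end = min(start + size, m)
            for i in range(start, end):
                for j in range(start, end):
                    if i != j:
                        corr[i, j] = r
            start = end
            if start >= m:
                break
    return corr, np.linalg.cholesky(corr + 1e-12 * np.eye(m))


def _record(snp, chrom, pos, a1, a2, eaf, beta, se, n) -> VariantAssociation:
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    underflow = p == 0.0
    if underflow:
        p = np.finfo(float).tiny
    return VariantAssociation(
        snp_id=snp, chrom=chrom, pos=int(pos), effect_allele=a1, other_allele=a2,
        eaf=float(eaf), beta=float(beta), se=float(se), pvalue=p, n=float(n),
        pvalue_underflow=underflow,
    )


def _structure(truth: SimTruth):
    """SNP map, frequencies, alleles and true effects; independent of the
    exposure/outcome noise streams so the same structure is reused when only
    the causal effect changes."""
    rng = np.random.default_rng([truth.seed, 7])
    m = truth.n_iv + truth.n_null
    ids = [f"{truth.snp_prefix}{i + 1:05d}" for i in range(m)]
    maf = rng.uniform(truth.maf_range[0], truth.maf_range[1], size=m)
    pal = rng.random(m) < truth.palindromic_rate
    pair_idx = rng.integers(0, 8, size=m)
    alleles = []
    for i in range(m):
        if pal[i]:
            alleles.append(_PALINDROMIC_PAIRS[pair_idx[i] % 4])
        else:
            alleles.append(_NONPALINDROMIC_PAIRS[pair_idx[i]])
    # per-IV variance explained: mildly heterogeneous around r2_total/n_iv
    u = rng.uniform(0.7, 1.3, size=truth.n_iv)
    r2 = u / u.sum() * truth.r2_total
    sign = rng.choice([-1.0, 1.0], size=truth.n_iv)
    beta_std = sign * np.sqrt(r2)  # per standardized genotype
    denom = np.sqrt(2.0 * maf * (1.0 - maf))
    beta_true = np.zeros(m)
    beta_true[: truth.n_iv] = beta_std / denom[: truth.n_iv]
    # genomic placement: far apart unless an LD block spec groups them
    chrom = [str(1 + (i % 22)) for i in range(m)]
    pos = [1_000_000 + 20_000_000 * (i // 22) for i in range(m)]
    if truth.ld_block_spec:
        chrom = ["1"] * m
        pos = [1_000_000 + 50_000 * i for i in range(m)]
    flip = rng.random(m) < truth.flip_rate
    eaf_shift = rng.normal(0.0, 0.01, size=m)
    return ids, maf, alleles, beta_true, chrom, pos, flip, eaf_shift


def _pleiotropy(truth: SimTruth, beta_true: np.ndarray, rng) -> np.ndarray:
    """Direct (pleiotropic) outcome effects per instrument, expressed
    relative to the exposure-increasing allele."""
    k = truth.n_iv
    if truth.pleiotropy_model == "none":
        alpha = np.zeros(k)
    elif truth.pleiotropy_model == "balanced":
        alpha = rng.normal(0.0, truth.pleiotropy_sd, size=k)
    elif truth.pleiotropy_model == "directional":
        alpha = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, size=k)
    else:  # correlated: direct effects track instrument strength (InSIDE violated)
        alpha = truth.pleiotropy_mean * np.abs(beta_true[:k]) + rng.normal(
            0.0, truth.pleiotropy_sd, size=k
        )
    if truth.pleiotropy_fraction < 1.0:
        n_invalid = int(round(truth.pleiotropy_fraction * k))
        rng_sub = np.random.default_rng([truth.seed, 19])
        invalid = rng_sub.choice(k, size=n_invalid, replace=False)
        mask = np.zeros(k)
        mask[invalid] = 1.0
        alpha = alpha * mask
    return alpha * np.sign(beta_true[:k])


def simulate_iv_dataset(truth: SimTruth) -> IVDataset:
    """Generate one exposure/outcome summary-statistic pair plus LD matrix.

    Instrument exposure effects are sized so the set jointly explains
    ``r2_total`` at ``n_exp`` (all genome-wide significant in
    expectation); each outcome effect is beta_causal * beta_exp plus
    the configured pleiotropy plus sampling noise.  Raises
    :class:`ConfigError` with the minimal feasible effect size when
    significance is unreachable at the configured design.
    """
    _check_feasible(truth)
    ids, maf, alleles, beta_true, chrom, pos, flip, eaf_shift = _structure(truth)
    m = len(ids)
    k = truth.n_iv
    rng_exp = np.random.default_rng([truth.seed, 11])
    rng_out = np.random.default_rng([truth.seed, 13])

    se_exp = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * truth.n_exp)
    se_out = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * truth.n_out)

    corr, chol = _block_correlation(m, truth.ld_block_spec)
    # marginal effects under LD: correlated neighbours pick up r * lead effect
    beta_marg_exp = corr @ beta_true if truth.ld_block_spec else beta_true.copy()

    alpha = np.zeros(m)
    alpha[:k] = _pleiotropy(truth, beta_true, rng_out)
    beta_marg_out = (
        corr @ (truth.beta_causal * beta_true + alpha)
        if truth.ld_block_spec
        else truth.beta_causal * beta_true + alpha
    )

    noise_exp = chol @ rng_exp.normal(size=m) * se_exp
    noise_out = chol @ rng_out.normal(size=m) * se_out
    bx = beta_marg_exp + noise_exp
    by = beta_marg_out + noise_out

    exposure, outcome = [], []
    for i in range(m):
        a1, a2 = alleles[i]
        exposure.append(
            _record(ids[i], chrom[i], pos[i], a1, a2, maf[i], bx[i], se_exp[i], truth.n_exp)
        )
        eaf_o = float(np.clip(maf[i] + eaf_shift[i], 0.01, 0.99))
        if flip[i]:
            outcome.append(
                _record(ids[i], chrom[i], pos[i], a2, a1, 1.0 - eaf_o, -by[i], se_out[i], truth.n_out)
            )
        else:
            outcome.append(
                _record(ids[i], chrom[i], pos[i], a1, a2, eaf_o, by[i], se_out[i], truth.n_out)
            )
    r2mat = pd.DataFrame(corr**2, index=ids, columns=ids)
    return IVDataset(
        exposure=exposure, outcome=outcome, ld=r2mat, truth=truth, iv_ids=ids[:k]
    )


@dataclass
class BMIPair:
    adjusted: list
    unadjusted: list
    stable_ids: list
    shifted_ids: list


def simulate_bmi_pair(truth: SimTruth, covariate_shift_fraction: float) -> BMIPair:
    """Two exposure datasets over the same SNPs differing by covariate adjustment.

    A chosen fraction of instruments lose genome-wide significance
    without adjustment (their unadjusted z is pinned at 4, well below
    the threshold); the rest are pinned comfortably above it in both
    datasets, so the ground-truth stable set is recovered exactly by
    construction.
    """
    if not (0.0 <= covariate_shift_fraction <= 1.0):
        raise ConfigError("covariate_shift_fraction must lie in [0,1]")
    ds = simulate_iv_dataset(truth)
    k = truth.n_iv
    n_shift = int(round(covariate_shift_fraction * k))
    rng = np.random.default_rng([truth.seed, 17])
    shifted = set(rng.choice(k, size=n_shift, replace=False).tolist())

    adjusted, unadjusted = [], []
    for i, rec in enumerate(ds.exposure):
        if i < k:
            sign = 1.0 if rec.beta >= 0 else -1.0
            z = abs(rec.beta) / rec.se
            z_adj = max(z, Z_GW + 0.8)
            adj = _record(
                rec.snp_id, rec.chrom, rec.pos, rec.effect_allele, rec.other_allele,
                rec.eaf, sign * z_adj * rec.se, rec.se, rec.n,
            )
            if i in shifted:
                una = _record(
                    rec.snp_id, rec.chrom, rec.pos, rec.effect_allele, rec.other_allele,
                    rec.eaf, sign * 4.0 * rec.se, rec.se, rec.n,
                )
            else:
                una = adj
            adjusted.append(adj)
            unadjusted.append(una)
        else:
            adjusted.append(rec)
            unadjusted.append(rec)
    stable = [ds.iv_ids[i] for i in range(k) if i not in shifted]
    shifted_ids = [ds.iv_ids[i] for i in sorted(shifted)]
    return BMIPair(
        adjusted=adjusted, unadjusted=unadjusted,
        stable_ids=stable, shifted_ids=shifted_ids,
    )


@dataclass
class GenomewideDataset:
    trait1: list
    trait2: list
    ld_scores: pd.DataFrame
    gcp_truth: float
    rho_g: float


def simulate_genomewide(
    m_snps: int,
    h2_1: float,
    h2_2: float,
    rho_g: float,
    gcp_truth: float,
    n1: float,
    n2: float,
    seed: int = 0,
    p_causal_latent: float = 0.05,
    p_causal_direct: float = 0.2,
    flip_rate: float = 0.1,
) -> GenomewideDataset:
    """Genome-wide summary statistics under a latent-factor architecture.

    Standardized effects: b_t = sqrt(h2_t/M) (q_t pi + sqrt(1-q_t^2) g_t)
    with pi the shared sparse latent factor and g_t trait-specific
    polygenic effects; the mediation shares q_1 = |rho|^{(1-gcp)/2},
    q_2 = sign(rho) |rho|^{(1+gcp)/2} realise the requested genetic
    correlation and genetic causality proportion.  Sparse (point-normal)
    effects supply the excess kurtosis the LCV moment estimator needs.
    SNPs are LD-free, so every emitted LD score is 1.
    """
    if not (0.0 < h2_1 < 1.0) or not (0.0 < h2_2 < 1.0):
        raise ConfigError("heritabilities must lie in (0,1)")
    if not (-1.0 <= gcp_truth <= 1.0):
        raise ConfigError("gcp_truth must lie in [-1,1]")
    if not (-1.0 < rho_g < 1.0):
        raise ConfigError("rho_g must lie in (-1,1)")
    if rho_g == 0.0 and gcp_truth != 0.0:
        raise ConfigError("gcp_truth != 0 is infeasible with rho_g = 0")
    rng = np.random.default_rng([seed, 29])
    a = abs(rho_g)
    if a > 0:
        q1 = a ** ((1.0 - gcp_truth) / 2.0)
        q2 = math.copysign(a ** ((1.0 + gcp_truth) / 2.0), rho_g)
    else:
        q1 = q2 = 0.0

    def sparse_normal(p):
        mask = rng.random(m_snps) < p
        return mask * rng.normal(0.0, 1.0 / math.sqrt(p), size=m_snps)

    pi = sparse_normal(p_causal_latent)
    g1 = sparse_normal(p_causal_direct)
    g2 = sparse_normal(p_causal_direct)
    b1 = math.sqrt(h2_1 / m_snps) * (q1 * pi + math.sqrt(max(0.0, 1 - q1**2)) * g1)
    b2 = math.sqrt(h2_2 / m_snps) * (q2 * pi + math.sqrt(max(0.0, 1 - q2**2)) * g2)
    z1 = math.sqrt(n1) * b1 + rng.normal(size=m_snps)
    z2 = math.sqrt(n2) * b2 + rng.normal(size=m_snps)

    maf = rng.uniform(0.05, 0.5, size=m_snps)
    pair_idx = rng.integers(0, 8, size=m_snps)
    flip = rng.random(m_snps) < flip_rate
    se1 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n1)
    se2 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n2)
    t1, t2 = [], []
    for i in range(m_snps):
        snp = f"rs{i + 1:06d}"
        a1, a2 = _NONPALINDROMIC_PAIRS[pair_idx[i]]
        pos = 1000 + 5000 * i
        t1.append(_record(snp, "1", pos, a1, a2, maf[i], z1[i] * se1[i], se1[i], n1))
        if flip[i]:
            t2.append(
                _record(snp, "1", pos, a2, a1, 1.0 - maf[i], -z2[i] * se2[i], se2[i], n2)
            )
        else:
            t2.append(_record(snp, "1", pos, a1, a2, maf[i], z2[i] * se2[i], se2[i], n2))
    ld_scores = pd.DataFrame(
        {"snp_id": [f"rs{i + 1:06d}" for i in range(m_snps)], "ldscore": 1.0}
    )
    return GenomewideDataset(
        trait1=t1, trait2=t2, ld_scores=ld_scores, gcp_truth=gcp_truth, rho_g=rho_g
    )


def truth_to_dict(truth: SimTruth) -> dict:
    d = asdict(truth)
    d["maf_range"] = list(truth.maf_range)
    if truth.ld_block_spec is not None:
        d["ld_block_spec"] = [list(b) for b in truth.ld_block_spec]
    return d


def truth_from_dict(d: dict) -> SimTruth:
    d = dict(d)
    if "maf_range" in d:
        d["maf_range"] = tuple(d["maf_range"])
    if d.get("ld_block_spec") is not None:
        d["ld_block_spec"] = tuple(tuple(b) for b in d["ld_block_spec"])
    return SimTruth(**d)
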