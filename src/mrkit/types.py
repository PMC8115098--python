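"""Domain types shared across the toolkit.

The records here mirror the columns of GWAS summary-statistic files
(one marginal association per SNP) plus the per-study metadata needed
for liability-scale work on binary traits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Optional

from scipy import stats

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization provenance flags
ACTION_ALIGNED = "aligned"
ACTION_FLIPPED = "flipped"
ACTION_PALINDROMIC_INFERRED = "palindromic_inferred"
ACTION_REMOVED_PALINDROMIC = "removed_palindromic"
ACTION_REMOVED_MISSING = "removed_missing"
ACTION_REMOVED_MISMATCH = "removed_mismatch"


class MRKitError(Exception):
    """Base class for toolkit errors."""


class DataError(MRKitError):
    """Invalid or inconsistent input data."""


class ConfigError(MRKitError):
    """Invalid analysis configuration."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's marginal association in one GWAS.

    ``beta`` is the per-unit effect of the effect allele on the study
    trait (log-odds for binary traits); ``eaf`` is the effect-allele
    frequency, ``None`` when the study did not report it.  Coordinates
    are 1-based.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: float
    pvalue_underflow: bool = False  # p was 0 in the source file


@dataclass(frozen=True)
class StudyMeta:
    """Per-study metadata carried alongside a summary-statistics table."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    unit: str
    n: float
    n_cases: Optional[float] = None
    prevalence: Optional[float] = None
    ancestry_label: str = "EUR"

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        if self.trait_type == "binary":
            if self.n_cases is None:
                raise ConfigError(f"binary trait {self.trait_name!r} requires n_cases")
            if self.n_cases > self.n:
                raise ConfigError(f"n_cases > n for trait {self.trait_name!r}")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise ConfigError(f"prevalence must lie in (0,1), got {self.prevalence}")

    @property
    def case_proportion(self) -> Optional[float]:
        if self.n_cases is None:
            return None
        return float(self.n_cases) / float(self.n)


@dataclass(frozen=True)
class InstrumentStrength:
    """Aggregate strength of an instrument set.

    ``r2_total`` is the fraction of exposure variance explained by the
    ``k`` instruments in a study of ``n`` individuals.
    """

    r2_total: float
    k: int
    n: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_total < 1.0):
            raise DataError(f"r2_total must lie in [0,1), got {self.r2_total}")
        if self.k < 1:
            raise DataError("instrument count k must be >= 1")
        if self.n <= self.k + 1:
            raise DataError("sample size n must exceed k + 1")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome-aligned instrumental variable.

    Effects are expressed per effect allele of the *exposure* study;
    ``action_taken`` records how the outcome association was aligned.
    Records whose action starts with ``removed`` carry no usable
    outcome effect and are excluded from estimation.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float]
    eaf_out: Optional[float]
    action_taken: str
    pvalue_exp: Optional[float] = None
    pvalue_out: Optional[float] = None
    n_exp: Optional[float] = None
    n_out: Optional[float] = None

    @property
    def usable(self) -> bool:
        return not self.action_taken.startswith("removed")


@dataclass(frozen=True)
class MRFit:
    """One estimator's causal estimate."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k_used: int
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SteigerResult:
    """Directionality test outcome."""

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    p_direction: float
    prevalence_used: Optional[float]
    undetermined: bool = False


@dataclass(frozen=True)
class SensitivityReport:
    """Heterogeneity / pleiotropy / directionality summary for one model."""

    q_stat: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso_global_p: float
    loo_estimates: tuple  # of (snp_id, MRFit, flagged)
    steiger: Optional[SteigerResult]
    i2_gx: Optional[float] = None


@dataclass(frozen=True)
class LCVResult:
    """Latent causal variable model output."""

    gcp: float
    gcp_se: float
    p_gcp_zero: float
    p_full_causal_fwd: float
    p_full_causal_rev: float
    rho_g: float
    h2_z1: float = float("nan")
    h2_z2: float = float("nan")


def is_valid_allele(a: str) -> bool:
    return len(a) == 1 and a in VALID_BASES


def variant_errors(v: VariantAssociation, p_consistency_tol: float = 0.10) -> list[str]:
    """Validate a record against the per-field invariants.

    Returns a list of human-readable violations (empty when valid).
    The beta/se/p consistency check compares the reported p-value with
    the two-sided normal approximation 2*Phi(-|beta|/se) at relative
    tolerance ``p_consistency_tol``; it is skipped for underflowed
    p-values.
    """
    errs: list[str] = []
    if not is_valid_allele(v.effect_allele) or not is_valid_allele(v.other_allele):
        errs.append("alleles must be single bases in {A,C,G,T}")
    elif v.effect_allele == v.other_allele:
        errs.append("effect and other allele must differ")
    if v.eaf is not None and not (0.0 <= v.eaf <= 1.0):
        errs.append("eaf outside [0,1]")
    if not (v.se > 0.0) or not math.isfinite(v.se):
        errs.append("se must be > 0")
    if not (0.0 < v.pvalue <= 1.0):
        errs.append("pvalue outside (0,1]")
    if not (v.n > 0):
        errs.append("n must be > 0")
    if v.pos < 1:
        errs.append("pos must be 1-based (>= 1)")
    if not errs and not v.pvalue_underflow:
        z = abs(v.beta) / v.se
        p_hat = 2.0 * stats.norm.sf(z)
        if p_hat > 1e-250:
            if abs(v.pvalue - p_hat) > p_consistency_tol * p_hat:
                errs.append("pvalue inconsistent with beta/se (normal approximation)")
        elif v.pvalue > 1e-200:
            errs.append("pvalue inconsistent with beta/se (normal approximation)")
    return errs
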