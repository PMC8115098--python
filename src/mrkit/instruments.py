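"""Instrument selection, LD clumping, harmonization, and strength metrics.

Instrument selection follows the genome-wide significance convention
(p < 5e-8); clumping greedily thins correlated variants below an LD
r-squared threshold; harmonization aligns outcome effects to the
exposure's effect allele, inferring the strand for palindromic SNPs
from allele frequencies where possible and removing them otherwise.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ACTION_ALIGNED,
    ACTION_FLIPPED,
    ACTION_PALINDROMIC_INFERRED,
    ACTION_REMOVED_MISMATCH,
    ACTION_REMOVED_MISSING,
    ACTION_REMOVED_PALINDROMIC,
    COMPLEMENT,
    DataError,
    HarmonizedInstrument,
    InstrumentStrength,
    VariantAssociation,
)

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_EAF_AMBIGUITY = 0.08


def select_instruments(
    records: Iterable[VariantAssociation], p_threshold: float = GENOME_WIDE_P
) -> list[VariantAssociation]:
    """Keep associations with p below threshold, sorted by ascending p.

    Ties are broken by snp_id for determinism.  An empty result is
    returned as an empty list; the caller decides whether that is an
    error.
    """
    hits = [r for r in records if r.pvalue < p_threshold]
    hits.sort(key=lambda r: (r.pvalue, r.snp_id))
    return hits


def clump(
    candidates: Sequence[VariantAssociation],
    ld: Optional[pd.DataFrame] = None,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> list[VariantAssociation]:
    """Greedy LD clumping of p-sorted candidates.

    Repeatedly keeps the most significant remaining SNP and discards
    all remaining SNPs on the same chromosome within ``window_kb``
    whose LD r-squared with it is at or above ``r2_threshold``.  ``ld``
    is a square r-squared matrix indexed by snp_id; when absent all
    pairs are treated as independent and a warning is emitted.  A
    missing LD entry for an in-window pair is a hard error.
    """
    if ld is None:
        if len(candidates) > 1:
            warnings.warn(
                "no LD matrix supplied; treating all candidate pairs as independent",
                stacklevel=2,
            )
        return list(candidates)
    order = sorted(candidates, key=lambda r: (r.pvalue, r.snp_id))
    kept: list[VariantAssociation] = []
    discarded: set[str] = set()
    window_bp = window_kb * 1000.0
    for i, lead in enumerate(order):
        if lead.snp_id in discarded:
            continue
        kept.append(lead)
        for other in order[i + 1 :]:
            if other.snp_id in discarded:
                continue
            if other.chrom != lead.chrom or abs(other.pos - lead.pos) > window_bp:
                continue
            try:
                r2 = float(ld.loc[lead.snp_id, other.snp_id])
            except KeyError:
                raise DataError(
                    f"LD matrix missing entry for in-window pair "
                    f"({lead.snp_id}, {other.snp_id})"
                )
            if np.isnan(r2):
                raise DataError(
                    f"LD matrix has NaN for in-window pair ({lead.snp_id}, {other.snp_id})"
                )
            if r2 >= r2_threshold:
                discarded.add(other.snp_id)
    return kept


def is_palindromic(variant: VariantAssociation) -> bool:
    """True iff the allele pair is its own reverse complement (A/T or C/G)."""
    return {variant.effect_allele, variant.other_allele} in ({"A", "T"}, {"C", "G"})


def _pval(rec: VariantAssociation) -> float:
    return rec.pvalue


def harmonize(
    exposure_ivs: Sequence[VariantAssociation],
    outcome_records: Iterable[VariantAssociation],
    eaf_ambiguity: float = DEFAULT_EAF_AMBIGUITY,
) -> list[HarmonizedInstrument]:
    """Align outcome associations to the exposure effect alleles.

    Matching is on snp_id.  Alleles that agree are aligned as-is;
    swapped effect/other alleles flip the outcome beta's sign (and
    mirror its frequency); strand complements are complemented then
    aligned.  Palindromic SNPs keep an inferred orientation only when
    both allele frequencies fall outside the ambiguity window
    [0.5 - eaf_ambiguity, 0.5 + eaf_ambiguity] and lie on the same
    side of 0.5; otherwise they are marked ``removed_palindromic``.
    Exposure IVs absent from the outcome become ``removed_missing``;
    non-complementary allele mismatches become ``removed_mismatch``
    (never silently dropped).  Exposure effects are never altered.
    """
    out_by_id: dict[str, VariantAssociation] = {}
    for rec in outcome_records:
        out_by_id.setdefault(rec.snp_id, rec)

    harmonized: list[HarmonizedInstrument] = []
    for exp in exposure_ivs:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            harmonized.append(
                _make_h(exp, None, 0.0, 1.0, None, ACTION_REMOVED_MISSING)
            )
            continue
        e1, e2 = exp.effect_allele, exp.other_allele
        o1, o2 = out.effect_allele, out.other_allele
        if is_palindromic(exp):
            if {o1, o2} != {e1, e2}:
                harmonized.append(
                    _make_h(exp, out, out.beta, out.se, out.eaf, ACTION_REMOVED_MISMATCH)
                )
                continue
            # Labels cannot distinguish strands here; align by label,
            # then require unambiguous, concordant frequencies.
            if o1 == e1:
                beta_out, eaf_out = out.beta, out.eaf
            else:
                beta_out = -out.beta
                eaf_out = None if out.eaf is None else 1.0 - out.eaf
            lo, hi = 0.5 - eaf_ambiguity, 0.5 + eaf_ambiguity
            if (
                exp.eaf is None
                or eaf_out is None
                or lo <= exp.eaf <= hi
                or lo <= eaf_out <= hi
                or (exp.eaf - 0.5) * (eaf_out - 0.5) <= 0
            ):
                harmonized.append(
                    _make_h(exp, out, beta_out, out.se, eaf_out, ACTION_REMOVED_PALINDROMIC)
                )
            else:
                harmonized.append(
                    _make_h(exp, out, beta_out, out.se, eaf_out, ACTION_PALINDROMIC_INFERRED)
                )
            continue
        c1, c2 = COMPLEMENT[o1], COMPLEMENT[o2]
        if (o1, o2) == (e1, e2) or (c1, c2) == (e1, e2):
            harmonized.append(
                _make_h(exp, out, out.beta, out.se, out.eaf, ACTION_ALIGNED)
            )
        elif (o2, o1) == (e1, e2) or (c2, c1) == (e1, e2):
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
            harmonized.append(
                _make_h(exp, out, -out.beta, out.se, eaf_out, ACTION_FLIPPED)
            )
        else:
            harmonized.append(
                _make_h(exp, out, out.beta, out.se, out.eaf, ACTION_REMOVED_MISMATCH)
            )
    return harmonized


def _make_h(
    exp: VariantAssociation,
    out: Optional[VariantAssociation],
    beta_out: float,
    se_out: float,
    eaf_out: Optional[float],
    action: str,
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=beta_out,
        se_out=se_out,
        eaf_exp=exp.eaf,
        eaf_out=eaf_out,
        action_taken=action,
        pvalue_exp=exp.pvalue,
        pvalue_out=out.pvalue if out is not None else None,
        n_exp=exp.n,
        n_out=out.n if out is not None else None,
    )


def usable(h: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """Instruments that survived harmonization."""
    return [x for x in h if x.usable]


def r2_from_pn(pvalue: float, n: float) -> float:
    """Variance explained implied by a p-value under a 1-df test.

    With t2 the upper-``pvalue`` quantile of F(1, n-2), returns
    t2 / (t2 + n - 2) — the squared correlation whose test statistic
    would give that p.  Summing over independent SNPs estimates the
    variance explained by an instrument set.
    """
    if n <= 2:
        raise DataError(f"r2_from_pn requires n > 2, got n={n}")
    if not (0.0 < pvalue <= 1.0):
        raise DataError(f"pvalue must lie in (0,1], got {pvalue}")
    t2 = stats.f.isf(pvalue, 1, n - 2)
    if not np.isfinite(t2):
        # extreme p underflows the F inversion; chi-square(1) is exact there
        t2 = stats.chi2.isf(pvalue, 1)
    return float(t2 / (t2 + n - 2))


def f_statistic(strength: InstrumentStrength) -> float:
    """Cragg-Donald style instrument strength F.

    F = R2 (N - k - 1) / ((1 - R2) k); values above 10 conventionally
    denote adequately strong instruments.
    """
    r2, k, n = strength.r2_total, strength.k, strength.n
    if r2 >= 1.0:
        raise DataError("r2_total must be < 1")
    return float(r2 * (n - k - 1) / ((1.0 - r2) * k))


def strength_from_ivs(
    ivs: Sequence[VariantAssociation], n: Optional[float] = None
) -> InstrumentStrength:
    """Instrument strength of a set: per-SNP r2 from p/n, summed."""
    if not ivs:
        raise DataError("cannot compute strength of an empty IV set")
    if n is None:
        n = float(np.median([r.n for r in ivs]))
    r2 = float(sum(r2_from_pn(r.pvalue, r.n) for r in ivs))
    return InstrumentStrength(r2_total=min(r2, 1.0 - 1e-12), k=len(ivs), n=n)


def subset_by_annotation(
    ivs: Sequence[VariantAssociation],
    annotation_map: Mapping[str, str],
    keep_label: str,
    default_label: str = "unannotated",
) -> list[VariantAssociation]:
    """Keep IVs whose annotation equals ``keep_label``.

    Used e.g. to restrict glycated-haemoglobin instruments to variants
    acting through glycaemic (rather than erythrocytic) pathways.
    """
    return [
        r for r in ivs if annotation_map.get(r.snp_id, default_label) == keep_label
    ]


def stable_instruments(
    ivs_adjusted: Sequence[VariantAssociation],
    ivs_unadjusted: Sequence[VariantAssociation],
    p_threshold: float = GENOME_WIDE_P,
) -> tuple[list[str], list[str], list[str]]:
    """Partition SNPs by covariate-adjustment stability of significance.

    Returns (stable, adjusted_only, unadjusted_only) snp_id lists over
    the union of SNPs significant in either input; "stable" SNPs reach
    ``p_threshold`` in both.  A SNP absent from one input counts as
    not significant there.  Disjoint snp_id universes are a hard error
    (the two inputs must describe the same trait).
    """
    adj = {r.snp_id: r for r in ivs_adjusted}
    una = {r.snp_id: r for r in ivs_unadjusted}
    if adj and una and not (set(adj) & set(una)):
        raise DataError(
            "adjusted and unadjusted IV sets share no snp_ids; are these the same trait?"
        )
    sig_adj = {s for s, r in adj.items() if r.pvalue < p_threshold}
    sig_una = {s for s, r in una.items() if r.pvalue < p_threshold}
    stable = sorted(sig_adj & sig_una)
    adjusted_only = sorted(sig_adj - sig_una)
    unadjusted_only = sorted(sig_una - sig_adj)
    return stable, adjusted_only, unadjusted_only


def remove_shared_hits(
    ivs: Sequence[VariantAssociation],
    confounder_records: Iterable[VariantAssociation],
    p_threshold: float = GENOME_WIDE_P,
) -> tuple[list[VariantAssociation], list[str]]:
    """Drop IVs that are genome-wide significant for a confounder trait.

    Returns (retained IVs, dropped snp_ids).  IVs absent from the
    confounder file are retained.
    """
    conf = {r.snp_id: r for r in confounder_records}
    kept: list[VariantAssociation] = []
    dropped: list[str] = []
    for r in ivs:
        c = conf.get(r.snp_id)
        if c is not None and c.pvalue < p_threshold:
            dropped.append(r.snp_id)
        else:
            kept.append(r)
    if not kept:
        warnings.warn(
            "all IVs were associated with the confounder at the given threshold",
            stacklevel=2,
        )
    return kept, dropped


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a whitespace-delimited square LD matrix with SNP-ID labels."""
    df = pd.read_csv(path, sep=r"\s+", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise DataError("LD matrix row and column labels differ")
    return df


def read_annotation_map(path) -> dict[str, str]:
    """Read a two-column (snp_id, label) annotation file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "label"], dtype=str)
    return dict(zip(df["snp_id"], df["label"]))
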