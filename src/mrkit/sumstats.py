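"""Read, validate, write, and munge GWAS summary-statistic tables.

File dialect: tab-delimited with a header; canonical columns are
``SNP CHR POS A1 A2 EAF BETA SE P N`` (A1 = effect allele).  A
user-supplied column map accommodates other GWAS header conventions.
Gzip input/output is handled transparently by pandas via the file
extension.
"""
from __future__ import annotations

import math
import sys
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DataError,
    StudyMeta,
    VariantAssociation,
    variant_errors,
)

CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "A1", "A2", "EAF", "BETA", "SE", "P", "N")

#: smallest positive double, used to rescue p-values that underflowed to 0
P_UNDERFLOW = sys.float_info.min


@dataclass
class ReadResult:
    """Validated records plus the bookkeeping of dropped rows."""

    records: list[VariantAssociation]
    n_input: int
    n_dropped: int
    drop_reasons: Counter = field(default_factory=Counter)
    pzero_flagged: list[str] = field(default_factory=list)
    meta: Optional[StudyMeta] = None


@dataclass
class MungeResult:
    """Filtered records plus per-filter removal counts.

    A record is attributed to the first filter that removes it
    (palindromic before allele-frequency).  SNPs whose chi-square
    exceeds the cap are retained but flagged, never rescaled.
    """

    records: list[VariantAssociation]
    removed: Counter = field(default_factory=Counter)
    chi2_flagged: list[str] = field(default_factory=list)


def _as_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    try:
        f = float(x)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def read_sumstats(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    meta: Optional[StudyMeta] = None,
) -> ReadResult:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps canonical names (``SNP``, ``CHR``, ... ``N``) to
    the file's header names; identity by default.  Rows violating the
    record invariants are dropped and counted by reason.  Alleles are
    upper-cased; p-values of exactly 0 are replaced by the smallest
    positive double and flagged (top hits stay usable as instruments).

    Raises :class:`DataError` for a missing mandatory column or an
    empty file.
    """
    cmap = {c: c for c in CANONICAL_COLUMNS}
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty summary-statistics file: {path}")
    missing = [c for c in CANONICAL_COLUMNS if cmap[c] not in df.columns and c != "EAF"]
    if missing:
        raise DataError(
            f"missing mandatory column(s) {[cmap[c] for c in missing]} in {path}"
        )
    has_eaf = cmap["EAF"] in df.columns

    records: list[VariantAssociation] = []
    reasons: Counter = Counter()
    pzero: list[str] = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            pval = _as_float(row[cmap["P"]])
            underflow = False
            if pval == 0.0:
                pval = P_UNDERFLOW
                underflow = True
            rec = VariantAssociation(
                snp_id=str(row[cmap["SNP"]]),
                chrom=str(row[cmap["CHR"]]),
                pos=int(float(row[cmap["POS"]])),
                effect_allele=str(row[cmap["A1"]]).upper(),
                other_allele=str(row[cmap["A2"]]).upper(),
                eaf=_as_float(row[cmap["EAF"]]) if has_eaf else None,
                beta=float(row[cmap["BETA"]]),
                se=float(row[cmap["SE"]]),
                pvalue=pval if pval is not None else float("nan"),
                n=float(row[cmap["N"]]),
                pvalue_underflow=underflow,
            )
        except (TypeError, ValueError):
            reasons["unparseable"] += 1
            continue
        errs = variant_errors(rec)
        if errs:
            reasons[errs[0]] += 1
            continue
        if underflow:
            pzero.append(rec.snp_id)
        records.append(rec)
    if len(df) == 0:
        raise DataError(f"summary-statistics file has no data rows: {path}")
    return ReadResult(
        records=records,
        n_input=len(df),
        n_dropped=len(df) - len(records),
        drop_reasons=reasons,
        pzero_flagged=pzero,
        meta=meta,
    )


def write_sumstats(records: Sequence[VariantAssociation], path) -> None:
    """Write records as a canonical tab-delimited table.

    Missing ``eaf`` is serialized as ``NA``.  Floats are written at
    full precision so that ``read_sumstats(write_sumstats(x)) == x``.
    """
    rows = [
        {
            "SNP": r.snp_id,
            "CHR": r.chrom,
            "POS": r.pos,
            "A1": r.effect_allele,
            "A2": r.other_allele,
            "EAF": r.eaf,
            "BETA": repr(r.beta),
            "SE": repr(r.se),
            "P": repr(r.pvalue) if not r.pvalue_underflow else "0.0",
            "N": repr(r.n),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    if len(df) and df["EAF"].notna().any():
        df["EAF"] = df["EAF"].map(lambda x: "NA" if x is None else repr(x))
    try:
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    except OSError as exc:
        raise DataError(f"cannot write summary statistics to {path}: {exc}")


def is_palindromic_pair(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def munge(
    records: Iterable[VariantAssociation],
    maf_min: float = 0.01,
    chi2_cap: float = 80.0,
) -> MungeResult:
    """Standardised cleaning ahead of genome-wide (LCV-style) analysis.

    Removes strand-ambiguous (palindromic) SNPs and SNPs with minor
    allele frequency below ``maf_min``; SNPs with chi-square
    (beta/se)^2 above ``chi2_cap`` are flagged but retained.  Raises
    :class:`DataError` with the per-filter tally if nothing survives.
    """
    kept: list[VariantAssociation] = []
    removed: Counter = Counter()
    flagged: list[str] = []
    for r in records:
        if is_palindromic_pair(r.effect_allele, r.other_allele):
            removed["palindromic"] += 1
            continue
        if r.eaf is not None and (r.eaf < maf_min or r.eaf > 1.0 - maf_min):
            removed["maf"] += 1
            continue
        if (r.beta / r.se) ** 2 > chi2_cap:
            flagged.append(r.snp_id)
        kept.append(r)
    if not kept:
        raise DataError(f"munge removed all records; per-filter tally: {dict(removed)}")
    return MungeResult(records=kept, removed=removed, chi2_flagged=flagged)


def zscores(records: Sequence[VariantAssociation]) -> np.ndarray:
    """Per-SNP z-scores beta/se, in record order."""
    return np.array([r.beta / r.se for r in records], dtype=float)
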