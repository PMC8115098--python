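"""Orchestrate the bidirectional exposure x outcome analysis grid.

For every eligible exposure-outcome pair: instrument selection ->
LD clumping -> harmonization -> primary IVW fit.  Pairs passing the
corrected significance threshold get the full estimator suite and
sensitivity report; pairs nominally significant (uncorrected p < 0.05)
get a lighter follow-up tier (MR-Egger, weighted median, weighted
mode); pairs with too few usable instruments are reported as
not-assessable with a reason code.  Binary-exposure estimates are
additionally reported on the liability scale.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import estimators, instruments, sensitivity
from .sumstats import read_sumstats, write_sumstats
from .types import (
    ConfigError,
    DataError,
    HarmonizedInstrument,
    MRFit,
    StudyMeta,
)

MIN_IVS_DEFAULT = 3  # pairs sharing fewer usable IVs are not assessable


@dataclass
class Study:
    """One GWAS summary-statistics table with metadata and grid roles."""

    meta: StudyMeta
    roles: frozenset  # subset of {"exposure", "outcome"}
    records: list = field(default_factory=list)
    path: Optional[str] = None
    ld: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        roles = frozenset(self.roles)
        if not roles <= {"exposure", "outcome"} or not roles:
            raise ConfigError(f"roles must be a non-empty subset of exposure/outcome, got {set(self.roles)}")
        object.__setattr__(self, "roles", roles)


@dataclass
class AnalysisConfig:
    studies: list
    iv_p_threshold: float = instruments.GENOME_WIDE_P
    clump_r2: float = instruments.DEFAULT_CLUMP_R2
    clump_window_kb: float = instruments.DEFAULT_CLUMP_WINDOW_KB
    eaf_ambiguity: float = instruments.DEFAULT_EAF_AMBIGUITY
    correction: str = "bonferroni"
    alpha: float = 0.05
    min_ivs: int = MIN_IVS_DEFAULT
    n_boot: int = 1000
    presso_n_sim: int = 1000
    force_full_suite: bool = False
    prevalence_bounds: dict = field(default_factory=dict)  # trait -> (low, high)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_ivs < 3:
            raise ConfigError("min_ivs must be >= 3")
        if self.correction not in ("bonferroni", "bh"):
            raise ConfigError(f"unknown correction {self.correction!r}")
        names = [s.meta.trait_name for s in self.studies]
        if len(names) != len(set(names)):
            raise ConfigError("study trait names must be distinct")


@dataclass
class GridResult:
    table: pd.DataFrame
    sensitivity: pd.DataFrame
    harmonized: dict  # (exposure, outcome) -> list[HarmonizedInstrument]
    log: list
    config: AnalysisConfig


def _pair_seed(seed: int, exposure: str, outcome: str) -> int:
    return zlib.crc32(f"{seed}:{exposure}->{outcome}".encode()) & 0x7FFFFFFF


def _row(exposure, outcome, method, fit: Optional[MRFit] = None, **kw) -> dict:
    row = {
        "exposure": exposure,
        "outcome": outcome,
        "method": method,
        "beta": np.nan,
        "se": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "pvalue": np.nan,
        "k_ivs": 0,
        "odds_ratio": np.nan,
        "or_ci_low": np.nan,
        "or_ci_high": np.nan,
        "beta_liability": np.nan,
        "tier": "",
        "reason": "",
    }
    if fit is not None:
        orr, olo, ohi = sensitivity.or_ci(fit.beta, fit.se)
        row.update(
            beta=fit.beta, se=fit.se, ci_low=fit.ci_low, ci_high=fit.ci_high,
            pvalue=fit.pvalue, k_ivs=fit.k_used,
            odds_ratio=orr, or_ci_low=olo, or_ci_high=ohi,
        )
    row.update(kw)
    return row


def _prepare_pair(exp: Study, out: Study, config: AnalysisConfig, log: list):
    ivs = instruments.select_instruments(exp.records, config.iv_p_threshold)
    n_sel = len(ivs)
    clumped = instruments.clump(
        ivs, ld=exp.ld, r2_threshold=config.clump_r2, window_kb=config.clump_window_kb
    ) if exp.ld is not None else list(ivs)
    h = instruments.harmonize(clumped, out.records, eaf_ambiguity=config.eaf_ambiguity)
    use = instruments.usable(h)
    log.append(
        f"{exp.meta.trait_name} -> {out.meta.trait_name}: "
        f"selected={n_sel} clumped={len(clumped)} harmonized={len(h)} usable={len(use)}"
    )
    return h, use


def run_grid(config: AnalysisConfig) -> GridResult:
    """Run the full analysis grid defined by ``config``.

    Per-pair failures are logged and do not abort the grid; zero
    eligible pairs is a hard error.  The primary IVW result for every
    pair is invariant to the order studies appear in the config (pairs
    are processed in sorted trait-name order with per-pair derived
    seeds).
    """
    exposures = sorted(
        (s for s in config.studies if "exposure" in s.roles),
        key=lambda s: s.meta.trait_name,
    )
    outcomes = sorted(
        (s for s in config.studies if "outcome" in s.roles),
        key=lambda s: s.meta.trait_name,
    )
    pairs = [
        (e, o)
        for e in exposures
        for o in outcomes
        if e.meta.trait_name != o.meta.trait_name
    ]
    if not pairs:
        raise ConfigError("no eligible exposure->outcome pairs in config")

    log: list[str] = [f"mrkit {_pkg_version}", f"seed {config.seed}"]
    rows: list[dict] = []
    sens_rows: list[dict] = []
    harmonized: dict = {}
    primary: dict = {}

    for e, o in pairs:
        key = (e.meta.trait_name, o.meta.trait_name)
        try:
            h, use = _prepare_pair(e, o, config, log)
            harmonized[key] = h
            if len(use) < config.min_ivs:
                rows.append(
                    _row(*key, "ivw", reason=f"not_assessable:insufficient_ivs({len(use)}<{config.min_ivs})")
                )
                continue
            fit = estimators.ivw(use)
            primary[key] = (fit, e, o, use)
            row = _row(*key, "ivw", fit, tier="primary")
            if e.meta.trait_type == "binary" and e.meta.prevalence is not None:
                row["beta_liability"] = sensitivity.liability_beta(
                    fit.beta, e.meta.prevalence
                )
            rows.append(row)
        except (DataError, ConfigError) as exc:
            log.append(f"{key[0]} -> {key[1]}: error: {exc}")
            rows.append(_row(*key, "ivw", reason=f"error:{exc}"))

    if primary:
        keys = sorted(primary)
        pvals = [primary[k][0].pvalue for k in keys]
        mt = sensitivity.multiple_testing(pvals, method=config.correction, alpha=config.alpha)
        corrected = {k: sig for k, sig in zip(keys, mt.significant)}
        if mt.threshold is not None:
            log.append(f"{config.correction} threshold {mt.threshold:.3g} over {len(keys)} pairs")
    else:
        corrected = {}

    for key, (fit, e, o, use) in sorted(primary.items()):
        is_corrected = corrected.get(key, False)
        is_nominal = fit.pvalue < 0.05
        pseed = _pair_seed(config.seed, *key)
        run_full = is_corrected or config.force_full_suite
        run_light = is_nominal and not run_full
        if not (run_full or run_light):
            continue
        tier = "corrected" if run_full else "nominal"
        try:
            i2 = estimators.i2_gx(use)
            if i2 <= 0.9:
                log.append(
                    f"{key[0]} -> {key[1]}: warning: I2_GX = {i2:.3f} <= 0.9; "
                    f"MR-Egger vulnerable to measurement-error dilution"
                )
            suite = [
                estimators.egger(use),
                estimators.weighted_median(use, n_boot=config.n_boot, seed=pseed),
                estimators.weighted_mode(use, n_boot=config.n_boot, seed=pseed + 1),
            ]
            if run_full:
                suite.append(
                    estimators.mr_presso(use, n_sim=config.presso_n_sim, seed=pseed + 2)
                )
                ld_corr = None
                if e.ld is not None:
                    ids = [x.snp_id for x in use]
                    ld_corr = np.sqrt(e.ld.loc[ids, ids].to_numpy(dtype=float))
                else:
                    ld_corr = np.eye(len(use))
                suite.append(estimators.ivw_correlated(use, ld_corr))
            for f in suite:
                row = _row(*key, f.method, f, tier=tier)
                if e.meta.trait_type == "binary" and e.meta.prevalence is not None:
                    row["beta_liability"] = sensitivity.liability_beta(
                        f.beta, e.meta.prevalence
                    )
                rows.append(row)
            if run_full:
                bounds = config.prevalence_bounds.get(
                    o.meta.trait_name,
                    (o.meta.prevalence, o.meta.prevalence),
                )
                reports = {}
                for tag, prev in zip(("lower", "upper"), bounds):
                    reports[tag] = sensitivity.build_report(
                        use, e.meta, o.meta, prevalence=prev,
                        presso_n_sim=config.presso_n_sim, seed=pseed + 3,
                    )
                    if o.meta.trait_type != "binary":
                        break  # continuous outcomes have no prevalence bounds
                rep = reports["lower"]
                srow = {
                    "exposure": key[0],
                    "outcome": key[1],
                    "q_stat": rep.q_stat,
                    "q_df": rep.q_df,
                    "q_p": rep.q_p,
                    "egger_intercept": rep.egger_intercept,
                    "egger_intercept_se": rep.egger_intercept_se,
                    "egger_intercept_p": rep.egger_intercept_p,
                    "presso_global_p": rep.presso_global_p,
                    "i2_gx": rep.i2_gx,
                    "n_loo_flagged": sum(1 for _, _, fl in rep.loo_estimates if fl),
                }
                for tag, r in reports.items():
                    if r.steiger is not None:
                        srow[f"steiger_correct_{tag}"] = r.steiger.correct_direction
                        srow[f"steiger_p_{tag}"] = r.steiger.p_direction
                        srow[f"steiger_r2_exp_{tag}"] = r.steiger.r2_exposure
                        srow[f"steiger_r2_out_{tag}"] = r.steiger.r2_outcome
                sens_rows.append(srow)
        except (DataError, ConfigError) as exc:
            log.append(f"{key[0]} -> {key[1]}: sensitivity-suite error: {exc}")

    table = pd.DataFrame(rows)
    sens = pd.DataFrame(sens_rows)
    return GridResult(table=table, sensitivity=sens, harmonized=harmonized, log=log, config=config)


def render_report(result: GridResult, outdir) -> list:
    """Write the results table, sensitivity table, run log, and per-pair
    harmonized sets under ``outdir``; returns the written paths."""
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "harmonized").mkdir(exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create report directory {out}: {exc}")
    paths = []
    results_path = out / "results.tsv"
    result.table.to_csv(results_path, sep="\t", index=False, na_rep="NA")
    paths.append(results_path)
    sens_path = out / "sensitivity.tsv"
    result.sensitivity.to_csv(sens_path, sep="\t", index=False, na_rep="NA")
    paths.append(sens_path)
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(result.log) + "\n")
    paths.append(log_path)
    for (e_name, o_name), h in result.harmonized.items():
        hdf = pd.DataFrame(
            {
                "snp_id": [x.snp_id for x in h],
                "beta_exp": [x.beta_exp for x in h],
                "se_exp": [x.se_exp for x in h],
                "beta_out": [x.beta_out for x in h],
                "se_out": [x.se_out for x in h],
                "eaf_exp": [x.eaf_exp for x in h],
                "eaf_out": [x.eaf_out for x in h],
                "action": [x.action_taken for x in h],
            }
        )
        hpath = out / "harmonized" / f"{e_name}__{o_name}.tsv"
        hdf.to_csv(hpath, sep="\t", index=False, na_rep="NA")
        paths.append(hpath)
    return paths


def load_study(entry: dict) -> Study:
    """Build a Study from one config-file entry."""
    meta = StudyMeta(
        trait_name=entry["trait_name"],
        trait_type=entry.get("trait_type", "continuous"),
        unit=entry.get("unit", ""),
        n=float(entry["n"]),
        n_cases=entry.get("n_cases"),
        prevalence=entry.get("prevalence"),
        ancestry_label=entry.get("ancestry_label", "EUR"),
    )
    res = read_sumstats(entry["path"], column_map=entry.get("column_map"), meta=meta)
    ld = None
    if entry.get("ld_matrix"):
        ld = instruments.read_ld_matrix(entry["ld_matrix"])
    return Study(meta=meta, roles=frozenset(entry["roles"]), records=res.records, path=entry["path"], ld=ld)


def config_from_dict(doc: dict) -> AnalysisConfig:
    studies = [load_study(e) for e in doc.get("studies", [])]
    params = doc.get("params", {})
    prevalence_bounds = {
        k: tuple(v) for k, v in params.get("prevalence_bounds", {}).items()
    }
    return AnalysisConfig(
        studies=studies,
        iv_p_threshold=float(params.get("iv_p_threshold", instruments.GENOME_WIDE_P)),
        clump_r2=float(params.get("clump_r2", instruments.DEFAULT_CLUMP_R2)),
        clump_window_kb=float(params.get("clump_window_kb", instruments.DEFAULT_CLUMP_WINDOW_KB)),
        eaf_ambiguity=float(params.get("eaf_ambiguity", instruments.DEFAULT_EAF_AMBIGUITY)),
        correction=params.get("correction", "bonferroni"),
        alpha=float(params.get("alpha", 0.05)),
        min_ivs=int(params.get("min_ivs", MIN_IVS_DEFAULT)),
        n_boot=int(params.get("n_boot", 1000)),
        presso_n_sim=int(params.get("presso_n_sim", 1000)),
        force_full_suite=bool(params.get("force_full_suite", False)),
        prevalence_bounds=prevalence_bounds,
        seed=int(params.get("seed", 0)),
    )
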