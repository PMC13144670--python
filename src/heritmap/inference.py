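"""Uncertainty quantification and aggregation for heritability estimates.

Pair-resampling bootstrap (stratified by analysis group), two-tailed
z-tests, Benjamini-Hochberg FDR control, inverse-variance-weighted
domain means, and weighted-regression comparisons between estimate sets
(cross-cohort, twin vs sibling, or against external benchmarks).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .liability_model import (
    HeritabilityEstimate,
    estimate_prepared,
    prepare_pairs,
)

__all__ = [
    "BootstrapResult",
    "AggregateSummary",
    "ComparisonFit",
    "bootstrap_estimate",
    "z_test",
    "bh_fdr",
    "ivw_mean",
    "compare_estimate_sets",
    "run_estimation",
]


@dataclass(frozen=True)
class BootstrapResult:
    """Stratified pair-resampling bootstrap summary for one phenotype."""

    point: float
    se: float
    ci95: tuple[float, float]        # percentile interval
    ci95_normal: tuple[float, float]  # normal-approximation interval (audit)
    replicates: np.ndarray
    n_boot: int
    seed: int
    n_failed: int = 0


def bootstrap_estimate(table: pd.DataFrame, p: float, *,
                       n_boot: int = 500, seed: int = 0,
                       stratified: bool = True,
                       variant: str = "reich",
                       max_failure_fraction: float = 0.2) -> BootstrapResult:
    """Bootstrap the full estimation pipeline by resampling pairs.

    Pairs are resampled with replacement, by default stratified by
    analysis group (SS and reference pairs resampled separately,
    preserving the group sizes), and the whole variance-component ->
    liability -> Falconer pipeline is re-run on each replicate, including
    the replicate's own prevalence.  The mixture probability ``p`` is a
    cohort-level constant and is held fixed.

    ``se`` is the standard deviation of the replicate estimates; ``ci95``
    the 2.5/97.5 percentile interval.  Deterministic under a fixed seed
    and invariant to the row order of ``table`` (rows are canonicalised
    by group and pair id before resampling).

    Raises
    ------
    RuntimeError
        If more than ``max_failure_fraction`` of replicates fail (with a
        census of the failure messages).
    """
    if "pair_id" in table.columns:
        table = table.sort_values(["group", "pair_id"], kind="stable",
                                  ignore_index=True)
    prep = prepare_pairs(table)
    point = estimate_prepared(prep, p, variant=variant)
    rng = np.random.default_rng(seed)
    idx_ss = np.flatnonzero(prep.is_ss)
    idx_ref = np.flatnonzero(~prep.is_ss)
    n = prep.n_pairs

    reps = np.full(n_boot, np.nan)
    failures: Counter[str] = Counter()
    for b in range(n_boot):
        if stratified:
            idx = np.concatenate([
                rng.choice(idx_ss, size=idx_ss.size, replace=True),
                rng.choice(idx_ref, size=idx_ref.size, replace=True),
            ])
        else:
            idx = rng.integers(0, n, size=n)
        try:
            reps[b] = estimate_prepared(prep, p, idx, variant=variant,
                                        xatol=1e-4, thorough=False).h2_raw
        except (ValueError, RuntimeError) as exc:
            failures[type(exc).__name__ + ": " + str(exc)[:80]] += 1
    n_failed = int(np.isnan(reps).sum())
    if n_failed > max_failure_fraction * n_boot:
        census = "; ".join(f"{k} x{v}" for k, v in failures.most_common(5))
        raise RuntimeError(
            f"bootstrap failed in {n_failed}/{n_boot} replicates: {census}")
    ok = reps[~np.isnan(reps)]
    se = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    lo, hi = (np.percentile(ok, [2.5, 97.5]) if ok.size else (np.nan, np.nan))
    return BootstrapResult(
        point=point.h2_raw, se=se, ci95=(float(lo), float(hi)),
        ci95_normal=(point.h2_raw - 1.959964 * se, point.h2_raw + 1.959964 * se),
        replicates=reps, n_boot=n_boot, seed=seed, n_failed=n_failed,
    )


def z_test(h2: float, se: float) -> float:
    """Two-tailed z-test p-value for h2 against zero.

    ``se = 0`` leaves the test undefined; NaN is returned as the error
    sentinel.
    """
    if se <= 0 or not math.isfinite(se):
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(h2 / se)))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class AggregateSummary:
    """Inverse-variance-weighted mean over a set of phenotype estimates."""

    key: str
    ivw_mean: float
    se: float
    ci95: tuple[float, float]
    n_phenotypes: int


def ivw_mean(estimates: Sequence[float], ses: Sequence[float],
             key: str = "", labels: Sequence[str] | None = None) -> AggregateSummary:
    """IVW mean with weights 1/se^2 and a normal 95% CI."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates to aggregate")
    bad = ~(se > 0)
    if bad.any():
        which = (labels[int(np.flatnonzero(bad)[0])] if labels is not None
                 else f"index {int(np.flatnonzero(bad)[0])}")
        raise ValueError(f"nonpositive standard error for {which}")
    w = 1.0 / se ** 2
    mean = float((w * est).sum() / w.sum())
    se_mean = float(1.0 / math.sqrt(w.sum()))
    return AggregateSummary(
        key=key, ivw_mean=mean, se=se_mean,
        ci95=(mean - 1.959964 * se_mean, mean + 1.959964 * se_mean),
        n_phenotypes=int(est.size),
    )


@dataclass(frozen=True)
class ComparisonFit:
    """Weighted linear regression of one estimate set on another."""

    x_label: str
    y_label: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_matched: int
    matched: pd.DataFrame
    excluded_sex_ratio: list[str] = field(default_factory=list)


def compare_estimate_sets(set_x: pd.DataFrame, set_y: pd.DataFrame, *,
                          on: str = "phecode",
                          x_label: str = "x", y_label: str = "y",
                          sex_ratio_col: str | None = None,
                          max_sex_ratio_ratio: float = 1.5) -> ComparisonFit:
    """Weighted regression of matched phenotype estimates (y on x).

    Both frames need columns ``[on, "h2", "se"]``.  Weights are
    ``1/(se_x^2 + se_y^2)``.  If ``sex_ratio_col`` is given, phenotypes
    whose case sex ratios differ by more than ``max_sex_ratio_ratio``
    (ratio of ratios) between the two sets are excluded and listed, since
    differential sex imbalance biases the same-sex/opposite-sex contrast.
    """
    cols = [on, "h2", "se"] + ([sex_ratio_col] if sex_ratio_col else [])
    merged = set_x[cols].merge(set_y[cols], on=on, suffixes=("_x", "_y"))
    excluded: list[str] = []
    if sex_ratio_col:
        rx = merged[f"{sex_ratio_col}_x"].to_numpy(dtype=float)
        ry = merged[f"{sex_ratio_col}_y"].to_numpy(dtype=float)
        rr = np.maximum(rx, ry) / np.minimum(rx, ry)
        drop = ~(rr <= max_sex_ratio_ratio)
        excluded = merged.loc[drop, on].astype(str).tolist()
        merged = merged[~drop].reset_index(drop=True)
    if len(merged) < 3:
        raise ValueError(
            f"need at least 3 matched phenotypes, got {len(merged)}")
    w = 1.0 / (merged["se_x"] ** 2 + merged["se_y"] ** 2)
    X = sm.add_constant(merged["h2_x"].to_numpy())
    fit = sm.WLS(merged["h2_y"].to_numpy(), X, weights=w.to_numpy()).fit()
    return ComparisonFit(
        x_label=x_label, y_label=y_label,
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]), intercept_se=float(fit.bse[0]),
        n_matched=len(merged),
        matched=merged.assign(weight=w),
        excluded_sex_ratio=excluded,
    )


def run_estimation(tables: Mapping[str, pd.DataFrame], p: float, *,
                   n_boot: int = 500, seed: int = 0,
                   cohort: str = "", design: str = "twin",
                   variant: str = "reich",
                   fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Estimate every phenotype table and assemble the tidy results frame.

    One row per phecode with the point estimate, all pipeline
    intermediates, bootstrap SE/CI, z-test p-value and BH q-value (the
    FDR family is the full set of phecodes in this run).  Per-phecode
    bootstrap seeds are derived deterministically from ``seed``.
    """
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(tables))
    for (phecode, table), ss in zip(sorted(tables.items()), child_seeds):
        boot_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        try:
            boot = bootstrap_estimate(table, p, n_boot=n_boot, seed=boot_seed,
                                      variant=variant)
            est = estimate_prepared(prepare_pairs(table), p, variant=variant,
                                    phecode=phecode)
        except (ValueError, RuntimeError) as exc:
            rows.append({"phecode": phecode, "cohort": cohort, "design": design,
                         "error": str(exc)})
            continue
        rows.append({
            "phecode": phecode, "cohort": cohort, "design": design,
            "h2_raw": est.h2_raw, "h2_report": est.h2_report,
            "se": boot.se, "ci_lo": boot.ci95[0], "ci_hi": boot.ci95[1],
            "p_mixture": p, "K": est.prevalence,
            "n_pairs_ss": est.n_pairs_ss, "n_pairs_ref": est.n_pairs_ref,
            "n_cases": est.n_cases,
            "v_pair": est.vc.v_pair, "v_only_ss": est.vc.v_only_ss,
            "v_e": est.vc.v_e,
            "r_ss_obs": est.correlations.r_ss_obs,
            "r_os_obs": est.correlations.r_os_obs,
            "r_ss_liab": est.correlations.r_ss_liab,
            "r_os_liab": est.correlations.r_os_liab,
            "p_value": z_test(est.h2_raw, boot.se),
            "error": "",
        })
    out = pd.DataFrame(rows)
    ok = out["error"].eq("") & out.get("p_value", pd.Series(dtype=float)).notna() \
        if "p_value" in out.columns else pd.Series(False, index=out.index)
    if "p_value" in out.columns and ok.any():
        out.loc[ok, "q_value"] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
        out["significant"] = out.get("q_value", np.nan) < fdr_alpha
    return out
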