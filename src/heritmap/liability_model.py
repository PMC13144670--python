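"""Estimation core for zygosity-free heritability mapping.

Implements the four stages that turn a per-phenotype table of paired binary
outcomes into a liability-scale heritability estimate:

1. the Weinberg-rule mixture probability that a same-sex twin pair is
   monozygotic (``mz_probability``),
2. a restricted-maximum-likelihood fit of a linear mixed model with two
   nested pair-level random intercepts (``fit_variance_components``),
3. conversion of observed-scale (0/1) within-pair covariances to
   liability-scale correlations via the classical threshold-model
   transformation (``liability_correlation``),
4. the classical and modified Falconer estimators
   (``falconer_classic`` / ``falconer_modified``).

The mixed model is

    y = X beta + u_pair + u_onlySS + e

with ``y`` the 0/1 disease indicator, fixed effects sex and birth year,
``u_pair`` shared by both members of every pair and ``u_onlySS`` shared
only within same-sex twin pairs.  Because every random-effect group has
exactly two members, the marginal covariance is block diagonal with 2x2
blocks; rotating each pair into within-pair sum and difference
coordinates diagonalises every block, so the REML criterion is evaluated
in O(1) from per-group sufficient statistics after an O(n) pass.  This
is what makes pair-resampling bootstraps affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MixtureProbability",
    "VarianceComponents",
    "CorrelationEstimates",
    "HeritabilityEstimate",
    "FalconerResult",
    "mz_probability",
    "fit_variance_components",
    "observed_correlations",
    "liability_correlation",
    "falconer_classic",
    "falconer_modified",
    "estimate_phenotype",
    "PreparedPairs",
    "prepare_pairs",
    "estimate_prepared",
]

_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Zygosity mixture probability (Weinberg's rule)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureProbability:
    """Probability that a same-sex twin pair is monozygotic.

    Derived purely from pair counts under Weinberg's rule (a dizygotic
    pair is same-sex with probability 1/2, so the monozygotic fraction of
    all pairs is ``1 - 2 N_OS / N_all``).
    """

    p: float          # P(MZ | same-sex)
    p_mz: float       # P(MZ) among all twin pairs
    p_ss: float       # P(same-sex) among all twin pairs
    n_all: int
    n_ss: int
    n_os: int


def mz_probability(n_all: int, n_ss: int, n_os: int) -> MixtureProbability:
    """Weinberg-rule estimate of P(MZ | same-sex) from twin-pair counts.

    Parameters
    ----------
    n_all, n_ss, n_os
        Total, same-sex, and opposite-sex twin-pair counts.  Must satisfy
        ``n_ss + n_os == n_all`` and ``n_all > 0``.

    Raises
    ------
    ValueError
        If the counts are inconsistent, or if ``n_os > n_all / 2`` so the
        implied monozygotic fraction is negative (a Weinberg violation).
    """
    if n_all <= 0:
        raise ValueError("n_all must be positive")
    if n_ss + n_os != n_all:
        raise ValueError(
            f"inconsistent counts: n_ss + n_os = {n_ss + n_os} != n_all = {n_all}"
        )
    if n_ss <= 0:
        raise ValueError("no same-sex pairs: mixture probability undefined")
    p_mz = 1.0 - 2.0 * n_os / n_all
    if p_mz < 0.0:
        raise ValueError(
            "Weinberg violation: negative MZ fraction "
            f"(n_os = {n_os} > n_all/2 = {n_all / 2:g})"
        )
    p_ss = n_ss / n_all
    return MixtureProbability(p=p_mz / p_ss, p_mz=p_mz, p_ss=p_ss,
                              n_all=n_all, n_ss=n_ss, n_os=n_os)


# ---------------------------------------------------------------------------
# Variance-component mixed model (REML)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """Observed-scale variance components from the paired mixed model.

    ``v_pair`` is the covariance shared by any pair (the opposite-sex /
    reference-group within-pair covariance), ``v_only_ss`` the extra
    covariance specific to same-sex twin pairs, ``v_e`` the residual.
    Components constrained to be nonnegative; a component estimated at
    the boundary is reported as exactly 0.
    """

    v_pair: float
    v_only_ss: float
    v_e: float
    reml_criterion: float = float("nan")
    converged: bool = True

    @property
    def v_ss(self) -> float:
        return self.v_pair + self.v_only_ss

    @property
    def v_os(self) -> float:
        return self.v_pair

    @property
    def v_total(self) -> float:
        return self.v_pair + self.v_only_ss + self.v_e


class PreparedPairs(NamedTuple):
    """Pair table rotated into within-pair sum/difference coordinates.

    Cached arrays from which REML sufficient statistics for any subset of
    pairs (e.g. a bootstrap resample) are recomputed in one vectorised
    pass.  Sum coordinates have variance ``v_e + 2*(v_pair [+ v_only_ss])``
    and difference coordinates variance ``v_e``.
    """

    ys: np.ndarray      # (n,) pair sums / sqrt(2)
    yd: np.ndarray      # (n,) pair differences / sqrt(2)
    xs: np.ndarray      # (n, p) rotated design, sum coordinate
    xd: np.ndarray      # (n, p) rotated design, difference coordinate
    is_ss: np.ndarray   # (n,) bool, True for the same-sex twin group
    y_sum: np.ndarray   # (n,) y1 + y2 (unrotated), for prevalence/case counts

    @property
    def n_pairs(self) -> int:
        return self.ys.shape[0]


_GROUP_SS = "SS"
_GROUP_REF = "REF"


def prepare_pairs(table: pd.DataFrame) -> PreparedPairs:
    """Rotate a per-phenotype pair table into sum/difference coordinates.

    Expects columns ``y1, y2, group, sex1, sex2, birth_year1, birth_year2``
    with ``group`` in {"SS", "REF"}.  Fixed effects are an intercept, a
    male indicator and the birth year (centred and scaled for
    conditioning; the fit is invariant to this affine change).
    """
    required = {"y1", "y2", "group", "sex1", "sex2", "birth_year1", "birth_year2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    groups = set(table["group"].unique())
    bad = groups - {_GROUP_SS, _GROUP_REF}
    if bad:
        raise ValueError(f"unknown analysis groups: {sorted(bad)}")

    y1 = table["y1"].to_numpy(dtype=float)
    y2 = table["y2"].to_numpy(dtype=float)
    male1 = (table["sex1"].to_numpy() == "M").astype(float)
    male2 = (table["sex2"].to_numpy() == "M").astype(float)
    by1 = table["birth_year1"].to_numpy(dtype=float)
    by2 = table["birth_year2"].to_numpy(dtype=float)
    centre = 0.5 * (by1.mean() + by2.mean())
    by1 = (by1 - centre) / 10.0
    by2 = (by2 - centre) / 10.0

    ones = np.ones_like(y1)
    x1 = np.column_stack([ones, male1, by1])
    x2 = np.column_stack([ones, male2, by2])
    return PreparedPairs(
        ys=(y1 + y2) / _SQRT2,
        yd=(y1 - y2) / _SQRT2,
        xs=(x1 + x2) / _SQRT2,
        xd=(x1 - x2) / _SQRT2,
        is_ss=(table["group"].to_numpy() == _GROUP_SS),
        y_sum=y1 + y2,
    )


class _SuffStats(NamedTuple):
    # cross products per weight class (group x sum/diff coordinate); in
    # units of v_e with a = v_pair/v_e, b = v_only_ss/v_e the variances are
    #   SS diff: 1        SS sum: 1 + 2a + 2b
    #   REF diff: 1 + b   REF sum: 1 + b + 2a
    # (u_onlySS adds variance to every individual but covariance only
    # within same-sex twin pairs, so it cancels in SS differences and
    # stays in REF coordinates)
    a_ds: np.ndarray
    b_ds: np.ndarray
    c_ds: float
    a_dr: np.ndarray
    b_dr: np.ndarray
    c_dr: float
    a_sr: np.ndarray
    b_sr: np.ndarray
    c_sr: float
    a_ss: np.ndarray
    b_ss: np.ndarray
    c_ss: float
    n_ss: int
    n_ref: int
    n_obs: int
    rank: int


def _suffstats(prep: PreparedPairs, idx: np.ndarray | None = None) -> _SuffStats:
    if idx is None:
        ys, yd, xs, xd, is_ss = prep.ys, prep.yd, prep.xs, prep.xd, prep.is_ss
    else:
        ys, yd, xs, xd, is_ss = (prep.ys[idx], prep.yd[idx], prep.xs[idx],
                                 prep.xd[idx], prep.is_ss[idx])
    ss = is_ss
    ref = ~is_ss
    xd_ss, xd_ref = xd[ss], xd[ref]
    yd_ss, yd_ref = yd[ss], yd[ref]
    xs_ss, xs_ref = xs[ss], xs[ref]
    ys_ss, ys_ref = ys[ss], ys[ref]
    return _SuffStats(
        a_ds=xd_ss.T @ xd_ss, b_ds=xd_ss.T @ yd_ss, c_ds=float(yd_ss @ yd_ss),
        a_dr=xd_ref.T @ xd_ref, b_dr=xd_ref.T @ yd_ref, c_dr=float(yd_ref @ yd_ref),
        a_sr=xs_ref.T @ xs_ref, b_sr=xs_ref.T @ ys_ref, c_sr=float(ys_ref @ ys_ref),
        a_ss=xs_ss.T @ xs_ss, b_ss=xs_ss.T @ ys_ss, c_ss=float(ys_ss @ ys_ss),
        n_ss=int(ss.sum()), n_ref=int(ref.sum()),
        n_obs=2 * ys.shape[0], rank=xs.shape[1],
    )


def _quad_form_inv(m: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """(log det M, v' M^-1 v) for a symmetric PD matrix, or (nan, nan).

    The 3x3 case (intercept + sex + birth year) is unrolled in scalar
    arithmetic: this sits in the innermost loop of every bootstrap
    replicate and the numpy dispatch overhead dominates at this size.
    """
    if m.shape[0] == 3:
        a = m[0, 0]; b = m[0, 1]; c = m[0, 2]
        d = m[1, 1]; e = m[1, 2]; f = m[2, 2]
        a11 = d * f - e * e
        a12 = c * e - b * f
        a13 = b * e - c * d
        det = a * a11 + b * a12 + c * a13
        if det <= 0.0 or a <= 0.0 or a * d - b * b <= 0.0:
            return float("nan"), float("nan")
        a22 = a * f - c * c
        a23 = b * c - a * e
        a33 = a * d - b * b
        v1 = v[0]; v2 = v[1]; v3 = v[2]
        quad = (v1 * v1 * a11 + v2 * v2 * a22 + v3 * v3 * a33
                + 2.0 * (v1 * v2 * a12 + v1 * v3 * a13 + v2 * v3 * a23)) / det
        return math.log(det), quad
    sign, logdet = np.linalg.slogdet(m)
    if sign <= 0:
        return float("nan"), float("nan")
    return logdet, float(v @ np.linalg.solve(m, v))


def _profiled_criterion(a: float, b: float, s: _SuffStats) -> tuple[float, float, float]:
    """-2 restricted log-likelihood with v_e profiled out.

    ``a = v_pair / v_e`` and ``b = v_only_ss / v_e``.  Returns
    ``(criterion, v_e_hat, rss)`` (additive constants dropped).
    """
    w_ss = 1.0 + 2.0 * a + 2.0 * b
    w_dr = 1.0 + b
    w_sr = 1.0 + b + 2.0 * a
    m = s.a_ds + s.a_dr / w_dr + s.a_sr / w_sr + s.a_ss / w_ss
    v = s.b_ds + s.b_dr / w_dr + s.b_sr / w_sr + s.b_ss / w_ss
    c = s.c_ds + s.c_dr / w_dr + s.c_sr / w_sr + s.c_ss / w_ss
    logdet_m, quad = _quad_form_inv(m, v)
    if not math.isfinite(logdet_m):
        return float("inf"), float("nan"), float("nan")
    rss = c - quad
    dof = s.n_obs - s.rank
    if rss <= 0.0:
        return float("inf"), float("nan"), float("nan")
    ve = rss / dof
    crit = (dof * math.log(ve) + s.n_ss * math.log(w_ss)
            + s.n_ref * (math.log(w_dr) + math.log(w_sr)) + logdet_m)
    return crit, ve, rss


def _moment_start(prep: PreparedPairs, s: _SuffStats) -> tuple[float, float]:
    """Method-of-moments starting ratios from the class second moments."""
    ve = max(s.c_ds / max(s.n_ss, 1), 1e-8)
    b0 = max(s.c_dr / max(s.n_ref, 1) / ve - 1.0, 0.0)
    # SS sums: ve (1 + 2a + 2b); raw moments (mean not removed) keep this crude
    a0 = max((s.c_ss / max(s.n_ss, 1) / ve - 1.0 - 2.0 * b0) / 2.0, 0.0)
    return min(a0, 20.0), min(b0, 20.0)


_RATIO_BOUND = 200.0


def _fit_from_suffstats(prep: PreparedPairs, s: _SuffStats,
                        xatol: float = 1e-10,
                        thorough: bool = True) -> VarianceComponents:
    if s.n_ss == 0 or s.n_ref == 0:
        empty = _GROUP_SS if s.n_ss == 0 else _GROUP_REF
        raise ValueError(f"analysis group {empty!r} has no pairs: design is singular")

    def nll(theta: np.ndarray) -> float:
        return _profiled_criterion(theta[0], theta[1], s)[0]

    starts = [np.asarray(_moment_start(prep, s))]
    fatol = 1e-9 if thorough else 1e-5
    if thorough:
        starts.append(np.array([0.02, 0.02]))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            bounds=[(0.0, _RATIO_BOUND), (0.0, _RATIO_BOUND)],
            options={"xatol": xatol, "fatol": fatol, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = best.x
    # snap to the boundary: a profiled ratio below optimizer resolution is 0
    if a < 10.0 * xatol:
        a = 0.0
    if b < 10.0 * xatol:
        b = 0.0
    crit, ve, _ = _profiled_criterion(a, b, s)
    if not math.isfinite(crit):
        raise RuntimeError("REML fit failed: criterion not finite at optimum")
    return VarianceComponents(
        v_pair=a * ve, v_only_ss=b * ve, v_e=ve,
        reml_criterion=crit, converged=bool(best.success),
    )


def fit_variance_components(table: pd.DataFrame, *,
                            xatol: float = 1e-10) -> VarianceComponents:
    """REML fit of the two nested pair-level variance components.

    Fits ``y = X beta + u_pair + u_onlySS + e`` (fixed effects: intercept,
    sex, birth year) by restricted maximum likelihood with the residual
    variance profiled out and the two variance ratios constrained to be
    nonnegative.  See the module docstring for the O(n) block rotation.

    Parameters
    ----------
    table
        Per-phenotype pair table (``y1, y2, group, sex1, sex2,
        birth_year1, birth_year2``); ``group`` must contain both "SS"
        and "REF" pairs.
    xatol
        Simplex tolerance on the variance ratios; the default resolves
        the optimum well beyond bootstrap noise.

    Raises
    ------
    ValueError
        If a group is empty (singular design) or the outcome is constant.
    """
    prep = prepare_pairs(table)
    y_all = np.concatenate([prep.ys + prep.yd, prep.ys - prep.yd])  # y1, y2 * sqrt2
    if np.ptp(y_all) == 0.0:
        raise ValueError("outcome is constant: variance components undefined")
    return _fit_from_suffstats(prep, _suffstats(prep), xatol=xatol)


# ---------------------------------------------------------------------------
# Observed-scale correlations and liability conversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationEstimates:
    """Observed- and liability-scale within-pair correlations."""

    r_ss_obs: float
    r_os_obs: float
    r_ss_liab: float
    r_os_liab: float
    prevalence: float
    threshold: float           # T = Phi^-1(1 - K)
    mean_liability_cases: float  # i = phi(T) / K


def observed_correlations(vc: VarianceComponents) -> tuple[float, float]:
    """Observed-scale correlations r_SS = V_SS/V_total, r_OS = V_OS/V_total."""
    if vc.v_total <= 0.0:
        raise ValueError("total variance is zero: correlations undefined")
    return vc.v_ss / vc.v_total, vc.v_os / vc.v_total


def liability_correlation(cov_obs: float, prevalence: float, *,
                          variant: str = "reich") -> float:
    """Convert an observed-scale within-pair covariance to a liability correlation.

    Under the liability-threshold model a binary trait with prevalence K
    arises when a standard-normal liability exceeds ``T = Phi^-1(1-K)``.
    The within-pair covariance of the 0/1 indicators determines the
    recurrence risk in co-members of affected individuals,
    ``q = K + cov/K``, whose threshold ``T_g = Phi^-1(1-q)`` enters the
    classical (Reich-type) conversion

        r = (T - T_g * sqrt(1 - (T^2 - T_g^2)(1 - T/i))) / (i + T_g^2 (i - T))

    with ``i = phi(T)/K`` the mean liability of affected individuals.

    Parameters
    ----------
    cov_obs
        Observed-scale within-pair covariance (e.g. V_SS or V_OS from the
        mixed model).
    prevalence
        Trait prevalence K in (0, 1).
    variant
        ``"reich"`` (default) uses the construction above, which is
        strictly increasing in ``cov_obs`` and maps 0 to 0.
        ``"printed"`` is retained for audit only: it flips the sign of
        the covariance term inside the recurrence-risk argument and
        applies the square root to the whole threshold difference; it is
        not monotone in the required direction.
    """
    k = prevalence
    if not 0.0 < k < 1.0:
        raise ValueError(f"prevalence must be in (0,1), got {k}")
    if variant not in ("reich", "printed"):
        raise ValueError(f"unknown variant {variant!r}")
    t = stats.norm.isf(k)
    i = stats.norm.pdf(t) / k
    if variant == "reich":
        q = k + cov_obs / k
    else:
        q = k - cov_obs / k
    if not 0.0 < q < 1.0:
        raise ValueError(
            f"covariance incompatible with prevalence: recurrence argument {q:g} "
            "outside (0,1)"
        )
    tg = stats.norm.isf(q)
    disc = 1.0 - (t * t - tg * tg) * (1.0 - t / i)
    if disc < 0.0:
        raise ValueError("liability conversion undefined: negative discriminant")
    root = math.sqrt(disc)
    denom = i + tg * tg * (i - t)
    if variant == "reich":
        return (t - tg * root) / denom
    return (t - tg) * root / denom


# ---------------------------------------------------------------------------
# Falconer estimators
# ---------------------------------------------------------------------------

class FalconerResult(NamedTuple):
    raw: float      # unclamped estimate
    report: float   # truncated to [0, 1]


def _truncate(x: float) -> float:
    return min(max(x, 0.0), 1.0)


def falconer_classic(r_mz: float, r_dz: float) -> FalconerResult:
    """Classical Falconer estimator ``h2 = 2 (r_MZ - r_DZ)``."""
    raw = 2.0 * (r_mz - r_dz)
    return FalconerResult(raw=raw, report=_truncate(raw))


def falconer_modified(r_ss: float, r_os: float, p: float) -> FalconerResult:
    """Zygosity-free Falconer estimator ``h2 = (2/p) (r_SS - r_OS)``.

    ``p`` is the probability that a same-sex twin pair is monozygotic
    (see :func:`mz_probability`); with ``p = 1`` this reduces exactly to
    :func:`falconer_classic`.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("no monozygotic information: p must be in (0, 1]")
    raw = (2.0 / p) * (r_ss - r_os)
    return FalconerResult(raw=raw, report=_truncate(raw))


# ---------------------------------------------------------------------------
# Per-phenotype pipeline
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    """Full per-phenotype estimate with all pipeline intermediates.

    Uncertainty fields (``se_boot``, ``ci95``, ``p_value``, ``q_value``)
    are filled in by the inference layer; the estimation pipeline itself
    produces the point estimate and diagnostics.
    """

    phecode: str
    h2_raw: float
    h2_report: float
    p_mixture: float
    prevalence: float
    n_pairs_ss: int
    n_pairs_ref: int
    n_cases: int
    vc: VarianceComponents
    correlations: CorrelationEstimates
    cohort: str = ""
    design: str = "twin"
    domain: str = ""
    se_boot: float | None = None
    ci95: tuple[float, float] | None = None
    p_value: float | None = None
    q_value: float | None = None


def estimate_prepared(prep: PreparedPairs, p: float,
                      idx: np.ndarray | None = None, *,
                      variant: str = "reich",
                      xatol: float = 1e-9,
                      thorough: bool = True,
                      phecode: str = "") -> HeritabilityEstimate:
    """Run the estimation pipeline on (a subset of) a prepared pair table.

    This is the resampling-friendly core behind :func:`estimate_phenotype`:
    REML variance components -> observed within-pair covariances ->
    liability-scale correlations at the subset's prevalence -> modified
    Falconer.  ``idx`` selects pairs (with repetition allowed), enabling
    bootstrap replicates without re-rotating the table.
    """
    ys = prep.ys if idx is None else prep.ys[idx]
    yd = prep.yd if idx is None else prep.yd[idx]
    if np.ptp(ys) == 0.0 and np.ptp(yd) == 0.0:
        raise ValueError("outcome is constant: variance components undefined")
    s = _suffstats(prep, idx)
    vc = _fit_from_suffstats(prep, s, xatol=xatol, thorough=thorough)
    r_ss_obs, r_os_obs = observed_correlations(vc)
    y_sum = prep.y_sum if idx is None else prep.y_sum[idx]
    n = y_sum.shape[0]
    n_cases = int(y_sum.sum())
    k = n_cases / (2.0 * n)
    if not 0.0 < k < 1.0:
        raise ValueError("prevalence is 0 or 1 in this sample")
    r_ss_liab = liability_correlation(vc.v_ss, k, variant=variant)
    r_os_liab = liability_correlation(vc.v_os, k, variant=variant)
    fal = falconer_modified(r_ss_liab, r_os_liab, p)
    t = stats.norm.isf(k)
    corr = CorrelationEstimates(
        r_ss_obs=r_ss_obs, r_os_obs=r_os_obs,
        r_ss_liab=r_ss_liab, r_os_liab=r_os_liab,
        prevalence=k, threshold=t,
        mean_liability_cases=stats.norm.pdf(t) / k,
    )
    is_ss = prep.is_ss if idx is None else prep.is_ss[idx]
    return HeritabilityEstimate(
        phecode=phecode, h2_raw=fal.raw, h2_report=fal.report,
        p_mixture=p, prevalence=k,
        n_pairs_ss=int(is_ss.sum()), n_pairs_ref=int((~is_ss).sum()),
        n_cases=n_cases, vc=vc, correlations=corr,
    )


def estimate_phenotype(table: pd.DataFrame, p: float, *,
                       variant: str = "reich",
                       phecode: str = "") -> HeritabilityEstimate:
    """Point heritability estimate for one phenotype pair table.

    Composition of the full pipeline: mixed-model variance components,
    observed-scale covariances, liability conversion at the table's
    prevalence, and the modified Falconer estimator with mixture
    probability ``p``.  All intermediates are retained on the returned
    :class:`HeritabilityEstimate` for diagnostics.
    """
    phecode = phecode or str(table.attrs.get("phecode", ""))
    try:
        return estimate_prepared(prepare_pairs(table), p, variant=variant,
                                 xatol=1e-10, phecode=phecode)
    except (ValueError, RuntimeError) as exc:
        raise type(exc)(f"phecode {phecode or '?'}: {exc}") from exc
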