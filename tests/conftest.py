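"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import multivariate_normal

from heritmap.cohort_builder import (
    build_phenotype_tables,
    identify_twin_pairs,
    map_codes,
)
from heritmap.liability_model import mz_probability
from heritmap.synthetic_registry import (
    PhenotypeSpec,
    SimulationParams,
    simulate_registry,
)

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def exact_indicator_cov(rho: float, k: float) -> float:
    """Exact within-pair covariance of threshold indicators.

    For bivariate standard-normal liabilities with correlation ``rho``
    thresholded at ``T = Phi^-1(1-k)``: P(both affected) - k^2, via the
    bivariate normal CDF.  Independent of the package's conversion code.
    """
    t = stats.norm.isf(k)
    p11 = float(multivariate_normal(mean=[0.0, 0.0],
                                    cov=[[1.0, rho], [rho, 1.0]]).cdf([-t, -t]))
    return p11 - k * k


def dense_reml_criterion(table: pd.DataFrame, a: float, b: float) -> float:
    """Brute-force -2 restricted log-likelihood with v_e profiled out.

    Builds the explicit 2x2-block marginal covariance (in units of v_e:
    SS pair block [[1+a+b, a+b], [a+b, 1+a+b]], reference block
    [[1+a+b, a], [a, 1+a+b]]) as a dense matrix and evaluates the REML
    criterion with dense linear algebra only — an independent route from
    the package's rotated sufficient-statistics evaluation.
    """
    y1 = table["y1"].to_numpy(dtype=float)
    y2 = table["y2"].to_numpy(dtype=float)
    male1 = (table["sex1"].to_numpy() == "M").astype(float)
    male2 = (table["sex2"].to_numpy() == "M").astype(float)
    by1 = table["birth_year1"].to_numpy(dtype=float)
    by2 = table["birth_year2"].to_numpy(dtype=float)
    centre = 0.5 * (by1.mean() + by2.mean())
    n = len(table)
    y = np.empty(2 * n)
    y[0::2], y[1::2] = y1, y2
    x = np.ones((2 * n, 3))
    x[0::2, 1], x[1::2, 1] = male1, male2
    x[0::2, 2], x[1::2, 2] = (by1 - centre) / 10.0, (by2 - centre) / 10.0

    w = np.zeros((2 * n, 2 * n))
    is_ss = table["group"].to_numpy() == "SS"
    for i in range(n):
        d = 1.0 + a + b
        off = a + b if is_ss[i] else a
        w[2 * i, 2 * i] = w[2 * i + 1, 2 * i + 1] = d
        w[2 * i, 2 * i + 1] = w[2 * i + 1, 2 * i] = off
    sign, logdet_w = np.linalg.slogdet(w)
    if sign <= 0:
        return np.inf
    wi = np.linalg.inv(w)
    m = x.T @ wi @ x
    sign_m, logdet_m = np.linalg.slogdet(m)
    if sign_m <= 0:
        return np.inf
    beta = np.linalg.solve(m, x.T @ wi @ y)
    r = y - x @ beta
    rss = float(r @ wi @ r)
    dof = 2 * n - 3
    if rss <= 0:
        return np.inf
    return dof * np.log(rss / dof) + logdet_w + logdet_m


def bruteforce_reml_fit(table: pd.DataFrame) -> "np.ndarray":
    """Grid search plus simplex refinement of the dense REML criterion.

    Returns the optimal variance ratios ``(a, b) = (v_pair/v_e,
    v_only_ss/v_e)``.  The coarse grid guards against the simplex
    stalling on a nonnegativity boundary.
    """
    from scipy import optimize

    grid = np.linspace(0.0, 1.0, 11)
    best, best_val = None, np.inf
    for a in grid:
        for b in grid:
            val = dense_reml_criterion(table, a, b)
            if val < best_val:
                best, best_val = (a, b), val
    res = optimize.minimize(
        lambda t: dense_reml_criterion(table, t[0], t[1]),
        np.asarray(best), method="Nelder-Mead",
        bounds=[(0.0, 50.0), (0.0, 50.0)],
        options={"xatol": 1e-10, "fatol": 1e-9, "maxiter": 4000})
    return res.x


def bh_qvalues_bruteforce(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values from the raw step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Simulation helpers / fixtures
# ---------------------------------------------------------------------------

def twin_params(n_families: int, seed: int, *, h2: float = 0.5,
                c2: float = 0.2, k: float = 0.1,
                p_mz: float = 0.28) -> SimulationParams:
    """Twin-only registry with censoring effectively disabled.

    Onset ages are short relative to follow-up and hazards are zero, so
    every affected individual's diagnosis is observed; parameter-recovery
    checks then probe the estimator rather than the censoring process.
    """
    spec = PhenotypeSpec(phecode="008", h2_true=h2, c2_twin=c2,
                         prevalence_K=k, onset_mean=5.0, onset_sd=2.0)
    return SimulationParams(
        n_families=n_families, phenotypes=[spec], twin_fraction=1.0,
        p_mz=p_mz, seed=seed, mortality_rate=0.0, emigration_rate=0.0,
        registry_start_year=1955, birth_year_range=(1955, 1995),
    )


def twin_pipeline_table(params: SimulationParams) -> tuple[pd.DataFrame, float]:
    """simulate -> pair up -> map -> phenotype table; returns (table, p-hat)."""
    sim = simulate_registry(params)
    twins = identify_twin_pairs(sim.persons)
    events = map_codes(sim.diagnoses).events
    tables = build_phenotype_tables(twins, events, "1955-01-01")
    code = params.phenotypes[0].phecode
    n_ss = int((twins["analysis_group"] == "SS").sum())
    mix = mz_probability(len(twins), n_ss, len(twins) - n_ss)
    return tables[code], mix.p


@pytest.fixture(scope="session")
def small_twin_table() -> tuple[pd.DataFrame, float]:
    """5000-pair twin phenotype table with h2=0.5, c2=0.2, K=0.2."""
    return twin_pipeline_table(twin_params(5000, seed=42, k=0.2))


def make_persons(rows: list[dict]) -> pd.DataFrame:
    """Hand-built person table with schema defaults filled in."""
    defaults = {"sex": "F", "birthplace": "BP1", "death_date": None,
                "emigration_date": None}
    frame = pd.DataFrame([{**defaults, **r} for r in rows])
    for col in ("birth_date", "death_date", "emigration_date"):
        frame[col] = pd.to_datetime(frame[col])
    return frame
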