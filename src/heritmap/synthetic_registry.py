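"""Synthetic population-registry generator with a known ACE liability structure.

Emulates the family data a national civil-registration/patient-register
linkage provides: families contributing either a twin pair or a non-twin
sibling pair, binary phenotypes arising from thresholded Gaussian
liabilities with additive-genetic (A), pair-shared environment (C) and
unique environment (E) components, sex-dependent liability shifts,
log-normal ages at onset, and death/emigration censoring with a
configurable registry start year (left truncation).

Ground truth (zygosity per pair, variance fractions per phenotype) is
returned alongside the person/diagnosis tables so that every stage of the
estimation pipeline can be tested for parameter recovery without any real
registry data.

Generative model per family f and phenotype:

    l_i = g_i + c + e_i,   i = 1, 2
    Var(g) = h2,  corr(g1, g2) = 1 (MZ) or 0.5 (DZ twins and siblings)
    Var(c) = c2_twin (twin pairs) or c2_sib (sibling pairs), shared
    Var(e) = 1 - h2 - c2,  independent
    affected  iff  l_i + sex_effect * 1[male_i] > T,  T = Phi^-1(1 - K)

Zygosity and sexes follow Weinberg's rule: a twin pair is MZ with
probability ``p_mz``; MZ pairs share one Bernoulli(1/2) sex draw while DZ
twins and siblings draw sexes i.i.d. Bernoulli(1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeSpec",
    "SimulationParams",
    "SimulatedRegistry",
    "simulate_registry",
    "expected_group_correlations",
    "write_registry",
]

_DAYS_PER_YEAR = 365.25
# calendar windows for a non-twin sibling pair, matching the pairing rule
_SIB_GAP_MIN_DAYS = 334     # 11 months
_SIB_GAP_MAX_DAYS = 1461    # 4 years


@dataclass(frozen=True)
class PhenotypeSpec:
    """True generative parameters of one binary phenotype.

    ``h2_true``, ``c2_twin`` and ``c2_sib`` are variance fractions of the
    unit-variance liability; ``prevalence_K`` fixes the threshold
    ``T = Phi^-1(1-K)``; ``sex_effect`` shifts male liability (0 keeps the
    sexes balanced); onset ages are log-normal with arithmetic mean
    ``onset_mean`` and SD ``onset_sd`` in years.
    """

    phecode: str
    h2_true: float
    c2_twin: float = 0.0
    c2_sib: float = 0.0
    prevalence_K: float = 0.1
    sex_effect: float = 0.0
    onset_mean: float = 30.0
    onset_sd: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"{self.phecode}: h2_true must be in [0,1]")
        if self.c2_twin < 0.0 or self.c2_sib < 0.0:
            raise ValueError(f"{self.phecode}: shared-environment fractions must be >= 0")
        if self.c2_sib > self.c2_twin:
            raise ValueError(f"{self.phecode}: c2_sib must not exceed c2_twin")
        if self.h2_true + self.c2_twin > 1.0 or self.h2_true + self.c2_sib > 1.0:
            raise ValueError(f"{self.phecode}: h2 + c2 exceeds 1")
        if not 0.0 < self.prevalence_K < 1.0:
            raise ValueError(f"{self.phecode}: prevalence_K must be in (0,1)")
        if self.onset_mean <= 0 or self.onset_sd <= 0:
            raise ValueError(f"{self.phecode}: onset parameters must be positive")

    @property
    def threshold(self) -> float:
        """Liability threshold T = Phi^-1(1 - K)."""
        return float(stats.norm.isf(self.prevalence_K))


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated registry.

    Defaults mirror a Nordic national-register setting: births 1955-2021,
    hospital diagnoses observable from 1977, follow-up to end of 2021, a
    monozygotic fraction of 0.28 among twin pairs and twins making up 6%
    of all analyzable pairs.
    """

    n_families: int
    phenotypes: Sequence[PhenotypeSpec]
    twin_fraction: float = 0.06
    p_mz: float = 0.28
    registry_start_year: int = 1977
    study_end_year: int = 2021
    birth_year_range: tuple[int, int] = (1955, 2021)
    mortality_rate: float = 0.002
    emigration_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 <= self.twin_fraction <= 1.0:
            raise ValueError("twin_fraction must be in [0,1]")
        if not 0.0 <= self.p_mz <= 1.0:
            raise ValueError("p_mz must be in [0,1]")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be ordered")
        if self.mortality_rate < 0 or self.emigration_rate < 0:
            raise ValueError("hazards must be >= 0")
        if not self.phenotypes:
            raise ValueError("at least one phenotype is required")


class SimulatedRegistry(NamedTuple):
    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    pair_truth: pd.DataFrame
    phenotype_truth: pd.DataFrame


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with given arithmetic mean and SD."""
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _censor_dates(birth: np.ndarray, rate: float, study_end: np.datetime64,
                  rng: np.random.Generator) -> np.ndarray:
    """Event dates from a constant annual hazard; NaT beyond study end."""
    n = birth.shape[0]
    out = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    if rate <= 0.0:
        return out
    t_years = rng.exponential(1.0 / rate, size=n)
    dates = birth + np.round(t_years * _DAYS_PER_YEAR).astype("timedelta64[D]")
    keep = dates <= study_end
    out[keep] = dates[keep]
    return out


def simulate_registry(params: SimulationParams) -> SimulatedRegistry:
    """Generate person, diagnosis and ground-truth tables.

    Returns a :class:`SimulatedRegistry` whose ``persons`` and
    ``diagnoses`` frames use the same schemas the cohort builder consumes
    (diagnosis codes are emitted directly in the ``phecode`` code system).
    Output is deterministic for identical parameters and seed.

    Notes
    -----
    * Twin pairs share birth date and birthplace; sibling pairs draw a
      birth-date gap uniform on [334, 1461] days, and the first-born's
      date is drawn so the pair fits inside ``birth_year_range``.
    * A diagnosis event is emitted only if the onset date falls on or
      after 1 January ``registry_start_year`` and on or before the
      individual's censoring date (death, emigration, or study end).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_families
    y0, y1 = params.birth_year_range
    base = np.datetime64(f"{y0}-01-01", "D")
    horizon = np.datetime64(f"{y1}-12-31", "D")
    study_end = np.datetime64(f"{params.study_end_year}-12-31", "D")
    registry_start = np.datetime64(f"{params.registry_start_year}-01-01", "D")
    span = int((horizon - base).astype(int)) + 1

    is_twin = rng.random(n) < params.twin_fraction
    is_mz = is_twin & (rng.random(n) < params.p_mz)

    # sexes: MZ share one draw; DZ twins and siblings draw independently
    sex_draw1 = rng.random(n) < 0.5
    sex_draw2 = rng.random(n) < 0.5
    male1 = sex_draw1
    male2 = np.where(is_mz, sex_draw1, sex_draw2)

    # birth dates
    gap_days = np.zeros(n, dtype=int)
    sib = ~is_twin
    gap_days[sib] = rng.integers(_SIB_GAP_MIN_DAYS, _SIB_GAP_MAX_DAYS + 1,
                                 size=int(sib.sum()))
    max_offset = np.maximum(span - gap_days, 1)
    offset1 = (rng.random(n) * max_offset).astype(int)
    birth1 = base + offset1.astype("timedelta64[D]")
    birth2 = birth1 + gap_days.astype("timedelta64[D]")

    birthplace = np.array([f"BP{b:03d}" for b in rng.integers(0, 500, size=n)])

    birth_all = np.empty(2 * n, dtype="datetime64[D]")
    birth_all[0::2] = birth1
    birth_all[1::2] = birth2
    death = _censor_dates(birth_all, params.mortality_rate, study_end, rng)
    emig = _censor_dates(birth_all, params.emigration_rate, study_end, rng)
    followup_end = np.minimum(
        np.where(np.isnat(death), study_end, death),
        np.where(np.isnat(emig), study_end, emig),
    )

    person_id = np.array([f"P{i:08d}" for i in range(2 * n)])
    fam = np.repeat(np.arange(n), 2)
    male_all = np.empty(2 * n, dtype=bool)
    male_all[0::2] = male1
    male_all[1::2] = male2

    persons = pd.DataFrame({
        "person_id": person_id,
        "sex": np.where(male_all, "M", "F"),
        "birth_date": birth_all,
        "birthplace": birthplace[fam],
        "mother_id": np.array([f"M{i:08d}" for i in fam]),
        "father_id": np.array([f"F{i:08d}" for i in fam]),
        "death_date": death,
        "emigration_date": emig,
    })

    # liability-threshold phenotypes
    rho_g = np.where(is_mz, 1.0, 0.5)
    diag_frames: list[pd.DataFrame] = []
    for spec in params.phenotypes:
        c2 = np.where(is_twin, spec.c2_twin, spec.c2_sib)
        e2 = 1.0 - spec.h2_true - c2
        z1, z2, zc, ze1, ze2 = rng.standard_normal((5, n))
        g1 = z1
        g2 = rho_g * z1 + np.sqrt(1.0 - rho_g ** 2) * z2
        sg = math.sqrt(spec.h2_true)
        l1 = sg * g1 + np.sqrt(c2) * zc + np.sqrt(e2) * ze1
        l2 = sg * g2 + np.sqrt(c2) * zc + np.sqrt(e2) * ze2
        t = spec.threshold
        aff1 = l1 + spec.sex_effect * male1 > t
        aff2 = l2 + spec.sex_effect * male2 > t
        affected = np.empty(2 * n, dtype=bool)
        affected[0::2] = aff1
        affected[1::2] = aff2

        mu, sigma = _lognormal_params(spec.onset_mean, spec.onset_sd)
        onset_years = rng.lognormal(mu, sigma, size=2 * n)
        onset_date = birth_all + np.round(
            onset_years * _DAYS_PER_YEAR).astype("timedelta64[D]")
        observed = affected & (onset_date >= registry_start) & (onset_date <= followup_end)
        idx = np.flatnonzero(observed)
        diag_frames.append(pd.DataFrame({
            "person_id": person_id[idx],
            "code": spec.phecode,
            "code_system": "phecode",
            "date": onset_date[idx],
        }))

    diagnoses = (pd.concat(diag_frames, ignore_index=True)
                 if diag_frames else
                 pd.DataFrame(columns=["person_id", "code", "code_system", "date"]))
    diagnoses = diagnoses.sort_values(["person_id", "code"], kind="stable",
                                      ignore_index=True)

    pair_truth = pd.DataFrame({
        "pair_id": [f"FAM{i:08d}" for i in range(n)],
        "person_id1": person_id[0::2],
        "person_id2": person_id[1::2],
        "relationship": np.where(is_twin, "twin", "nontwin_sibling"),
        "zygosity": np.where(is_twin, np.where(is_mz, "MZ", "DZ"), "NA"),
    })
    phenotype_truth = pd.DataFrame([{
        "phecode": s.phecode, "h2_true": s.h2_true, "c2_twin": s.c2_twin,
        "c2_sib": s.c2_sib, "prevalence_K": s.prevalence_K,
        "sex_effect": s.sex_effect,
    } for s in params.phenotypes])

    return SimulatedRegistry(persons, diagnoses, pair_truth, phenotype_truth)


def expected_group_correlations(params: SimulationParams, spec: PhenotypeSpec,
                                design: str = "twin") -> tuple[float, float]:
    """Analytic liability-scale correlation expectations per analysis group.

    For the twin design the reference group is the opposite-sex twin
    pairs, ``r_REF = 0.5 h2 + c2_twin``, and the same-sex group is the
    Weinberg mixture ``r_SS = p (h2 + c2_twin) + (1-p)(0.5 h2 + c2_twin)``
    with ``p = P(MZ | SS)``.  For the sibling design the reference group
    additionally contains every non-twin sibling pair, mixed in by the
    expected pair-type proportions (a first-order mixture of covariances;
    exact for the generator's equal-variance groups).

    Returns ``(r_ss, r_ref)``.
    """
    if design not in ("twin", "sibling"):
        raise ValueError(f"unknown design {design!r}")
    h2, c2t, c2s = spec.h2_true, spec.c2_twin, spec.c2_sib
    p_mz = params.p_mz
    p_ss_twin = p_mz + (1.0 - p_mz) / 2.0
    p = p_mz / p_ss_twin if p_ss_twin > 0 else 0.0
    r_ss = p * (h2 + c2t) + (1.0 - p) * (0.5 * h2 + c2t)
    r_os_twin = 0.5 * h2 + c2t
    if design == "twin":
        return r_ss, r_os_twin
    f_os_twin = params.twin_fraction * (1.0 - p_mz) / 2.0
    f_sib = 1.0 - params.twin_fraction
    tot = f_os_twin + f_sib
    if tot <= 0:
        raise ValueError("sibling design requires opposite-sex twin or sibling pairs")
    r_ref = (f_os_twin * r_os_twin + f_sib * (0.5 * h2 + c2s)) / tot
    return r_ss, r_ref


def write_registry(sim: SimulatedRegistry, outdir: str | Path) -> dict[str, Path]:
    """Write the four registry tables as TSV; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in sim._asdict().items():
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
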