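"""Twin/sibling pair identification, code mapping, and phenotype-table assembly.

Turns raw person records and diagnosis events into per-phenotype tables
of paired binary outcomes ready for the estimation core:

* twin pairs: children of the same mother and father born within one
  calendar day of each other at the same birthplace (one pair per parent
  couple, the earliest born);
* non-twin sibling pairs: children of the same parent couple born
  between 11 months (334 days) and 4 years (1461 days) apart, the
  closest-gap pair per couple;
* diagnosis codes mapped ICD-8 -> ICD-10 -> phecode and propagated up
  the dotted-decimal phecode hierarchy;
* phenotype eligibility filters (prevalence, case counts, concordant
  pairs per group, case sex ratio with ancestor propagation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "MappedEvents",
    "read_persons",
    "read_diagnoses",
    "read_code_map",
    "identify_twin_pairs",
    "identify_sibling_pairs",
    "sibling_cohort",
    "restrict_birth_cohort",
    "phecode_ancestors",
    "map_codes",
    "build_phenotype_tables",
    "classify_onset",
    "filter_phecodes",
    "tables_to_long",
]

_DAYS_PER_YEAR = 365.25
TWIN_MAX_GAP_DAYS = 1
SIB_MIN_GAP_DAYS = 334     # 11 months
SIB_MAX_GAP_DAYS = 1461    # 4 years

PERSON_COLUMNS = ["person_id", "sex", "birth_date", "birthplace",
                  "mother_id", "father_id", "death_date", "emigration_date"]
DIAGNOSIS_COLUMNS = ["person_id", "code", "code_system", "date"]


@dataclass(frozen=True)
class FilterConfig:
    """Phenotype eligibility thresholds.

    ``min_cases`` applies only to twin-cohort analyses (the sibling
    cohort's power comes from its size); the prevalence, concordant-pair
    and sex-ratio rules always apply.
    """

    min_prevalence: float = 0.005
    min_cases: int = 400
    min_concordant_pairs_per_group: int = 5
    max_sex_ratio: float = 5.0
    fdr_alpha: float = 0.05
    early_onset_threshold: float = 0.10
    early_onset_age: float = 18.0

    def __post_init__(self) -> None:
        for name in ("min_prevalence", "min_cases",
                     "min_concordant_pairs_per_group", "max_sex_ratio",
                     "fdr_alpha", "early_onset_threshold", "early_onset_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_persons(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PERSON_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing person columns {sorted(missing)}")
    for col in ("birth_date", "death_date", "emigration_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="raise")
    return df


def read_diagnoses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(DIAGNOSIS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing diagnosis columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="raise")
    return df


def read_code_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV (source code, target code) -> dict, with line checks."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed map entry at line {lineno}: {line!r}")
            if lineno == 1 and parts[1].lower() in ("icd10", "phecode", "target"):
                continue  # header
            mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# Pair identification
# ---------------------------------------------------------------------------

def _validated_children(persons: pd.DataFrame) -> pd.DataFrame:
    if persons["person_id"].duplicated().any():
        dups = persons.loc[persons["person_id"].duplicated(), "person_id"].head()
        raise ValueError(f"duplicate person ids: {list(dups)}")
    df = persons.dropna(subset=["mother_id", "father_id", "birth_date"]).copy()
    for col in ("birth_date", "death_date", "emigration_date"):
        df[col] = pd.to_datetime(df[col])
    # parent couple key is unordered: half-siblings never match
    m = df["mother_id"].astype(str)
    f = df["father_id"].astype(str)
    df["couple"] = np.where(m < f, m + "|" + f, f + "|" + m)
    df = df.sort_values(["couple", "birth_date", "person_id"],
                        kind="stable", ignore_index=True)
    return df


_PAIR_COLUMNS = ["pair_id", "person_id1", "person_id2", "relationship",
                 "sex1", "sex2", "birth_date1", "birth_date2",
                 "death_date1", "death_date2", "followup_end",
                 "age_gap_years", "analysis_group"]


def _pair_frame(first: pd.DataFrame, second: pd.DataFrame,
                relationship: str, study_end: pd.Timestamp) -> pd.DataFrame:
    """Assemble PairRecords; members ordered by birth date then person id."""
    if len(first) == 0:
        return pd.DataFrame(columns=_PAIR_COLUMNS)
    first = first.reset_index(drop=True)
    second = second.reset_index(drop=True)
    # follow-up ends at the first member-level censoring event or study end
    fu = pd.concat([
        pd.Series(study_end, index=first.index),
        first["death_date"], first["emigration_date"],
        second["death_date"], second["emigration_date"],
    ], axis=1).min(axis=1, skipna=True)
    gap_days = (second["birth_date"].to_numpy() - first["birth_date"].to_numpy())
    pairs = pd.DataFrame({
        "pair_id": relationship[0].upper() + ":" + first["person_id"].to_numpy()
                   + "|" + second["person_id"].to_numpy(),
        "person_id1": first["person_id"].to_numpy(),
        "person_id2": second["person_id"].to_numpy(),
        "relationship": relationship,
        "sex1": first["sex"].to_numpy(),
        "sex2": second["sex"].to_numpy(),
        "birth_date1": first["birth_date"].to_numpy(),
        "birth_date2": second["birth_date"].to_numpy(),
        "death_date1": first["death_date"].to_numpy(),
        "death_date2": second["death_date"].to_numpy(),
        "followup_end": fu.to_numpy(),
        "age_gap_years": gap_days.astype("timedelta64[D]").astype(float) / _DAYS_PER_YEAR,
    })
    if relationship == "twin":
        pairs["analysis_group"] = np.where(pairs["sex1"] == pairs["sex2"], "SS", "REF")
    else:
        # full siblings are as genetically similar as DZ twins: always reference
        pairs["analysis_group"] = "REF"
    return pairs[_PAIR_COLUMNS]


def identify_twin_pairs(persons: pd.DataFrame,
                        study_end: str | pd.Timestamp = "2021-12-31") -> pd.DataFrame:
    """One twin pair per parent couple: same-day-or-adjacent birth, same birthplace.

    Children of the same mother *and* father born within one calendar day
    of each other at an identical birthplace form a twin pair; only the
    earliest-born such pair per couple is kept (ties broken by person id
    through the canonical child ordering).
    """
    study_end = pd.Timestamp(study_end)
    df = _validated_children(persons)
    same_couple = df["couple"].to_numpy()[1:] == df["couple"].to_numpy()[:-1]
    gap = (df["birth_date"].to_numpy()[1:] - df["birth_date"].to_numpy()[:-1])
    gap_days = gap.astype("timedelta64[D]").astype(int)
    same_place = df["birthplace"].to_numpy()[1:] == df["birthplace"].to_numpy()[:-1]
    cand = same_couple & (gap_days <= TWIN_MAX_GAP_DAYS) & same_place
    i = np.flatnonzero(cand)
    if i.size == 0:
        return _pair_frame(df.iloc[:0], df.iloc[:0], "twin", study_end)
    first = df.iloc[i].reset_index(drop=True)
    second = df.iloc[i + 1].reset_index(drop=True)
    pairs = _pair_frame(first, second, "twin", study_end)
    pairs["couple"] = df["couple"].to_numpy()[i]
    # earliest-born eligible pair per couple (candidates are birth-ordered)
    pairs = pairs.drop_duplicates("couple", keep="first")
    # a child can appear in overlapping candidate windows (triplets): the
    # per-couple de-duplication above already keeps a single disjoint pair
    return pairs.drop(columns="couple").reset_index(drop=True)


def identify_sibling_pairs(persons: pd.DataFrame,
                           twin_pairs: pd.DataFrame | None = None,
                           study_end: str | pd.Timestamp = "2021-12-31") -> pd.DataFrame:
    """Closest-gap non-twin sibling pair (11 months - 4 years) per parent couple.

    Twin-pair members are never reused as non-twin siblings, so
    ``twin_pairs`` (as returned by :func:`identify_twin_pairs`) should be
    supplied whenever the person table contains twins.  Ties on the gap
    are broken by earliest first-born birth date, then person id.
    """
    study_end = pd.Timestamp(study_end)
    if twin_pairs is None:
        twin_pairs = identify_twin_pairs(persons, study_end)
    twin_members = set(twin_pairs["person_id1"]) | set(twin_pairs["person_id2"])
    df = _validated_children(persons)
    df = df[~df["person_id"].isin(twin_members)].reset_index(drop=True)

    couples = df["couple"].to_numpy()
    same_couple = couples[1:] == couples[:-1]
    gap_days = (df["birth_date"].to_numpy()[1:] - df["birth_date"].to_numpy()[:-1]
                ).astype("timedelta64[D]").astype(int)
    eligible = same_couple & (gap_days >= SIB_MIN_GAP_DAYS) & (gap_days <= SIB_MAX_GAP_DAYS)

    # adjacent pairs suffice unless a couple has 3+ children with some
    # adjacent gap below the 11-month floor; handle those couples exactly
    counts = df.groupby("couple", sort=False)["person_id"].transform("size").to_numpy()
    short_gap = same_couple & (gap_days < SIB_MIN_GAP_DAYS)
    tricky = set(couples[:-1][short_gap & (counts[:-1] > 2)])

    rows_i: list[int] = []
    rows_j: list[int] = []
    chosen: dict[str, tuple[int, int, int]] = {}  # couple -> (gap, i, j)
    for k in np.flatnonzero(eligible):
        c = couples[k]
        if c in tricky:
            continue
        if c not in chosen or gap_days[k] < chosen[c][0]:
            chosen[c] = (int(gap_days[k]), k, k + 1)
    for c in sorted(tricky):
        idx = np.flatnonzero(couples == c)
        best: tuple[int, int, int] | None = None
        for a, b in itertools.combinations(idx, 2):
            g = int((df["birth_date"].iloc[b] - df["birth_date"].iloc[a]).days)
            if SIB_MIN_GAP_DAYS <= g <= SIB_MAX_GAP_DAYS and (best is None or g < best[0]):
                best = (g, a, b)
        if best is not None:
            chosen[c] = best
    for _, i, j in chosen.values():
        rows_i.append(i)
        rows_j.append(j)
    order = np.argsort(rows_i, kind="stable")
    first = df.iloc[np.asarray(rows_i, dtype=int)[order]].reset_index(drop=True)
    second = df.iloc[np.asarray(rows_j, dtype=int)[order]].reset_index(drop=True)
    return _pair_frame(first, second, "nontwin_sibling", study_end)


def sibling_cohort(twin_pairs: pd.DataFrame,
                   nontwin_pairs: pd.DataFrame) -> pd.DataFrame:
    """Sibling-design cohort: twin pairs plus non-twin sibling pairs.

    Same-sex twin pairs remain the "SS" group; opposite-sex twins and
    every non-twin sibling pair (regardless of sex) form the reference
    group.
    """
    return pd.concat([twin_pairs, nontwin_pairs], ignore_index=True)


def restrict_birth_cohort(pairs: pd.DataFrame, cohort: int | str) -> pd.DataFrame:
    """Apply one of the two birth-cohort definitions.

    ``1955``: both members born 1955-2021 and both alive on 1 Jan 1977
    (left-truncated follow-up).  ``1977``: both members born 1977-2021
    (followed from birth).
    """
    cohort = str(cohort)
    by1 = pd.to_datetime(pairs["birth_date1"]).dt.year
    by2 = pd.to_datetime(pairs["birth_date2"]).dt.year
    if cohort == "1955":
        cutoff = pd.Timestamp("1977-01-01")
        alive1 = pairs["death_date1"].isna() | (pairs["death_date1"] >= cutoff)
        alive2 = pairs["death_date2"].isna() | (pairs["death_date2"] >= cutoff)
        keep = by1.between(1955, 2021) & by2.between(1955, 2021) & alive1 & alive2
    elif cohort == "1977":
        keep = by1.between(1977, 2021) & by2.between(1977, 2021)
    else:
        raise ValueError(f"unknown cohort label {cohort!r} (expected 1955 or 1977)")
    return pairs[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Code mapping
# ---------------------------------------------------------------------------

def phecode_ancestors(code: str) -> list[str]:
    """Hierarchical ancestors of a dotted-decimal phecode (nearest first).

    ``"751.11" -> ["751.1", "751"]``; integer-level codes have none.
    """
    if "." not in code:
        return []
    root, decimals = code.split(".", 1)
    out = [f"{root}.{decimals[:k]}" for k in range(len(decimals) - 1, 0, -1)]
    out.append(root)
    return out


class MappedEvents(NamedTuple):
    events: pd.DataFrame           # person_id, phecode, date
    n_unmapped_icd8: int
    n_unmapped_icd10: int


_ICD8_LABELS = {"icd-8", "icd8"}
_ICD10_LABELS = {"icd-10", "icd10"}
_PHECODE_LABELS = {"phecode"}


def map_codes(diagnoses: pd.DataFrame,
              icd8_to_icd10: Mapping[str, str] | None = None,
              icd10_to_phecode: Mapping[str, str] | None = None) -> MappedEvents:
    """Map diagnosis events to phecodes and close over the hierarchy.

    ICD-8 events are first converted to ICD-10, then (with native ICD-10
    events) to phecodes; events already coded as phecodes pass through.
    Every event is propagated to all ancestor phecodes.  Unmapped codes
    are counted and logged, never fatal.
    """
    system = diagnoses["code_system"].astype(str).str.lower()
    code = diagnoses["code"].astype(str)
    unknown = ~system.isin(_ICD8_LABELS | _ICD10_LABELS | _PHECODE_LABELS)
    if unknown.any():
        raise ValueError(
            f"unknown code systems: {sorted(diagnoses.loc[unknown, 'code_system'].unique())}")

    icd8 = system.isin(_ICD8_LABELS)
    n_un8 = 0
    code = code.copy()
    if icd8.any():
        conv = code[icd8].map(lambda c: (icd8_to_icd10 or {}).get(c))
        n_un8 = int(conv.isna().sum())
        code.loc[icd8] = conv
    as_icd10 = icd8 | system.isin(_ICD10_LABELS)
    n_un10 = 0
    if as_icd10.any():
        conv = code[as_icd10].map(
            lambda c: (icd10_to_phecode or {}).get(c) if pd.notna(c) else None)
        n_un10 = int(conv.isna().sum()) - n_un8
        code.loc[as_icd10] = conv
    if n_un8:
        logger.warning("map_codes: %d ICD-8 events had no ICD-10 mapping", n_un8)
    if n_un10:
        logger.warning("map_codes: %d ICD-10 events had no phecode mapping", n_un10)

    mapped = pd.DataFrame({
        "person_id": diagnoses["person_id"],
        "phecode": code,
        "date": diagnoses["date"],
    }).dropna(subset=["phecode"])

    frames = [mapped]
    # ancestor closure: an event at a child implies events at all ancestors
    for codes_str in mapped["phecode"].unique():
        anc = phecode_ancestors(codes_str)
        if anc:
            sub = mapped[mapped["phecode"] == codes_str]
            for a in anc:
                frames.append(sub.assign(phecode=a))
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(["person_id", "phecode", "date"],
                                kind="stable", ignore_index=True)
    return MappedEvents(events, n_un8, n_un10)


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

def build_phenotype_tables(pairs: pd.DataFrame, events: pd.DataFrame,
                           registry_start: str | pd.Timestamp = "1977-01-01",
                           phecodes: Iterable[str] | None = None,
                           ) -> dict[str, pd.DataFrame]:
    """Per-phecode tables of paired ever/never outcomes.

    ``y_i = 1`` iff the member has at least one event for the phecode
    dated within ``[registry_start, followup_end]`` of the pair.  Events
    for persons outside any pair are dropped with a warning.  Each
    returned table carries ``attrs["phecode"]`` and ``attrs["K"]`` (the
    prevalence over individuals in pairs).  By default one table per
    phecode with at least one event; pass ``phecodes`` to fix the
    phenotype universe (codes without events yield all-zero tables).
    """
    registry_start = pd.Timestamp(registry_start)
    members = pd.concat([
        pairs[["pair_id", "person_id1", "followup_end"]]
            .rename(columns={"person_id1": "person_id"}).assign(slot=1),
        pairs[["pair_id", "person_id2", "followup_end"]]
            .rename(columns={"person_id2": "person_id"}).assign(slot=2),
    ], ignore_index=True)

    ev = events.merge(members, on="person_id", how="left")
    unknown = ev["pair_id"].isna()
    if unknown.any():
        logger.warning("build_phenotype_tables: dropping %d events for persons "
                       "outside any pair", int(unknown.sum()))
    ev = ev[~unknown]
    ev = ev[(ev["date"] >= registry_start) & (ev["date"] <= ev["followup_end"])]
    hits = ev[["phecode", "pair_id", "slot"]].drop_duplicates()

    base = pd.DataFrame({
        "pair_id": pairs["pair_id"],
        "group": pairs["analysis_group"],
        "sex1": pairs["sex1"],
        "sex2": pairs["sex2"],
        "birth_year1": pd.to_datetime(pairs["birth_date1"]).dt.year,
        "birth_year2": pd.to_datetime(pairs["birth_date2"]).dt.year,
    })
    n_ind = 2 * len(base)
    universe = (sorted({str(c) for c in phecodes}) if phecodes is not None
                else sorted(hits["phecode"].astype(str).unique()))
    grouped = {str(code): sub for code, sub in hits.groupby("phecode", sort=True)}
    tables: dict[str, pd.DataFrame] = {}
    for phecode in universe:
        sub = grouped.get(phecode, hits.iloc[:0])
        tab = base.copy()
        y1 = tab["pair_id"].isin(sub.loc[sub["slot"] == 1, "pair_id"])
        y2 = tab["pair_id"].isin(sub.loc[sub["slot"] == 2, "pair_id"])
        tab.insert(2, "y1", y1.astype(int))
        tab.insert(3, "y2", y2.astype(int))
        tab.attrs["phecode"] = str(phecode)
        tab.attrs["K"] = float((tab["y1"].sum() + tab["y2"].sum()) / n_ind)
        tables[str(phecode)] = tab
    return tables


def classify_onset(events: pd.DataFrame, persons: pd.DataFrame,
                   config: FilterConfig = FilterConfig(),
                   phecodes: Iterable[str] | None = None) -> pd.DataFrame:
    """Early/late onset per phecode from the age at first event.

    A phenotype is early-onset when at least ``early_onset_threshold`` of
    its cases have their first event at or before ``early_onset_age``
    years.  Phecodes without cases are labelled "undefined".
    """
    birth = pd.to_datetime(persons.set_index("person_id")["birth_date"])
    first = (events.sort_values("date", kind="stable")
             .drop_duplicates(["person_id", "phecode"]))
    age = ((pd.to_datetime(first["date"])
            - first["person_id"].map(birth)).dt.days / _DAYS_PER_YEAR)
    first = first.assign(onset_age=age.to_numpy())
    universe = (sorted({str(c) for c in phecodes}) if phecodes is not None
                else sorted(first["phecode"].astype(str).unique()))
    grouped = {str(code): sub for code, sub in first.groupby("phecode", sort=True)}
    rows = []
    for phecode in universe:
        sub = grouped.get(phecode, first.iloc[:0])
        n = len(sub)
        frac = float((sub["onset_age"] <= config.early_onset_age).mean()) if n else float("nan")
        label = ("undefined" if n == 0 else
                 "early" if frac >= config.early_onset_threshold else "late")
        rows.append({"phecode": phecode, "n_cases": n,
                     "frac_early": frac, "onset_class": label})
    return pd.DataFrame(rows, columns=["phecode", "n_cases", "frac_early", "onset_class"])


def filter_phecodes(tables: Mapping[str, pd.DataFrame],
                    config: FilterConfig = FilterConfig(),
                    design: str = "twin") -> tuple[list[str], pd.DataFrame]:
    """Apply phenotype eligibility rules; returns (eligible, exclusion ledger).

    Rules, in order of reporting: prevalence >= ``min_prevalence``; case
    count >= ``min_cases`` (twin design only); at least
    ``min_concordant_pairs_per_group`` concordant pairs in the SS group
    and in the reference group; case sex ratio <= ``max_sex_ratio``.  A
    phecode excluded by the sex-ratio rule drags its hierarchical
    ancestors out with it (an apparently balanced parent may merely
    aggregate imbalanced children).  The ledger records the first failing
    rule per phecode; eligible and excluded phecodes partition the input.
    """
    if design not in ("twin", "sibling"):
        raise ValueError(f"unknown design {design!r}")
    records: dict[str, dict] = {}
    sex_ratio_excluded: list[str] = []
    for phecode, tab in tables.items():
        k = tab.attrs.get("K")
        y1 = tab["y1"].to_numpy()
        y2 = tab["y2"].to_numpy()
        n_cases = int(y1.sum() + y2.sum())
        if k is None:
            k = n_cases / (2.0 * len(tab))
        conc = (y1 == 1) & (y2 == 1)
        ss = tab["group"].to_numpy() == "SS"
        n_conc_ss = int(conc[ss].sum())
        n_conc_ref = int(conc[~ss].sum())
        male_cases = int((y1[tab["sex1"].to_numpy() == "M"]).sum()
                         + (y2[tab["sex2"].to_numpy() == "M"]).sum())
        female_cases = n_cases - male_cases
        if min(male_cases, female_cases) == 0:
            ratio = float("inf") if n_cases else float("nan")
        else:
            ratio = max(male_cases, female_cases) / min(male_cases, female_cases)

        reason = ""
        if k < config.min_prevalence:
            reason = "prevalence"
        elif design == "twin" and n_cases < config.min_cases:
            reason = "min_cases"
        elif min(n_conc_ss, n_conc_ref) < config.min_concordant_pairs_per_group:
            reason = "concordant_pairs"
        elif not ratio <= config.max_sex_ratio:
            reason = "sex_ratio"
            sex_ratio_excluded.append(phecode)
        records[phecode] = {
            "phecode": phecode, "K": float(k), "n_cases": n_cases,
            "n_concordant_ss": n_conc_ss, "n_concordant_ref": n_conc_ref,
            "sex_ratio": ratio, "reason": reason,
        }

    # sex-ratio exclusions remove all hierarchical ancestors present
    for phecode in sex_ratio_excluded:
        for anc in phecode_ancestors(phecode):
            rec = records.get(anc)
            if rec is not None and not rec["reason"]:
                rec["reason"] = "sex_ratio_ancestor"

    ledger = pd.DataFrame(records.values()).sort_values(
        "phecode", ignore_index=True)
    ledger.insert(1, "eligible", ledger["reason"] == "")
    eligible = sorted(ledger.loc[ledger["eligible"], "phecode"])
    return eligible, ledger


def tables_to_long(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-phecode tables into one long-format frame."""
    frames = [tab.assign(phecode=code) for code, tab in sorted(tables.items())]
    if not frames:
        return pd.DataFrame(columns=["phecode", "pair_id", "group", "y1", "y2",
                                     "sex1", "sex2", "birth_year1", "birth_year2"])
    long = pd.concat(frames, ignore_index=True)
    cols = ["phecode"] + [c for c in long.columns if c != "phecode"]
    return long[cols]
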