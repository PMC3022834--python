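"""Slope endpoints: CD4/VL pairing, eligibility, three-point slopes and
time-updated covariates.

A *concurrent pair* is a CD4 test matched to the nearest viral-load test
within 28 days (each VL test anchors at most one CD4 test; ties go to the
earlier VL).  A *slope endpoint* at time T is the ordinary-least-squares
slope of CD4 on time over the pair at T and its two neighbouring pairs,
expressed in cells/μL per year, carrying the covariate vector evaluated at
T.  Model rows are restricted to T > 183 days after cART initiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ANALYTE_CD4, ANALYTE_HB, ANALYTE_VL, CohortTables
from .model import (
    DAYS_PER_YEAR,
    PERIOD_EARLY,
    PHASE_BOUNDARY_DAYS,
    STAGE_NONTB,
    STAGE_REF,
    STAGE_TB,
    period_from_days,
)

log = logging.getLogger(__name__)

PAIR_WINDOW_DAYS = 28
# sub-detection viral loads enter the regression at the assay limit
VL_CENSOR_FLOOR = 400.0

SUBSET_RULES = ("INITIAL_REGIMEN", "INITIAL_NNRTI", "MIN4")

ENDPOINT_COLUMNS = [
    "patient_id",
    "t_days",
    "slope",
    "female",
    "age_decades",
    "stage",
    "haemoglobin",
    "cd4_per100",
    "log10_vl",
    "hepatitis",
    "period",
    "nnrti",
    "boosted_pi",
    "abacavir",
]


@dataclass
class PhaseSummary:
    """Raw mean slopes before/after the 6-month boundary with a two-sided
    Welch test of their difference."""

    mean_slope_early: float
    mean_slope_late: float
    n_early: int
    n_late: int
    p_value: float

    @property
    def undefined(self) -> bool:
        return self.n_early == 0 or self.n_late == 0


# ----------------------------------------------------------------------
def pair_concurrent(
    labs: pd.DataFrame,
    cart_starts: pd.Series | None = None,
    window_days: int = PAIR_WINDOW_DAYS,
    vl_floor: float = VL_CENSOR_FLOOR,
) -> pd.DataFrame:
    """Match each CD4 test to the nearest-in-time VL test within the window.

    CD4 tests are processed chronologically; each VL test is used at most
    once; equidistant candidates resolve to the earlier VL.  Returns one row
    per matched pair with columns patient_id, cd4_date, vl_date, days_apart,
    cd4, log10_vl (and t_days when ``cart_starts``, a Series indexed by
    patient_id, is given).
    """
    rows = []
    if len(labs):
        for pid, grp in labs.groupby("patient_id", sort=True):
            cd4 = grp[grp["analyte"] == ANALYTE_CD4].sort_values("date")
            vl = grp[grp["analyte"] == ANALYTE_VL].sort_values("date")
            if not len(cd4) or not len(vl):
                continue
            vl_days = vl["date"].values.astype("datetime64[D]").astype(np.int64)
            vl_values = vl["value"].to_numpy()
            vl_dates = vl["date"].to_numpy()
            used = np.zeros(len(vl), dtype=bool)
            for cd4_date, cd4_value in zip(cd4["date"], cd4["value"]):
                d = np.int64(np.datetime64(cd4_date, "D").astype(np.int64))
                dist = np.abs(vl_days - d)
                dist = np.where(used, np.iinfo(np.int64).max, dist)
                j = int(np.argmin(dist))  # argmin keeps the earlier VL on ties
                if dist[j] > window_days:
                    continue
                used[j] = True
                rows.append((
                    pid, cd4_date, vl_dates[j], int(dist[j]),
                    float(cd4_value), float(np.log10(max(vl_values[j], vl_floor))),
                ))
    pairs = pd.DataFrame(
        rows, columns=["patient_id", "cd4_date", "vl_date", "days_apart", "cd4", "log10_vl"]
    )
    if cart_starts is not None and len(pairs):
        starts = pairs["patient_id"].map(cart_starts)
        pairs["t_days"] = (pd.to_datetime(pairs["cd4_date"]) - pd.to_datetime(starts)).dt.days
    elif cart_starts is not None:
        pairs["t_days"] = pd.Series(dtype="int64")
    return pairs


def add_t_days(pairs: pd.DataFrame, cohort: CohortTables) -> pd.DataFrame:
    """Attach days-since-cART-start to a pair table lacking it."""
    starts = cohort.patients.set_index("patient_id")["cart_start"]
    pairs = pairs.copy()
    pairs["t_days"] = (
        pd.to_datetime(pairs["cd4_date"]) - pairs["patient_id"].map(starts)
    ).dt.days
    return pairs


def _initial_drug_counts(cohort: CohortTables) -> pd.Series:
    """Number of drugs in each patient's first treatment episode."""
    tr = cohort.treatments.sort_values("start").groupby("patient_id").first()
    return tr["classes"].str.split("+").str.len()


def eligible_patients(cohort: CohortTables, pairs: pd.DataFrame) -> set[str]:
    """Patients on triple-or-more initial cART with >= 3 concurrent pairs
    beyond day 183."""
    if not len(pairs):
        return set()
    if "t_days" not in pairs.columns:
        pairs = add_t_days(pairs, cohort)
    late_counts = pairs[pairs["t_days"] > PHASE_BOUNDARY_DAYS].groupby("patient_id").size()
    enough_pairs = set(late_counts[late_counts >= 3].index)
    drugs = _initial_drug_counts(cohort)
    triple_plus = set(drugs[drugs >= 3].index)
    dropped_dual = enough_pairs - triple_plus
    if dropped_dual:
        log.info("excluded %d patient(s) on mono/dual therapy", len(dropped_dual))
    return enough_pairs & triple_plus


# ----------------------------------------------------------------------
def compute_slope(t_days, cd4) -> float:
    """OLS slope of CD4 on time (years = days/365.25) over exactly three
    consecutive measurements, in cells/μL per year."""
    t = np.asarray(t_days, dtype=float)
    y = np.asarray(cd4, dtype=float)
    if t.shape != (3,) or y.shape != (3,):
        raise ValueError("compute_slope expects exactly three (t, cd4) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    ty = t / DAYS_PER_YEAR
    d = ty - ty.mean()
    return float(np.dot(d, y - y.mean()) / np.dot(d, d))


def _triplet_slopes(t_days: np.ndarray, cd4: np.ndarray) -> np.ndarray:
    """Vectorised three-point OLS slopes for interior points of one patient's
    ordered pair sequence."""
    ty = t_days / DAYS_PER_YEAR
    t3 = np.stack([ty[:-2], ty[1:-1], ty[2:]], axis=1)
    y3 = np.stack([cd4[:-2], cd4[1:-1], cd4[2:]], axis=1)
    d = t3 - t3.mean(axis=1, keepdims=True)
    return (d * (y3 - y3.mean(axis=1, keepdims=True))).sum(axis=1) / (d * d).sum(axis=1)


def build_endpoints(
    cohort: CohortTables,
    pairs: pd.DataFrame,
    restrict: set[str] | None = None,
) -> pd.DataFrame:
    """One slope endpoint per interior pair, with covariates evaluated at T.

    ``restrict`` limits patients (normally the eligible set).  The returned
    table includes early endpoints (T <= 183 d, period ``P0_6``) so that the
    two-phase summary can be computed; model rows are ``t_days > 183``
    (see :func:`model_rows`).
    """
    if "t_days" not in pairs.columns:
        pairs = add_t_days(pairs, cohort)
    if restrict is not None:
        pairs = pairs[pairs["patient_id"].isin(restrict)]
    pairs = pairs.sort_values(["patient_id", "t_days"], kind="mergesort")

    pat = cohort.patients.set_index("patient_id")
    age0 = (pat["cart_start"] - pat["birth_date"]).dt.days / DAYS_PER_YEAR

    # first TB / non-TB event day per patient (days since cART start)
    ev = cohort.events.merge(cohort.patients[["patient_id", "cart_start"]], on="patient_id") \
        if len(cohort.events) else pd.DataFrame(columns=["patient_id", "date", "event", "cart_start"])
    if len(ev):
        ev["day"] = (ev["date"] - ev["cart_start"]).dt.days
        tb_first = ev[ev["event"] == "TB_ADI"].groupby("patient_id")["day"].min()
        adi_first = ev[ev["event"] == "NONTB_ADI"].groupby("patient_id")["day"].min()
    else:
        tb_first = pd.Series(dtype=float)
        adi_first = pd.Series(dtype=float)

    # haemoglobin: last observation carried forward; never-tested patients
    # get the cohort median at initiation
    hb = cohort.labs[cohort.labs["analyte"] == ANALYTE_HB]
    hb_default = 14.0
    if len(hb):
        hb = hb.merge(cohort.patients[["patient_id", "cart_start"]], on="patient_id")
        hb["t_days"] = (hb["date"] - hb["cart_start"]).dt.days
        baseline_hb = hb[hb["t_days"] <= 30].groupby("patient_id")["value"].first()
        hb_default = float(baseline_hb.median()) if len(baseline_hb) else float(hb["value"].median())
        hb = hb.sort_values(["t_days"], kind="mergesort")[["patient_id", "t_days", "value"]]

    out = []
    for pid, grp in pairs.groupby("patient_id", sort=True):
        if len(grp) < 3:
            continue
        t = grp["t_days"].to_numpy(dtype=float)
        y = grp["cd4"].to_numpy(dtype=float)
        keep = np.ones(len(t), dtype=bool)
        keep[1:] = np.diff(t) > 0  # same-day duplicate pairs: keep the first
        t, y = t[keep], y[keep]
        grp = grp[keep]
        if len(grp) < 3:
            continue
        slopes = _triplet_slopes(t, y)
        interior = grp.iloc[1:-1]
        df = pd.DataFrame({
            "patient_id": pid,
            "t_days": interior["t_days"].to_numpy(),
            "slope": slopes,
            "cd4_per100": interior["cd4"].to_numpy() / 100.0,
            "log10_vl": interior["log10_vl"].to_numpy(),
        })
        out.append(df)

    if not out:
        return pd.DataFrame(columns=ENDPOINT_COLUMNS)
    endpoints = pd.concat(out, ignore_index=True)

    pid = endpoints["patient_id"]
    endpoints["female"] = (pat["sex"].reindex(pid) == "F").astype(int).to_numpy()
    endpoints["age_decades"] = (
        age0.reindex(pid).to_numpy() + endpoints["t_days"].to_numpy() / DAYS_PER_YEAR
    ) / 10.0
    tb_day = tb_first.reindex(pid).to_numpy(dtype=float)
    adi_day = adi_first.reindex(pid).to_numpy(dtype=float)
    t_arr = endpoints["t_days"].to_numpy(dtype=float)
    stage = np.where(
        np.nan_to_num(tb_day, nan=np.inf) <= t_arr, STAGE_TB,
        np.where(np.nan_to_num(adi_day, nan=np.inf) <= t_arr, STAGE_NONTB, STAGE_REF),
    )
    endpoints["stage"] = stage
    endpoints["hepatitis"] = pat["hepatitis_bc"].reindex(pid).to_numpy()
    endpoints["nnrti"] = pat["regimen_nnrti"].reindex(pid).to_numpy()
    endpoints["boosted_pi"] = pat["regimen_boosted_pi"].reindex(pid).to_numpy()
    endpoints["abacavir"] = pat["abacavir"].reindex(pid).to_numpy()
    endpoints["period"] = [period_from_days(t) for t in endpoints["t_days"]]

    if isinstance(hb, pd.DataFrame) and len(hb):
        endpoints = endpoints.sort_values("t_days", kind="mergesort")
        endpoints = pd.merge_asof(
            endpoints, hb.rename(columns={"value": "haemoglobin"}),
            on="t_days", by="patient_id", direction="backward",
        )
        endpoints["haemoglobin"] = endpoints["haemoglobin"].fillna(hb_default)
        endpoints = endpoints.sort_values(["patient_id", "t_days"], kind="mergesort")
    else:
        endpoints["haemoglobin"] = hb_default

    return endpoints.reset_index(drop=True)[ENDPOINT_COLUMNS]


def model_rows(endpoints: pd.DataFrame) -> pd.DataFrame:
    """Endpoints entering the regression: strictly beyond 6 months."""
    return endpoints[endpoints["t_days"] > PHASE_BOUNDARY_DAYS].reset_index(drop=True)


# ----------------------------------------------------------------------
def phase_slope_summary(endpoints: pd.DataFrame) -> PhaseSummary:
    """Mean slope in the first 6 months vs afterwards (Welch two-sided test)."""
    early = endpoints.loc[endpoints["t_days"] <= PHASE_BOUNDARY_DAYS, "slope"]
    late = endpoints.loc[endpoints["t_days"] > PHASE_BOUNDARY_DAYS, "slope"]
    if len(early) == 0 or len(late) == 0:
        log.warning("phase summary undefined: early n=%d, late n=%d", len(early), len(late))
        return PhaseSummary(
            float(early.mean()) if len(early) else float("nan"),
            float(late.mean()) if len(late) else float("nan"),
            len(early), len(late), float("nan"),
        )
    if early.var(ddof=1) == 0 and late.var(ddof=1) == 0:
        p = 1.0 if early.mean() == late.mean() else 0.0
    else:
        p = float(stats.ttest_ind(early, late, equal_var=False).pvalue)
    return PhaseSummary(float(early.mean()), float(late.mean()), len(early), len(late), p)


# ----------------------------------------------------------------------
def _initial_regimen_cutoffs(cohort: CohortTables) -> pd.Series:
    """Per patient: first day (since cART start) of a drug-class change or of
    a treatment gap longer than 30 days; +inf if neither occurs."""
    tr = cohort.treatments.merge(cohort.patients[["patient_id", "cart_start"]], on="patient_id")
    tr["start_day"] = (tr["start"] - tr["cart_start"]).dt.days
    tr["stop_day"] = (tr["stop"] - tr["cart_start"]).dt.days
    cutoffs = {}
    for pid, grp in tr.sort_values("start_day").groupby("patient_id"):
        cut = np.inf
        initial = grp.iloc[0]["classes"]
        prev_stop = None
        for _, row in grp.iterrows():
            if prev_stop is not None and row["start_day"] - prev_stop > 30:
                cut = min(cut, prev_stop)
            if row["classes"] != initial:
                cut = min(cut, row["start_day"])
            prev_stop = row["stop_day"]
        cutoffs[pid] = cut
    return pd.Series(cutoffs, dtype=float)


def sensitivity_subset(
    endpoints: pd.DataFrame, cohort: CohortTables, rule: str
) -> pd.DataFrame:
    """Sensitivity-analysis subsets of the endpoint table.

    INITIAL_REGIMEN keeps endpoints dated before any drug-class change or any
    >30-day treatment interruption; INITIAL_NNRTI additionally restricts to
    patients whose initial regimen was NNRTI-based; MIN4 keeps patients
    contributing at least four endpoints.
    """
    if rule not in SUBSET_RULES:
        raise ValueError(f"unknown sensitivity rule {rule!r}; expected one of {SUBSET_RULES}")
    if rule == "MIN4":
        counts = endpoints.groupby("patient_id")["t_days"].transform("size")
        return endpoints[counts >= 4].reset_index(drop=True)
    cutoffs = _initial_regimen_cutoffs(cohort)
    cut = endpoints["patient_id"].map(cutoffs).fillna(np.inf)
    kept = endpoints[endpoints["t_days"].to_numpy() < cut.to_numpy()]
    if rule == "INITIAL_NNRTI":
        nnrti_ids = set(
            cohort.patients.loc[cohort.patients["regimen_nnrti"] == 1, "patient_id"]
        )
        kept = kept[kept["patient_id"].isin(nnrti_ids)]
    return kept.reset_index(drop=True)
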