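"""Seeded synthetic longitudinal cohort: patients, labs, events, treatments.

Every patient starts cART at day 0 of their own clock.  Visits follow an
early monitoring phase and then routine semi-annual spacing.  The viral-load
trajectory declines from the pretreatment level; responders suppress below
the detection limit within ~1-3 months and may later rebound to low-level
failure, with a per-visit hazard whose starting value is solved from the
printed 6- and 12-month suppressed fractions and which grows as treatment
failure accumulates.  The latent CD4 count rises at a patient-specific
phase-1 slope until day 183 (smaller among virological non-responders, with
the marginal mean preserved) and thereafter advances at the generating
model's linear predictor — covariates frozen at the most recent visit, the
time-since-initiation effect averaged piecewise across period boundaries —
plus a patient-level random slope; observed CD4 adds measurement noise and
is floored at zero.  Sub-detection VL is stored as detection_limit/2 in the
lab table but enters the dynamics (and later the regression) censored at
the detection limit.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import GeneratorConfig
from .model import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    PERIOD_6_12,
    PHASE_BOUNDARY_DAYS,
    STAGE_NONTB,
    STAGE_REF,
    STAGE_TB,
)

log = logging.getLogger(__name__)

ANALYTE_CD4 = "CD4"
ANALYTE_VL = "VL"
ANALYTE_HB = "HB"

EVENT_TB = "TB_ADI"
EVENT_NONTB = "NONTB_ADI"

PATIENT_COLUMNS = [
    "patient_id",
    "sex",
    "birth_date",
    "cart_start",
    "regimen_nnrti",
    "regimen_boosted_pi",
    "regimen_nonboosted_pi",
    "abacavir",
    "hepatitis_bc",
]
LAB_COLUMNS = ["patient_id", "date", "analyte", "value"]
EVENT_COLUMNS = ["patient_id", "date", "event"]
TREATMENT_COLUMNS = ["patient_id", "start", "stop", "classes"]

_FILES = {
    "patients": PATIENT_COLUMNS,
    "labs": LAB_COLUMNS,
    "events": EVENT_COLUMNS,
    "treatments": TREATMENT_COLUMNS,
}
_DATE_COLUMNS = {
    "patients": ["birth_date", "cart_start"],
    "labs": ["date"],
    "events": ["date"],
    "treatments": ["start", "stop"],
}


class SchemaError(ValueError):
    """A cohort CSV does not match the documented schema."""


@dataclass
class CohortTables:
    """Long-format cohort: one patients row per patient; dated labs, clinical
    events and treatment episodes referencing ``patient_id``."""

    patients: pd.DataFrame
    labs: pd.DataFrame
    events: pd.DataFrame
    treatments: pd.DataFrame

    def validate(self, pretreatment_window_days: float = 365.0) -> None:
        ids = set(self.patients["patient_id"])
        for name in ("labs", "events", "treatments"):
            table = getattr(self, name)
            missing = set(table["patient_id"]) - ids
            if missing:
                raise ValueError(f"{name} references unknown patient_id(s): {sorted(missing)[:5]}")
        if len(self.labs):
            cd4 = self.labs.loc[self.labs["analyte"] == ANALYTE_CD4, "value"]
            if (cd4 < 0).any():
                raise ValueError("CD4 values must be >= 0")
            vl = self.labs.loc[self.labs["analyte"] == ANALYTE_VL, "value"]
            if (vl < 1).any():
                raise ValueError("VL values must be >= 1 copies/mL")
            merged = self.labs.merge(
                self.patients[["patient_id", "cart_start"]], on="patient_id"
            )
            lead = (merged["cart_start"] - merged["date"]).dt.days
            if (lead > pretreatment_window_days).any():
                raise ValueError("lab date precedes cART start beyond the allowed window")


def _mean_period_effect(tm, a: float, b: float) -> float:
    """Time-weighted mean of the period effect over days (a, b), a < b.

    The period effect is a step function of time since cART start; averaging
    it across any boundaries a between-visit segment straddles keeps the
    realized segment slope consistent with the model's instantaneous slope.
    Within a single period this reduces to the period's own effect.
    """
    pieces = (
        (0.0, 12 * DAYS_PER_MONTH, 0.0),
        (12 * DAYS_PER_MONTH, 18 * DAYS_PER_MONTH, tm.beta_period_12_18),
        (18 * DAYS_PER_MONTH, 24 * DAYS_PER_MONTH, tm.beta_period_18_24),
        (24 * DAYS_PER_MONTH, math.inf, tm.beta_period_24plus),
    )
    total = 0.0
    for lo, hi, effect in pieces:
        overlap = min(b, hi) - max(a, lo)
        if overlap > 0:
            total += overlap * effect
    return total / (b - a)


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float,
                      lo: float, hi: float) -> float:
    if scale <= 0:
        return float(np.clip(loc, lo, hi))
    for _ in range(1000):
        x = rng.normal(loc, scale)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(loc, lo, hi))


def solve_rebound_probability(config: GeneratorConfig) -> float:
    """Initial per-visit probability of losing suppression, solved so that
    the expected suppressed fraction falls from ``p_suppress_6m`` at 6 months
    to ``p_still_suppressed_12m`` at 12 months given the routine visit
    spacing (the hazard then grows by ``rebound_hazard_ratio`` per visit)."""
    p6, p12 = config.p_suppress_6m, config.p_still_suppressed_12m
    if p6 <= 0 or p12 >= p6:
        return 0.0
    mean_interval = math.exp(
        config.visit_interval_log_location + config.visit_interval_log_scale**2 / 2.0
    )
    m = (DAYS_PER_YEAR / 2.0) / mean_interval  # expected visits between 6 and 12 months
    f = lambda r: p6 * (1.0 - r) ** m - p12
    return float(brentq(f, 0.0, 0.999999, xtol=1e-12))


def generate_cohort(config: GeneratorConfig) -> CohortTables:
    """Generate a seeded synthetic cohort.  Identical config (including seed)
    yields byte-identical tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tm = config.true_model
    rebound_p = solve_rebound_probability(config)
    log10_dl = math.log10(config.detection_limit)

    epoch = datetime.date(2003, 1, 1)

    patients, labs, events, treatments = [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        cart_start = epoch + datetime.timedelta(days=int(rng.integers(0, 2192)))
        male = rng.random() < config.prop_male
        age0 = _truncated_normal(rng, config.age_location, config.age_scale,
                                 config.age_min, config.age_max)
        birth = cart_start - datetime.timedelta(days=int(round(age0 * DAYS_PER_YEAR)))
        hepatitis = int(rng.random() < config.prop_hepatitis)

        u = rng.random()
        p_ref, p_tb, p_nontb = config.stage_probs
        if u < p_tb:
            stage0 = STAGE_TB
        elif u < p_tb + p_nontb:
            stage0 = STAGE_NONTB
        else:
            stage0 = STAGE_REF

        u = rng.random()
        p_nnrti, p_pi, p_bpi = config.regimen_probs
        nnrti = int(u < p_nnrti)
        nonboosted = int(p_nnrti <= u < p_nnrti + p_pi)
        boosted = int(p_nnrti + p_pi <= u < p_nnrti + p_pi + p_bpi)
        abacavir = int(rng.random() < config.prop_abacavir)

        cd4_latent = float(np.clip(
            rng.lognormal(config.baseline_cd4_log_location, config.baseline_cd4_log_scale),
            1.0, 2000.0))
        vl0 = float(np.clip(
            rng.normal(config.baseline_log10vl_location, config.baseline_log10vl_scale),
            1.0, 7.5))

        followup_years = max(
            rng.lognormal(config.followup_log_location, config.followup_log_scale),
            config.min_followup_years,
        )
        followup_days = followup_years * DAYS_PER_YEAR

        # visit schedule
        visit_days = [0.0]
        t = 0.0
        k = 0
        while True:
            if k < config.n_early_visits:
                gap = rng.lognormal(config.early_interval_log_location,
                                    config.early_interval_log_scale)
            else:
                gap = rng.lognormal(config.visit_interval_log_location,
                                    config.visit_interval_log_scale)
            gap = max(gap, config.min_interval_days)
            t += gap
            k += 1
            if t > followup_days:
                break
            visit_days.append(round(t))

        # viral-load course
        responder = rng.random() < config.p_suppress_6m
        supp_day = rng.uniform(config.suppression_day_min, config.suppression_day_max)
        setpoint = float(np.clip(
            rng.normal(config.setpoint_log10vl_location, config.setpoint_log10vl_scale),
            log10_dl + 0.05, 7.0))
        rebound_level = float(np.clip(
            rng.normal(config.rebound_log10vl_location, config.rebound_log10vl_scale),
            log10_dl + 0.05, 7.0))

        # CD4 course: early gain is tied to virological response, with the
        # responder mean derived so the marginal mean stays phase1_slope_mean
        p_resp = config.p_suppress_6m
        if 0.0 < p_resp < 1.0:
            m_resp = (config.phase1_slope_mean
                      - (1.0 - p_resp) * config.phase1_nonresponder_mean) / p_resp
        else:
            m_resp = config.phase1_slope_mean
        phase1_mean = m_resp if responder else (
            config.phase1_nonresponder_mean if p_resp < 1.0 else config.phase1_slope_mean)
        phase1_slope = rng.normal(phase1_mean, config.phase1_slope_sd) \
            if config.phase1_slope_sd > 0 else phase1_mean
        b_i = rng.normal(0.0, config.sigma_b) if config.sigma_b > 0 else 0.0

        has_hb = rng.random() >= config.prop_no_haemoglobin
        hb = _truncated_normal(rng, config.haemoglobin_location, config.haemoglobin_scale,
                               7.0, 18.0)

        # clinical events: prevalent stage at initiation, then incident events
        tb_day = math.inf
        adi_day = math.inf
        if stage0 == STAGE_TB:
            tb_day = -rng.uniform(0.0, 180.0)
        elif stage0 == STAGE_NONTB:
            adi_day = -rng.uniform(0.0, 180.0)
        if config.tb_incidence > 0:
            t_inc = rng.exponential(1.0 / config.tb_incidence) * DAYS_PER_YEAR
            if t_inc < followup_days:
                tb_day = min(tb_day, t_inc)
        if config.adi_incidence > 0:
            t_inc = rng.exponential(1.0 / config.adi_incidence) * DAYS_PER_YEAR
            if t_inc < followup_days:
                adi_day = min(adi_day, t_inc)
        for day, ev in ((tb_day, EVENT_TB), (adi_day, EVENT_NONTB)):
            if math.isfinite(day):
                events.append((pid, cart_start + datetime.timedelta(days=round(day)), ev))

        # treatment episodes: one change of drug class and/or one gap at most
        if nnrti:
            classes0 = "NRTI+NRTI+NNRTI"
        elif nonboosted:
            classes0 = "NRTI+NRTI+PI"
        elif boosted:
            classes0 = "NRTI+NRTI+bPI"
        else:
            classes0 = "NRTI+NRTI+NRTI"
        change_day = (rng.exponential(1.0 / config.class_change_rate) * DAYS_PER_YEAR
                      if config.class_change_rate > 0 else math.inf)
        gap_day = (rng.exponential(1.0 / config.gap_rate) * DAYS_PER_YEAR
                   if config.gap_rate > 0 else math.inf)
        gap_len = rng.lognormal(config.gap_duration_log_location,
                                config.gap_duration_log_scale)
        episodes = []  # (start_day, stop_day, classes)
        cursor, cur_classes = 0.0, classes0
        breaks = sorted(
            [(d, kind) for d, kind in ((change_day, "change"), (gap_day, "gap"))
             if d < followup_days]
        )
        for day, kind in breaks:
            if day <= cursor:
                continue
            episodes.append((cursor, day, cur_classes))
            if kind == "gap":
                cursor = min(day + gap_len, followup_days)
            else:
                cursor = day
                cur_classes = "NRTI+NRTI+bPI" if "NNRTI" in cur_classes else "NRTI+NRTI+NNRTI"
        if cursor < followup_days:
            episodes.append((cursor, followup_days, cur_classes))
        for start, stop, cls in episodes:
            treatments.append((
                pid,
                cart_start + datetime.timedelta(days=round(start)),
                cart_start + datetime.timedelta(days=round(stop)),
                cls,
            ))

        # walk the visits
        rebounded = False
        rebound_day = 0.0
        suppressed_visits = 0  # post-6-month visits survived while suppressed
        stage_at = lambda day: (STAGE_TB if tb_day <= day
                                else STAGE_NONTB if adi_day <= day else STAGE_REF)
        n_visits = len(visit_days)
        for j, day in enumerate(visit_days):
            date = cart_start + datetime.timedelta(days=int(day))

            # latent log10 VL at this visit; rebound can start at any visit
            # after the patient's first post-6-month (measurement) visit,
            # with a hazard growing as treatment failure accumulates, and
            # viraemia then ramps back up to the set-point over months
            if responder and not rebounded and day >= supp_day:
                if day > PHASE_BOUNDARY_DAYS and rebound_p > 0:
                    if suppressed_visits > 0:
                        hazard = min(
                            rebound_p * config.rebound_hazard_ratio ** (suppressed_visits - 1),
                            0.5,
                        )
                        if rng.random() < hazard:
                            rebounded = True
                            rebound_day = day
                    suppressed_visits += 1
            if rebounded:
                ramp = min((day - rebound_day) / config.rebound_ramp_days, 1.0) \
                    if config.rebound_ramp_days > 0 else 1.0
                lvl = (log10_dl - 1.0) + (rebound_level - (log10_dl - 1.0)) * ramp
            elif responder:
                if day >= supp_day:
                    lvl = log10_dl - 1.0  # well below the assay limit
                else:
                    lvl = vl0 + (log10_dl - 1.0 - vl0) * day / supp_day
            else:
                if day >= 90.0:
                    lvl = setpoint
                else:
                    lvl = vl0 + (setpoint - vl0) * day / 90.0
            vl_value = (config.detection_limit / 2.0 if lvl < log10_dl
                        else float(10.0 ** min(lvl, 7.5)))
            # the analysis left-censors sub-detection VL at the limit, so the
            # CD4 dynamics see the same covariate the regression will use
            log10_vl_stored = math.log10(max(vl_value, config.detection_limit))

            # observed CD4
            obs_cd4 = cd4_latent
            if config.sigma_m > 0:
                obs_cd4 = cd4_latent + rng.normal(0.0, config.sigma_m)
            obs_cd4 = max(obs_cd4, 0.0)

            labs.append((pid, date, ANALYTE_CD4, float(obs_cd4)))
            if rng.random() >= config.prop_vl_missing:
                vl_date = date
                if rng.random() < config.prop_vl_offset:
                    vl_date = date + datetime.timedelta(
                        days=int(rng.integers(1, config.vl_offset_max_days + 1)))
                labs.append((pid, vl_date, ANALYTE_VL, vl_value))
            if has_hb:
                labs.append((pid, date, ANALYTE_HB, float(round(hb, 1))))
                hb = float(np.clip(hb + rng.normal(0.0, config.haemoglobin_drift_sd),
                                   7.0, 18.0))

            # advance latent CD4 to the next visit
            if j + 1 < n_visits:
                nxt = visit_days[j + 1]
                # linear predictor with covariates frozen at this visit; the
                # period (time-since-initiation) effect alone is averaged
                # piecewise over the segment it spans
                lp_base = tm.linear_predictor(
                    female=0 if male else 1,
                    age_years=age0 + day / DAYS_PER_YEAR,
                    stage=stage_at(day),
                    haemoglobin=hb,
                    cd4=cd4_latent,
                    log10_vl=log10_vl_stored,
                    hepatitis=hepatitis,
                    period=PERIOD_6_12,  # zero period effect; added below
                    nnrti=nnrti,
                    boosted_pi=boosted,
                    abacavir=abacavir,
                ) + b_i
                if nxt <= PHASE_BOUNDARY_DAYS:
                    cd4_latent += phase1_slope * (nxt - day) / DAYS_PER_YEAR
                else:
                    seg_start = max(day, PHASE_BOUNDARY_DAYS)
                    if day < PHASE_BOUNDARY_DAYS:
                        cd4_latent += phase1_slope * (PHASE_BOUNDARY_DAYS - day) / DAYS_PER_YEAR
                    lp = lp_base + _mean_period_effect(tm, seg_start, nxt)
                    cd4_latent += lp * (nxt - seg_start) / DAYS_PER_YEAR
                cd4_latent = max(cd4_latent, 0.0)

        patients.append((
            pid, "M" if male else "F", birth, cart_start,
            nnrti, boosted, nonboosted, abacavir, hepatitis,
        ))

    def frame(rows, columns, dates):
        df = pd.DataFrame(rows, columns=columns)
        if not len(df):
            df = pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c in dates else object)
                               for c in columns})
        for c in dates:
            df[c] = pd.to_datetime(df[c])
        return df

    tables = CohortTables(
        patients=frame(patients, PATIENT_COLUMNS, _DATE_COLUMNS["patients"]),
        labs=frame(labs, LAB_COLUMNS, _DATE_COLUMNS["labs"]),
        events=frame(events, EVENT_COLUMNS, _DATE_COLUMNS["events"]),
        treatments=frame(treatments, TREATMENT_COLUMNS, _DATE_COLUMNS["treatments"]),
    )
    tables.validate(config.pretreatment_window_days)
    return tables


# ----------------------------------------------------------------------
# CSV round trip

def write_cohort(tables: CohortTables, directory: str | Path) -> dict[str, Path]:
    """Write the four cohort CSVs (ISO-8601 dates) and return their paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, columns in _FILES.items():
        df = getattr(tables, name).copy()
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} table is missing column(s): {missing}")
        for c in _DATE_COLUMNS[name]:
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        df[columns].to_csv(path, index=False)
        paths[name] = path
    return paths


def read_cohort(directory: str | Path) -> CohortTables:
    """Read cohort CSVs written by :func:`write_cohort`, enforcing the schema."""
    directory = Path(directory)
    frames = {}
    for name, columns in _FILES.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing cohort file: {path}")
        df = pd.read_csv(path, dtype={"patient_id": str})
        extra = [c for c in df.columns if c not in columns]
        if extra:
            raise SchemaError(f"{name}.csv has unknown column(s): {extra}")
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}.csv is missing column(s): {missing}")
        for c in _DATE_COLUMNS[name]:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d")
        for c in columns:
            if c not in _DATE_COLUMNS[name] and c not in ("patient_id", "sex", "analyte",
                                                          "event", "classes"):
                df[c] = pd.to_numeric(df[c])
        frames[name] = df[columns]
    tables = CohortTables(**frames)
    tables.validate(math.inf)
    return tables
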