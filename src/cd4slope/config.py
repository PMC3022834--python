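"""Cohort-generator configuration.

Defaults emulate the source cohort: ~2000 treatment-naive adults starting
triple-or-more cART, 74% male, median age 36 (IQR 30-42), baseline CD4 median
140 cells/μL, baseline VL median 4.93 log10 copies/mL, 12% hepatitis B/C
co-infected, VL suppression (<400 copies/mL) in 83% at 6 months and 82% at
12 months, a two-phase CD4 response (fast first 6 months, slower after),
visit spacing with overall median ≈165 days, and median follow-up 4.2 years.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .model import TrueModel


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator.

    Rates are per person-year, durations in days unless noted.  Log-normal
    distributions are parameterised by the natural log of their median
    (``*_log_location``) and the SD on the log scale (``*_log_scale``).
    """

    n_patients: int = 2000
    seed: int = 1

    # demographics
    prop_male: float = 0.74
    age_location: float = 36.0          # years; truncated normal
    age_scale: float = 8.9              # IQR 30-42 => sigma = 12/1.349
    age_min: float = 18.0
    age_max: float = 75.0
    prop_hepatitis: float = 0.12

    # disease stage at initiation: (CDC A/B reference, TB-ADI, non-TB ADI).
    # 36% with an ADI at initiation, split 30/70 TB vs non-TB.
    stage_probs: tuple[float, float, float] = (0.64, 0.108, 0.252)

    # initial regimen: (NNRTI-based, non-boosted PI, boosted PI); remainder "other"
    regimen_probs: tuple[float, float, float] = (0.63, 0.15, 0.20)
    prop_abacavir: float = 0.05

    # baseline labs
    baseline_cd4_log_location: float = math.log(140.0)   # cells/μL, median 140
    baseline_cd4_log_scale: float = 0.8
    baseline_log10vl_location: float = 4.93              # log10 copies/mL
    baseline_log10vl_scale: float = 0.96
    haemoglobin_location: float = 14.0                   # g/dL
    haemoglobin_scale: float = 1.3
    haemoglobin_drift_sd: float = 0.3                    # per-visit random walk
    prop_no_haemoglobin: float = 0.13                    # never tested for Hb

    # visit process: an early monitoring phase (first ``n_early_visits``
    # intervals, roughly monthly-to-quarterly) followed by semi-annual
    # routine intervals; pooled interval median ≈ 165 d.
    n_early_visits: int = 3
    early_interval_log_location: float = math.log(85.0)
    early_interval_log_scale: float = 0.35
    visit_interval_log_location: float = math.log(220.0)
    visit_interval_log_scale: float = 0.45
    min_interval_days: float = 14.0
    followup_log_location: float = math.log(4.2)         # years, median 4.2
    followup_log_scale: float = 0.62
    min_followup_years: float = 0.75

    # viral-load process
    p_suppress_6m: float = 0.83
    p_still_suppressed_12m: float = 0.82
    detection_limit: float = 400.0                       # copies/mL
    suppression_day_min: float = 30.0
    suppression_day_max: float = 90.0
    # set-point of viraemia in patients who never achieve suppression
    # (near the pretreatment level) and, separately, of low-level failure
    # after rebound from suppression (log10 copies/mL)
    setpoint_log10vl_location: float = 4.25
    setpoint_log10vl_scale: float = 0.6
    rebound_log10vl_location: float = 3.5
    rebound_log10vl_scale: float = 0.5
    # per-visit rebound hazard grows by this factor at each successive
    # suppressed visit beyond 6 months (accumulating treatment failure);
    # the initial hazard is solved from the 6- and 12-month fractions
    rebound_hazard_ratio: float = 1.25
    rebound_ramp_days: float = 200.0                     # suppressed -> set-point ramp
    prop_vl_offset: float = 0.3                          # VL drawn days after CD4
    vl_offset_max_days: int = 21
    prop_vl_missing: float = 0.03

    # CD4 process.  The marginal phase-1 mean is phase1_slope_mean; patients
    # without virological response gain less early on, so their mean is
    # phase1_nonresponder_mean and responders' mean is derived to preserve
    # the marginal value.
    phase1_slope_mean: float = 179.0                     # cells/μL/yr, first 6 months
    phase1_slope_sd: float = 80.0
    phase1_nonresponder_mean: float = 110.0
    true_model: TrueModel = field(default_factory=TrueModel)
    sigma_b: float = 20.0                                # between-patient slope SD
    sigma_m: float = 25.0                                # CD4 measurement noise SD

    # clinical events and treatment episodes
    tb_incidence: float = 0.02                           # per person-year
    adi_incidence: float = 0.03
    class_change_rate: float = 0.2
    gap_rate: float = 0.08
    gap_duration_log_location: float = math.log(45.0)
    gap_duration_log_scale: float = 0.5
    pretreatment_window_days: float = 365.0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise ValueError("n_patients must be a non-negative integer")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float, np.floating, np.integer)):
                if not np.isfinite(v):
                    raise ValueError(f"config field {f.name} is not finite: {v!r}")
        fracs = {
            "prop_male": self.prop_male,
            "prop_hepatitis": self.prop_hepatitis,
            "prop_abacavir": self.prop_abacavir,
            "p_suppress_6m": self.p_suppress_6m,
            "p_still_suppressed_12m": self.p_still_suppressed_12m,
            "prop_no_haemoglobin": self.prop_no_haemoglobin,
            "prop_vl_offset": self.prop_vl_offset,
            "prop_vl_missing": self.prop_vl_missing,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, probs in (("stage_probs", self.stage_probs), ("regimen_probs", self.regimen_probs)):
            probs = tuple(probs)
            if len(probs) != 3:
                raise ValueError(f"{name} must have three entries")
            if any(p < 0 for p in probs) or sum(probs) > 1.0 + 1e-9:
                raise ValueError(f"{name} entries must be non-negative and sum to <= 1")
        if self.p_still_suppressed_12m > self.p_suppress_6m:
            raise ValueError("p_still_suppressed_12m cannot exceed p_suppress_6m")
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be positive")
        if self.sigma_b < 0 or self.sigma_m < 0 or self.phase1_slope_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.tb_incidence < 0 or self.adi_incidence < 0:
            raise ValueError("event incidences must be non-negative")
        if self.suppression_day_max < self.suppression_day_min:
            raise ValueError("suppression_day_max < suppression_day_min")
        self.true_model.validate()

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_probs"] = list(self.stage_probs)
        d["regimen_probs"] = list(self.regimen_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "true_model" in d and isinstance(d["true_model"], dict):
            d["true_model"] = TrueModel(**d["true_model"])
        for key in ("stage_probs", "regimen_probs"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "GeneratorConfig":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kwargs)
        return GeneratorConfig(**d)
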