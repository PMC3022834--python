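"""Final-model coefficient structure shared by the generator, the fitter and the calculator.

The response throughout is the CD4-count slope in cells/μL per year.  The
linear predictor combines patient covariates at the time of the slope
endpoint: sex, current age (per decade), disease stage (CDC category A as
reference, tuberculosis-ADI, non-TB ADI), haemoglobin, concurrent CD4
(per 100 cells/μL), concurrent viral load (log10 copies/mL), hepatitis B/C
co-infection, time since cART initiation in half-yearly periods, and
initial-regimen indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

# Disease-stage levels (CDC category A/B is the reference level).
STAGE_REF = "REF"
STAGE_TB = "TB_ADI"
STAGE_NONTB = "NONTB_ADI"
STAGES = (STAGE_REF, STAGE_TB, STAGE_NONTB)

# Time-since-initiation periods; model rows start beyond 6 months.
PERIOD_EARLY = "P0_6"
PERIOD_6_12 = "P6_12"
PERIOD_12_18 = "P12_18"
PERIOD_18_24 = "P18_24"
PERIOD_24PLUS = "P24PLUS"
PERIODS = (PERIOD_6_12, PERIOD_12_18, PERIOD_18_24, PERIOD_24PLUS)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.4375
PHASE_BOUNDARY_DAYS = 183  # 6 months; slope endpoints beyond this enter the model

# Canonical design-matrix column order (Table-2-style layout).
DESIGN_COLUMNS = (
    "const",
    "female",
    "age_decades",
    "stage_tb",
    "stage_nontb",
    "haemoglobin",
    "cd4_per100",
    "log10_vl",
    "hepatitis",
    "period_12_18",
    "period_18_24",
    "period_24plus",
    "nnrti",
    "boosted_pi",
    "abacavir",
)

# Covariate blocks as they are scanned / selected: categorical blocks enter
# and leave the model jointly with all their non-reference levels.
TERM_BLOCKS = {
    "sex": ("female",),
    "age": ("age_decades",),
    "stage": ("stage_tb", "stage_nontb"),
    "haemoglobin": ("haemoglobin",),
    "cd4": ("cd4_per100",),
    "vl": ("log10_vl",),
    "hepatitis": ("hepatitis",),
    "period": ("period_12_18", "period_18_24", "period_24plus"),
    "nnrti": ("nnrti",),
    "boosted_pi": ("boosted_pi",),
    "abacavir": ("abacavir",),
}
ALL_TERMS = tuple(TERM_BLOCKS)


def period_from_days(t_days: float) -> str:
    """Period label for a slope endpoint at ``t_days`` since cART start.

    Boundaries are half-open on the left: (6,12], (12,18], (18,24], (24,∞)
    months, with months = days / 30.4375.  Endpoints at or before day 183
    belong to the early phase and are excluded from the model.
    """
    if t_days <= PHASE_BOUNDARY_DAYS:
        return PERIOD_EARLY
    months = t_days / DAYS_PER_MONTH
    if months <= 12:
        return PERIOD_6_12
    if months <= 18:
        return PERIOD_12_18
    if months <= 24:
        return PERIOD_18_24
    return PERIOD_24PLUS


@dataclass
class TrueModel:
    """Generating coefficients for the synthetic cohort (cells/μL/yr per unit).

    Defaults are the published final multivariate model.
    """

    constant: float = 205.5
    beta_female: float = 7.8
    beta_age_per10: float = -4.8
    beta_tb: float = 26.3
    beta_nontb_adi: float = 12.0
    beta_haemoglobin: float = 0.0
    beta_cd4_per100: float = 1.9
    beta_log10vl: float = -40.5
    beta_hepatitis: float = -17.7
    beta_period_12_18: float = -21.5
    beta_period_18_24: float = -25.8
    beta_period_24plus: float = -59.1
    beta_nnrti: float = -1.3
    beta_boosted_pi: float = -3.4
    beta_abacavir: float = -5.6

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"TrueModel.{f.name} must be finite, got {v!r}")

    def coefficients(self) -> dict[str, float]:
        """Coefficients keyed by design-matrix column name."""
        return {
            "const": self.constant,
            "female": self.beta_female,
            "age_decades": self.beta_age_per10,
            "stage_tb": self.beta_tb,
            "stage_nontb": self.beta_nontb_adi,
            "haemoglobin": self.beta_haemoglobin,
            "cd4_per100": self.beta_cd4_per100,
            "log10_vl": self.beta_log10vl,
            "hepatitis": self.beta_hepatitis,
            "period_12_18": self.beta_period_12_18,
            "period_18_24": self.beta_period_18_24,
            "period_24plus": self.beta_period_24plus,
            "nnrti": self.beta_nnrti,
            "boosted_pi": self.beta_boosted_pi,
            "abacavir": self.beta_abacavir,
        }

    def linear_predictor(
        self,
        *,
        female: int,
        age_years: float,
        stage: str,
        haemoglobin: float,
        cd4: float,
        log10_vl: float,
        hepatitis: int,
        period: str,
        nnrti: int = 0,
        boosted_pi: int = 0,
        abacavir: int = 0,
    ) -> float:
        """Expected CD4 slope (cells/μL/yr) at the given covariate values."""
        lp = (
            self.constant
            + self.beta_female * female
            + self.beta_age_per10 * (age_years / 10.0)
            + self.beta_haemoglobin * haemoglobin
            + self.beta_cd4_per100 * (cd4 / 100.0)
            + self.beta_log10vl * log10_vl
            + self.beta_hepatitis * hepatitis
            + self.beta_nnrti * nnrti
            + self.beta_boosted_pi * boosted_pi
            + self.beta_abacavir * abacavir
        )
        if stage == STAGE_TB:
            lp += self.beta_tb
        elif stage == STAGE_NONTB:
            lp += self.beta_nontb_adi
        elif stage != STAGE_REF:
            raise ValueError(f"unknown stage {stage!r}")
        if period == PERIOD_12_18:
            lp += self.beta_period_12_18
        elif period == PERIOD_18_24:
            lp += self.beta_period_18_24
        elif period == PERIOD_24PLUS:
            lp += self.beta_period_24plus
        elif period not in (PERIOD_6_12, PERIOD_EARLY):
            raise ValueError(f"unknown period {period!r}")
        return lp

    @classmethod
    def zero(cls) -> "TrueModel":
        """All coefficients (including the constant) set to zero."""
        return cls(**{f.name: 0.0 for f in fields(cls)})
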