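"""Predicted CD4 slope from patient covariates and model coefficients.

The calculator evaluates the linear predictor of the final model for a
patient profile at a chosen viral load, builds the period × VL prediction
grid with borderline flags (|slope| ≤ 20 cells/μL/yr), and solves for the
largest viral load compatible with a target slope, per period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedlm import ModelFit
from .model import (
    PERIODS,
    PERIOD_6_12,
    STAGES,
    STAGE_REF,
)

DEFAULT_VL_GRID = (
    500, 1000, 2000, 3000, 4000, 5000, 10000, 20000,
    30000, 40000, 50000, 100000, 150000,
)
BORDERLINE_BAND = 20.0  # cells/μL/yr; endpoints inclusive


@dataclass
class PatientProfile:
    """Covariates of the patient whose slope is being estimated.

    ``haemoglobin`` defaults to 0.0 because the final-model haemoglobin
    coefficient is 0.0; any value may be supplied for fitted models.
    """

    female: int = 0
    age_years: float = 30.0
    stage: str = STAGE_REF
    haemoglobin: float = 0.0
    cd4: float = 200.0
    hepatitis: int = 0
    period: str = PERIOD_6_12
    nnrti: int = 0
    boosted_pi: int = 0
    abacavir: int = 0

    def validate(self) -> None:
        if self.age_years <= 0:
            raise ValueError("age_years must be positive")
        if self.cd4 < 0:
            raise ValueError("cd4 must be non-negative")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}")

    def design_values(self, period: str | None = None) -> dict[str, float]:
        """Design-column values for this profile (VL term excluded)."""
        period = period or self.period
        return {
            "const": 1.0,
            "female": float(self.female),
            "age_decades": self.age_years / 10.0,
            "stage_tb": 1.0 if self.stage == "TB_ADI" else 0.0,
            "stage_nontb": 1.0 if self.stage == "NONTB_ADI" else 0.0,
            "haemoglobin": float(self.haemoglobin),
            "cd4_per100": self.cd4 / 100.0,
            "hepatitis": float(self.hepatitis),
            "period_12_18": 1.0 if period == "P12_18" else 0.0,
            "period_18_24": 1.0 if period == "P18_24" else 0.0,
            "period_24plus": 1.0 if period == "P24PLUS" else 0.0,
            "nnrti": float(self.nnrti),
            "boosted_pi": float(self.boosted_pi),
            "abacavir": float(self.abacavir),
        }


@dataclass
class PredictionGrid:
    """Period × VL matrix of predicted slopes (raw and 1-dp) with
    borderline flags."""

    vl_grid: tuple
    periods: tuple
    raw: pd.DataFrame
    rounded: pd.DataFrame
    borderline: pd.DataFrame

    def to_tsv(self) -> str:
        out = self.rounded.copy().astype(object)
        out[self.borderline] = out[self.borderline].map(lambda v: f"*{v}*")
        return out.to_csv(sep="\t")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the printed grids)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def _lp_excluding_vl(profile: PatientProfile, model: ModelFit, period: str | None = None) -> float:
    coef = model.coef
    values = profile.design_values(period)
    return sum(coef.get(name, 0.0) * v for name, v in values.items())


def predict_slope(profile: PatientProfile, model: ModelFit, vl: float) -> float:
    """Predicted CD4 slope (cells/μL/yr) at viral load ``vl`` copies/mL."""
    if vl <= 0:
        raise ValueError("viral load must be positive (copies/mL)")
    profile.validate()
    return _lp_excluding_vl(profile, model) + model.coef.get("log10_vl", 0.0) * math.log10(vl)


def build_grid(
    profile: PatientProfile,
    model: ModelFit,
    vl_grid=DEFAULT_VL_GRID,
    periods=PERIODS,
) -> PredictionGrid:
    """Full period × VL grid of predicted slopes, rounded to 1 dp, with
    borderline flags where −20 ≤ slope ≤ +20."""
    vl_grid = tuple(vl_grid)
    if not vl_grid or any(b <= a for a, b in zip(vl_grid, vl_grid[1:])):
        raise ValueError("vl_grid must be non-empty and strictly ascending")
    beta_vl = model.coef.get("log10_vl", 0.0)
    raw = {}
    for period in periods:
        base = _lp_excluding_vl(profile, model, period)
        raw[period] = [base + beta_vl * math.log10(v) for v in vl_grid]
    raw = pd.DataFrame(raw, index=list(vl_grid)).T
    raw.index.name = "period"
    rounded = raw.map(lambda v: round_half_away(v, 1))
    borderline = raw.abs() <= BORDERLINE_BAND
    return PredictionGrid(vl_grid=vl_grid, periods=tuple(periods),
                          raw=raw, rounded=rounded, borderline=borderline)


def solve_vl_threshold(
    profile: PatientProfile,
    model: ModelFit,
    target_slope: float = 20.0,
    mode: str = "GRID",
    vl_grid=DEFAULT_VL_GRID,
    periods=PERIODS,
) -> pd.DataFrame:
    """Largest viral load keeping the predicted slope at or above the target.

    GRID mode returns the largest grid VL whose predicted slope is ≥ target
    (status ``below_grid_min``/``above_grid_max`` when the threshold falls
    off the grid); CONTINUOUS inverts the affine-in-log10(VL) predictor in
    closed form.  Requires a negative VL coefficient.
    """
    mode = mode.upper()
    if mode not in ("GRID", "CONTINUOUS"):
        raise ValueError("mode must be 'GRID' or 'CONTINUOUS'")
    beta_vl = model.coef.get("log10_vl", 0.0)
    if beta_vl >= 0:
        raise ValueError("VL threshold undefined: the VL coefficient must be negative")
    profile.validate()
    rows = []
    for period in periods:
        base = _lp_excluding_vl(profile, model, period)
        if mode == "CONTINUOUS":
            vl = 10.0 ** ((base - target_slope) / (-beta_vl))
            rows.append((period, vl, "ok"))
            continue
        ok = [v for v in vl_grid if base + beta_vl * math.log10(v) >= target_slope]
        if not ok:
            rows.append((period, float("nan"), "below_grid_min"))
        elif len(ok) == len(tuple(vl_grid)):
            rows.append((period, float(max(ok)), "above_grid_max"))
        else:
            rows.append((period, float(max(ok)), "ok"))
    return pd.DataFrame(rows, columns=["period", "vl_copies_per_ml", "status"])


# ----------------------------------------------------------------------
# Published final-model coefficients (multivariate column + constant),
# with SEs back-computed from the printed 95% CIs.
_PUBLISHED = [
    # name, estimate, ci_low, ci_high
    ("const", 205.5, 174.4, 236.6),
    ("female", 7.8, -1.5, 17.2),
    ("age_decades", -4.8, -8.6, -1.0),
    ("stage_tb", 26.3, 15.6, 37.0),
    ("stage_nontb", 12.0, 2.5, 21.4),
    ("haemoglobin", 0.0, -0.0, 0.1),
    ("cd4_per100", 1.9, 0.2, 3.7),
    ("log10_vl", -40.5, -48.4, -32.6),
    ("hepatitis", -17.7, -29.7, -5.7),
    ("period_12_18", -21.5, -37.8, -5.2),
    ("period_18_24", -25.8, -42.0, -9.7),
    ("period_24plus", -59.1, -71.7, -46.5),
    ("nnrti", -1.3, -9.2, 6.6),
    ("boosted_pi", -3.4, -13.2, 6.3),
    ("abacavir", -5.6, -18.5, 7.3),
]


def published_coefficients() -> ModelFit:
    """The published final multivariate model as a coefficient fixture
    (10 899 observations on 1 676 patients; variance components were not
    reported and are NaN)."""
    names = [row[0] for row in _PUBLISHED]
    beta = np.array([row[1] for row in _PUBLISHED])
    se = np.array([(row[3] - row[2]) / (2.0 * 1.96) for row in _PUBLISHED])
    return ModelFit(
        names=names, beta=beta, se=se,
        sigma_b2=float("nan"), sigma_e2=float("nan"), loglik=float("nan"),
        criterion="published", n_obs=10899, n_patients=1676,
        flags=["published_fixture"],
    )
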