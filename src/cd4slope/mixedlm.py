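"""Random-intercept linear regression fitted by profiled (RE)ML.

Model: y_ij = x_ij'β + b_i + ε_ij with b_i ~ N(0, σ_b²) per patient and
ε_ij ~ N(0, σ_e²).  Writing λ = σ_b²/σ_e², the marginal covariance of a
patient's y-vector is σ_e²(I + λJ), whose inverse is (I − λ/(1+λn_i)·J)/σ_e².
For fixed λ, β has a generalized-least-squares closed form and σ_e² is
profiled out analytically, leaving a one-dimensional criterion in log λ that
is maximised by bracketed search with an explicit boundary check at λ = 0.
Wald z-tests and 95% CIs (±1.96·SE) come from the GLS covariance at the
optimum; categorical blocks are tested jointly with a Wald chi-square.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .model import ALL_TERMS, TERM_BLOCKS

log = logging.getLogger(__name__)

Z95 = 1.96
_LOG_LAMBDA_RANGE = (-16.0, 16.0)


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is singular; collinear column(s): {self.columns}")


@dataclass
class ModelFit:
    """Coefficients and variance components of one random-intercept fit."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma_b2: float
    sigma_e2: float
    loglik: float
    criterion: str                 # "REML", "ML" or "published"
    n_obs: int
    n_patients: int
    flags: list[str] = field(default_factory=list)
    cov: np.ndarray | None = None  # fixed-effect covariance (for joint Wald tests)

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.names, (float(b) for b in self.beta)))

    @property
    def constant(self) -> float:
        return self.coef.get("const", 0.0)

    @property
    def ci95_low(self) -> np.ndarray:
        return self.beta - Z95 * self.se

    @property
    def ci95_high(self) -> np.ndarray:
        return self.beta + Z95 * self.se

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.beta / self.se, np.inf * np.sign(self.beta))

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    def term_p(self, term: str) -> float:
        """Two-sided p for a covariate block: Wald z for a single column,
        joint Wald chi-square for a multi-column (categorical) block."""
        cols = TERM_BLOCKS.get(term, (term,))
        idx = [self.names.index(c) for c in cols if c in self.names]
        if not idx:
            raise KeyError(f"term {term!r} not in fit")
        if len(idx) == 1:
            return float(self.wald_p[idx[0]])
        if self.cov is None:
            raise ValueError("joint Wald test requires the fitted covariance")
        b = self.beta[idx]
        V = self.cov[np.ix_(idx, idx)]
        w = float(b @ np.linalg.solve(V, b))
        return float(stats.chi2.sf(w, len(idx)))

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "names": list(self.names),
            "beta": [float(x) for x in self.beta],
            "se": [float(x) for x in self.se],
            "ci95_low": [float(x) for x in self.ci95_low],
            "ci95_high": [float(x) for x in self.ci95_high],
            "wald_p": [float(x) for x in self.wald_p],
            "sigma_b2": float(self.sigma_b2),
            "sigma_e2": float(self.sigma_e2),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "n_patients": int(self.n_patients),
            "flags": list(self.flags),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        return cls(
            names=list(d["names"]),
            beta=np.asarray(d["beta"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            sigma_b2=float(d["sigma_b2"]),
            sigma_e2=float(d["sigma_e2"]),
            loglik=float(d["loglik"]),
            criterion=d["criterion"],
            n_obs=int(d["n_obs"]),
            n_patients=int(d["n_patients"]),
            flags=list(d.get("flags", [])),
        )


@dataclass
class SelectionTrace:
    """Forward-selection audit: entry order with p at entry, the final term
    set, and each dropped term's p when added once to the final model."""

    steps: list[tuple[int, str, float]]
    final_terms: list[str]
    dropped_p: dict[str, float]


# ----------------------------------------------------------------------
def design_matrix(endpoints: pd.DataFrame, terms=ALL_TERMS) -> pd.DataFrame:
    """Design matrix (with intercept) for the requested covariate blocks."""
    X = pd.DataFrame(index=endpoints.index)
    X["const"] = 1.0
    for term in terms:
        for col in TERM_BLOCKS[term]:
            if col == "stage_tb":
                X[col] = (endpoints["stage"] == "TB_ADI").astype(float)
            elif col == "stage_nontb":
                X[col] = (endpoints["stage"] == "NONTB_ADI").astype(float)
            elif col.startswith("period_"):
                label = {"period_12_18": "P12_18", "period_18_24": "P18_24",
                         "period_24plus": "P24PLUS"}[col]
                X[col] = (endpoints["period"] == label).astype(float)
            else:
                X[col] = endpoints[col].astype(float)
    return X


# ----------------------------------------------------------------------
class _Profile:
    """Per-group sufficient statistics and the profiled criterion in λ."""

    def __init__(self, y, X, groups):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        codes, uniques = pd.factorize(np.asarray(groups))
        order = np.argsort(codes, kind="stable")
        self.y = y[order]
        self.X = X[order]
        codes = codes[order]
        self.n, self.p = self.X.shape
        self.n_groups = len(uniques)
        self.counts = np.bincount(codes).astype(float)
        # group sums via segment reduction
        boundaries = np.flatnonzero(np.diff(codes)) + 1
        self.Sx = np.add.reduceat(self.X, np.r_[0, boundaries], axis=0)
        self.Sy = np.add.reduceat(self.y, np.r_[0, boundaries])
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def gls(self, lam: float):
        """Return (beta, A, Q) at fixed λ, where A = X'V*⁻¹X (V* unit-scaled)
        and Q = r'V*⁻¹r at the GLS solution."""
        c = lam / (1.0 + lam * self.counts) if lam > 0 else np.zeros_like(self.counts)
        A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.Sy)
        beta = np.linalg.solve(A, b)
        ywy = self.yty - float((c * self.Sy) @ self.Sy)
        Q = max(ywy - float(beta @ b), 0.0)
        return beta, A, Q

    def criterion(self, lam: float, reml: bool) -> float:
        """Profiled log-likelihood (REML or ML) at λ, up to no constants."""
        beta, A, Q = self.gls(lam)
        logdet_v = float(np.sum(np.log1p(lam * self.counts))) if lam > 0 else 0.0
        Q = max(Q, 1e-300)
        if reml:
            dof = self.n - self.p
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return -np.inf
            return -0.5 * (
                dof * (math.log(2.0 * math.pi * Q / dof) + 1.0) + logdet_v + logdet_a
            )
        return -0.5 * (
            self.n * (math.log(2.0 * math.pi * Q / self.n) + 1.0) + logdet_v
        )


def _check_rank(X: np.ndarray, names) -> None:
    # pivoted QR exposes which columns complete the rank deficiency
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in sorted(piv[rank:])]
        raise SingularDesignError(bad)


def fit_random_intercept(
    y,
    X,
    groups,
    criterion: str = "REML",
    names: list[str] | None = None,
) -> ModelFit:
    """Fit the random-intercept model by 1-D profile optimisation over λ.

    ``X`` may be a DataFrame (column names are used) or an array with
    ``names``.  ``criterion`` is "REML" (default) or "ML".  The returned λ
    maximises the profiled criterion; the boundary λ = 0 (no between-patient
    variance, i.e. pooled OLS) is always checked.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    criterion = criterion.upper()
    if criterion not in ("REML", "ML"):
        raise ValueError("criterion must be 'REML' or 'ML'")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n_obs > n_terms, got n={n}, p={p}")
    _check_rank(X, names)

    prof = _Profile(y, X, groups)
    reml = criterion == "REML"
    flags: list[str] = []

    if prof.counts.max() <= 1:
        flags.append("sigma_b_unidentifiable")
        lam_hat = 0.0
    else:
        grid = np.concatenate([[-np.inf], np.linspace(*_LOG_LAMBDA_RANGE, 81)])
        vals = np.array([prof.criterion(0.0 if not np.isfinite(t) else math.exp(t), reml)
                         for t in grid])
        j = int(np.nanargmax(vals))
        if j == 0:
            lam_hat = 0.0
            # still polish near zero in case the maximum sits just inside
            lo, hi = _LOG_LAMBDA_RANGE[0], grid[2]
        else:
            lo = grid[max(j - 1, 1)]
            hi = grid[min(j + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda t: -prof.criterion(math.exp(t), reml),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        lam_hat = math.exp(res.x)
        if prof.criterion(0.0, reml) >= -res.fun:
            lam_hat = 0.0
            flags.append("boundary_lambda_zero")

    beta, A, Q = prof.gls(lam_hat)
    dof = n - p if reml else n
    sigma_e2 = Q / dof
    if sigma_e2 <= 0 or Q < 1e-10 * max(prof.yty, 1.0):
        flags.append("residual_degenerate")
        sigma_e2 = max(sigma_e2, 1e-300)
    sigma_b2 = lam_hat * sigma_e2
    cov = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    loglik = prof.criterion(lam_hat, reml)

    return ModelFit(
        names=names, beta=beta, se=se,
        sigma_b2=float(sigma_b2), sigma_e2=float(sigma_e2),
        loglik=float(loglik), criterion=criterion,
        n_obs=n, n_patients=int(prof.n_groups),
        flags=flags, cov=cov,
    )


# ----------------------------------------------------------------------
def fit_terms(endpoints: pd.DataFrame, terms, criterion: str = "REML") -> ModelFit:
    """Fit intercept + the given covariate blocks on an endpoint table."""
    X = design_matrix(endpoints, terms)
    return fit_random_intercept(
        endpoints["slope"], X, endpoints["patient_id"], criterion=criterion
    )


def univariate_scan(
    endpoints: pd.DataFrame, terms=ALL_TERMS, criterion: str = "REML"
) -> dict[str, ModelFit]:
    """One single-covariate random-intercept fit per block; singular blocks
    are skipped with a warning and the scan continues."""
    if not len(endpoints):
        raise ValueError("endpoint table is empty")
    fits: dict[str, ModelFit] = {}
    for term in terms:
        try:
            fits[term] = fit_terms(endpoints, [term], criterion=criterion)
        except SingularDesignError as exc:
            log.warning("univariate scan: term %s skipped (%s)", term, exc)
    return fits


def forward_select(
    endpoints: pd.DataFrame,
    candidates=ALL_TERMS,
    alpha: float = 0.20,
    criterion: str = "REML",
) -> tuple[ModelFit, SelectionTrace]:
    """Forward stepwise selection on block Wald p-values.

    At each step the candidate with the smallest p (joint Wald for
    categorical blocks) enters if p <= alpha.  Afterwards every excluded
    candidate is refitted once on top of the final model and reported as
    adjusted-for without retention.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate terms")
    selected: list[str] = []
    steps: list[tuple[int, str, float]] = []
    remaining = list(candidates)
    step = 0
    while remaining:
        best_term, best_p = None, np.inf
        for term in remaining:
            try:
                fit = fit_terms(endpoints, selected + [term], criterion=criterion)
            except SingularDesignError:
                continue
            p = fit.term_p(term)
            if p < best_p:
                best_term, best_p = term, p
        if best_term is None or best_p > alpha:
            break
        step += 1
        selected.append(best_term)
        remaining.remove(best_term)
        steps.append((step, best_term, float(best_p)))
    final = fit_terms(endpoints, selected, criterion=criterion) if selected else \
        fit_terms(endpoints, [], criterion=criterion)
    dropped: dict[str, float] = {}
    for term in candidates:
        if term in selected:
            continue
        try:
            fit = fit_terms(endpoints, selected + [term], criterion=criterion)
            dropped[term] = float(fit.term_p(term))
        except SingularDesignError:
            dropped[term] = float("nan")
    return final, SelectionTrace(steps=steps, final_terms=selected, dropped_p=dropped)


# ----------------------------------------------------------------------
_REPORT_LAYOUT = [
    ("Sex", "sex", [("Male (ref)", None), ("Female", "female")]),
    ("Current age", "age", [("per 10 years older", "age_decades")]),
    ("Disease stage", "stage", [
        ("CDC category A (ref)", None),
        ("TB with or without other ADI", "stage_tb"),
        ("Non-TB ADI(s)", "stage_nontb"),
    ]),
    ("Haemoglobin level", "haemoglobin", [("per 1 g/dL higher", "haemoglobin")]),
    ("Concurrent CD4 count", "cd4", [("per 100 cells/uL higher", "cd4_per100")]),
    ("Concurrent viral load", "vl", [("per log10 copies/mL higher", "log10_vl")]),
    ("Hepatitis B or C coinfection", "hepatitis", [("No (ref)", None), ("Yes", "hepatitis")]),
    ("Time since cART initiation", "period", [
        (">6 to <=12 months (ref)", None),
        (">12 to <=18 months", "period_12_18"),
        (">18 to <=24 months", "period_18_24"),
        (">24 or more months", "period_24plus"),
    ]),
    ("Initial cART containing NNRTI", "nnrti", [("No (ref)", None), ("Yes", "nnrti")]),
    ("Initial cART containing boosted PI", "boosted_pi", [("No (ref)", None), ("Yes", "boosted_pi")]),
    ("Initial cART containing abacavir", "abacavir", [("No (ref)", None), ("Yes", "abacavir")]),
]


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def _cells(fit: ModelFit | None, col: str | None) -> tuple[str, str, str]:
    if fit is None:
        return "", "", ""
    if col is None:
        return "0.0", "", ""
    coef = fit.coef
    if col not in coef:
        return "", "", ""
    j = fit.names.index(col)
    est = f"{fit.beta[j]:.1f}"
    ci = f"({fit.ci95_low[j]:.1f}, {fit.ci95_high[j]:.1f})"
    return est, ci, _fmt_p(float(fit.wald_p[j]))


def report_table(
    univariate: dict[str, ModelFit] | None, final: ModelFit | None
) -> str:
    """Markdown table of coefficient estimates (cells/μL/yr), univariate and
    multivariate side by side, in the conventional covariate order."""
    univariate = univariate or {}
    lines = [
        "| Covariate | Univariate | (95% CI) | p | Multivariate | (95% CI) | p |",
        "|---|---|---|---|---|---|---|",
    ]
    for heading, term, rows in _REPORT_LAYOUT:
        lines.append(f"| **{heading}** |  |  |  |  |  |  |")
        uni = univariate.get(term)
        for label, col in rows:
            u = _cells(uni, col)
            m = _cells(final, col)
            lines.append(f"| {label} | {u[0]} | {u[1]} | {u[2]} | {m[0]} | {m[1]} | {m[2]} |")
    if final is not None:
        c = _cells(final, "const")
        lines.append(f"| Constant |  |  |  | {c[0]} | {c[1]} | {c[2]} |")
        if final.flags:
            lines.append("")
            lines.append(f"Notes: {'; '.join(final.flags)}")
    return "\n".join(lines) + "\n"
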