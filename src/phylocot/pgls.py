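"""Phylogenetic generalised least squares with ML Pagel's lambda.

PGLS regresses a single value per species on covariates under residual
covariance sigma² · C_lambda, where C_lambda is the phylogenetic covariance
with off-diagonals scaled by lambda in [0, 1].  lambda is estimated by
profiling the (by default ML) log-likelihood over a 0.01 grid on [0, 1]
followed by a bounded golden-section refinement — the profile is often flat
or multimodal at small n, so a grid is safer than unconstrained descent.
At lambda = 0 the fit reduces to OLS; at lambda = 1 it is plain GLS on the
untransformed tree covariance.

The module also derives the aerobic-scope variables used in the
eco-physiological battery (AAS = MMR − BMR, FAS = MMR / BMR,
AMR = FMR − BMR) and runs a one-covariate-at-a-time battery of models
log10(NCOT) ~ log10(mass) + covariate with listwise deletion per model and
no multiple-comparison correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import PhyloCovariance, lambda_transform

log = logging.getLogger(__name__)

__all__ = [
    "PGLSFit",
    "ECO_COVARIATES",
    "derive_eco_variables",
    "pgls_fit",
    "run_battery",
]

#: Battery covariates: (column, pretty label, log10-transform?).  Binary or
#: ordinal codes (terrestriality, diet breadth, trophic level, habitat
#: breadth) enter untransformed.
ECO_COVARIATES: list[tuple[str, str, bool]] = [
    ("home_range", "Log(Home range), km^2", True),
    ("dmd", "Log(DMD), km", True),
    ("geographic_range", "Log(Geographic range), km^2", True),
    ("group_size", "Log(Group size), individuals", True),
    ("terrestriality", "Terrestriality", False),
    ("diet_breadth", "Diet breadth", False),
    ("trophic_level", "Trophic level", False),
    ("habitat_breadth", "Habitat breadth", False),
    ("bmr", "Log(BMR), mlO2 h^-1", True),
    ("fmr", "Log(FMR), mlO2 h^-1", True),
    ("mmr", "Log(MMR), mlO2 h^-1", True),
    ("amr", "Log(AMR), mlO2 h^-1", True),
    ("fas", "Log(FAS)", True),
    ("aas", "Log(AAS)", True),
    ("max_speed", "Log(Max. running speed), km h^-1", True),
    ("fat", "Log(fat), g", True),
]


def derive_eco_variables(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the derived aerobic-scope columns of a species-level eco table.

    AAS = MMR − BMR, FAS = MMR / BMR and AMR = FMR − BMR are computed from
    the metabolic-rate columns (all mlO₂ h⁻¹); a derived value whose input
    is missing stays missing, and FAS with BMR = 0 is set missing with a
    warning rather than infinite.
    """
    out = table.copy()
    bmr = out.get("bmr")
    mmr = out.get("mmr")
    fmr = out.get("fmr")
    nan = pd.Series(np.nan, index=out.index)
    bmr = nan if bmr is None else pd.to_numeric(bmr, errors="coerce")
    mmr = nan if mmr is None else pd.to_numeric(mmr, errors="coerce")
    fmr = nan if fmr is None else pd.to_numeric(fmr, errors="coerce")
    out["aas"] = mmr - bmr
    with np.errstate(divide="ignore", invalid="ignore"):
        fas = mmr / bmr
    bad = bmr == 0
    if bad.any() and mmr.notna().any():
        log.warning("BMR = 0 for %d species; FAS set missing", int(bad.sum()))
    out["fas"] = fas.where(~bad)
    out["amr"] = fmr - bmr
    return out


@dataclass
class PGLSFit:
    """PGLS estimates at the ML value of Pagel's lambda."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lam: float
    loglik: float
    n: int
    df_resid: int
    method: str
    lam_grid: np.ndarray
    lam_profile: np.ndarray

    def summary_row(self, term: str) -> dict:
        return {
            "estimate": float(self.params[term]),
            "se": float(self.se[term]),
            "t": float(self.tvalues[term]),
            "p": float(self.pvalues[term]),
            "lambda": float(self.lam),
            "n": self.n,
        }


def _gls_loglik(y: np.ndarray, X: np.ndarray, Cl: np.ndarray, method: str):
    n, p = X.shape
    cho = linalg.cho_factor(Cl, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    Ci_X = linalg.cho_solve(cho, X)
    Ci_y = linalg.cho_solve(cho, y)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    r = y - X @ beta
    quad = float(r @ linalg.cho_solve(cho, r))
    if method == "ML":
        s2 = quad / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    else:  # REML
        s2 = quad / (n - p)
        sign, logdetXtCiX = np.linalg.slogdet(XtCiX)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * s2)
            + logdet
            + logdetXtCiX
            - np.linalg.slogdet(X.T @ X)[1]
            + (n - p)
        )
    return ll, beta, XtCiX, quad


def pgls_fit(
    y: pd.Series,
    X: pd.DataFrame,
    C: PhyloCovariance,
    *,
    method: str = "ML",
    lam: float | None = None,
) -> PGLSFit:
    """Fit response-per-species GLS with Pagel's lambda profiled on [0, 1].

    ``y`` is indexed by species (one value each); ``X`` shares that index
    and should include an intercept column.  ``lam`` fixes lambda instead
    of estimating it.  Coefficient SEs use the residual-variance estimate
    with n − p df; t and two-sided p follow.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    species = list(y.index)
    if len(set(species)) != len(species):
        raise ValueError("PGLS needs exactly one value per species")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"too few complete species ({n}) for {p} coefficients")
    Csub = C.submatrix(species)
    Csub.ensure_psd()
    Xm = X.to_numpy(float)
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError("rank-deficient design matrix")
    yv = y.to_numpy(float)

    def nll(l_):
        Cl = lambda_transform(Csub, l_).matrix
        try:
            return -_gls_loglik(yv, Xm, Cl, method)[0]
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            return np.inf

    if lam is None:
        grid = np.linspace(0.0, 1.0, 101)
        prof = np.array([-nll(l_) for l_ in grid])
        best = int(np.argmax(prof))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        lam_hat = float(res.x) if -res.fun >= prof[best] else float(grid[best])
    else:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        grid = np.array([lam])
        prof = np.array([-nll(lam)])
        lam_hat = float(lam)

    Cl = lambda_transform(Csub, lam_hat).matrix
    ll, beta, XtCiX, quad = _gls_loglik(yv, Xm, Cl, method)
    s2 = quad / (n - p)  # unbiased residual variance for the Wald table
    cov = s2 * np.linalg.inv(XtCiX)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    cols = list(X.columns)
    return PGLSFit(
        params=pd.Series(beta, index=cols),
        se=pd.Series(se, index=cols),
        tvalues=pd.Series(tvals, index=cols),
        pvalues=pd.Series(pvals, index=cols),
        lam=lam_hat,
        loglik=float(ll),
        n=n,
        df_resid=n - p,
        method=method,
        lam_grid=grid,
        lam_profile=prof,
    )


def run_battery(
    table: pd.DataFrame,
    C: PhyloCovariance,
    covariates: list[tuple[str, str, bool]] | None = None,
    *,
    response: str = "ncot",
    mass: str = "mass",
    min_n: int = 5,
    method: str = "ML",
) -> pd.DataFrame:
    """One PGLS model per covariate: log10(response) ~ log10(mass) + covariate.

    ``table`` is species-level with a ``species`` column.  Covariates marked
    for log-transform are log10-ed (non-positive values become missing);
    species with any missing value are dropped listwise per model, so n
    varies by row as in real compilations.  Models with fewer than
    ``min_n`` complete species are skipped with a warning; a rank-deficient
    design fails only its own row.  No multiple-comparison correction is
    applied.  Returns a table with covariate, n, estimate, SE, t, P and
    lambda_ML, in input order.
    """
    covariates = ECO_COVARIATES if covariates is None else covariates
    rows = []
    for col, label, do_log in covariates:
        row = {"covariate": label, "column": col}
        if col not in table.columns:
            row.update(note="column absent; skipped")
            rows.append(row)
            continue
        sub = pd.DataFrame(
            {
                "species": table["species"],
                "y": pd.to_numeric(table[response], errors="coerce"),
                "mass": pd.to_numeric(table[mass], errors="coerce"),
                "x": pd.to_numeric(table[col], errors="coerce"),
            }
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            sub["y"] = np.log10(sub["y"].where(sub["y"] > 0))
            sub["mass"] = np.log10(sub["mass"].where(sub["mass"] > 0))
            if do_log:
                sub["x"] = np.log10(sub["x"].where(sub["x"] > 0))
        sub = sub.dropna()
        sub = sub[sub["species"].isin(C.taxa)]
        if len(sub) < min_n:
            log.warning("covariate %s: only %d complete species; skipped", col, len(sub))
            row.update(n=len(sub), note="too few complete species; skipped")
            rows.append(row)
            continue
        y = pd.Series(sub["y"].to_numpy(), index=sub["species"].to_list())
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "log_mass": sub["mass"].to_numpy(),
                col: sub["x"].to_numpy(),
            },
            index=y.index,
        )
        try:
            fit = pgls_fit(y, X, C, method=method)
        except (ValueError, np.linalg.LinAlgError) as exc:
            row.update(n=len(sub), note=f"model failed: {exc}")
            rows.append(row)
            continue
        row.update(
            n=fit.n,
            estimate=fit.params[col],
            se=fit.se[col],
            t=fit.tvalues[col],
            p=fit.pvalues[col],
            lambda_ml=fit.lam,
            note="",
        )
        rows.append(row)
    return pd.DataFrame(rows)
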