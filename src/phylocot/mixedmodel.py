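"""REML phylogenetic mixed models (the comparative "animal model").

The observation vector y (long format over one or two traits) is modelled as

    y ~ N(X beta, V),   V = sum_i theta_i * G_i,

a linear covariance structure whose components are

* a phylogenetic random effect per species (and per trait in the bivariate
  model) with covariance Sigma_P kron A, where A is the Grafen-normalised
  relatedness matrix (diagonal 1) from the phylo module;
* an optional species-identity effect (univariate models only) capturing
  consistent among-species differences unrelated to phylogeny;
* residuals, with a separate variance per trait; the between-trait residual
  covariance is only estimable when observational units carry both traits,
  so by default it is fixed at zero (trait-disjoint data) and an explicit
  paired mode exists for frames whose rows share ``obs_id`` across traits.

Estimation is REML by bounded quasi-Newton on a log-variance /
tanh-correlation parameterisation with a fixed list of deterministic
multistarts, using analytic gradients.  Because V is linear in the
parameters, the expected information, Kenward–Roger adjusted F-tests and
delta-method standard errors all have closed forms.

Derived summaries follow quantitative-genetics conventions: phylogenetic
heritability h² = sigma²_phylo / total (the mixed-model analogue of Pagel's
lambda), the phylogenetic correlation r = c_P / sqrt(sigma²_P1 sigma²_P2),
chi-square likelihood-ratio tests for (co)variance components, and BLUPs of
the species-level phylogenetic effects for visualisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import PhyloCovariance

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "TestResult",
    "reml_fit",
    "h2",
    "species_fraction",
    "phylo_correlation",
    "lrt_component",
    "fixed_effect_tests",
    "blups",
]

FIXED_TERMS = ("intercept", "logM", "logU", "logM:logU")
_BOUNDARY_TOL = 1e-7


@dataclass(frozen=True)
class ModelSpec:
    """Which traits, fixed effects and random effects to fit.

    ``traits`` holds 1 or 2 trait labels matching the model frame's
    ``trait`` column.  ``fixed`` lists design terms from
    ``("intercept", "logM", "logU", "logM:logU")``, applied to every trait.
    The species-identity effect is only available univariately (with two
    traits there is not enough replication to separate it from phylogeny).
    ``phylo_covariance=False`` fixes the between-trait phylogenetic
    covariance c_P at zero (the constrained model of the LRT);
    ``residual_covariance=True`` estimates a between-trait residual
    covariance for rows paired via ``obs_id``.
    """

    traits: tuple[str, ...]
    fixed: tuple[str, ...] = ("intercept", "logM", "logU")
    phylo: bool = True
    species_effect: bool = False
    phylo_covariance: bool = True
    residual_covariance: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.traits) <= 2:
            raise ValueError("1 or 2 traits required")
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("duplicate trait")
        if self.species_effect and len(self.traits) == 2:
            raise ValueError("species identity effect is univariate-only")
        unknown = set(self.fixed) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms: {sorted(unknown)}")

    @property
    def bivariate(self) -> bool:
        return len(self.traits) == 2


@dataclass
class TestResult:
    """A single hypothesis test: statistic, reference distribution, p."""

    statistic: float
    distribution: str  # "chi2" or "F"
    df: tuple[float, ...]
    p_value: float
    description: str = ""


def _term_column(term: str, frame: pd.DataFrame) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(frame))
    if term == "logM:logU":
        return (frame["logM"] * frame["logU"]).to_numpy(float)
    return frame[term].to_numpy(float)


class _Problem:
    """Design matrices and covariance structure for one model fit.

    Precomputes the structure matrices G_i so that V(theta) = sum theta_i G_i
    is a cheap linear combination during optimisation.
    """

    def __init__(
        self,
        spec: ModelSpec,
        frame: pd.DataFrame,
        C: PhyloCovariance,
        reml: bool = True,
    ) -> None:
        self.spec = spec
        self.reml = reml
        frame = frame[frame["trait"].isin(spec.traits)].reset_index(drop=True)
        if frame.empty:
            raise ValueError("no observations for requested traits")
        present = [s for s in C.taxa if s in set(frame["species"])]
        missing = sorted(set(frame["species"]) - set(C.taxa))
        if missing:
            raise ValueError(f"species absent from covariance matrix: {', '.join(missing)}")
        self.species = present
        self.C = C.submatrix(present)
        self.C.ensure_psd()
        self.A = self.C.matrix
        self.frame = frame
        self.n = len(frame)
        self.y = frame["y"].to_numpy(float)
        sp_index = {s: k for k, s in enumerate(present)}
        self.z = frame["species"].map(sp_index).to_numpy(int)
        self.t = frame["trait"].map({tr: k for k, tr in enumerate(spec.traits)}).to_numpy(int)

        cols = []
        names = []
        for ti, trait in enumerate(spec.traits):
            mask = (self.t == ti).astype(float)
            for term in spec.fixed:
                cols.append(_term_column(term, frame) * mask)
                names.append(f"{trait}:{term}" if spec.bivariate else term)
        self.X = np.column_stack(cols)
        self.beta_names = names
        self.p = self.X.shape[1]
        if np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("fixed-effect design matrix is rank deficient")

        # structure matrices, all linear in their parameters
        Aobs = self.A[np.ix_(self.z, self.z)]
        same_species = (self.z[:, None] == self.z[None, :]).astype(float)
        self.structures: list[np.ndarray] = []
        self.comp_names: list[str] = []
        self.comp_kind: list[str] = []  # "var" | "cov"
        if not spec.bivariate:
            if spec.phylo:
                self._add("phylo", "var", Aobs)
            if spec.species_effect:
                self._add("species", "var", same_species)
            self._add("resid", "var", np.eye(self.n))
        else:
            t1 = (self.t == 0).astype(float)
            t2 = (self.t == 1).astype(float)
            if spec.phylo:
                self._add("phylo_1", "var", Aobs * np.outer(t1, t1))
                self._add("phylo_2", "var", Aobs * np.outer(t2, t2))
                if spec.phylo_covariance:
                    self._add(
                        "phylo_cov", "cov", Aobs * (np.outer(t1, t2) + np.outer(t2, t1))
                    )
            self._add("resid_1", "var", np.diag(t1))
            self._add("resid_2", "var", np.diag(t2))
            if spec.residual_covariance:
                obs = frame["obs_id"].to_numpy()
                paired = (obs[:, None] == obs[None, :]) & (self.t[:, None] != self.t[None, :])
                if not paired.any():
                    raise ValueError(
                        "residual_covariance requested but no rows share obs_id across traits"
                    )
                self._add("resid_cov", "cov", paired.astype(float))
        self.k = len(self.structures)
        # map each covariance parameter to its two parent variances
        self.cov_parents: dict[int, tuple[int, int]] = {}
        for i, name in enumerate(self.comp_names):
            if name == "phylo_cov":
                self.cov_parents[i] = (
                    self.comp_names.index("phylo_1"),
                    self.comp_names.index("phylo_2"),
                )
            elif name == "resid_cov":
                self.cov_parents[i] = (
                    self.comp_names.index("resid_1"),
                    self.comp_names.index("resid_2"),
                )
        self.logdetXtX = np.linalg.slogdet(self.X.T @ self.X)[1]
        # per-trait response variance, used to scale starting values
        self.scale = np.array(
            [max(np.var(self.y[self.t == ti]), 1e-8) for ti in range(len(spec.traits))]
        )

    def _add(self, name: str, kind: str, G: np.ndarray) -> None:
        self.comp_names.append(name)
        self.comp_kind.append(kind)
        self.structures.append(G)

    # -- parameter transforms ------------------------------------------------
    # free vector z: log(sigma2) for variances, atanh(rho) for covariances

    def theta_from_z(self, zv: np.ndarray) -> np.ndarray:
        theta = np.empty(self.k)
        for i in range(self.k):
            if self.comp_kind[i] == "var":
                theta[i] = np.exp(zv[i])
        for i, (a, b) in self.cov_parents.items():
            theta[i] = np.tanh(zv[i]) * np.sqrt(theta[a] * theta[b])
        return theta

    def jacobian(self, zv: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """d theta / d z (k x k)."""
        J = np.zeros((self.k, self.k))
        for i in range(self.k):
            if self.comp_kind[i] == "var":
                J[i, i] = theta[i]
        for i, (a, b) in self.cov_parents.items():
            rho = np.tanh(zv[i])
            s = np.sqrt(theta[a] * theta[b])
            J[i, i] = (1.0 - rho**2) * s
            J[i, a] = 0.5 * theta[i]  # via dtheta_a/dz_a = theta_a
            J[i, b] = 0.5 * theta[i]
        return J

    # -- likelihood ----------------------------------------------------------

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for th, G in zip(theta, self.structures):
            V += th * G
        return V

    def _factor(self, theta: np.ndarray):
        V = self.build_V(theta)
        jit = 0.0
        for jit in (0.0, 1e-10, 1e-8):
            try:
                cho = linalg.cho_factor(V + jit * np.eye(self.n), lower=True)
                break
            except linalg.LinAlgError:
                cho = None
        if cho is None:
            return None
        logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Vinv = linalg.cho_solve(cho, np.eye(self.n))
        return V, Vinv, logdetV

    def nll_grad(self, zv: np.ndarray) -> tuple[float, np.ndarray]:
        theta = self.theta_from_z(zv)
        fac = self._factor(theta)
        if fac is None:
            return 1e10, np.zeros_like(zv)
        _, Vinv, logdetV = fac
        XtVi = self.X.T @ Vinv
        XtViX = XtVi @ self.X
        try:
            Phi = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(zv)
        beta = Phi @ (XtVi @ self.y)
        r = self.y - self.X @ beta
        Vir = Vinv @ r
        quad = float(r @ Vir)
        if self.reml:
            sign, logdetXtViX = np.linalg.slogdet(XtViX)
            nll = 0.5 * (
                (self.n - self.p) * np.log(2 * np.pi)
                + logdetV
                + logdetXtViX
                - self.logdetXtX
                + quad
            )
            # P = Vinv - Vinv X Phi X' Vinv ; Py = Vir for r built from GLS beta
            PX = XtVi.T @ Phi  # n x p
            g_theta = np.empty(self.k)
            for i, G in enumerate(self.structures):
                trPG = np.sum(Vinv * G) - np.sum((XtVi @ G) * PX.T)
                g_theta[i] = 0.5 * (trPG - Vir @ G @ Vir)
        else:
            nll = 0.5 * (self.n * np.log(2 * np.pi) + logdetV + quad)
            g_theta = np.empty(self.k)
            for i, G in enumerate(self.structures):
                g_theta[i] = 0.5 * (np.sum(Vinv * G) - Vir @ G @ Vir)
        J = self.jacobian(zv, theta)
        return float(nll), J.T @ g_theta

    # -- starting values -----------------------------------------------------

    def starts(self, n_starts: int) -> list[np.ndarray]:
        """Deterministic multistart list: variance-fraction patterns."""
        patterns = [
            (1 / 3, 1 / 3, 1 / 3),
            (0.05, 0.05, 0.90),
            (0.80, 0.10, 0.10),
            (0.10, 0.80, 0.10),
            (0.45, 0.45, 0.10),
        ][:n_starts]
        rhos = [0.0, 0.0, 0.5, -0.5, 0.0]
        out = []
        for pat, rho in zip(patterns, rhos):
            zv = np.empty(self.k)
            for i, name in enumerate(self.comp_names):
                if self.comp_kind[i] == "cov":
                    zv[i] = np.arctanh(rho)
                    continue
                if name.startswith("phylo"):
                    frac = pat[0]
                elif name.startswith("species"):
                    frac = pat[1]
                else:
                    frac = pat[2]
                ti = 0
                if name.endswith("_2"):
                    ti = 1
                zv[i] = np.log(max(frac, 1e-4) * self.scale[ti])
            out.append(zv)
        return out

    # -- post-fit quantities -------------------------------------------------

    def expected_information(self, theta: np.ndarray) -> np.ndarray:
        """REML expected information for the natural (variance-scale) params."""
        fac = self._factor(theta)
        if fac is None:
            raise np.linalg.LinAlgError("V not positive definite at the estimate")
        _, Vinv, _ = fac
        XtVi = self.X.T @ Vinv
        Phi = np.linalg.inv(XtVi @ self.X)
        P = Vinv - XtVi.T @ Phi @ XtVi
        PG = [P @ G for G in self.structures]
        info = np.empty((self.k, self.k))
        for i in range(self.k):
            for j in range(i, self.k):
                info[i, j] = info[j, i] = 0.5 * np.sum(PG[i] * PG[j].T)
        return info


@dataclass
class MixedModelFit:
    """REML (or ML) fit of a phylogenetic mixed model."""

    spec: ModelSpec
    beta: pd.Series
    beta_cov: pd.DataFrame
    varcomps: pd.Series
    varcomp_cov: pd.DataFrame
    loglik: float
    reml: bool
    converged: bool
    n_obs: int
    n_species: int
    species: list[str]
    boundary: list[str] = field(default_factory=list)
    non_identifiable: bool = False
    message: str = ""
    n_starts_used: int = 0
    _problem: _Problem | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        """Human-readable fit table: fixed effects then variance components."""
        lines = [
            f"Phylogenetic mixed model ({'REML' if self.reml else 'ML'}), "
            f"traits: {', '.join(self.spec.traits)}",
            f"n = {self.n_obs} observations, {self.n_species} species; "
            f"logL = {self.loglik:.3f}",
            "",
            f"{'Term':<28}{'Estimate':>10}{'SE':>10}",
        ]
        for name in self.beta.index:
            se = float(np.sqrt(self.beta_cov.loc[name, name]))
            lines.append(f"{name:<28}{self.beta[name]:>10.4f}{se:>10.4f}")
        lines.append("")
        for name in self.varcomps.index:
            se = float(np.sqrt(max(self.varcomp_cov.loc[name, name], 0.0)))
            flag = " (boundary)" if name in self.boundary else ""
            lines.append(f"{name:<28}{self.varcomps[name]:>10.4f}{se:>10.4f}{flag}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (estimates, components, diagnostics)."""
        return {
            "traits": list(self.spec.traits),
            "fixed": list(self.spec.fixed),
            "beta": {k: float(v) for k, v in self.beta.items()},
            "beta_se": {
                k: float(np.sqrt(self.beta_cov.loc[k, k])) for k in self.beta.index
            },
            "varcomps": {k: float(v) for k, v in self.varcomps.items()},
            "varcomp_se": {
                k: float(np.sqrt(max(self.varcomp_cov.loc[k, k], 0.0)))
                for k in self.varcomps.index
            },
            "loglik": float(self.loglik),
            "reml": self.reml,
            "converged": self.converged,
            "boundary": list(self.boundary),
            "non_identifiable": self.non_identifiable,
            "n_obs": self.n_obs,
            "n_species": self.n_species,
        }


def reml_fit(
    spec: ModelSpec,
    frame: pd.DataFrame,
    C: PhyloCovariance,
    *,
    reml: bool = True,
    n_starts: int = 5,
    extra_starts: list[np.ndarray] | None = None,
    maxiter: int = 500,
) -> MixedModelFit:
    """Fit the mixed model by REML (default) or ML.

    Runs a fixed list of deterministic multistarts of L-BFGS-B with
    analytic gradients and keeps the best optimum; fixed effects come from
    GLS at the variance estimates.  Variances that end within tolerance of
    the zero boundary are reported as 0 and flagged (their SEs are
    unreliable).  Raises on non-convergence of every start.
    """
    prob = _Problem(spec, frame, C, reml=reml)
    starts = prob.starts(n_starts)
    if extra_starts:
        starts = starts + [np.asarray(s, float) for s in extra_starts]
    lo = np.log(prob.scale.min()) - 18.0
    hi = np.log(prob.scale.max()) + 6.0
    bounds = [
        (lo, hi) if kind == "var" else (-6.0, 6.0) for kind in prob.comp_kind
    ]
    best = None
    any_ok = False
    for zv0 in starts:
        res = optimize.minimize(
            prob.nll_grad,
            np.clip(zv0, [b[0] for b in bounds], [b[1] for b in bounds]),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-6},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("mixed model failed to converge from any start")
    if not any_ok:
        log.warning("no optimizer start reported formal convergence: %s", best.message)
    theta = prob.theta_from_z(best.x)

    fac = prob._factor(theta)
    _, Vinv, _ = fac
    XtVi = prob.X.T @ Vinv
    Phi = np.linalg.inv(XtVi @ prob.X)
    beta = Phi @ (XtVi @ prob.y)

    boundary = [
        name
        for name, kind, th, sc in zip(
            prob.comp_names, prob.comp_kind, theta, prob.scale[[0] * prob.k]
        )
        if kind == "var" and th < _BOUNDARY_TOL * prob.scale.max()
    ]
    theta_rep = theta.copy()
    for i, name in enumerate(prob.comp_names):
        if name in boundary:
            theta_rep[i] = 0.0

    non_ident = False
    try:
        info = prob.expected_information(theta)
        if np.linalg.cond(info) > 1e10:
            # e.g. phylogeny + species identity on a star tree: the two
            # variance components enter V identically and only their sum
            # is estimable
            non_ident = True
            log.warning(
                "expected information is singular: variance components are "
                "not separately identifiable (profile likelihood flat)"
            )
        W = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        W = np.full((prob.k, prob.k), np.nan)
        non_ident = True
    names = prob.comp_names
    fit = MixedModelFit(
        spec=spec,
        beta=pd.Series(beta, index=prob.beta_names),
        beta_cov=pd.DataFrame(Phi, index=prob.beta_names, columns=prob.beta_names),
        varcomps=pd.Series(theta_rep, index=names),
        varcomp_cov=pd.DataFrame(W, index=names, columns=names),
        loglik=-float(best.fun),
        reml=reml,
        converged=bool(any_ok),
        n_obs=prob.n,
        n_species=len(prob.species),
        species=list(prob.species),
        boundary=boundary,
        non_identifiable=non_ident,
        message=str(best.message),
        n_starts_used=len(starts),
        _problem=prob,
        _theta=theta,
    )
    if boundary:
        log.info("variance components at zero boundary: %s", boundary)
    return fit


def _delta_se(fit: MixedModelFit, grad: dict[str, float]) -> float:
    names = list(fit.varcomps.index)
    g = np.array([grad.get(n, 0.0) for n in names])
    W = fit.varcomp_cov.to_numpy()
    var = float(g @ W @ g)
    return float(np.sqrt(var)) if var >= 0 and np.isfinite(var) else np.nan


def h2(fit: MixedModelFit) -> tuple[float, float]:
    """Phylogenetic heritability: variance fraction of the phylogeny effect.

    h² = sigma²_phylo / (sigma²_phylo + sigma²_species + sigma²_resid),
    conditional on the fixed effects; SE by the first-order delta method on
    the inverse expected REML information (the mixed-model analogue of the
    'pin' calculation).  Univariate fits only.
    """
    if fit.spec.bivariate or not fit.spec.phylo:
        raise ValueError("h2 needs a univariate fit with a phylogeny effect")
    vp = fit.varcomps["phylo"]
    vs = fit.varcomps.get("species", 0.0)
    vr = fit.varcomps["resid"]
    tot = vp + vs + vr
    if tot <= 0:
        raise ZeroDivisionError("total variance is zero; h2 undefined")
    est = vp / tot
    grad = {"phylo": (tot - vp) / tot**2, "species": -vp / tot**2, "resid": -vp / tot**2}
    return float(est), _delta_se(fit, grad)


def species_fraction(fit: MixedModelFit) -> tuple[float, float]:
    """Fraction of conditional variance from species identity (non-phylogenetic)."""
    if fit.spec.bivariate or not fit.spec.species_effect:
        raise ValueError("species_fraction needs a univariate fit with a species effect")
    vp = fit.varcomps.get("phylo", 0.0)
    vs = fit.varcomps["species"]
    vr = fit.varcomps["resid"]
    tot = vp + vs + vr
    if tot <= 0:
        raise ZeroDivisionError("total variance is zero")
    est = vs / tot
    grad = {"species": (tot - vs) / tot**2, "phylo": -vs / tot**2, "resid": -vs / tot**2}
    return float(est), _delta_se(fit, grad)


def phylo_correlation(fit: MixedModelFit) -> tuple[float, float]:
    """Between-trait phylogenetic correlation r = c_P / sqrt(v_P1 v_P2).

    Undefined (NaN, flagged via the fit's boundary list) when either
    phylogenetic variance sits on the zero boundary.
    """
    if not fit.spec.bivariate or not fit.spec.phylo_covariance:
        raise ValueError("phylo_correlation needs a bivariate fit with free c_P")
    v1 = fit.varcomps["phylo_1"]
    v2 = fit.varcomps["phylo_2"]
    c = fit.varcomps["phylo_cov"]
    if "phylo_1" in fit.boundary or "phylo_2" in fit.boundary or v1 <= 0 or v2 <= 0:
        log.warning("phylogenetic variance at boundary; correlation undefined")
        return np.nan, np.nan
    r = c / np.sqrt(v1 * v2)
    grad = {
        "phylo_cov": 1.0 / np.sqrt(v1 * v2),
        "phylo_1": -r / (2 * v1),
        "phylo_2": -r / (2 * v2),
    }
    return float(r), _delta_se(fit, grad)


_CONSTRAIN = {
    "phylo": dict(phylo=False),
    "species": dict(species_effect=False),
    "phylo_cov": dict(phylo_covariance=False),
    "resid_cov": dict(residual_covariance=False),
}


def lrt_component(
    spec: ModelSpec,
    frame: pd.DataFrame,
    C: PhyloCovariance,
    component: str,
    *,
    fits: tuple[MixedModelFit, MixedModelFit] | None = None,
    **fit_kwargs,
) -> TestResult:
    """Likelihood-ratio test that one (co)variance component is zero.

    Fits the model with and without ``component`` (one of ``phylo``,
    ``species``, ``phylo_cov``, ``resid_cov``) and refers
    2·(logL_full − logL_reduced) to chi-square with 1 df — the plain
    reference distribution, with no boundary mixture correction.  If the
    full model's likelihood falls below the reduced one, the full model is
    refitted with the reduced optimum added as an extra start.
    """
    if component not in _CONSTRAIN:
        raise ValueError(f"unknown component {component!r}")
    if fits is not None:
        full, reduced = fits
    else:
        full = reml_fit(spec, frame, C, **fit_kwargs)
        reduced = reml_fit(replace(spec, **_CONSTRAIN[component]), frame, C, **fit_kwargs)
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        # full model stuck in a worse optimum: restart from the reduced solution
        prob_r = reduced._problem
        zmap = dict(zip(prob_r.comp_names, np.log(np.maximum(reduced.varcomps.values, 1e-12))))
        prob_f = _Problem(spec, frame, C)
        z0 = np.array(
            [
                zmap.get(n, 0.0 if k == "cov" else np.log(prob_f.scale.max() * 1e-3))
                for n, k in zip(prob_f.comp_names, prob_f.comp_kind)
            ]
        )
        full = reml_fit(spec, frame, C, extra_starts=[z0], **fit_kwargs)
        stat = 2.0 * (full.loglik - reduced.loglik)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(
        statistic=float(stat),
        distribution="chi2",
        df=(1.0,),
        p_value=p,
        description=f"LRT: {component} = 0",
    )


def _kr_pieces(fit: MixedModelFit):
    prob = fit._problem
    theta = fit._theta
    fac = prob._factor(theta)
    _, Vinv, _ = fac
    XtVi = prob.X.T @ Vinv
    Phi = np.linalg.inv(XtVi @ prob.X)
    W = fit.varcomp_cov.to_numpy()
    Pmats = []  # P_i = X' Vinv G_i Vinv X
    Qmats = {}  # Q_ij = X' Vinv G_i Vinv G_j Vinv X
    VG = [Vinv @ G for G in prob.structures]
    XtViG = [XtVi @ G for G in prob.structures]  # p x n
    for i in range(prob.k):
        Pmats.append(XtViG[i] @ XtVi.T)
    for i in range(prob.k):
        for j in range(prob.k):
            Qmats[(i, j)] = XtViG[i] @ (VG[j] @ XtVi.T)
    return prob, Phi, W, Pmats, Qmats


def fixed_effect_tests(fit: MixedModelFit, method: str = "kenward-roger") -> list[TestResult]:
    """Wald-type conditional F-tests for each fixed-effect term.

    Default is the Kenward–Roger small-sample method: the covariance of the
    fixed effects is inflated for the uncertainty of the variance estimates
    and the denominator degrees of freedom solved from the first two
    moments of the scaled F statistic.  Because V is linear in the
    parameters the KR second-derivative terms vanish and the adjustment is
    exact to first order.  ``method="satterthwaite"`` gives the simpler
    Satterthwaite df on the unadjusted covariance (flagged in the output
    description).
    """
    if method not in ("kenward-roger", "satterthwaite"):
        raise ValueError("method must be 'kenward-roger' or 'satterthwaite'")
    prob, Phi, W, Pmats, Qmats = _kr_pieces(fit)
    if not np.all(np.isfinite(W)):
        raise np.linalg.LinAlgError("singular information matrix; cannot compute df")
    k = prob.k
    p = prob.p
    beta = fit.beta.to_numpy()

    if method == "kenward-roger":
        M = np.zeros((p, p))
        for i in range(k):
            for j in range(k):
                M += W[i, j] * (Qmats[(i, j)] - Pmats[i] @ Phi @ Pmats[j])
        Phi_A = Phi + 2.0 * Phi @ M @ Phi
    else:
        Phi_A = Phi

    out: list[TestResult] = []
    for idx, name in enumerate(prob.beta_names):
        L = np.zeros((1, p))
        L[0, idx] = 1.0
        LPhiL = float((L @ Phi @ L.T).item())
        Fstat = float(((L @ beta) ** 2).item() / (L @ Phi_A @ L.T).item())
        if method == "satterthwaite":
            d = np.array([(L @ Phi @ Pmats[i] @ Phi @ L.T).item() for i in range(k)])
            denom = float(d @ W @ d)
            ddf = 2.0 * LPhiL**2 / denom if denom > 0 else float(prob.n - p)
            pval = float(stats.f.sf(Fstat, 1, ddf))
            out.append(
                TestResult(Fstat, "F", (1.0, float(ddf)), pval, f"{name} (satterthwaite)")
            )
            continue
        # KR moment matching (rank-1 contrast)
        Theta = L.T @ np.linalg.inv(L @ Phi @ L.T) @ L
        TP = [Theta @ Phi @ Pmats[i] @ Phi for i in range(k)]
        tr1 = np.array([np.trace(M_) for M_ in TP])
        A1 = float(tr1 @ W @ tr1)
        A2 = 0.0
        for i in range(k):
            for j in range(k):
                A2 += W[i, j] * np.trace(TP[i] @ TP[j])
        ell = 1.0
        denomA2 = max(A2, 1e-300)
        g = ((ell + 1) * A1 - (ell + 4) * A2) / ((ell + 2) * denomA2)
        c1 = g / (3 * ell + 2 * (1 - g))
        c2 = (ell - g) / (3 * ell + 2 * (1 - g))
        c3 = (ell + 2 - g) / (3 * ell + 2 * (1 - g))
        B = (A1 + 6 * A2) / (2 * ell)
        Estar = 1.0 / (1.0 - A2 / ell) if A2 < ell else np.inf
        Vstar = (2.0 / ell) * (1 + c1 * B) / max((1 - c2 * B) ** 2 * (1 - c3 * B), 1e-300)
        rho = Vstar / (2.0 * Estar**2) if np.isfinite(Estar) else np.nan
        if not np.isfinite(rho) or ell * rho <= 1.0:
            ddf = float(prob.n - p)  # degenerate: fall back to residual df
            lam = 1.0
        else:
            ddf = 4.0 + (ell + 2.0) / (ell * rho - 1.0)
            lam = ddf / (Estar * (ddf - 2.0))
        Fscaled = lam * Fstat
        pval = float(stats.f.sf(Fscaled, 1, ddf))
        out.append(TestResult(float(Fscaled), "F", (1.0, float(ddf)), pval, name))
    return out


def blups(fit: MixedModelFit) -> pd.DataFrame:
    """BLUPs of the species-level phylogenetic effects, with prediction SEs.

    Solves the mixed-model prediction u_hat = Cov(u, y) V⁻¹ (y − X beta_hat)
    at the REML estimates; the SE is sqrt of the diagonal of
    Var(u_hat − u) = G − Cov(u, y) P Cov(u, y)ᵀ.  One row per species per
    trait.  All BLUPs are exactly zero when the phylogenetic variance is 0.
    """
    if not fit.spec.phylo:
        raise ValueError("fit has no phylogenetic effect")
    prob = fit._problem
    theta = fit._theta
    ntr = len(fit.spec.traits)
    S = len(prob.species)
    vc = fit.varcomps
    if ntr == 1:
        Sigma_P = np.array([[vc["phylo"]]])
    else:
        c = vc.get("phylo_cov", 0.0)
        Sigma_P = np.array([[vc["phylo_1"], c], [c, vc["phylo_2"]]])
    A = prob.A
    G_latent = np.kron(Sigma_P, A)  # (ntr*S) x (ntr*S), trait-major
    # Cov(u, y): latent row (t, s), obs column o -> Sigma_P[t, t_o] * A[s, z_o]
    Mcov = np.empty((ntr * S, prob.n))
    for t_lat in range(ntr):
        block = Sigma_P[t_lat, prob.t][None, :] * A[:, prob.z]
        Mcov[t_lat * S : (t_lat + 1) * S, :] = block
    fac = prob._factor(theta)
    _, Vinv, _ = fac
    XtVi = prob.X.T @ Vinv
    Phi = np.linalg.inv(XtVi @ prob.X)
    beta = Phi @ (XtVi @ prob.y)
    r = prob.y - prob.X @ beta
    u = Mcov @ (Vinv @ r)
    P = Vinv - XtVi.T @ Phi @ XtVi
    pev = G_latent - Mcov @ P @ Mcov.T  # prediction error variance
    se = np.sqrt(np.maximum(np.diag(pev), 0.0))
    rows = []
    for t_lat, trait in enumerate(fit.spec.traits):
        for s, sp in enumerate(prob.species):
            k = t_lat * S + s
            rows.append(dict(species=sp, trait=trait, blup=u[k], se=se[k]))
    return pd.DataFrame(rows)
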