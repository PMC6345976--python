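import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space
from scipy.stats import multivariate_normal

from phylocot import mixedmodel as mm
from phylocot import pgls
from phylocot.mixedmodel import ModelSpec
from phylocot.phylo import grafen_branch_lengths, read_newick, vcv

from conftest import simulate_bivariate


def reml_oracle(y, X, V):
    """Independent REML criterion: MVN logpdf of an orthonormal error contrast.

    K spans null(X'); K'y ~ N(0, K'VK) carries exactly the information REML
    uses, computed via scipy's multivariate normal rather than the
    production log-determinant identity.
    """
    K = null_space(X.T)
    return float(
        multivariate_normal.logpdf(K.T @ y, mean=np.zeros(K.shape[1]), cov=K.T @ V @ K)
    )


class TestRemlCriterion:
    def test_intercept_only_sample_variance(self, cov4):
        """With no random effects, REML residual variance is the n-1 sample variance."""
        frame = pd.DataFrame(
            dict(
                obs_id=range(3),
                species=["A", "B", "C"],
                trait="logVO2",
                y=[1.0, 2.0, 3.0],
                logM=0.0,
                logU=0.0,
                source="s",
            )
        )
        spec = ModelSpec(traits=("logVO2",), fixed=("intercept",), phylo=False)
        fit = mm.reml_fit(spec, frame, cov4)
        assert fit.varcomps["resid"] == pytest.approx(1.0, rel=1e-5)

    @pytest.mark.parametrize("species_effect", [False, True])
    def test_criterion_matches_mvn_oracle_on_grid(self, cov4, toy_frame, species_effect):
        spec = ModelSpec(traits=("logVO2",), species_effect=species_effect)
        prob = mm._Problem(spec, toy_frame, cov4)
        grid = [0.05, 0.4, 1.5]
        for vp in grid:
            for vr in grid:
                theta = [vp, 0.3, vr] if species_effect else [vp, vr]
                nll, _ = prob.nll_grad(np.log(np.array(theta)))
                V = prob.build_V(np.array(theta))
                assert -nll == pytest.approx(
                    reml_oracle(prob.y, prob.X, V), abs=1e-8
                )

    def test_bivariate_criterion_matches_oracle(self):
        frame, C, _ = simulate_bivariate(3, n_species=6, n_obs=(6, 6))
        spec = ModelSpec(traits=("logVO2", "logInvTc"))
        prob = mm._Problem(spec, frame, C)
        for z in ([0.0, 0.0, 0.3, -1.0, -1.0], [-2.0, 1.0, -0.7, 0.5, -3.0]):
            theta = prob.theta_from_z(np.array(z))
            nll, _ = prob.nll_grad(np.array(z))
            V = prob.build_V(theta)
            assert -nll == pytest.approx(reml_oracle(prob.y, prob.X, V), abs=1e-8)

    def test_gls_limit_equals_ols(self, cov4, toy_frame):
        """All random variances at ~0: GLS fixed effects collapse to OLS."""
        spec = ModelSpec(traits=("logVO2",), species_effect=True)
        prob = mm._Problem(spec, toy_frame, cov4)
        theta = np.array([1e-12, 1e-12, 1.0])
        V = prob.build_V(theta)
        Vinv = np.linalg.inv(V)
        beta_gls = np.linalg.solve(prob.X.T @ Vinv @ prob.X, prob.X.T @ Vinv @ prob.y)
        beta_ols = np.linalg.lstsq(prob.X, prob.y, rcond=None)[0]
        assert np.allclose(beta_gls, beta_ols, atol=1e-10)

    def test_boundary_estimate_flagged(self, cov4):
        """Data simulated with zero phylogenetic variance ends at the boundary."""
        rng = np.random.default_rng(11)
        rows = []
        for sp in cov4.taxa:
            for _ in range(10):
                rows.append(
                    dict(
                        obs_id=len(rows),
                        species=sp,
                        trait="logVO2",
                        y=rng.normal(),
                        logM=rng.normal(),
                        logU=rng.normal(),
                        source="s",
                    )
                )
        frame = pd.DataFrame(rows)
        spec = ModelSpec(traits=("logVO2",))
        fit = mm.reml_fit(spec, frame, cov4)
        h2_est, _ = mm.h2(fit)
        assert h2_est <= 0.15
        if fit.varcomps["phylo"] == 0.0:
            assert "phylo" in fit.boundary


class TestInvariances:
    def test_response_shift_moves_only_intercept(self, cov4, toy_frame):
        spec = ModelSpec(traits=("logVO2",), species_effect=True)
        f1 = mm.reml_fit(spec, toy_frame, cov4)
        shifted = toy_frame.assign(y=toy_frame["y"] + 5.0)
        f2 = mm.reml_fit(spec, shifted, cov4)
        assert f2.beta["intercept"] == pytest.approx(f1.beta["intercept"] + 5.0, abs=1e-5)
        assert f2.beta["logM"] == pytest.approx(f1.beta["logM"], abs=1e-5)
        assert f2.beta["logU"] == pytest.approx(f1.beta["logU"], abs=1e-5)
        assert np.allclose(f2.varcomps, f1.varcomps, atol=1e-5)

    def test_covariate_rescale_rescales_coefficient(self, cov4, toy_frame):
        spec = ModelSpec(traits=("logVO2",), species_effect=True)
        f1 = mm.reml_fit(spec, toy_frame, cov4)
        scaled = toy_frame.assign(logM=2.0 * toy_frame["logM"])
        f2 = mm.reml_fit(spec, scaled, cov4)
        assert f2.beta["logM"] == pytest.approx(f1.beta["logM"] / 2.0, abs=1e-5)
        assert f2.beta["logU"] == pytest.approx(f1.beta["logU"], abs=1e-5)


class TestDerivedQuantities:
    def test_h2_definition(self):
        """h2 and species fraction are the variance ratios by definition."""
        frame, C, _ = simulate_bivariate(8, n_species=25)
        uni = frame[frame["trait"] == "logVO2"]
        spec = ModelSpec(traits=("logVO2",), species_effect=True)
        fit = mm.reml_fit(spec, uni, C)
        vp, vs, vr = (fit.varcomps[k] for k in ("phylo", "species", "resid"))
        est, se = mm.h2(fit)
        assert est == pytest.approx(vp / (vp + vs + vr), abs=1e-10)
        sf, _ = mm.species_fraction(fit)
        assert sf == pytest.approx(vs / (vp + vs + vr), abs=1e-10)
        assert est + sf + vr / (vp + vs + vr) == pytest.approx(1.0, abs=1e-8)
        assert np.isfinite(se) and se >= 0

    def test_phylo_correlation_definition(self):
        frame, C, _ = simulate_bivariate(9, n_species=40, phylo_corr=0.6,
                                         sigma2_phylo=(0.05, 0.05),
                                         sigma2_resid=(0.01, 0.01))
        spec = ModelSpec(traits=("logVO2", "logInvTc"))
        fit = mm.reml_fit(spec, frame, C)
        r, se = mm.phylo_correlation(fit)
        v1, v2, c = (fit.varcomps[k] for k in ("phylo_1", "phylo_2", "phylo_cov"))
        assert r == pytest.approx(c / np.sqrt(v1 * v2), abs=1e-10)
        assert abs(r) <= 1.0 and np.isfinite(se)

    def test_h2_matches_pgls_lambda_one_obs_per_species(self):
        """One observation per species, no species effect: mixed-model h2
        equals the restricted-likelihood Pagel's lambda estimate."""
        cfg_frame, C, _ = simulate_bivariate(
            21, n_species=60, n_obs=(60, 60),
            sigma2_phylo=(0.03, 0.03), sigma2_resid=(0.02, 0.02),
        )
        uni = cfg_frame[cfg_frame["trait"] == "logVO2"]
        assert uni["species"].nunique() == len(uni)
        spec = ModelSpec(traits=("logVO2",))
        fit = mm.reml_fit(spec, uni, C)
        h2_est, _ = mm.h2(fit)
        y = pd.Series(uni["y"].to_numpy(), index=uni["species"].to_numpy())
        X = pd.DataFrame(
            {"intercept": 1.0, "logM": uni["logM"].to_numpy(), "logU": uni["logU"].to_numpy()},
            index=y.index,
        )
        pfit = pgls.pgls_fit(y, X, C, method="REML")
        assert h2_est == pytest.approx(pfit.lam, abs=1e-4)


class TestLRT:
    def test_identical_models_statistic_zero(self, cov4, toy_frame):
        spec = ModelSpec(traits=("logVO2",), species_effect=True)
        fit = mm.reml_fit(spec, toy_frame, cov4)
        res = mm.lrt_component(spec, toy_frame, cov4, "species", fits=(fit, fit))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_reference_values(self):
        """Plain chi-square(1) reference: 0.69 -> 0.41, 14.7 -> <0.001."""
        from scipy.stats import chi2

        assert chi2.sf(0.69, 1) == pytest.approx(0.41, abs=0.005)
        assert chi2.sf(14.7, 1) < 0.001

    def test_lrt_detects_strong_covariance(self):
        frame, C, _ = simulate_bivariate(13, n_species=60, phylo_corr=0.9,
                                         sigma2_phylo=(0.05, 0.05),
                                         sigma2_resid=(0.005, 0.005))
        spec = ModelSpec(traits=("logVO2", "logInvTc"))
        res = mm.lrt_component(spec, frame, C, "phylo_cov", n_starts=3)
        assert res.statistic > 3.84 and res.p_value < 0.05


class TestFixedEffectTests:
    def test_kr_df_matches_classical_balanced_anova(self):
        """Balanced one-way layout with a random group effect: KR denominator
        df are the classical exact values (g-1 between, N-g-1 within)."""
        g, npg = 8, 5
        newick = "(" + ",".join(f"g{i}" for i in range(g)) + ");"
        C = vcv(grafen_branch_lengths(read_newick(newick)))
        rng = np.random.default_rng(3)
        rows = []
        for i in range(g):
            x = rng.normal(size=npg)
            x -= x.mean()
            a = rng.normal()
            for k in range(npg):
                rows.append(
                    dict(
                        obs_id=len(rows),
                        species=f"g{i}",
                        trait="logVO2",
                        y=2.0 + 0.5 * x[k] + a + rng.normal() * 0.7,
                        logM=x[k],
                        logU=0.0,
                        source="s",
                    )
                )
        frame = pd.DataFrame(rows)
        spec = ModelSpec(
            traits=("logVO2",), fixed=("intercept", "logM"), phylo=False, species_effect=True
        )
        fit = mm.reml_fit(spec, frame, C)
        tests = {t.description: t for t in mm.fixed_effect_tests(fit)}
        assert tests["intercept"].df[1] == pytest.approx(g - 1, abs=0.1)
        assert tests["logM"].df[1] == pytest.approx(g * npg - g - 1, abs=0.1)

    def test_null_term_f_near_zero(self, cov4, toy_frame):
        """A coefficient that is ~0 with positive SE yields F ~ 0, P ~ 1."""
        frame = toy_frame.copy()
        rng = np.random.default_rng(0)
        frame["y"] = rng.normal(size=len(frame))  # no dependence on logU
        spec = ModelSpec(traits=("logVO2",), fixed=("intercept", "logU"), phylo=False)
        fit = mm.reml_fit(spec, frame, cov4)
        test = [t for t in mm.fixed_effect_tests(fit) if t.description == "logU"][0]
        assert test.p_value > 0.2

    def test_satterthwaite_close_to_kr(self):
        frame, C, _ = simulate_bivariate(17, n_species=30)
        uni = frame[frame["trait"] == "logVO2"]
        spec = ModelSpec(traits=("logVO2",))
        fit = mm.reml_fit(spec, uni, C)
        kr = mm.fixed_effect_tests(fit, "kenward-roger")
        sat = mm.fixed_effect_tests(fit, "satterthwaite")
        for a, b in zip(kr, sat):
            assert a.p_value == pytest.approx(b.p_value, abs=0.05)


class TestBlups:
    def _frame_star(self, n=6, npg=4, seed=5):
        newick = "(" + ",".join(f"s{i}" for i in range(n)) + ");"
        C = vcv(grafen_branch_lengths(read_newick(newick)))
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            a = rng.normal() * 0.8
            for _ in range(npg):
                rows.append(
                    dict(
                        obs_id=len(rows),
                        species=f"s{i}",
                        trait="logVO2",
                        y=1.0 + a + rng.normal() * 0.5,
                        logM=0.0,
                        logU=0.0,
                        source="s",
                    )
                )
        return pd.DataFrame(rows), C

    def test_zero_phylo_variance_zero_blups(self, cov4, toy_frame):
        spec = ModelSpec(traits=("logVO2",), species_effect=True)
        fit = mm.reml_fit(spec, toy_frame, cov4)
        # evaluate the predictor at sigma2_phylo = 0 exactly
        vs, vr = fit.varcomps["species"], fit.varcomps["resid"]
        fit._theta = np.array([0.0, vs, vr])
        fit.varcomps = pd.Series([0.0, vs, vr], index=["phylo", "species", "resid"])
        b = mm.blups(fit)
        assert np.allclose(b["blup"], 0.0, atol=1e-12)

    def test_shrinkage_below_raw_species_means(self):
        """With A = I and equal n, BLUP = ridge-shrunken species mean residual:
        |BLUP| <= |raw mean residual| for every species (closed-form check)."""
        frame, C = self._frame_star()
        spec = ModelSpec(traits=("logVO2",), fixed=("intercept",))
        fit = mm.reml_fit(spec, frame, C)
        b = mm.blups(fit).set_index("species")["blup"]
        mu = fit.beta["intercept"]
        raw = frame.groupby("species")["y"].mean() - mu
        vp, vr = fit.varcomps["phylo"], fit.varcomps["resid"]
        npg = 4
        shrink = vp / (vp + vr / npg)
        for sp in raw.index:
            assert abs(b[sp]) <= abs(raw[sp]) + 1e-10
            assert b[sp] == pytest.approx(shrink * raw[sp], abs=1e-6)

    def test_blups_shrink_monotonically_with_residual_variance(self):
        frame, C = self._frame_star()
        spec = ModelSpec(traits=("logVO2",), fixed=("intercept",))
        prob = mm._Problem(spec, frame, C)
        fit = mm.reml_fit(spec, frame, C)
        vp = fit.varcomps["phylo"]
        prev = None
        for vr in (0.1, 0.5, 2.0, 10.0):
            fit._theta = np.array([vp, vr])
            fit.varcomps = pd.Series([vp, vr], index=["phylo", "resid"])
            mag = mm.blups(fit)["blup"].abs().sum()
            if prev is not None:
                assert mag < prev
            prev = mag


def test_star_tree_phylo_species_confounding_flagged():
    """With A = I the phylogeny and species-identity effects enter V
    identically: only their sum is estimable and the fit says so."""
    newick = "(" + ",".join(f"s{i}" for i in range(5)) + ");"
    C = vcv(grafen_branch_lengths(read_newick(newick)))
    rng = np.random.default_rng(2)
    rows = []
    for i in range(5):
        a = rng.normal() * 0.6
        for _ in range(3):
            rows.append(
                dict(
                    obs_id=len(rows),
                    species=f"s{i}",
                    trait="logVO2",
                    y=1.0 + a + rng.normal() * 0.4,
                    logM=0.0,
                    logU=0.0,
                    source="s",
                )
            )
    frame = pd.DataFrame(rows)
    spec = ModelSpec(traits=("logVO2",), fixed=("intercept",), species_effect=True)
    fit = mm.reml_fit(spec, frame, C)
    assert fit.non_identifiable
    # the identified sum still matches a phylogeny-only fit's variance
    fit_single = mm.reml_fit(
        ModelSpec(traits=("logVO2",), fixed=("intercept",)), frame, C
    )
    assert fit.varcomps["phylo"] + fit.varcomps["species"] == pytest.approx(
        fit_single.varcomps["phylo"], rel=1e-3, abs=1e-6
    )


class TestSpecValidation:
    def test_bivariate_species_effect_rejected(self):
        with pytest.raises(ValueError, match="univariate"):
            ModelSpec(traits=("logVO2", "logInvTc"), species_effect=True)

    def test_missing_species_in_covariance(self, cov4, toy_frame):
        frame = toy_frame.copy()
        frame.loc[0, "species"] = "ZZZ"
        with pytest.raises(ValueError, match="ZZZ"):
            mm.reml_fit(ModelSpec(traits=("logVO2",)), frame, cov4)

    def test_rank_deficient_design_rejected(self, cov4, toy_frame):
        frame = toy_frame.assign(logU=toy_frame["logM"])
        with pytest.raises(ValueError, match="rank"):
            mm.reml_fit(
                ModelSpec(traits=("logVO2",), fixed=("intercept", "logM", "logU")),
                frame,
                cov4,
            )
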