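"""Analysis orchestration and command-line interface.

``run_locomotion_analysis`` executes the full comparative sequence on a
model frame + phylogenetic covariance:

1. univariate mixed models per trait with the mass × speed interaction;
2. univariate additive models with phylogenetic heritability, the species
   variance fraction, and likelihood-ratio tests of both random effects;
3. bivariate models under three fixed-effect conditionings (mass only,
   speed only, both) with the phylogenetic correlation, its delta-method
   SE, and the covariance-zero LRT;
4. BLUP extraction per bivariate fit for visualisation.

``run_eco_analysis`` derives the aerobic-scope variables and runs the PGLS
battery.  ``residual_regression`` reproduces the classic check of whether
relative limb length tracks relative rate of force production: residuals of
log10(effective limb length) on log10(mass) regressed against
species-level residuals of log10(1/t_c) on log10(mass) + log10(speed).

The CLI (``phylocot``) exposes simulate / fit-locomotion / fit-eco /
report / recover subcommands as a thin layer over these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__, dataio, mixedmodel, pgls, synthetic, synthetic_study
from .mixedmodel import ModelSpec
from .phylo import PhyloCovariance, grafen_branch_lengths, read_newick, vcv

log = logging.getLogger(__name__)

__all__ = [
    "run_locomotion_analysis",
    "run_eco_analysis",
    "residual_regression",
    "load_tree_covariance",
    "cli",
]

TRAITS = (dataio.TRAIT_VO2, dataio.TRAIT_TC)
CONDITIONINGS = {
    "mass_only": ("intercept", "logM"),
    "speed_only": ("intercept", "logU"),
    "mass_and_speed": ("intercept", "logM", "logU"),
}


def load_tree_covariance(newick_text: str, rho: float = 1.0) -> PhyloCovariance:
    """Parse newick, assign Grafen lengths if any are missing, return the VCV."""
    tree = read_newick(newick_text)
    lengths = [nd.edge.length for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    if any(l is None for l in lengths):
        tree = grafen_branch_lengths(tree, rho=rho)
    return vcv(tree)


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def run_locomotion_analysis(
    frame: pd.DataFrame,
    C: PhyloCovariance,
    *,
    kr_method: str = "kenward-roger",
    n_starts: int = 5,
) -> dict:
    """Run the full mixed-model sequence; returns a JSON-serialisable report."""
    if frame.empty:
        raise ValueError("empty model frame")
    t0 = time.time()
    frame_bytes = frame.to_csv(sep="\t", index=False).encode()
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "model_frame_sha256": hashlib.sha256(frame_bytes).hexdigest(),
            "covariance_sha256": hashlib.sha256(
                np.ascontiguousarray(C.matrix).tobytes()
            ).hexdigest(),
            "kr_method": kr_method,
            "n_starts": n_starts,
        },
        "n_obs": int(len(frame)),
        "n_obs_by_trait": frame["trait"].value_counts().to_dict(),
        "n_species": int(frame["species"].nunique()),
    }

    univariate = {}
    for trait in TRAITS:
        if trait not in set(frame["trait"]):
            continue
        block: dict = {}
        spec_int = ModelSpec(
            traits=(trait,),
            fixed=("intercept", "logM", "logU", "logM:logU"),
            species_effect=True,
        )
        fit_int = mixedmodel.reml_fit(spec_int, frame, C, n_starts=n_starts)
        block["interaction_model"] = fit_int.to_dict()
        block["interaction_model"]["f_tests"] = [
            dataclasses.asdict(t) for t in mixedmodel.fixed_effect_tests(fit_int, kr_method)
        ]

        spec_add = ModelSpec(traits=(trait,), species_effect=True)
        fit_add = mixedmodel.reml_fit(spec_add, frame, C, n_starts=n_starts)
        block["additive_model"] = fit_add.to_dict()
        block["additive_model"]["f_tests"] = [
            dataclasses.asdict(t) for t in mixedmodel.fixed_effect_tests(fit_add, kr_method)
        ]
        h2_est, h2_se = mixedmodel.h2(fit_add)
        sf_est, sf_se = mixedmodel.species_fraction(fit_add)
        block["h2"] = {"estimate": h2_est, "se": h2_se}
        block["species_fraction"] = {"estimate": sf_est, "se": sf_se}
        fit_nophylo = mixedmodel.reml_fit(
            dataclasses.replace(spec_add, phylo=False), frame, C, n_starts=n_starts
        )
        fit_nospec = mixedmodel.reml_fit(
            dataclasses.replace(spec_add, species_effect=False), frame, C, n_starts=n_starts
        )
        block["lrt_phylo"] = dataclasses.asdict(
            mixedmodel.lrt_component(spec_add, frame, C, "phylo", fits=(fit_add, fit_nophylo))
        )
        block["lrt_species"] = dataclasses.asdict(
            mixedmodel.lrt_component(spec_add, frame, C, "species", fits=(fit_add, fit_nospec))
        )
        univariate[trait] = block
    report["univariate"] = univariate

    bivariate = {}
    have_both = set(TRAITS) <= set(frame["trait"])
    if have_both:
        for name, fixed in CONDITIONINGS.items():
            spec = ModelSpec(traits=TRAITS, fixed=fixed)
            fit = mixedmodel.reml_fit(spec, frame, C, n_starts=n_starts)
            r, r_se = mixedmodel.phylo_correlation(fit)
            fit0 = mixedmodel.reml_fit(
                dataclasses.replace(spec, phylo_covariance=False), frame, C, n_starts=n_starts
            )
            lrt = mixedmodel.lrt_component(spec, frame, C, "phylo_cov", fits=(fit, fit0))
            blup_tab = mixedmodel.blups(fit)
            bivariate[name] = {
                "fit": fit.to_dict(),
                "phylo_correlation": {"estimate": r, "se": r_se},
                "lrt_phylo_cov": dataclasses.asdict(lrt),
                "blups": blup_tab.to_dict(orient="records"),
            }
    report["bivariate"] = bivariate
    report["elapsed_s"] = round(time.time() - t0, 2)
    return report


def residual_regression(limb_table: pd.DataFrame, frame: pd.DataFrame) -> dict:
    """Relative limb length vs relative rate of force production.

    ``limb_table`` needs columns species, limb_length, mass.  The x side is
    the OLS residual of log10(limb length) on log10(mass) across species;
    the y side is the per-species mean residual of log10(1/t_c) on
    log10(mass) + log10(speed) from the observation-level frame.  Returns
    R², the signed correlation r and N for the regression of x-residuals on
    y-residuals.  Requires at least 3 species with both quantities.
    """
    tc = frame[frame["trait"] == dataio.TRAIT_TC]
    if tc.empty:
        raise ValueError("model frame has no contact-time rows")
    X = np.column_stack([np.ones(len(tc)), tc["logM"], tc["logU"]])
    beta = _ols(tc["y"].to_numpy(float), X)
    resid_y = tc["y"].to_numpy(float) - X @ beta
    y_by_species = pd.Series(resid_y, index=tc["species"].to_numpy()).groupby(level=0).mean()

    lt = limb_table.dropna(subset=["limb_length", "mass"])
    merged = pd.DataFrame(
        {
            "log_limb": np.log10(lt["limb_length"].to_numpy(float)),
            "log_mass": np.log10(lt["mass"].to_numpy(float)),
        },
        index=lt["species"].to_numpy(),
    ).join(y_by_species.rename("y_resid"), how="inner")
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} species with both limb length and contact time")
    Xl = np.column_stack([np.ones(n), merged["log_mass"]])
    beta_l = _ols(merged["log_limb"].to_numpy(), Xl)
    resid_x = merged["log_limb"].to_numpy() - Xl @ beta_l
    yv = merged["y_resid"].to_numpy()
    r = float(np.corrcoef(resid_x, yv)[0, 1]) if np.std(yv) > 0 and np.std(resid_x) > 0 else 0.0
    return {"r2": r * r, "r": r, "n": n}


def run_eco_analysis(ecotable: pd.DataFrame, C: PhyloCovariance, **battery_kwargs) -> dict:
    """Derive aerobic-scope variables, run the PGLS battery, report a table."""
    if ecotable.empty:
        raise ValueError("empty eco table")
    derived = pgls.derive_eco_variables(ecotable)
    battery = pgls.run_battery(derived, C, **battery_kwargs)
    return {
        "package_version": __version__,
        "n_species": int(len(ecotable)),
        "battery": battery.to_dict(orient="records"),
    }


def _write_report(report: dict, out_dir: Path, name: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.json"
    path.write_text(json.dumps(report, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _battery_tsv(report: dict, path: Path) -> None:
    pd.DataFrame(report["battery"]).to_csv(path, sep="\t", index=False)


def plot_blup_pairs(report: dict, out_dir: Path) -> list[Path]:
    """Scatter the per-species BLUP pairs (one panel per conditioning).

    x: phylogenetic BLUP of log10(1/t_c), y: of log10(net V̇O₂), with SE
    bars; the axis choice is arbitrary and purely for visualisation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for name, blk in report.get("bivariate", {}).items():
        blups = pd.DataFrame(blk["blups"])
        wide_b = blups.pivot(index="species", columns="trait", values="blup")
        wide_se = blups.pivot(index="species", columns="trait", values="se")
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.errorbar(
            wide_b[dataio.TRAIT_TC],
            wide_b[dataio.TRAIT_VO2],
            xerr=wide_se[dataio.TRAIT_TC],
            yerr=wide_se[dataio.TRAIT_VO2],
            fmt="o",
            ms=4,
            lw=0.8,
            alpha=0.8,
        )
        r = blk["phylo_correlation"]["estimate"]
        ax.set_xlabel("BLUP log10(1/tc)")
        ax.set_ylabel("BLUP log10(net VO2)")
        ax.set_title(f"{name}: r = {r:.2f}")
        fig.tight_layout()
        path = out_dir / f"blups_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.version_option(__version__)
def cli() -> None:
    """Phylogenetic mixed models and PGLS for locomotor energetics."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--seed", type=int, required=True)
@click.option("--n-species", type=int, default=21, show_default=True)
@click.option("--out-dir", type=click.Path(path_type=Path), required=True)
def simulate(seed: int, n_species: int, out_dir: Path) -> None:
    """Simulate a locomotion dataset + tree and write them as text."""
    cfg = synthetic.SimConfig(seed=seed, n_species=n_species)
    tree = synthetic.simulate_tree(cfg)
    data, _ = synthetic.simulate_traits(tree, cfg)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "tree.nwk").write_text(
        tree.as_string(schema="newick", unquoted_underscores=True)
    )
    dataio.write_dataset(data, out_dir / "locomotion.tsv")
    click.echo(f"wrote {out_dir / 'locomotion.tsv'} and tree.nwk")


@cli.command("fit-locomotion")
@click.option("--data", "data_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--tree", "tree_path", type=click.Path(exists=True, path_type=Path), default=None)
@click.option("--taxonomy", "tax_path", type=click.Path(exists=True, path_type=Path), default=None)
@click.option("--out-dir", type=click.Path(path_type=Path), required=True)
@click.option("--net-adjusted/--raw", default=False, help="Input already net of y-intercepts.")
@click.option("--grouping", type=click.Choice(["source", "species"]), default="source")
def fit_locomotion(data_path, tree_path, tax_path, out_dir, net_adjusted, grouping) -> None:
    """Preprocess an observation table and run the mixed-model sequence."""
    C = _covariance_from_options(tree_path, tax_path)
    data = dataio.read_dataset(data_path)
    if not net_adjusted:
        data = dataio.subtract_intercepts(data, grouping=grouping)
    else:
        data.net_adjusted = True
    frame = dataio.to_model_frame(data, phylo_taxa=C.taxa)
    report = run_locomotion_analysis(frame, C)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataio.write_model_frame(frame, out_dir / "model_frame.tsv")
    path = _write_report(report, out_dir, "locomotion_report")
    click.echo(f"wrote {path}")


@cli.command("fit-eco")
@click.option("--eco", "eco_path", type=click.Path(exists=True, path_type=Path), required=True)
@click.option("--tree", "tree_path", type=click.Path(exists=True, path_type=Path), default=None)
@click.option("--taxonomy", "tax_path", type=click.Path(exists=True, path_type=Path), default=None)
@click.option("--out-dir", type=click.Path(path_type=Path), required=True)
def fit_eco(eco_path, tree_path, tax_path, out_dir) -> None:
    """Run the PGLS covariate battery on a species-level eco table."""
    C = _covariance_from_options(tree_path, tax_path)
    table = pd.read_csv(eco_path, sep=None, engine="python")
    report = run_eco_analysis(table, C)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = _write_report(report, out_dir, "eco_report")
    _battery_tsv(report, out_dir / "battery.tsv")
    click.echo(f"wrote {path}")


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(path_type=Path), required=True)
@click.option("--plots/--no-plots", default=False, help="Write BLUP-pair scatter panels.")
def report(seed: int, out_dir: Path, plots: bool) -> None:
    """Full analysis on the reconstructed 21-species study (synthetic stand-in)."""
    data = synthetic_study.reconstruct_dataset(seed=seed)
    C = vcv(synthetic_study.study_tree())
    data = dataio.subtract_intercepts(data, grouping="source")
    frame = dataio.to_model_frame(data, phylo_taxa=C.taxa)
    rep = run_locomotion_analysis(frame, C)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataio.write_model_frame(frame, out_dir / "model_frame.tsv")
    path = _write_report(rep, out_dir, "study_report")
    if plots:
        for p in plot_blup_pairs(rep, out_dir):
            click.echo(f"wrote {p}")
    click.echo(f"wrote {path}")


@cli.command()
@click.option("--seed", type=int, required=True)
@click.option("--n-replicates", type=int, default=20, show_default=True)
@click.option("--n-species", type=int, default=50, show_default=True)
@click.option("--out-dir", type=click.Path(path_type=Path), required=True)
def recover(seed: int, n_replicates: int, n_species: int, out_dir: Path) -> None:
    """Parameter-recovery experiment: simulate, refit, summarise bias."""
    rows = []
    for rep_i in range(n_replicates):
        cfg = synthetic.SimConfig(
            seed=seed + rep_i,
            n_species=n_species,
            n_obs=(n_species, n_species),
            phylo_corr=0.5,
            sigma2_phylo=(0.03, 0.03),
            sigma2_species=(0.0, 0.0),
        )
        tree = synthetic.simulate_tree(cfg)
        data, truth = synthetic.simulate_traits(tree, cfg)
        frame = dataio.to_model_frame(data, require_net=False)
        C = vcv(tree)
        spec = ModelSpec(traits=TRAITS)
        fit = mixedmodel.reml_fit(spec, frame, C, n_starts=3)
        r, _ = mixedmodel.phylo_correlation(fit)
        rows.append(
            dict(replicate=rep_i, r_hat=r, **{k: v for k, v in fit.varcomps.items()})
        )
    out = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    out.to_csv(out_dir / "recovery.tsv", sep="\t", index=False)
    click.echo(f"mean r_hat = {out['r_hat'].mean():.3f} (truth 0.5)")


def _covariance_from_options(tree_path, tax_path) -> PhyloCovariance:
    if tree_path is not None:
        return load_tree_covariance(Path(tree_path).read_text())
    if tax_path is not None:
        tab = pd.read_csv(tax_path, sep="\t")
        species = [
            (row.iloc[0], tuple(str(v) for v in row.iloc[1:] if pd.notna(v)))
            for _, row in tab.iterrows()
        ]
        from .phylo import taxonomy_fallback_tree

        return vcv(grafen_branch_lengths(taxonomy_fallback_tree(species)))
    raise click.UsageError("provide --tree or --taxonomy")
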