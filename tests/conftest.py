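import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from phylocot import dataio, synthetic
from phylocot.phylo import grafen_branch_lengths, read_newick, vcv

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def balanced4():
    """Balanced 4-tip tree with Grafen branch lengths."""
    return grafen_branch_lengths(read_newick("((A,B),(C,D));"))


@pytest.fixture
def cov4(balanced4):
    return vcv(balanced4)


@pytest.fixture
def toy_frame(cov4):
    """Small univariate model frame over the 4-tip tree (3 obs/species)."""
    rng = np.random.default_rng(42)
    rows = []
    for sp in cov4.taxa:
        for _ in range(3):
            rows.append(
                dict(
                    obs_id=len(rows),
                    species=sp,
                    trait="logVO2",
                    y=rng.normal(),
                    logM=rng.normal(),
                    logU=rng.normal(),
                    source="toy",
                )
            )
    return pd.DataFrame(rows)


def simulate_bivariate(seed, n_species=40, n_obs=None, **kwargs):
    """Shared helper: simulate a disjoint bivariate dataset + its covariance."""
    if n_obs is None:
        n_obs = (2 * n_species, 2 * n_species)
    cfg = synthetic.SimConfig(
        seed=seed,
        n_species=n_species,
        n_obs=n_obs,
        sigma2_species=(0.0, 0.0),
        **kwargs,
    )
    tree = synthetic.simulate_tree(cfg)
    data, truth = synthetic.simulate_traits(tree, cfg)
    frame = dataio.to_model_frame(data, require_net=False)
    return frame, vcv(tree), truth
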