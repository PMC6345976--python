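"""Synthetic reconstruction of the 21-species treadmill compilation.

The original observation-level compilation (288 oxygen-consumption and 126
foot-contact-time measurements across 21 bird and mammal species) is
archived externally; what is reproducible from the published record is the
per-species summary: speed range, V̇O₂ range, contact-time range, body-mass
range and the fitted V̇O₂–speed y-intercept, plus the species list itself.
This module rebuilds a synthetic observation table from those summaries:

* speeds are evenly spaced within each species' published range;
* raw V̇O₂ follows the species' linear V̇O₂–speed relationship implied by
  the published endpoints (whose implied y-intercept closely matches the
  published one), with multiplicative log-normal noise applied to the net
  (speed-dependent) component so intercept subtraction stays well-posed;
* 1/t_c is log-log linear in speed between the published endpoints, again
  with log-normal noise;
* per-observation masses are evenly log-spaced within the published range;
* observation counts per species split the published totals as evenly as
  possible in the published species order.

Noise standard deviations default to the residual scales of the fitted
mixed models (log10 sd ≈ 0.118 for V̇O₂, 0.05 for 1/t_c).  The companion
tree is built by the taxonomy fallback (class → subclass/infraclass →
order → family polytomies) with Grafen branch lengths, since the original
tree-service topology is not reconstructible offline.

This is a synthetic stand-in, useful for exercising the full pipeline at
the real study's scale and design; it is not the original data.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from .dataio import LocomotionDataset
from .phylo import grafen_branch_lengths, taxonomy_fallback_tree

__all__ = ["SPECIES_SUMMARIES", "reconstruct_dataset", "study_tree", "study_taxonomy"]

#: Published per-species summaries: label; speed range (m/s); raw V̇O₂ range
#: (ml kg⁻¹ min⁻¹); foot contact time range (s); mass range (kg); published
#: y-intercept range (ml kg⁻¹ min⁻¹); taxonomy (class, subclass/infraclass,
#: order, family).
SPECIES_SUMMARIES: list[dict] = [
    dict(species="Colinus_virginianus", u=(0.28, 0.69), vo2=(38.55, 62.00), tc=(0.24, 0.33),
         mass=(0.13, 0.19), intercept=(21.97, 62.00),
         taxonomy=("Aves", "Neognathae", "Galliformes", "Odontophoridae")),
    dict(species="Dipodomys_merriami", u=(1.03, 2.85), vo2=(9.91, 118.25), tc=(0.04, 0.06),
         mass=(0.032, 0.032), intercept=(-47.63, -47.63),
         taxonomy=("Mammalia", "Placentalia", "Rodentia", "Heteromyidae")),
    dict(species="Spermophilus_tridecemlineatus", u=(0.60, 2.62), vo2=(101.84, 161.02),
         tc=(0.05, 0.14), mass=(0.21, 0.23), intercept=(94.35, 94.35),
         taxonomy=("Mammalia", "Placentalia", "Rodentia", "Sciuridae")),
    dict(species="Pedetes_capensis", u=(0.57, 2.83), vo2=(41.25, 100.38), tc=(0.12, 0.15),
         mass=(3.0, 3.0), intercept=(30.72, 30.72),
         taxonomy=("Mammalia", "Placentalia", "Rodentia", "Pedetidae")),
    dict(species="Numida_meleagris", u=(0.41, 1.99), vo2=(33.24, 70.78), tc=(0.20, 0.33),
         mass=(1.3, 1.44), intercept=(23.14, 23.14),
         taxonomy=("Aves", "Neognathae", "Galliformes", "Numididae")),
    dict(species="Canis_familiaris", u=(1.43, 7.04), vo2=(19.02, 57.07), tc=(0.08, 0.24),
         mass=(24.0, 25.8), intercept=(6.20, 6.20),
         taxonomy=("Mammalia", "Placentalia", "Carnivora", "Canidae")),
    dict(species="Meleagris_gallopavo", u=(0.69, 3.50), vo2=(26.84, 77.41), tc=(0.17, 0.33),
         mass=(4.31, 5.31), intercept=(0.68, 0.68),
         taxonomy=("Aves", "Neognathae", "Galliformes", "Phasianidae")),
    dict(species="Equus_caballus", u=(2.00, 7.01), vo2=(15.62, 43.54), tc=(0.11, 0.39),
         mass=(140.0, 467.0), intercept=(0.664, 0.664),
         taxonomy=("Mammalia", "Placentalia", "Perissodactyla", "Equidae")),
    dict(species="Rhea_americana", u=(0.49, 3.80), vo2=(16.23, 76.95), tc=(0.21, 0.55),
         mass=(19.9, 22.0), intercept=(5.83, 5.83),
         taxonomy=("Aves", "Palaeognathae", "Rheiformes", "Rheidae")),
    dict(species="Dromaius_novaehollandiae", u=(1.50, 4.00), vo2=(20.79, 37.67), tc=(0.25, 0.62),
         mass=(40.1, 40.1), intercept=(4.74, 4.74),
         taxonomy=("Aves", "Palaeognathae", "Casuariiformes", "Dromaiidae")),
    dict(species="Homo_sapiens", u=(2.19, 4.02), vo2=(30.09, 46.41), tc=(0.25, 0.38),
         mass=(78.88, 80.20), intercept=(-0.51, -0.51),
         taxonomy=("Mammalia", "Placentalia", "Primates", "Hominidae")),
    dict(species="Bettongia_penicillata", u=(1.10, 6.20), vo2=(81.80, 114.39), tc=(0.05, 0.10),
         mass=(0.97, 0.97), intercept=(70.95, 70.95),
         taxonomy=("Mammalia", "Marsupialia", "Diprotodontia", "Potoroidae")),
    dict(species="Pavo_cristatus", u=(0.5, 1.0), vo2=(9.15, 16.61), tc=(0.49, 0.79),
         mass=(4.58, 4.58), intercept=(1.43, 1.43),
         taxonomy=("Aves", "Neognathae", "Galliformes", "Phasianidae")),
    dict(species="Aptenodytes_patagonicus", u=(0.08, 0.50), vo2=(15.91, 25.63), tc=(0.56, 0.79),
         mass=(11.5, 11.65), intercept=(13.25, 13.25),
         taxonomy=("Aves", "Neognathae", "Sphenisciformes", "Spheniscidae")),
    dict(species="Lagopus_muta", u=(0.22, 0.75), vo2=(33.76, 46.22), tc=(0.30, 0.55),
         mass=(0.73, 0.73), intercept=(29.3, 29.3),
         taxonomy=("Aves", "Neognathae", "Galliformes", "Phasianidae")),
    dict(species="Branta_leucopsis", u=(0.24, 1.25), vo2=(28.52, 64.81), tc=(0.21, 0.81),
         mass=(1.79, 1.79), intercept=(20.46, 20.46),
         taxonomy=("Aves", "Neognathae", "Anseriformes", "Anatidae")),
    dict(species="Phalacrocorax_carbo", u=(0.08, 0.52), vo2=(9.95, 49.88), tc=(0.46, 1.26),
         mass=(2.26, 2.26), intercept=(29.21, 29.21),
         taxonomy=("Aves", "Neognathae", "Suliformes", "Phalacrocoracidae")),
    dict(species="Ornithorhynchus_anatinus", u=(0.19, 1.08), vo2=(11.98, 29.05), tc=(0.18, 1.30),
         mass=(1.40, 1.40), intercept=(9.59, 9.59),
         taxonomy=("Mammalia", "Prototheria", "Monotremata", "Ornithorhynchidae")),
    dict(species="Aptenodytes_forsteri", u=(0.28, 2.72), vo2=(10.81, 30.25), tc=(0.33, 0.54),
         mass=(20.79, 21.0), intercept=(7.26, 7.26),
         taxonomy=("Aves", "Neognathae", "Sphenisciformes", "Spheniscidae")),
    dict(species="Gallus_gallus", u=(0.28, 0.69), vo2=(29.72, 52.20), tc=(0.36, 0.84),
         mass=(1.39, 1.92), intercept=(14.11, 14.11),
         taxonomy=("Aves", "Neognathae", "Galliformes", "Phasianidae")),
    dict(species="Mus_musculus", u=(0.08, 0.33), vo2=(82.61, 93.86), tc=(0.11, 0.18),
         mass=(0.047, 0.047), intercept=(79.00, 79.98),
         taxonomy=("Mammalia", "Placentalia", "Rodentia", "Muridae")),
]

N_VO2_TOTAL = 288
N_TC_TOTAL = 126


def study_taxonomy() -> list[tuple[str, tuple[str, ...]]]:
    """(species, taxonomy ranks) pairs for the taxonomy fallback tree."""
    return [(row["species"], row["taxonomy"]) for row in SPECIES_SUMMARIES]


def study_tree(rho: float = 1.0) -> dendropy.Tree:
    """Taxonomy-fallback tree of the study species with Grafen branch lengths."""
    return grafen_branch_lengths(taxonomy_fallback_tree(study_taxonomy()), rho=rho)


def _allocate(total: int, n: int) -> list[int]:
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


def reconstruct_dataset(
    seed: int = 0,
    noise_sd: tuple[float, float] = (0.118, 0.05),
    n_vo2: int = N_VO2_TOTAL,
    n_tc: int = N_TC_TOTAL,
) -> LocomotionDataset:
    """Synthetic observation table matching the published species summaries.

    ``noise_sd`` gives the log10 standard deviations of the multiplicative
    noise applied to the net V̇O₂ and 1/t_c components.  The returned raw
    dataset still carries its V̇O₂ y-intercepts (``net_adjusted=False``),
    so the usual preprocessing applies.
    """
    rng = np.random.default_rng(seed)
    S = len(SPECIES_SUMMARIES)
    counts_v = _allocate(n_vo2, S)
    counts_t = _allocate(n_tc, S)
    rows = []
    for si, row in enumerate(SPECIES_SUMMARIES):
        u_lo, u_hi = row["u"]
        v_lo, v_hi = row["vo2"]
        t_lo, t_hi = row["tc"]
        m_lo, m_hi = row["mass"]
        slope = (v_hi - v_lo) / (u_hi - u_lo)
        a_implied = v_lo - slope * u_lo  # endpoint-implied y-intercept
        nv = counts_v[si]
        speeds = np.linspace(u_lo, u_hi, nv)
        masses = np.logspace(np.log10(m_lo), np.log10(m_hi), nv)
        net = slope * speeds * 10 ** rng.normal(0.0, noise_sd[0], size=nv)
        for u, m, nvo2 in zip(speeds, masses, net):
            rows.append(dict(species=row["species"], mass=m, speed=u,
                             vo2=a_implied + nvo2, tc=np.nan, source=row["species"]))
        nt = counts_t[si]
        speeds_t = np.linspace(u_lo, u_hi, nt)
        masses_t = np.logspace(np.log10(m_lo), np.log10(m_hi), nt)
        # 1/tc log-log linear in speed between the published endpoints
        li_lo, li_hi = np.log10(1.0 / t_hi), np.log10(1.0 / t_lo)
        s_slope = (li_hi - li_lo) / (np.log10(u_hi) - np.log10(u_lo))
        log_inv_tc = li_lo + s_slope * (np.log10(speeds_t) - np.log10(u_lo))
        log_inv_tc = log_inv_tc + rng.normal(0.0, noise_sd[1], size=nt)
        for u, m, lit in zip(speeds_t, masses_t, log_inv_tc):
            rows.append(dict(species=row["species"], mass=m, speed=u,
                             vo2=np.nan, tc=10 ** (-lit), source=row["species"]))
    frame = pd.DataFrame(rows)
    return LocomotionDataset(frame=frame, net_adjusted=False)
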