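"""Locomotion dataset I/O and preprocessing.

The observation table holds one row per treadmill measurement: species,
body mass M (kg), speed U (m s⁻¹), and at least one of the two response
measurements — mass-specific oxygen consumption rate V̇O₂ (ml kg⁻¹ min⁻¹)
or foot contact time t_c (s).  Preprocessing mirrors the standard net-cost
convention: within each data set a linear regression V̇O₂ = a + b·U is
fitted and its y-intercept ``a`` subtracted from every V̇O₂ value, leaving
only the speed-dependent increment.  The model frame stacks the two traits
long-format with log₁₀ responses (log₁₀ net V̇O₂ and log₁₀ 1/t_c) and
log₁₀-transformed mass and speed covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRAIT_VO2 = "logVO2"
TRAIT_TC = "logInvTc"

#: Recognised header spellings for each logical column (lower-cased match).
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "species": ("species", "latin_name", "taxon", "binomial"),
    "mass": ("mass", "mass_kg", "body_mass", "body_mass_kg", "m"),
    "speed": ("speed", "speed_ms", "speed_m_s", "u"),
    "vo2": ("vo2", "vo2_ml_kg_min", "vo2_raw", "oxygen"),
    "tc": ("tc", "tc_s", "contact_time", "foot_contact_time"),
    "source": ("source", "dataset", "study", "reference"),
}


class SchemaError(ValueError):
    """Raised when an input table lacks a mandatory column."""


@dataclass
class LocomotionDataset:
    """Typed locomotion observations plus preprocessing state.

    ``frame`` columns: species, mass, speed, vo2, tc, source.  ``intercepts``
    records the fitted per-group V̇O₂–speed regressions once
    :func:`subtract_intercepts` has run (``net_adjusted`` then flips to
    True); ``rejected`` lists (row, reason) pairs dropped at read time.
    """

    frame: pd.DataFrame
    net_adjusted: bool = False
    intercepts: pd.DataFrame | None = None
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_vo2(self) -> int:
        return int(self.frame["vo2"].notna().sum())

    @property
    def n_tc(self) -> int:
        return int(self.frame["tc"].notna().sum())

    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())


def _resolve_columns(columns: list[str], aliases: dict[str, tuple[str, ...]]) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    mapping: dict[str, str] = {}
    for logical, names in aliases.items():
        for name in names:
            if name in lower:
                mapping[logical] = lower[name]
                break
    return mapping


def read_dataset(path, aliases: dict[str, tuple[str, ...]] | None = None) -> LocomotionDataset:
    """Read a delimited (tab or comma, sniffed) locomotion table.

    Mandatory columns: species, mass, speed and at least one of vo2/tc.
    Rows with non-positive mass, speed, V̇O₂ or t_c, or with neither
    response, are rejected and logged with their row numbers.
    """
    alias_map = dict(COLUMN_ALIASES)
    if aliases:
        alias_map.update(aliases)
    raw = pd.read_csv(path, sep=None, engine="python", comment="#")
    if raw.empty:
        raise SchemaError(f"empty dataset: {path}")
    mapping = _resolve_columns(list(raw.columns), alias_map)
    for required in ("species", "mass", "speed"):
        if required not in mapping:
            raise SchemaError(f"missing mandatory column {required!r} in {list(raw.columns)}")
    if "vo2" not in mapping and "tc" not in mapping:
        raise SchemaError("need at least one response column (vo2 or tc)")

    df = pd.DataFrame({"species": raw[mapping["species"]].astype(str).str.strip()})
    for col in ("mass", "speed", "vo2", "tc"):
        if col in mapping:
            df[col] = pd.to_numeric(raw[mapping[col]], errors="coerce").astype(float)
        else:
            df[col] = np.nan
    df["source"] = (
        raw[mapping["source"]].astype(str).str.strip() if "source" in mapping else df["species"]
    )

    rejected: list[tuple[int, str]] = []
    keep = pd.Series(True, index=df.index)
    for i, row in df.iterrows():
        reason = None
        if not row["species"]:
            reason = "empty species label"
        elif not np.isfinite(row["mass"]) or row["mass"] <= 0:
            reason = "non-positive or missing mass"
        elif not np.isfinite(row["speed"]) or row["speed"] <= 0:
            reason = "non-positive or missing speed"
        elif np.isnan(row["vo2"]) and np.isnan(row["tc"]):
            reason = "no response measurement"
        elif np.isfinite(row["vo2"]) and row["vo2"] <= 0:
            reason = "non-positive vo2"
        elif np.isfinite(row["tc"]) and row["tc"] <= 0:
            reason = "non-positive tc"
        if reason:
            rejected.append((int(i), reason))
            keep.loc[i] = False
    if rejected:
        log.warning("rejected %d rows: %s", len(rejected), rejected[:10])
    return LocomotionDataset(frame=df[keep].reset_index(drop=True), rejected=rejected)


def subtract_intercepts(data: LocomotionDataset, grouping: str = "source") -> LocomotionDataset:
    """Subtract per-group OLS y-intercepts of the V̇O₂–speed regression.

    Within each group (default: species × source data set; ``grouping`` may
    also be ``"species"``) an ordinary least-squares line V̇O₂ = a + b·U is
    fitted and ``a`` subtracted from every V̇O₂ in the group, leaving the
    speed-dependent increment.  Groups with fewer than two distinct speeds
    are passed through unadjusted and flagged.  Calling this twice on the
    same dataset is an error (the operation is not idempotent).
    """
    if data.net_adjusted:
        raise ValueError("intercepts already subtracted from this dataset")
    if grouping not in ("source", "species"):
        raise ValueError("grouping must be 'source' or 'species'")
    df = data.frame.copy()
    keys = ["species", "source"] if grouping == "source" else ["species"]
    records = []
    for key, grp in df.groupby(keys, sort=False):
        sub = grp.dropna(subset=["vo2"])
        n_speeds = sub["speed"].nunique()
        if len(sub) >= 2 and n_speeds >= 2:
            b, a = np.polyfit(sub["speed"].to_numpy(), sub["vo2"].to_numpy(), 1)
            df.loc[sub.index, "vo2"] = sub["vo2"] - a
            flag = ""
        elif len(sub) == 0:
            a, b, flag = np.nan, np.nan, "no vo2 data"
        else:
            a, b, flag = np.nan, np.nan, "fewer than 2 distinct speeds; unadjusted"
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(intercept=a, slope=b, n=len(sub), flag=flag)
        records.append(rec)
    intercepts = pd.DataFrame(records)
    flagged = intercepts[intercepts["flag"] != ""]
    if not flagged.empty:
        log.warning("%d groups passed through unadjusted", len(flagged))
    return LocomotionDataset(
        frame=df, net_adjusted=True, intercepts=intercepts, rejected=list(data.rejected)
    )


def to_model_frame(
    data: LocomotionDataset,
    phylo_taxa: list[str] | None = None,
    require_net: bool = True,
) -> pd.DataFrame:
    """Stack the dataset into the long trait × observation model frame.

    One row per (observation, trait): ``trait`` is ``logVO2`` (response
    log₁₀ net V̇O₂) or ``logInvTc`` (response log₁₀ 1/t_c); covariates are
    ``logM`` = log₁₀ mass and ``logU`` = log₁₀ speed.  Rows whose net V̇O₂
    is non-positive after intercept subtraction are dropped and counted in
    the frame's ``attrs['dropped']``.  If ``phylo_taxa`` is given, species
    absent from it are reported in a single validation error.
    """
    if require_net and not data.net_adjusted:
        raise ValueError("subtract intercepts before building the model frame")
    if phylo_taxa is not None:
        missing = sorted(set(data.frame["species"]) - set(phylo_taxa))
        if missing:
            raise ValueError(f"species absent from phylogeny: {', '.join(missing)}")
    rows = []
    dropped: dict[str, int] = {}
    for i, row in data.frame.iterrows():
        base = dict(
            obs_id=int(i),
            species=row["species"],
            logM=np.log10(row["mass"]),
            logU=np.log10(row["speed"]),
            source=row["source"],
        )
        if np.isfinite(row["vo2"]):
            if row["vo2"] > 0:
                rows.append(dict(base, trait=TRAIT_VO2, y=np.log10(row["vo2"])))
            else:
                dropped["non-positive net vo2"] = dropped.get("non-positive net vo2", 0) + 1
        if np.isfinite(row["tc"]):
            rows.append(dict(base, trait=TRAIT_TC, y=np.log10(1.0 / row["tc"])))
    frame = pd.DataFrame(rows, columns=["obs_id", "species", "trait", "y", "logM", "logU", "source"])
    frame.attrs["dropped"] = dropped
    if dropped:
        log.warning("dropped model rows: %s", dropped)
    return frame


def write_model_frame(frame: pd.DataFrame, path) -> None:
    """Write the model frame as TSV so fits are reproducible from disk."""
    frame.to_csv(path, sep="\t", index=False)


def read_model_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    expected = {"species", "trait", "y", "logM", "logU"}
    missing = expected - set(frame.columns)
    if missing:
        raise SchemaError(f"model frame missing columns: {sorted(missing)}")
    return frame


def write_dataset(data: LocomotionDataset, path) -> None:
    """Write the raw observation table as TSV (dataio's own input format)."""
    data.frame.to_csv(Path(path), sep="\t", index=False)
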