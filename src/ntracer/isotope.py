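"""The 15N tracer computation chain, per-plant measurements → actual N uptake.

The chain runs

    δ15N → atom% → atom% excess (APE) → 15N uptake → 15N uptake rate
         → actual uptake of pre-existing soil NH4+/NO3- → per-quadrat uptake

where "actual" uptake scales the tracer signal by the ratio of the native
soil pool (C_available) to the labeled pool added per kg of soil
(C15N_added).  All scalar operations accept numpy arrays and broadcast.

A note on the 15N-uptake formula: with APE and N concentration both carried
as percent and biomass in grams, the dimensionally consistent expression for
a μg result is (APE/100) × biomass × (N%/100) × 1e6; a frequently printed
"× 1000" shorthand is off by a factor of ten and is not used here.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .config import ATM_RATIO_15N, LabelingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "atom_percent_excess",
    "n15_uptake",
    "n15_uptake_rate",
    "c15n_added",
    "actual_uptake",
    "actual_uptake_rate",
    "uptake_per_quadrat",
    "pool_shoot_root",
    "compute_uptake_table",
]

#: Treatment label → N form whose pool the tracer marks.
TREATMENT_FORM = {"nh4_label": "nh4", "no3_label": "no3"}

ID_COLS = ["site", "habitat", "quadrat", "species"]


def delta_to_atom_percent(delta15n):
    """Convert δ15N (‰ vs air N2) to atom% 15N.

    AT% = 100·R/(1+R) with R = R_atm·(δ/1000 + 1).  Strictly increasing in δ;
    δ = 0 gives the natural-abundance 0.3663 atom%.
    """
    delta15n = np.asarray(delta15n, dtype=float)
    if np.any(delta15n <= -1000.0):
        raise ValueError("delta15N must be > -1000 per mil")
    ratio = ATM_RATIO_15N * (delta15n / 1000.0 + 1.0)
    out = 100.0 * ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def atom_percent_to_delta(at_percent):
    """Inverse of :func:`delta_to_atom_percent`: atom% 15N → δ15N (‰)."""
    at_percent = np.asarray(at_percent, dtype=float)
    if np.any(at_percent <= 0) or np.any(at_percent >= 100):
        raise ValueError("atom percent must be in (0, 100)")
    ratio = at_percent / (100.0 - at_percent)
    out = (ratio / ATM_RATIO_15N - 1.0) * 1000.0
    return out if out.ndim else float(out)


def atom_percent_excess(at_labeled, at_control, *, clamp: bool = False):
    """Atom% excess of a labeled plant over its same-quadrat control.

    The atmospheric baseline cancels in the subtraction, so
    APE = AT%_labeled − AT%_control.  A negative APE (control exceeding the
    labeled plant, possible under measurement noise) is physically
    meaningless tracer-wise; with ``clamp=True`` negatives are set to zero
    and a count is logged — callers should carry the pre-clamp flag.
    """
    at_labeled = np.asarray(at_labeled, dtype=float)
    at_control = np.asarray(at_control, dtype=float)
    for name, arr in (("at_labeled", at_labeled), ("at_control", at_control)):
        if np.any(arr < 0.2) or np.any(arr >= 100):
            raise ValueError(f"{name} outside the plausible [0.2, 100) atom% range")
    ape = at_labeled - at_control
    if clamp:
        n_neg = int(np.sum(ape < 0))
        if n_neg:
            logger.warning("clamped %d negative APE value(s) to 0", n_neg)
        ape = np.maximum(ape, 0.0)
    return ape if ape.ndim else float(ape)


def n15_uptake(ape, total_biomass, n_content):
    """Tracer 15N taken up by the labeled plant, μg.

    (APE/100) × total biomass (g) × (N%/100) × 1e6.
    """
    ape = np.asarray(ape, dtype=float)
    total_biomass = np.asarray(total_biomass, dtype=float)
    n_content = np.asarray(n_content, dtype=float)
    out = (ape / 100.0) * total_biomass * (n_content / 100.0) * 1e6
    return out if out.ndim else float(out)


def n15_uptake_rate(uptake, root_biomass, time):
    """Tracer uptake rate, μg N g-1 root h-1 = uptake / (root biomass × time)."""
    uptake = np.asarray(uptake, dtype=float)
    root_biomass = np.asarray(root_biomass, dtype=float)
    time = np.asarray(time, dtype=float)
    if np.any(root_biomass <= 0) or np.any(time <= 0):
        raise ValueError("root biomass and incubation time must be > 0")
    out = uptake / (root_biomass * time)
    return out if out.ndim else float(out)


def c15n_added(config: LabelingConfig) -> float:
    """Labeled-N content added to the soil, mg N kg-1 dw soil.

    dose (μg) / cylinder soil mass (g) — μg g-1 equals mg kg-1 directly.
    """
    return config.dose_15N / config.labeled_soil_mass


def actual_uptake(uptake_15n, c_available, c15n):
    """Uptake of pre-existing soil N, μg: 15N uptake × C_available / C15N_added."""
    uptake_15n = np.asarray(uptake_15n, dtype=float)
    c_available = np.asarray(c_available, dtype=float)
    c15n = np.asarray(c15n, dtype=float)
    if np.any(c15n <= 0):
        raise ValueError("C15N_added must be > 0")
    if np.any(c_available < 0):
        raise ValueError("C_available must be >= 0")
    out = uptake_15n * c_available / c15n
    return out if out.ndim else float(out)


def actual_uptake_rate(rate_15n, c_available, c15n):
    """Actual uptake rate, μg N g-1 root h-1: 15N rate × C_available / C15N_added."""
    return actual_uptake(rate_15n, c_available, c15n)


def uptake_per_quadrat(actual_rate, root_biomass_m2, time):
    """Quadrat-scale uptake over the incubation, μg m-2: rate × root g m-2 × h."""
    actual_rate = np.asarray(actual_rate, dtype=float)
    root_biomass_m2 = np.asarray(root_biomass_m2, dtype=float)
    time = np.asarray(time, dtype=float)
    if np.any(actual_rate < 0) or np.any(root_biomass_m2 < 0) or np.any(time < 0):
        raise ValueError("inputs must be >= 0")
    out = actual_rate * root_biomass_m2 * time
    return out if out.ndim else float(out)


def pool_shoot_root(shoot_mass, shoot_value, root_mass, root_value):
    """Mass-weighted whole-plant value from separate shoot and root analyses.

    Used when N% or atom% were measured on shoot and root separately rather
    than on one pooled whole-plant powder.
    """
    shoot_mass = np.asarray(shoot_mass, dtype=float)
    root_mass = np.asarray(root_mass, dtype=float)
    total = shoot_mass + root_mass
    if np.any(total <= 0):
        raise ValueError("total biomass must be > 0")
    out = (shoot_mass * np.asarray(shoot_value, float) + root_mass * np.asarray(root_value, float)) / total
    return out if out.ndim else float(out)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing column(s): {missing}")


def compute_uptake_table(
    plants: pd.DataFrame,
    soil: pd.DataFrame,
    quadrats: pd.DataFrame | None,
    config: LabelingConfig,
) -> pd.DataFrame:
    """Run the full tracer chain on tidy plant/soil tables.

    Parameters
    ----------
    plants : DataFrame
        One row per plant with ``site, habitat, quadrat, species, treatment,
        shoot_biomass, root_biomass, n_concentration`` and either
        ``at_percent`` or ``delta15n``.
    soil : DataFrame
        One row per plant (same ids + treatment) with rhizosphere
        ``nh4`` and ``no3`` pools, mg N kg-1 dw soil.
    quadrats : DataFrame, optional
        Per species × quadrat harvest with ``shoot_biomass_m2,
        root_biomass_m2``; enables the per-quadrat uptake column.
    config : LabelingConfig
        Labeling constants (dose, geometry, incubation time).

    Returns
    -------
    DataFrame
        One row per labeled plant with ``form, ape, ape_clamped, n15_uptake,
        n15_uptake_rate, actual_uptake, actual_uptake_rate`` and, when
        harvest data are present, ``uptake_per_quadrat``.
    """
    plants = plants.copy()
    _require_columns(
        plants,
        ID_COLS + ["treatment", "shoot_biomass", "root_biomass", "n_concentration"],
        "plants",
    )
    _require_columns(soil, ID_COLS + ["treatment", "nh4", "no3"], "soil")
    if "at_percent" not in plants.columns:
        if "delta15n" not in plants.columns:
            raise ValueError("plants table needs an 'at_percent' or 'delta15n' column")
        plants["at_percent"] = delta_to_atom_percent(plants["delta15n"].to_numpy())

    labeled = plants[plants["treatment"].isin(TREATMENT_FORM)].copy()
    controls = plants[plants["treatment"] == "control"]
    if labeled.empty:
        raise ValueError("no labeled plants found")
    ctrl = controls[ID_COLS + ["at_percent"]].rename(columns={"at_percent": "at_control"})
    labeled = labeled.merge(ctrl, on=ID_COLS, how="left", validate="many_to_one")
    if labeled["at_control"].isna().any():
        bad = labeled.loc[labeled["at_control"].isna(), ID_COLS].drop_duplicates()
        raise ValueError(f"labeled plants without a same-quadrat control:\n{bad}")

    soil_keyed = soil.set_index(ID_COLS + ["treatment"])
    idx = pd.MultiIndex.from_frame(labeled[ID_COLS + ["treatment"]])
    try:
        pools = soil_keyed.loc[idx, ["nh4", "no3"]].reset_index(drop=True)
    except KeyError as err:
        raise ValueError(f"labeled plant without a rhizosphere soil record: {err}") from err
    labeled = pd.concat([labeled.reset_index(drop=True), pools], axis=1)

    labeled["form"] = labeled["treatment"].map(TREATMENT_FORM)
    ape_raw = atom_percent_excess(
        labeled["at_percent"].to_numpy(), labeled["at_control"].to_numpy()
    )
    labeled["ape_clamped"] = ape_raw < 0
    n_neg = int(labeled["ape_clamped"].sum())
    if n_neg:
        logger.warning("clamped %d negative APE value(s) to 0", n_neg)
    labeled["ape"] = np.maximum(ape_raw, 0.0)

    total_biomass = labeled["shoot_biomass"].to_numpy() + labeled["root_biomass"].to_numpy()
    labeled["n15_uptake"] = n15_uptake(
        labeled["ape"].to_numpy(), total_biomass, labeled["n_concentration"].to_numpy()
    )
    labeled["n15_uptake_rate"] = n15_uptake_rate(
        labeled["n15_uptake"].to_numpy(),
        labeled["root_biomass"].to_numpy(),
        config.incubation_time,
    )
    c15n = c15n_added(config)
    c_avail = np.where(labeled["form"] == "nh4", labeled["nh4"], labeled["no3"])
    labeled["c_available"] = c_avail
    labeled["c15n_added"] = c15n
    labeled["actual_uptake"] = actual_uptake(labeled["n15_uptake"].to_numpy(), c_avail, c15n)
    labeled["actual_uptake_rate"] = actual_uptake_rate(
        labeled["n15_uptake_rate"].to_numpy(), c_avail, c15n
    )

    if quadrats is not None:
        _require_columns(quadrats, ID_COLS + ["root_biomass_m2"], "quadrats")
        labeled = labeled.merge(
            quadrats[ID_COLS + ["root_biomass_m2"]], on=ID_COLS, how="left", validate="many_to_one"
        )
        labeled["uptake_per_quadrat"] = uptake_per_quadrat(
            labeled["actual_uptake_rate"].to_numpy(),
            labeled["root_biomass_m2"].to_numpy(),
            config.incubation_time,
        )

    keep = ID_COLS + [
        "treatment",
        "form",
        "at_percent",
        "at_control",
        "ape",
        "ape_clamped",
        "n15_uptake",
        "n15_uptake_rate",
        "c_available",
        "c15n_added",
        "actual_uptake",
        "actual_uptake_rate",
    ]
    if "uptake_per_quadrat" in labeled.columns:
        keep += ["root_biomass_m2", "uptake_per_quadrat"]
    return labeled[keep]
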