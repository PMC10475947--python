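"""Nitrogen-form acquisition-strategy indices.

Three per-quadrat quantities summarise how a plant partitions its inorganic
N uptake between ammonium and nitrate relative to what the rhizosphere soil
offers:

* ``f_NF`` — proportional contribution of a form to total actual uptake rate,
  ``f_nh4 = rate_nh4 / (rate_nh4 + rate_no3)``;
* ``beta_NF`` — preference index, ``f_NF − [NF]/[DIN]``: positive means the
  plant takes a form beyond its soil availability;
* ``PS`` — percentage similarity between the uptake composition and the soil
  composition, ``100·(1 − ½Σ|f − p|)``; 100% means perfectly proportional
  ("plastic") uptake, lower values mean a fixed preference.

Because both compositions are two-part, these are tied by exact algebraic
identities: f_no3 + f_nh4 = 1, beta_no3 = −beta_nh4, and
PS = 100 − 100·|beta_nh4|.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .isotope import ID_COLS

logger = logging.getLogger(__name__)

__all__ = [
    "proportional_contribution",
    "preference_index",
    "percentage_similarity",
    "classify_preference",
    "aggregate_indices",
    "compute_indices_table",
]


def proportional_contribution(rate_no3, rate_nh4):
    """Fractions of total actual uptake rate carried by each N form.

    Returns ``(f_no3, f_nh4)``; they sum to one.  Rows where both rates are
    zero are undefined and returned as NaN (callers flag and exclude them).
    """
    rate_no3 = np.asarray(rate_no3, dtype=float)
    rate_nh4 = np.asarray(rate_nh4, dtype=float)
    if np.any(rate_no3 < 0) or np.any(rate_nh4 < 0):
        raise ValueError("uptake rates must be >= 0")
    total = rate_no3 + rate_nh4
    with np.errstate(invalid="ignore", divide="ignore"):
        f_no3 = np.where(total > 0, rate_no3 / total, np.nan)
        f_nh4 = np.where(total > 0, rate_nh4 / total, np.nan)
    if f_no3.ndim == 0:
        return float(f_no3), float(f_nh4)
    return f_no3, f_nh4


def preference_index(f_nf, soil_nf, soil_din):
    """Preference β for one N form: f_NF − [NF]/[DIN], in [−1, 1].

    β > 0: preference for this form; β < 0: preference for the other form;
    β = 0: uptake proportional to availability.  The population-level call
    in the comparison layer is a one-sample t-test of β against zero.
    """
    f_nf = np.asarray(f_nf, dtype=float)
    soil_nf = np.asarray(soil_nf, dtype=float)
    soil_din = np.asarray(soil_din, dtype=float)
    if np.any(soil_din <= 0):
        raise ValueError("soil DIN must be > 0")
    if np.any((soil_nf < 0) | (soil_nf > soil_din)):
        raise ValueError("soil pool of one form must lie in [0, DIN]")
    if np.any((f_nf < 0) | (f_nf > 1)):
        raise ValueError("f must lie in [0, 1]")
    out = f_nf - soil_nf / soil_din
    return out if out.ndim else float(out)


def percentage_similarity(f_nh4, f_no3, p_nh4, p_no3):
    """Percentage similarity between uptake and soil compositions, in [0, 100].

    PS = 100·(1 − ½(|f_nh4 − p_nh4| + |f_no3 − p_no3|)); equals 100 exactly
    when the plant absorbs the two forms in their soil proportions.
    """
    f_nh4 = np.asarray(f_nh4, dtype=float)
    f_no3 = np.asarray(f_no3, dtype=float)
    p_nh4 = np.asarray(p_nh4, dtype=float)
    p_no3 = np.asarray(p_no3, dtype=float)
    for name, pair_sum in (("f", f_nh4 + f_no3), ("p", p_nh4 + p_no3)):
        if np.any(np.abs(pair_sum - 1.0) > 1e-9):
            raise ValueError(f"{name} fractions must sum to 1 (tolerance 1e-9)")
    for arr in (f_nh4, f_no3, p_nh4, p_no3):
        if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
            raise ValueError("fractions must lie in [0, 1]")
    out = 100.0 * (1.0 - 0.5 * (np.abs(f_nh4 - p_nh4) + np.abs(f_no3 - p_no3)))
    return out if out.ndim else float(out)


def classify_preference(beta_nh4, tol: float = 0.0):
    """Sample-level preference call from β_NH4: 'NH4', 'NO3' or 'none'."""
    beta_nh4 = np.asarray(beta_nh4, dtype=float)
    call = np.where(beta_nh4 > tol, "NH4", np.where(beta_nh4 < -tol, "NO3", "none"))
    return call if call.ndim else str(call)


def compute_indices_table(
    uptake: pd.DataFrame,
    soil: pd.DataFrame,
    *,
    soil_source: str = "plant_pair",
) -> pd.DataFrame:
    """Per-quadrat strategy indices from the uptake table and soil records.

    Each quadrat × species contributes one row built from its pair of labeled
    plants (the NH4-labeled and the NO3-labeled individual): f from their
    actual uptake rates, soil proportions p from rhizosphere pools.

    Parameters
    ----------
    uptake : DataFrame
        Output of :func:`ntracer.isotope.compute_uptake_table`.
    soil : DataFrame
        Per-plant rhizosphere pools (``nh4``, ``no3``).
    soil_source : str
        ``"plant_pair"`` (default) averages the two labeled plants' own
        rhizosphere measurements; ``"quadrat"`` averages all soil records of
        the quadrat × species, including the control plant's.
    """
    if soil_source not in {"plant_pair", "quadrat"}:
        raise ValueError("soil_source must be 'plant_pair' or 'quadrat'")

    rates = uptake.pivot_table(
        index=ID_COLS, columns="form", values="actual_uptake_rate", aggfunc="first"
    )
    if "nh4" not in rates.columns or "no3" not in rates.columns:
        raise ValueError("uptake table must contain both nh4 and no3 labeled plants")
    rates = rates.rename(columns={"nh4": "rate_nh4", "no3": "rate_no3"})

    if soil_source == "plant_pair":
        soil_use = soil[soil["treatment"].isin(["nh4_label", "no3_label"])]
    else:
        soil_use = soil
    pools = soil_use.groupby(ID_COLS)[["nh4", "no3"]].mean()
    pools = pools.rename(columns={"nh4": "soil_nh4", "no3": "soil_no3"})

    df = rates.join(pools, how="left").reset_index()
    df.columns.name = None
    df["soil_din"] = df["soil_nh4"] + df["soil_no3"]

    missing_rate = df["rate_nh4"].isna() | df["rate_no3"].isna()
    zero_rates = (df["rate_nh4"].fillna(0) + df["rate_no3"].fillna(0)) <= 0
    bad_soil = df["soil_din"].isna() | (df["soil_din"] <= 0)
    df["excluded"] = missing_rate | zero_rates | bad_soil
    n_excl = int(df["excluded"].sum())
    if n_excl:
        logger.warning(
            "excluded %d quadrat row(s) with undefined indices "
            "(missing pair member, zero total rate, or empty soil DIN)",
            n_excl,
        )

    ok = ~df["excluded"]
    df["f_no3"] = np.nan
    df["f_nh4"] = np.nan
    if ok.any():
        f_no3, f_nh4 = proportional_contribution(
            df.loc[ok, "rate_no3"].to_numpy(), df.loc[ok, "rate_nh4"].to_numpy()
        )
        df.loc[ok, "f_no3"] = f_no3
        df.loc[ok, "f_nh4"] = f_nh4
    df["p_nh4"] = df["soil_nh4"] / df["soil_din"]
    df["p_no3"] = df["soil_no3"] / df["soil_din"]
    df["beta_nh4"] = df["f_nh4"] - df["p_nh4"]
    df["beta_no3"] = df["f_no3"] - df["p_no3"]
    df["ps"] = np.nan
    if ok.any():
        df.loc[ok, "ps"] = percentage_similarity(
            df.loc[ok, "f_nh4"].to_numpy(),
            df.loc[ok, "f_no3"].to_numpy(),
            df.loc[ok, "p_nh4"].to_numpy(),
            df.loc[ok, "p_no3"].to_numpy(),
        )
    df["preference_call"] = "excluded"
    if ok.any():
        df.loc[ok, "preference_call"] = classify_preference(df.loc[ok, "beta_nh4"].to_numpy())
    return df


def aggregate_indices(
    indices: pd.DataFrame,
    by: list[str] | tuple[str, ...] = ("species", "habitat"),
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Cell means ± SE with n, the form figure panels report (n = 12 default design).

    Excluded rows (flagged undefined upstream) are dropped before
    aggregation; empty cells appear with n = 0 and NaN summaries rather than
    raising.
    """
    by = list(by)
    if value_cols is None:
        value_cols = [
            c
            for c in ("f_nh4", "f_no3", "beta_nh4", "beta_no3", "ps", "rate_nh4", "rate_no3")
            if c in indices.columns
        ]
    data = indices
    if "excluded" in indices.columns:
        data = indices[~indices["excluded"]]

    records = []
    grouped = data.groupby(by, sort=True, dropna=False)
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(by, key))
        for col in value_cols:
            vals = sub[col].dropna()
            n = len(vals)
            rec[f"{col}_mean"] = vals.mean() if n else np.nan
            rec[f"{col}_se"] = vals.std(ddof=1) / np.sqrt(n) if n > 1 else (0.0 if n == 1 else np.nan)
            rec[f"{col}_n"] = n
        records.append(rec)
    return pd.DataFrame.from_records(records)
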