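"""Pipeline orchestration: table validation, end-to-end runs, artifact output.

A run is a pure function of (input tables, configuration, seed): the output
directory receives ``uptake.csv``, ``indices.csv``, ``summary.csv``,
``tests.csv`` and ``stats_report.json``, plus a ``run_meta.json`` sidecar
recording the seed, a configuration hash and the SHA-256 of every artifact,
and a ``schema.json`` sidecar documenting column units.  CSVs are UTF-8
with '.' decimals and a mandatory header row, kept free of comment lines so
field ecologists can open and hand-edit them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .indices import aggregate_indices, compute_indices_table
from .isotope import ID_COLS, TREATMENT_FORM, compute_uptake_table
from .simulate import simulate_dataset
from . import stats as nstats
from .sma import sma_compare

logger = logging.getLogger(__name__)

__all__ = ["validate_tables", "run_pipeline", "COLUMN_UNITS"]

COLUMN_UNITS = {
    "plants.csv": {
        "shoot_biomass": "g dry mass",
        "root_biomass": "g dry mass (roots within the labeled cylinder)",
        "n_concentration": "% of dry mass",
        "delta15n": "per mil vs air N2",
        "at_percent": "atom% 15N",
    },
    "soil.csv": {
        "nh4": "mg N kg-1 dw soil",
        "no3": "mg N kg-1 dw soil",
        "din": "mg N kg-1 dw soil",
        "ratio_no3_nh4": "dimensionless",
    },
    "quadrats.csv": {
        "shoot_biomass_m2": "g m-2",
        "root_biomass_m2": "g m-2",
        "root_shoot_ratio": "dimensionless",
    },
    "uptake.csv": {
        "ape": "atom% excess",
        "n15_uptake": "ug 15N",
        "n15_uptake_rate": "ug N g-1 root h-1",
        "c_available": "mg N kg-1 dw soil",
        "c15n_added": "mg N kg-1 dw soil",
        "actual_uptake": "ug N",
        "actual_uptake_rate": "ug N g-1 root h-1",
        "uptake_per_quadrat": "ug N m-2 per incubation",
    },
    "indices.csv": {
        "rate_nh4": "ug N g-1 root h-1",
        "rate_no3": "ug N g-1 root h-1",
        "f_nh4": "fraction",
        "f_no3": "fraction",
        "p_nh4": "fraction",
        "p_no3": "fraction",
        "beta_nh4": "dimensionless, [-1, 1]",
        "beta_no3": "dimensionless, [-1, 1]",
        "ps": "%",
    },
}


class ValidationError(ValueError):
    """Input tables violate the schema or referential-integrity contract."""


def _fail(messages: list[str]) -> None:
    if messages:
        raise ValidationError("input validation failed:\n" + "\n".join(f"- {m}" for m in messages))


def validate_tables(
    plants: pd.DataFrame, soil: pd.DataFrame, quadrats: pd.DataFrame | None = None
) -> dict:
    """Schema, sign and referential-integrity checks on the input tables.

    Fails fast with row-level messages: every labeled plant must have a
    same-quadrat control plant and its own rhizosphere soil record;
    biomasses and N concentration must be positive, soil pools non-negative.
    Returns a small report dict when the tables are clean.
    """
    errors: list[str] = []
    need_plants = ID_COLS + ["treatment", "shoot_biomass", "root_biomass", "n_concentration"]
    for col in need_plants:
        if col not in plants.columns:
            errors.append(f"plants: missing column {col!r}")
    if "at_percent" not in plants.columns and "delta15n" not in plants.columns:
        errors.append("plants: need an 'at_percent' or 'delta15n' column")
    for col in ID_COLS + ["treatment", "nh4", "no3"]:
        if col not in soil.columns:
            errors.append(f"soil: missing column {col!r}")
    if quadrats is not None:
        for col in ID_COLS + ["shoot_biomass_m2", "root_biomass_m2"]:
            if col not in quadrats.columns:
                errors.append(f"quadrats: missing column {col!r}")
    _fail(errors)

    for col in ("shoot_biomass", "root_biomass", "n_concentration"):
        bad = plants.index[~(plants[col] > 0)].tolist()
        if bad:
            errors.append(f"plants: non-positive {col} at row(s) {bad}")
    if "at_percent" in plants.columns:
        bad = plants.index[~plants["at_percent"].between(0.2, 100, inclusive="left")].tolist()
        if bad:
            errors.append(f"plants: at_percent outside [0.2, 100) at row(s) {bad}")
    for col in ("nh4", "no3"):
        bad = soil.index[soil[col] < 0].tolist()
        if bad:
            errors.append(f"soil: negative {col} at row(s) {bad}")
    if quadrats is not None:
        for col in ("shoot_biomass_m2", "root_biomass_m2"):
            bad = quadrats.index[~(quadrats[col] > 0)].tolist()
            if bad:
                errors.append(f"quadrats: non-positive {col} at row(s) {bad}")

    labeled = plants[plants["treatment"].isin(TREATMENT_FORM)]
    controls = plants[plants["treatment"] == "control"]
    ctrl_keys = set(map(tuple, controls[ID_COLS].to_numpy()))
    soil_keys = set(map(tuple, soil[ID_COLS + ["treatment"]].to_numpy()))
    for _, row in labeled.iterrows():
        key = tuple(row[ID_COLS])
        if key not in ctrl_keys:
            errors.append(
                f"labeled plant without same-quadrat control: site={key[0]} habitat={key[1]} "
                f"quadrat={key[2]} species={key[3]}"
            )
        if tuple(row[ID_COLS + ["treatment"]]) not in soil_keys:
            errors.append(
                f"labeled plant without rhizosphere soil record: {key} treatment={row['treatment']}"
            )
    dup = plants.duplicated(subset=ID_COLS + ["treatment"])
    if dup.any():
        errors.append(f"plants: duplicated plant slots at row(s) {plants.index[dup].tolist()}")
    _fail(errors)

    return {
        "n_plants": int(len(plants)),
        "n_labeled": int(len(labeled)),
        "n_controls": int(len(controls)),
        "n_soil": int(len(soil)),
        "clean": True,
    }


def _species_comparisons(indices: pd.DataFrame, alpha: float) -> list[dict]:
    """Habitat-wise species t-tests and per-cell one-sample β tests."""
    rows: list[dict] = []
    species = sorted(indices["species"].unique())
    ok = indices[~indices["excluded"]] if "excluded" in indices.columns else indices
    for habitat, sub in ok.groupby("habitat", sort=True):
        if len(species) == 2:
            a = sub.loc[sub["species"] == species[0], "beta_nh4"].dropna()
            b = sub.loc[sub["species"] == species[1], "beta_nh4"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                res = nstats.welch_or_student_t(a, b)
                rows.append(
                    {
                        "test": "species_t",
                        "variable": "beta_nh4",
                        "habitat": habitat,
                        "species": "|".join(species),
                        "statistic": res.t,
                        "df": res.df,
                        "p_value": res.p,
                        "significant": res.p < alpha,
                    }
                )
        for sp, cell in sub.groupby("species", sort=True):
            for var in ("beta_nh4", "beta_no3"):
                vals = cell[var].dropna()
                if len(vals) >= 2:
                    res = nstats.one_sample_t(vals, 0.0)
                    rows.append(
                        {
                            "test": "beta_vs_zero",
                            "variable": var,
                            "habitat": habitat,
                            "species": sp,
                            "statistic": res.t,
                            "df": res.df,
                            "p_value": res.p,
                            "significant": res.p < alpha,
                        }
                    )
    return rows


def _habitat_anovas(indices: pd.DataFrame, alpha: float) -> tuple[list[dict], dict]:
    rows: list[dict] = []
    letters_out: dict = {}
    ok = indices[~indices["excluded"]] if "excluded" in indices.columns else indices
    for sp, sub in ok.groupby("species", sort=True):
        if sub["habitat"].nunique() < 2:
            continue
        for var in ("ps", "beta_nh4", "f_nh4"):
            vals = sub[var].dropna()
            grp = sub.loc[vals.index, "habitat"]
            if grp.nunique() < 2 or grp.value_counts().min() < 2:
                continue
            try:
                res = nstats.oneway_anova_letters(vals.to_numpy(), grp.to_numpy(), alpha=alpha)
            except ValueError:
                continue
            rows.append(
                {
                    "test": "habitat_anova",
                    "variable": var,
                    "habitat": "all",
                    "species": sp,
                    "statistic": res.f_statistic,
                    "df": np.nan,
                    "p_value": res.p_value,
                    "significant": res.p_value < alpha,
                }
            )
            letters_out[f"{sp}:{var}"] = res.letters
    return rows, letters_out


def _sma_layer(indices: pd.DataFrame, soil: pd.DataFrame, alpha: float) -> dict:
    """Species-wise SMA of (quantile-transformed) β_NH4 against log soil DIN."""
    ok = indices[~indices["excluded"]] if "excluded" in indices.columns else indices
    groups = {}
    for sp, sub in ok.groupby("species", sort=True):
        din = sub["soil_din"].to_numpy(dtype=float)
        beta = sub["beta_nh4"].to_numpy(dtype=float)
        keep = np.isfinite(din) & np.isfinite(beta) & (din > 0)
        if keep.sum() < 3:
            continue
        x, _ = nstats.log_transform(din[keep])
        try:
            y = nstats.quantile_transform(beta[keep])
        except ValueError:
            continue
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            groups[sp] = (x, y)
    if len(groups) < 2:
        return {"available": False}
    comp = sma_compare(groups, alpha=alpha)
    return {
        "available": True,
        "x": "ln(soil DIN)",
        "y": "quantile(beta_nh4)",
        "slopes": comp.slopes,
        "common_slope_stat": comp.common_slope_stat,
        "common_slope_p": comp.common_slope_p,
        "common_slope_estimate": comp.common_slope_estimate,
        "slopes_homogeneous": comp.slopes_homogeneous,
        "elevation_p": comp.elevation_p,
        "shift_p": comp.shift_p,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write artifacts; returns the output directory.

    In simulate mode (``config.design`` set) the input tables are generated
    by the forward simulator under ``config.seed``; otherwise they are read
    from the configured CSV paths.  Artifacts are a deterministic function
    of (inputs, config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, pd.DataFrame] = {}

    if config.design is not None:
        logger.info("stage: simulate (seed=%d)", config.seed)
        design = config.design.model_copy(update={"seed": config.seed})
        ds = simulate_dataset(design, None, config.noise, config.labeling)
        plants, soil, quadrats = ds.plants, ds.soil, ds.quadrats
        written["truth.csv"] = ds.truth
    else:
        logger.info("stage: load tables")
        try:
            plants = pd.read_csv(config.plants_path)
            soil = pd.read_csv(config.soil_path)
            quadrats = pd.read_csv(config.quadrats_path) if config.quadrats_path else None
        except FileNotFoundError as err:
            raise ValidationError(f"stage load: missing input file ({err})") from err
    written["plants.csv"] = plants
    written["soil.csv"] = soil
    if quadrats is not None:
        written["quadrats.csv"] = quadrats

    logger.info("stage: validate")
    validate_tables(plants, soil, quadrats)

    logger.info("stage: uptake chain")
    uptake = compute_uptake_table(plants, soil, quadrats, config.labeling)
    written["uptake.csv"] = uptake

    logger.info("stage: strategy indices")
    indices = compute_indices_table(uptake, soil, soil_source=config.soil_source)
    written["indices.csv"] = indices
    written["summary.csv"] = aggregate_indices(indices)

    logger.info("stage: comparisons")
    test_rows = _species_comparisons(indices, config.alpha)
    anova_rows, letters = _habitat_anovas(indices, config.alpha)
    tests = pd.DataFrame(test_rows + anova_rows)
    written["tests.csv"] = tests

    report = {
        "alpha": config.alpha,
        "multiple_testing_correction": "none (applied across response variables deliberately)",
        "letters": letters,
        "sma": _sma_layer(indices, soil, config.alpha),
        "n_clamped_ape": int(uptake["ape_clamped"].sum()),
        "n_excluded_quadrats": int(indices["excluded"].sum()),
    }

    for name, df in written.items():
        df.to_csv(out / name, index=False)
    (out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "schema.json").write_text(json.dumps(COLUMN_UNITS, indent=2))

    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": {
            name: _sha256(out / name) for name in sorted(list(written) + ["stats_report.json"])
        },
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    logger.info("pipeline complete: %s", out)
    return out
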