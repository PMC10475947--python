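"""Forward simulator of the 15N field-labeling design.

Generates a complete synthetic dataset — plant isotope/biomass records,
per-plant rhizosphere soil pools, quadrat harvests — from a ground-truth
table of actual uptake rates and soil/biomass levels, by running the tracer
chain FORWARD:

    true actual uptake rate → actual uptake over the incubation
    → 15N uptake (scaled by C15N_added / C_available)
    → atom% excess → labeled atom% = control atom% + APE
    → δ15N, plus normal noise in δ-space.

Biomass, N concentration and soil pools are drawn log-normally around their
truth means (mean-preserving parameterisation) so every draw is positive;
with all noise at zero, the dataset inverts exactly through the analysis
chain, which is the basis of the parameter-recovery tests.

The default truth table emulates a paired invasive/native field contrast:
ammonium-dominant farmland and wasteland soils, nitrate-dominant roadside
soil, an invader whose uptake tracks the locally dominant form, and a
native that leans on nitrate everywhere.  Its values are illustrative
levels typical of temperate herbaceous communities, not estimates from any
particular study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LabelingConfig, NoiseModel, StudyDesign
from .isotope import (
    ID_COLS,
    TREATMENT_FORM,
    atom_percent_to_delta,
    c15n_added,
    delta_to_atom_percent,
)

__all__ = [
    "InfeasibleLabelingError",
    "SimulatedDataset",
    "generate_design",
    "default_truth",
    "validate_truth",
    "truth_expectations",
    "simulate_dataset",
]

TRUTH_COLUMNS = [
    "species",
    "habitat",
    "rate_nh4",
    "rate_no3",
    "soil_nh4",
    "soil_no3",
    "shoot_g_m2",
    "root_g_m2",
    "plant_shoot_g",
    "n_concentration",
]


class InfeasibleLabelingError(ValueError):
    """Truth implies a labeled-plant atom% above the label enrichment (dose too small)."""


@dataclass
class SimulatedDataset:
    """Bundle of simulator outputs: tidy tables plus the truth echo."""

    plants: pd.DataFrame
    soil: pd.DataFrame
    quadrats: pd.DataFrame
    truth: pd.DataFrame


def generate_design(design: StudyDesign) -> pd.DataFrame:
    """Expand a :class:`StudyDesign` into one row per plant individual.

    Exactly one plant per treatment per quadrat per species; row count is
    the product of all design constants (216 for the default design).
    """
    sites = [f"site{i + 1}" for i in range(design.n_sites)]
    quadrats = [f"q{i + 1}" for i in range(design.n_quadrats_per_cell)]
    idx = pd.MultiIndex.from_product(
        [sites, design.habitats, quadrats, design.species, design.treatments],
        names=["site", "habitat", "quadrat", "species", "treatment"],
    )
    return idx.to_frame(index=False)


def default_truth() -> pd.DataFrame:
    """Ground-truth table for the default two-species × three-habitat contrast.

    Actual uptake rates are μg N g-1 root h-1, soil pools mg N kg-1 dw,
    biomass g m-2 (quadrat scale) or g (per plant), N concentration % of
    dry mass.
    """
    rows = [
        # species, habitat, rate_nh4, rate_no3, soil_nh4, soil_no3,
        # shoot_g_m2, root_g_m2, plant_shoot_g, n_concentration
        ("invasive", "farmland", 5.0, 1.5, 8.0, 4.0, 600.0, 180.0, 6.0, 1.5),
        ("invasive", "wasteland", 6.0, 1.2, 6.0, 2.5, 500.0, 150.0, 5.0, 1.5),
        ("invasive", "roadside", 1.0, 7.0, 2.0, 8.0, 380.0, 110.0, 3.5, 1.5),
        ("native", "farmland", 2.0, 1.5, 8.0, 4.0, 300.0, 90.0, 3.0, 1.3),
        ("native", "wasteland", 1.6, 1.4, 6.0, 2.5, 240.0, 75.0, 2.4, 1.3),
        ("native", "roadside", 0.6, 3.4, 2.0, 8.0, 340.0, 110.0, 3.2, 1.3),
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def validate_truth(truth: pd.DataFrame, design: StudyDesign) -> None:
    """Check the truth table covers every species × habitat cell with sane values."""
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ValueError(f"truth table missing column(s): {missing}")
    cells = set(zip(truth["species"], truth["habitat"]))
    wanted = {(s, h) for s in design.species for h in design.habitats}
    absent = wanted - cells
    if absent:
        raise ValueError(f"truth table missing species × habitat cell(s): {sorted(absent)}")
    numeric = truth[TRUTH_COLUMNS[2:]]
    if (numeric < 0).any().any():
        raise ValueError("truth rates, pools and biomasses must be >= 0")
    if ((truth["rate_nh4"] + truth["rate_no3"]) <= 0).any():
        raise ValueError("each truth cell needs a positive total uptake rate")


def truth_expectations(truth: pd.DataFrame) -> pd.DataFrame:
    """Closed-form f, β and PS implied by a truth table (the recovery targets)."""
    out = truth.copy()
    total = out["rate_nh4"] + out["rate_no3"]
    out["f_nh4"] = out["rate_nh4"] / total
    out["f_no3"] = out["rate_no3"] / total
    din = out["soil_nh4"] + out["soil_no3"]
    out["p_nh4"] = out["soil_nh4"] / din
    out["p_no3"] = out["soil_no3"] / din
    out["beta_nh4"] = out["f_nh4"] - out["p_nh4"]
    out["beta_no3"] = out["f_no3"] - out["p_no3"]
    out["ps"] = 100.0 * (1.0 - np.abs(out["beta_nh4"]))
    return out


def _lognormal_around(rng: np.random.Generator, mean, cv: float, size: int) -> np.ndarray:
    """Mean-preserving log-normal draws: E[X] = mean, sd(X)/mean = cv."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if cv <= 0:
        return mean.copy()
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def simulate_dataset(
    design: StudyDesign,
    truth: pd.DataFrame | None = None,
    noise: NoiseModel | None = None,
    config: LabelingConfig | None = None,
    *,
    seed: int | None = None,
) -> SimulatedDataset:
    """Simulate plant, soil and quadrat-harvest tables under a truth table.

    Parameters
    ----------
    design : StudyDesign
        Factor layout; ``design.seed`` seeds the generator unless ``seed``
        is given explicitly.
    truth : DataFrame, optional
        Per species × habitat ground truth (:func:`default_truth` if None).
    noise : NoiseModel, optional
        Measurement/field noise (defaults: 0.2‰ δ15N, 20% biomass CV,
        25% soil-pool CV, 5% N-concentration CV).
    config : LabelingConfig, optional
        Labeling constants; also supplies the cylinder root fraction that
        converts quadrat root standing crop to per-plant labeled-zone root
        biomass.

    Raises
    ------
    InfeasibleLabelingError
        If the truth implies a labeled plant more enriched than the label
        itself — the tracer dose cannot support the requested uptake.
    """
    truth = default_truth() if truth is None else truth
    noise = NoiseModel() if noise is None else noise
    config = LabelingConfig() if config is None else config
    validate_truth(truth, design)
    rng = np.random.default_rng(design.seed if seed is None else seed)

    plants = generate_design(design)
    n = len(plants)
    tkey = truth.set_index(["species", "habitat"])
    per_row = tkey.loc[pd.MultiIndex.from_frame(plants[["species", "habitat"]])].reset_index(
        drop=True
    )

    # Quadrat harvests: one draw per site × habitat × quadrat × species,
    # shared by that quadrat's three plants.
    quadrats = plants[ID_COLS].drop_duplicates().reset_index(drop=True)
    qtruth = tkey.loc[pd.MultiIndex.from_frame(quadrats[["species", "habitat"]])].reset_index(
        drop=True
    )
    nq = len(quadrats)
    quadrats["shoot_biomass_m2"] = _lognormal_around(
        rng, qtruth["shoot_g_m2"], noise.relative_sd_biomass, nq
    )
    quadrats["root_biomass_m2"] = _lognormal_around(
        rng, qtruth["root_g_m2"], noise.relative_sd_biomass, nq
    )
    quadrats["root_shoot_ratio"] = quadrats["root_biomass_m2"] / quadrats["shoot_biomass_m2"]

    qroot = quadrats.set_index(ID_COLS)["root_biomass_m2"]
    plant_qroot = qroot.loc[pd.MultiIndex.from_frame(plants[ID_COLS])].to_numpy()

    plants["shoot_biomass"] = _lognormal_around(
        rng, per_row["plant_shoot_g"], noise.relative_sd_biomass, n
    )
    root_jitter = _lognormal_around(rng, np.ones(n), noise.relative_sd_biomass, n)
    plants["root_biomass"] = config.cylinder_root_fraction * plant_qroot * root_jitter
    plants["n_concentration"] = _lognormal_around(
        rng, per_row["n_concentration"], noise.relative_sd_nconc, n
    )

    soil = plants[ID_COLS + ["treatment"]].copy()
    soil["nh4"] = _lognormal_around(rng, per_row["soil_nh4"], noise.relative_sd_soilN, n)
    soil["no3"] = _lognormal_around(rng, per_row["soil_no3"], noise.relative_sd_soilN, n)
    soil["din"] = soil["nh4"] + soil["no3"]
    soil["ratio_no3_nh4"] = np.where(soil["nh4"] > 0, soil["no3"] / soil["nh4"], np.nan)

    # Forward tracer chain for labeled plants, using each plant's own drawn
    # biomass/soil values so the analysis chain inverts them exactly.
    c15n = c15n_added(config)
    is_labeled = plants["treatment"].isin(TREATMENT_FORM).to_numpy()
    form = plants["treatment"].map(TREATMENT_FORM)
    true_rate = np.where(
        form == "nh4", per_row["rate_nh4"], np.where(form == "no3", per_row["rate_no3"], 0.0)
    )
    c_avail = np.where(form == "nh4", soil["nh4"], np.where(form == "no3", soil["no3"], np.nan))

    actual = true_rate * plants["root_biomass"].to_numpy() * config.incubation_time
    with np.errstate(invalid="ignore", divide="ignore"):
        n15 = np.where(c_avail > 0, actual * c15n / c_avail, 0.0)
    total_biomass = plants["shoot_biomass"].to_numpy() + plants["root_biomass"].to_numpy()
    # Invert the uptake formula: APE (%) = n15 / (100 · biomass(g) · N%).
    ape_true = np.where(is_labeled, n15 / (100.0 * total_biomass * plants["n_concentration"]), 0.0)

    at_true = config.atm_at_percent + ape_true
    enrich = np.where(form == "nh4", config.enrichment_nh4, config.enrichment_no3)
    too_hot = is_labeled & (at_true > enrich)
    if too_hot.any():
        worst = float(at_true[too_hot].max())
        raise InfeasibleLabelingError(
            f"truth implies labeled-plant atom% up to {worst:.2f}, above the label "
            "enrichment — increase the tracer dose or lower the truth uptake rates"
        )

    delta_true = atom_percent_to_delta(at_true)
    delta_obs = delta_true + (
        rng.normal(0.0, noise.delta15N_sd, size=n) if noise.delta15N_sd > 0 else 0.0
    )
    plants["delta15n"] = delta_obs
    plants["at_percent"] = delta_to_atom_percent(delta_obs)

    truth_echo = truth_expectations(truth)
    return SimulatedDataset(plants=plants, soil=soil, quadrats=quadrats, truth=truth_echo)
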