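"""Configuration models for the labeling experiment, the study design and noise.

All percent-valued quantities are stored as percent (atom%, N% of dry mass),
matching how isotope laboratories report them; conversion to fractions happens
only inside formulas.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: 15N atom% of atmospheric N2, the delta-notation reference standard.
ATM_AT_PERCENT = 0.3663

#: 15N/14N isotope ratio of atmospheric N2.
ATM_RATIO_15N = 0.0036765

#: Molar mass of 15N, g mol-1 (dose bookkeeping uses the heavy isotope only).
MOLAR_MASS_15N = 15.0


class LabelingConfig(BaseModel):
    """Constants of the 15N field-labeling protocol.

    Defaults describe a tracer addition of 360 μg 15N per plant, delivered as
    48 mL of a 0.5 mmol 15N L-1 solution into a soil cylinder of 5 cm radius
    and 15 cm depth around each plant, harvested after 48 h.

    Parameters
    ----------
    dose_15N : float
        Tracer mass added per plant, μg 15N.
    solution_volume : float
        Labeling solution volume per plant, mL.
    solution_conc : float
        Labeling solution concentration, mmol 15N L-1.
    enrichment_nh4, enrichment_no3 : float
        atom% 15N of the labeled ammonium and nitrate salts.
    cylinder_radius, cylinder_depth : float
        Geometry of the labeled soil cylinder, cm.
    bulk_density : float
        Soil bulk density, g cm-3. The default makes the labeled cylinder
        hold ≈ 1500 g of soil.
    incubation_time : float
        Labeling-to-harvest interval, h.
    atm_at_percent : float
        Natural-abundance baseline, atom% 15N of air N2.
    cylinder_root_fraction : float
        Fraction of the per-m2 quadrat root standing crop found inside one
        labeled cylinder; used by the simulator to draw per-plant root
        biomass (field studies do not report it directly).
    """

    dose_15N: float = 360.0
    solution_volume: float = 48.0
    solution_conc: float = 0.5
    enrichment_nh4: float = 99.12
    enrichment_no3: float = 99.21
    cylinder_radius: float = 5.0
    cylinder_depth: float = 15.0
    bulk_density: float = 1.273
    incubation_time: float = 48.0
    atm_at_percent: float = ATM_AT_PERCENT
    cylinder_root_fraction: float = 0.02

    @field_validator(
        "dose_15N",
        "solution_volume",
        "solution_conc",
        "cylinder_radius",
        "cylinder_depth",
        "bulk_density",
        "incubation_time",
        "cylinder_root_fraction",
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("labeling constants must be > 0")
        return v

    @field_validator("enrichment_nh4", "enrichment_no3")
    @classmethod
    def _enrichment_range(cls, v: float) -> float:
        if not (ATM_AT_PERCENT < v <= 100.0):
            raise ValueError(
                f"label enrichment must be in ({ATM_AT_PERCENT}, 100] atom%, got {v}"
            )
        return v

    @property
    def labeled_soil_mass(self) -> float:
        """Dry soil mass inside the labeled cylinder, g (π r² h ρ_b)."""
        return math.pi * self.cylinder_radius**2 * self.cylinder_depth * self.bulk_density

    def enrichment(self, form: str) -> float:
        """Label enrichment (atom%) for ``'nh4'`` or ``'no3'``."""
        if form == "nh4":
            return self.enrichment_nh4
        if form == "no3":
            return self.enrichment_no3
        raise ValueError(f"unknown N form {form!r}")

    def dose_from_solution(self) -> float:
        """Per-plant dose implied by solution volume × concentration, μg 15N.

        Consistency check: 0.5 mmol L-1 × 48 mL × 15 g mol-1 → 360 μg.
        """
        return self.solution_conc * 1e-3 * self.solution_volume * 1e-3 * MOLAR_MASS_15N * 1e9 * 1e-3


class StudyDesign(BaseModel):
    """Hierarchical field design: sites × habitats × quadrats × species × treatments.

    The default is four sites, three habitats, three quadrats per
    species × habitat cell per site, two species and three treatments,
    giving 12 quadrat replicates per species × habitat cell and 216 plants.
    """

    n_sites: int = 4
    habitats: list[str] = Field(default_factory=lambda: ["farmland", "wasteland", "roadside"])
    n_quadrats_per_cell: int = 3
    species: list[str] = Field(default_factory=lambda: ["invasive", "native"])
    treatments: list[str] = Field(default_factory=lambda: ["nh4_label", "no3_label", "control"])
    seed: int = 0

    @field_validator("n_sites", "n_quadrats_per_cell")
    @classmethod
    def _count_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("design counts must be >= 1")
        return v

    @field_validator("habitats", "species", "treatments")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if len(v) < 1:
            raise ValueError("design factor lists must be non-empty")
        if len(set(v)) != len(v):
            raise ValueError("design factor levels must be unique")
        return v

    @property
    def replicates_per_cell(self) -> int:
        """Quadrat replicates per species × habitat cell."""
        return self.n_sites * self.n_quadrats_per_cell

    @property
    def n_rows(self) -> int:
        """Total number of plant individuals in the design."""
        return (
            self.n_sites
            * len(self.habitats)
            * self.n_quadrats_per_cell
            * len(self.species)
            * len(self.treatments)
        )


class NoiseModel(BaseModel):
    """Measurement / field-variability noise for the simulator.

    delta15N noise is normal in δ-space (the scale on which mass-spectrometer
    precision is quoted, default 0.2‰); biomass, N concentration and soil
    pools are log-normal around their truth means so draws stay positive.
    """

    delta15N_sd: float = 0.2
    relative_sd_biomass: float = 0.20
    relative_sd_soilN: float = 0.25
    relative_sd_nconc: float = 0.05

    @field_validator("delta15N_sd", "relative_sd_biomass", "relative_sd_soilN", "relative_sd_nconc")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise standard deviations must be >= 0")
        return v

    @classmethod
    def zero(cls) -> "NoiseModel":
        """A noise-free model, used for exact-inversion checks."""
        return cls(delta15N_sd=0.0, relative_sd_biomass=0.0, relative_sd_soilN=0.0, relative_sd_nconc=0.0)


class PipelineConfig(BaseModel):
    """End-to-end pipeline configuration (simulate mode or run-on-files mode)."""

    labeling: LabelingConfig = Field(default_factory=LabelingConfig)
    design: Optional[StudyDesign] = None
    noise: Optional[NoiseModel] = None
    plants_path: Optional[str] = None
    soil_path: Optional[str] = None
    quadrats_path: Optional[str] = None
    alpha: float = 0.05
    log_base: str = "e"
    soil_source: str = "plant_pair"  # or "quadrat"
    seed: int = 0
    out_dir: str = "out"

    @field_validator("alpha")
    @classmethod
    def _alpha_range(cls, v: float) -> float:
        if not (0 < v < 1):
            raise ValueError("alpha must be in (0, 1)")
        return v

    @field_validator("soil_source")
    @classmethod
    def _soil_source(cls, v: str) -> str:
        if v not in {"plant_pair", "quadrat"}:
            raise ValueError("soil_source must be 'plant_pair' or 'quadrat'")
        return v

    @model_validator(mode="after")
    def _mode_consistency(self) -> "PipelineConfig":
        simulate_mode = self.design is not None
        file_mode = self.plants_path is not None
        if not simulate_mode and not file_mode:
            raise ValueError("config must specify either a design (simulate mode) or input tables")
        return self

    def config_hash(self) -> str:
        """Stable SHA-256 of the scientific configuration (output path excluded)."""
        payload = self.model_dump()
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
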