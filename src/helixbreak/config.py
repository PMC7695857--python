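"""Validated run configuration (pydantic, unknown keys rejected).

Defaults reproduce the damage-parameter set of the simulated study
conditions: R_dir 0.35 nm, E_min 5 eV, E_max 37.5 eV, P_OH 0.405,
T_chem 5 ns, d_kill 9 nm.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import chemistry, geometry, pipeline, scoring, tracks


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    n_bp: int = Field(default=100_000, ge=1)
    histone_scavenging: bool = True
    histone_spacing_bp: int = Field(default=200, ge=1)
    container_margin_nm: float = Field(default=15.0, gt=0)
    rise_nm: float = Field(default=0.34, gt=0)
    twist_deg: float = 34.0
    helix_radius_nm: float = Field(default=1.0, gt=0)


class TracksSection(_Strict):
    dose_gy: float = Field(default=1.0, ge=0)
    deposits_per_um: float = Field(default=100.0, gt=0)
    energy_mean_ev: float = Field(default=45.0, gt=0)
    energy_min_ev: float = Field(default=1.0, gt=0)
    radial_sigma_nm: float = Field(default=2.0, gt=0)
    g_oh_per_100ev: float = Field(default=2.5, gt=0)


class ChemistrySection(_Strict):
    d_oh_nm2_per_ns: float = Field(default=2.8, gt=0)
    dt_ns: float = Field(default=0.001, gt=0)
    t_chem_ns: float = Field(default=5.0, ge=0)
    reaction_radius_nm: float = Field(default=0.22, ge=0)
    d_kill_nm: float = Field(default=9.0, gt=0)


class ScoringSection(_Strict):
    r_dir_nm: float = Field(default=0.35, gt=0)
    e_min_break_ev: float = Field(default=5.0, gt=0)
    e_max_break_ev: float = Field(default=37.5, gt=0)
    p_oh_break: float = Field(default=0.405, ge=0, le=1)

    @model_validator(mode="after")
    def _ordered(self):
        if self.e_min_break_ev >= self.e_max_break_ev:
            raise ValueError("e_min_break_ev must be below e_max_break_ev")
        return self


class ClassificationSection(_Strict):
    d_dsb_bp: int = Field(default=10, ge=1)
    cluster_gap_bp: int = Field(default=100, ge=1)
    distant_gap_bp: int = Field(default=10_000, ge=1)


class RepairSection(_Strict):
    rate_table_path: Optional[str] = None
    t_end_h: float = Field(default=25.0, gt=0)
    dt_out_h: float = Field(default=0.1, gt=0)
    normalize: Literal["max", "absolute"] = "max"


class RunConfig(_Strict):
    geometry: GeometrySection = GeometrySection()
    tracks: TracksSection = TracksSection()
    chemistry: ChemistrySection = ChemistrySection()
    scoring: ScoringSection = ScoringSection()
    classification: ClassificationSection = ClassificationSection()
    repair: RepairSection = RepairSection()
    seed: int = 0
    output_dir: str = "helixbreak_out"
    verbosity: int = Field(default=1, ge=0, le=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_pipeline_config(self) -> pipeline.PipelineConfig:
        g, t, c, s, cl = (self.geometry, self.tracks, self.chemistry,
                          self.scoring, self.classification)
        return pipeline.PipelineConfig(
            n_bp=g.n_bp, dose_gy=t.dose_gy,
            histone_scavenging=g.histone_scavenging,
            histone_spacing_bp=g.histone_spacing_bp,
            container_margin_nm=g.container_margin_nm,
            d_kill_nm=c.d_kill_nm,
            geometry=geometry.GeometryConfig(
                rise_nm=g.rise_nm, twist_deg=g.twist_deg,
                helix_radius_nm=g.helix_radius_nm),
            irradiation=tracks.IrradiationConfig(
                dose_gy=t.dose_gy, deposits_per_um=t.deposits_per_um,
                energy_mean_ev=t.energy_mean_ev,
                energy_min_ev=t.energy_min_ev,
                radial_sigma_nm=t.radial_sigma_nm,
                g_oh_per_100ev=t.g_oh_per_100ev),
            chem=chemistry.ChemConfig(
                d_oh_nm2_per_ns=c.d_oh_nm2_per_ns, dt_ns=c.dt_ns,
                t_chem_ns=c.t_chem_ns,
                reaction_radius_nm=c.reaction_radius_nm),
            scoring=scoring.ScoringParams(
                r_dir_nm=s.r_dir_nm, e_min_break_ev=s.e_min_break_ev,
                e_max_break_ev=s.e_max_break_ev, p_oh_break=s.p_oh_break),
            d_dsb_bp=cl.d_dsb_bp, cluster_gap_bp=cl.cluster_gap_bp,
            distant_gap_bp=cl.distant_gap_bp)
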