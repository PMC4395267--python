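"""Flat run configuration shared by the command-line entry points.

One config object carries every pipeline parameter with its standard default
(sigma_h=10, sigma_v=3, sigma_log=10, k=2, w=5, chi=1, theta=0.9) plus the
simulation settings and seeds.  Configs load from a flat YAML file; unknown
keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .model import AlignParams, GraphParams, PreprocessParams, SourceEdgeScheme
from .synthetic import BarcodeSpec, DynamicsSpec


@dataclass
class RunConfig:
    # pre-processing
    sigma_h: float = 10.0
    sigma_v: float = 3.0
    sigma_log: float = 10.0
    # path search
    k: int = 2
    theta: float = 0.3
    source_edge_scheme: str = "destination_intensity"
    # recursion
    feature_half_width: int = 5
    # metrics
    chi: float = 1.0
    trace_smoothing_sigma: float = 2.0
    min_prominence: float | None = None
    # simulation
    sim_frames: int = 200
    sim_width: int = 170
    sim_n_features: int = 1
    sim_feature_width_px: float = 10.0
    sim_min_spacing_px: float = 45.0
    sim_amplitude_min: float = 50.0
    sim_amplitude_max: float = 100.0
    sim_baseline: float = 100.0
    sim_undulation_sd: float = 15.0
    sim_undulation_corr_len: float = 20.0
    sim_end_margin_px: float = 32.0
    sim_background: float = 10.0
    sim_com_step_sd: float = 0.5
    sim_stretch_sd: float = 1.0
    sim_stretch_corr_len: float = 30.0
    sim_stretch_relax_frames: float = 20.0
    sim_noise_sd: float = 5.0
    seed: int = 0
    pixel_size: float = 0.16

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def align_params(self) -> AlignParams:
        return AlignParams(
            feature_half_width=self.feature_half_width,
            preprocess=PreprocessParams(self.sigma_h, self.sigma_v, self.sigma_log),
            graph=GraphParams(self.k, SourceEdgeScheme(self.source_edge_scheme), self.theta),
        )

    def barcode_spec(self, seed: int | None = None) -> BarcodeSpec:
        return BarcodeSpec(
            n=self.sim_width,
            n_features=self.sim_n_features,
            feature_width_px=self.sim_feature_width_px,
            min_spacing_px=self.sim_min_spacing_px,
            amplitude_range=(self.sim_amplitude_min, self.sim_amplitude_max),
            baseline=self.sim_baseline,
            undulation_sd=self.sim_undulation_sd,
            undulation_corr_len=self.sim_undulation_corr_len,
            end_margin_px=self.sim_end_margin_px,
            background=self.sim_background,
            seed=self.seed if seed is None else seed,
        )

    def dynamics_spec(self, seed: int | None = None) -> DynamicsSpec:
        s = self.seed if seed is None else seed
        return DynamicsSpec(
            m=self.sim_frames,
            com_step_sd=self.sim_com_step_sd,
            stretch_sd=self.sim_stretch_sd,
            stretch_corr_len=self.sim_stretch_corr_len,
            stretch_relax_frames=self.sim_stretch_relax_frames,
            noise_sd=self.sim_noise_sd,
            seed=s + 1,  # decouple barcode and dynamics streams
        )
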