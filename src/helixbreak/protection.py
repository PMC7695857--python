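"""Scavengeable-damage experiments: paired histone-on/off replicate runs.

``cell`` mode is a chromatin-like preset (histone scavenging available,
snug container, higher effective bp density); ``plasmid`` mode emulates a
naked DNA fibre in dilute solution: no histones and a wider container
(lower bp density), on the same straight-segment geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import sqrt
from typing import List, Sequence

import numpy as np

from .classification import YieldSummary
from .pipeline import PipelineConfig, PipelineResult, run_pipeline

MODE_PRESETS = {
    "cell": {"container_margin_nm": 15.0, "histones_allowed": True},
    "plasmid": {"container_margin_nm": 60.0, "histones_allowed": False},
}

AGGREGATE_KEYS = ("n_ssb", "n_dsb", "ssb_yield", "dsb_yield",
                  "scavengeable_fraction")


@dataclass(frozen=True)
class ExperimentPlan:
    mode: str = "cell"
    histone_scavenging: bool = True
    seeds: Sequence[int] = (0,)
    dose_gy: float = 1.0
    n_bp: int = 20_000
    base_config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        if self.mode not in MODE_PRESETS:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.histone_scavenging and not MODE_PRESETS[self.mode]["histones_allowed"]:
            raise ValueError("plasmid mode has no histones to scavenge with")
        if len(self.seeds) < 1:
            raise ValueError("need at least one replicate seed")
        if self.dose_gy < 0:
            raise ValueError("dose must be non-negative")

    def pipeline_config(self) -> PipelineConfig:
        preset = MODE_PRESETS[self.mode]
        return replace(self.base_config, n_bp=self.n_bp, dose_gy=self.dose_gy,
                       histone_scavenging=self.histone_scavenging,
                       container_margin_nm=preset["container_margin_nm"])


@dataclass
class ExperimentResult:
    plan: ExperimentPlan
    replicates: List[PipelineResult]
    aggregate: dict

    @property
    def summaries(self) -> List[YieldSummary]:
        return [r.summary for r in self.replicates]


def _mean_se(values: np.ndarray) -> dict:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return {"mean": float("nan"), "se": float("nan"), "n": 0}
    se = (float(np.std(values, ddof=1)) / sqrt(values.size)
          if values.size > 1 else 0.0)
    return {"mean": float(np.mean(values)), "se": se, "n": int(values.size)}


def run_experiment(plan: ExperimentPlan) -> ExperimentResult:
    """Run the full chain for every replicate seed and aggregate yields.

    The aggregate holds the mean and standard error (ddof=1, NaN replicates
    dropped) of each key quantity across replicates.
    """
    cfg = plan.pipeline_config()
    replicates = []
    for seed in plan.seeds:
        try:
            replicates.append(run_pipeline(cfg, seed))
        except Exception as exc:
            raise RuntimeError(
                f"replicate seed={seed} failed in pipeline stage: {exc}") from exc
    aggregate = {}
    for key in AGGREGATE_KEYS:
        vals = np.array([getattr(r.summary, key) for r in replicates],
                        dtype=float)
        aggregate[key] = _mean_se(vals)
    return ExperimentResult(plan=plan, replicates=replicates,
                            aggregate=aggregate)
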