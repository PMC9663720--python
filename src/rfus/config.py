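"""Run configuration: one YAML-serializable object holding every setting.

Defaults reproduce the standard acquisition and analysis settings (1660 s
protocol, blocks of 200 with 60 singular values removed, alpha 0.05, 1.4 mm
ROI, bootstrap N = 5..50 with 100 resamples).  The ``scaled`` preset swaps in
the fast problem size used for synthetic end-to-end runs while preserving the
2.5 Hz Doppler rate and the 30% singular-value cut.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import synthetic

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # protocol
    baseline_duration: float = 45.0
    n_trials: int = 50
    pre_off: float = 15.0
    flash_duration: float = 0.8
    post_off: float = 15.0
    recovery_duration: float = 75.0
    # simulation
    wt_amplitude: float = 0.2083      # fraction of baseline
    tg_amplitude: float = 0.3725
    wt_between_sd: float = 0.0        # fractional between-animal spread
    tg_between_sd: float = 0.0
    n_animals_per_group: int = 6
    grid_nz: int = 32
    grid_nx: int = 32
    frame_rate: float = synthetic.SCALED_FRAME_RATE
    noise_sd: float = 0.05
    trace_noise_sd: float = 0.10      # per-Doppler-sample, fraction of baseline
    tissue_rank: int = 2
    seed: int = 0
    # doppler
    block_size: int = synthetic.SCALED_BLOCK_SIZE
    n_removed: int = synthetic.SCALED_N_REMOVED
    # activation
    alpha: float = 0.05
    roi_diameter_m: float = 1.4e-3
    # hrf fitting
    n_restarts: int = 8
    # bootstrap
    bootstrap_min: int = 5
    bootstrap_max: int = 50
    n_resamples: int = 100
    stability_tolerance: float = 0.05
    # ulm
    ulm_frame_rate: float = 1000.0
    ulm_n_frames: int = 2000
    ulm_psf_sigma: float = 1.2
    ulm_bubble_rate: float = 5.0
    ulm_noise_sd: float = 0.05
    ulm_map_pitch_m: float = 10e-6
    # output
    output_dir: str = "rfus_output"

    def protocol(self) -> synthetic.StimulusProtocol:
        return synthetic.StimulusProtocol(
            baseline_duration=self.baseline_duration,
            n_trials=self.n_trials,
            pre_off=self.pre_off,
            flash_duration=self.flash_duration,
            post_off=self.post_off,
            recovery_duration=self.recovery_duration,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
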