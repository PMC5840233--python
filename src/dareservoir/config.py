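"""Experiment configuration schema and seed fan-out.

A single JSON-serializable config captures every knob of a D/A run: network
sizes, LIF and synapse constants, derivation and learning parameters,
encoder settings and the master seed.  Unknown keys are rejected so stale
configs fail loudly.  The master seed fans out to per-stage seeds through a
stable hash of the stage name, so individual stages are independently
reproducible.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .autonomous import StdpParams
from .codec import EncoderParams
from .core import LIFParams, SynapseParams
from .driven import BumpSpec

__all__ = ["ExperimentConfig", "fanout_seed"]


def fanout_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 from the master seed.

    Stable scheme: SeedSequence over (master, crc32(stage name)).
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


class ExperimentConfig(BaseModel):
    """All parameters of a D/A action-recognition experiment."""

    model_config = ConfigDict(extra="forbid")

    # topology
    n_res: int = 400
    p_conn: float = 0.10
    weight_scale: float = 50.0
    u_scale: float = 1.0

    # neuron / synapse constants (ms, mV)
    tau_mem: float = 20.0
    tau_fast: float = 5.0
    tau_slow: float = 100.0
    tau_pre: float | None = 3.0
    v_th: float = -50.0
    v_rest: float = -70.0
    v_reset: float = -70.0
    t_ref: float = 5.0
    dt: float = 1.0

    # derivation + training
    b_max: float = 0.15
    u_r: float = 100.0
    eta: float = 0.05
    eta_decay: float = 0.95
    w_init_scale: float = 1e-2
    alpha: float = 1e5
    epochs_driven: int = 15
    epochs_auto: int = 30
    trial_steps: int = 300
    apportion_over: str = "inputs"

    # one-hot target bump
    bump_t0: float = 30.0
    bump_dur: float = 240.0
    bump_amplitude: float = 30.0
    spike_period: float = 6.0
    bump_shape: str = "hann"

    # encoder
    thresholds: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    binarize_theta: float = 0.1
    bb_size: int = 41
    stride: int = 10
    min_active_frac: float = 0.08
    max_active_frac: float = 0.75

    # evaluation
    eval_repeats: int = 10
    eval_noise: float = 0.0

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        # constructing the parameter objects runs their invariant checks
        self.lif()
        self.syn()
        self.encoder()
        return self

    # ---- typed views -----------------------------------------------------
    def lif(self) -> LIFParams:
        return LIFParams(tau_mem=self.tau_mem, v_rest=self.v_rest,
                         v_th=self.v_th, v_reset=self.v_reset,
                         t_ref=self.t_ref, dt=self.dt)

    def syn(self) -> SynapseParams:
        return SynapseParams(tau_fast=self.tau_fast, tau_slow=self.tau_slow,
                             tau_pre=self.tau_pre)

    def encoder(self) -> EncoderParams:
        return EncoderParams(thresholds=tuple(self.thresholds),
                             binarize_theta=self.binarize_theta,
                             bb_size=self.bb_size, stride=self.stride,
                             min_active_frac=self.min_active_frac,
                             max_active_frac=self.max_active_frac)

    def bump(self) -> BumpSpec:
        return BumpSpec(t0=self.bump_t0, dur=self.bump_dur,
                        amplitude=self.bump_amplitude,
                        spike_period=self.spike_period,
                        shape=self.bump_shape)

    def stdp(self) -> StdpParams:
        return StdpParams(eta=self.eta, eta_decay=self.eta_decay,
                          tau_pre=self.tau_pre)

    def stage_seed(self, stage: str) -> int:
        return fanout_seed(self.seed, stage)

    # ---- (de)serialization ----------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ExperimentConfig":
        """Parse a config from a JSON string or a path to a JSON file."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.model_validate(json.loads(text))
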