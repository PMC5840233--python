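"""Autonomous spiking network derived from a trained driven network.

The autonomous model imports the driven network's fast recurrent matrix,
adds slow recurrent connections J_slow = u_D B w (a rank-<=Y product of the
driven input weights, a random nonnegative mixing matrix B, and the trained
rate readout w), and operates on real binary spike input.  Its spiking
readout w' is trained by a supervised STDP rule:

    dw'_j = eta * x_trace * (target_j(t) - actual_j(t))

which potentiates at desired-spike instants, depresses at actual-spike
instants, and is exactly zero once the two trains coincide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    LIFParams,
    ReservoirState,
    SynapseParams,
    Topology,
    exp_filter,
    lif_step,
    pad_stream,
    update_traces,
)
from .driven import DrivenNetwork, TargetPattern

__all__ = [
    "StdpParams",
    "AutoNetwork",
    "derive_auto",
    "stdp_step",
    "van_rossum",
    "run_auto",
    "train_auto",
    "predict_single",
]


@dataclass(frozen=True)
class StdpParams:
    """Supervised-STDP readout learning parameters.

    eta: weight increment per unit presynaptic trace; eta_decay: per-epoch
    multiplicative annealing factor (1 = constant rate); tau_pre: presynaptic
    trace time constant (defaults to the synapse tau_fast when None);
    w_clip: optional symmetric bound on |w'|.
    """

    eta: float = 0.05
    eta_decay: float = 1.0
    tau_pre: float | None = None
    w_clip: float | None = None

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not (0.0 < self.eta_decay <= 1.0):
            raise ValueError("eta_decay must be in (0, 1]")


@dataclass
class AutoNetwork:
    """Fully spiking reservoir + readout derived from a driven network."""

    topology: Topology
    j_slow: np.ndarray           # (N, N) dense, for spectra/serialization
    j_slow_factors: tuple[np.ndarray, np.ndarray]  # (N, Y), (Y, N): applied form
    u: np.ndarray                # (N, X) input weights (u_D u_R)
    u_r: float
    b: np.ndarray                # (X, Y) mixing matrix
    w_prime: np.ndarray          # (Y, N) spiking readout
    lif: LIFParams
    syn: SynapseParams
    seed: int

    def input_drive(self, stream: np.ndarray, n_steps: int) -> np.ndarray:
        """Current from binary input spikes via their fast synaptic trace."""
        padded = pad_stream(stream, n_steps)
        traces = exp_filter(padded, self.syn.tau_fast, self.lif.dt)
        return self.u_r * (self.u @ traces)


def derive_auto(
    driven: DrivenNetwork,
    b_max: float = 0.15,
    seed: int = 0,
    u_r: float = 1.0,
    w_init_scale: float = 1e-2,
    scalar_b: bool = False,
) -> AutoNetwork:
    """Derive an autonomous network from a trained driven network.

    u = u_D u_R (u_R a scalar gain, 1 by default); B has i.i.d.
    Uniform[0, b_max] entries (X x Y, or one scalar broadcast when
    ``scalar_b``); J_slow = u_D B w.  J_fast is shared with the driven
    network (same Topology object, bitwise identical).
    """
    if not driven.is_trained:
        raise ValueError("train driven first: readout w is all zero")
    if b_max < 0:
        raise ValueError("b_max must be non-negative")
    topo = driven.topology
    rng = np.random.default_rng(seed)
    if scalar_b:
        b = np.full((topo.n_in, topo.n_out), rng.uniform(0.0, b_max))
    else:
        b = rng.uniform(0.0, b_max, size=(topo.n_in, topo.n_out))
    left = driven.u_d @ b                 # (N, Y)
    right = driven.w                      # (Y, N)
    j_slow = left @ right
    w_prime = rng.normal(0.0, w_init_scale, size=(topo.n_out, topo.n_res))
    return AutoNetwork(
        topology=topo,
        j_slow=j_slow,
        j_slow_factors=(left, right),
        u=driven.u_d.copy(),
        u_r=u_r,
        b=b,
        w_prime=w_prime,
        lif=driven.lif,
        syn=driven.syn,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# learning rule
# ---------------------------------------------------------------------------

def stdp_step(
    w_prime: np.ndarray,
    pre_trace: np.ndarray,
    target_spikes_t: np.ndarray,
    actual_spikes_t: np.ndarray,
    params: StdpParams,
) -> np.ndarray:
    """One supervised-STDP update of the readout weights (pure function).

    For output j: dw'_j = eta * pre_trace * (target_j - actual_j).  Weights
    are untouched at steps where target and actual agree.
    """
    diff = target_spikes_t.astype(float) - actual_spikes_t.astype(float)
    w_new = w_prime + params.eta * np.outer(diff, pre_trace)
    if params.w_clip is not None:
        np.clip(w_new, -params.w_clip, params.w_clip, out=w_new)
    return w_new


def van_rossum(
    train_a: np.ndarray,
    train_b: np.ndarray,
    tau: float = 10.0,
    dt: float = 1.0,
) -> float:
    """van Rossum distance between two binary spike trains.

    Both trains are filtered with a causal exponential of time constant tau
    and the squared difference is integrated: D = sqrt(dt/tau * sum (fa-fb)^2).
    """
    fa = exp_filter(np.asarray(train_a, dtype=float), tau, dt)
    fb = exp_filter(np.asarray(train_b, dtype=float), tau, dt)
    return float(np.sqrt((dt / tau) * np.sum((fa - fb) ** 2)))


# ---------------------------------------------------------------------------
# simulation and training
# ---------------------------------------------------------------------------

def run_auto(
    auto: AutoNetwork,
    spike_input: np.ndarray,
    n_steps: int = 300,
    record: bool = False,
):
    """Run the autonomous network (no learning) on one spike stream.

    Returns (reservoir raster, readout spike raster, history-or-None).
    """
    topo = auto.topology
    stream = np.asarray(spike_input)
    if stream.ndim != 2 or stream.shape[0] != topo.n_in:
        raise ValueError(
            f"spike input must be (n_in={topo.n_in}, T), got {stream.shape}"
        )
    drive = auto.input_drive(stream, n_steps)
    lif, syn = auto.lif, auto.syn
    left, right = auto.j_slow_factors
    state = ReservoirState.rest(topo.n_res, lif)
    out_state = ReservoirState.rest(topo.n_out, lif)
    raster = np.zeros((topo.n_res, n_steps), dtype=np.uint8)
    out_raster = np.zeros((topo.n_out, n_steps), dtype=np.uint8)
    history = (
        {k: np.zeros((topo.n_res, n_steps)) for k in ("f", "s")}
        if record
        else None
    )
    for t in range(n_steps):
        current = (
            topo.j_fast @ state.f_trace
            + left @ (right @ state.s_trace)
            + drive[:, t]
        )
        _, spikes = lif_step(state, current, lif)
        update_traces(state, spikes, syn, lif.dt)
        raster[:, t] = spikes
        _, out_spikes = lif_step(out_state, auto.w_prime @ state.f_trace, lif)
        out_raster[:, t] = out_spikes
        if record:
            history["f"][:, t] = state.f_trace
            history["s"][:, t] = state.s_trace
    return raster, out_raster, history


def train_auto(
    auto: AutoNetwork,
    labelled_spike_inputs: list[tuple[np.ndarray, int]],
    targets: dict[int, TargetPattern],
    n_epochs: int = 30,
    stdp: StdpParams | None = None,
    n_steps: int = 300,
    presentation: str = "interleave",
) -> tuple[AutoNetwork, pd.DataFrame]:
    """Train the spiking readout w' with supervised STDP.

    Within each epoch every pattern is presented once in class order:
    ``interleave`` (default) cycles Class1->Class2->Class3->Class1->... so
    consecutive class blocks do not overwrite each other, ``blocks`` presents
    all patterns of a class back to back.  Reservoir, readout and trace
    state is reset between patterns.  The log records the summed van Rossum
    distance (tau = 10 ms) between actual and target readout spikes per
    epoch/pattern.
    """
    stdp = stdp or StdpParams()
    for _, label in labelled_spike_inputs:
        if label not in targets:
            raise KeyError(f"label {label} has no target pattern")
    lif, syn = auto.lif, auto.syn
    topo = auto.topology
    tau_pre = stdp.tau_pre if stdp.tau_pre is not None else syn.tau_pre
    pre_decay = math.exp(-lif.dt / tau_pre)
    by_label = sorted(range(len(labelled_spike_inputs)),
                      key=lambda i: (labelled_spike_inputs[i][1], i))
    if presentation == "blocks":
        order = by_label
    elif presentation == "interleave":
        groups: dict[int, list[int]] = {}
        for i in by_label:
            groups.setdefault(labelled_spike_inputs[i][1], []).append(i)
        order = []
        for j in range(max(len(g) for g in groups.values())):
            for label in sorted(groups):
                if j < len(groups[label]):
                    order.append(groups[label][j])
    else:
        raise ValueError(f"unknown presentation {presentation!r}")
    # input drive depends only on the fixed input stream: compute once
    drives = [
        auto.input_drive(stream, n_steps)
        for stream, _ in labelled_spike_inputs
    ]
    left, right = auto.j_slow_factors
    j_fast = topo.j_fast
    w_prime = auto.w_prime
    rows = []
    for epoch in range(n_epochs):
        eta_t = stdp.eta * stdp.eta_decay**epoch
        epoch_params = StdpParams(eta=eta_t, eta_decay=stdp.eta_decay,
                                  tau_pre=tau_pre, w_clip=stdp.w_clip)
        for idx in order:
            stream, label = labelled_spike_inputs[idx]
            spike_target = pad_stream(targets[label].spike_target, n_steps)
            drive = drives[idx]
            state = ReservoirState.rest(topo.n_res, lif)
            out_state = ReservoirState.rest(topo.n_out, lif)
            pre_trace = np.zeros(topo.n_res)
            out_raster = np.zeros((topo.n_out, n_steps), dtype=np.uint8)
            for t in range(n_steps):
                current = (
                    j_fast @ state.f_trace
                    + left @ (right @ state.s_trace)
                    + drive[:, t]
                )
                _, spikes = lif_step(state, current, lif)
                update_traces(state, spikes, syn, lif.dt)
                pre_trace *= pre_decay
                pre_trace += spikes
                _, out_spikes = lif_step(out_state, w_prime @ state.f_trace, lif)
                out_raster[:, t] = out_spikes
                tgt = spike_target[:, t]
                if tgt.any() or out_spikes.any():
                    w_prime = stdp_step(w_prime, pre_trace, tgt, out_spikes,
                                        epoch_params)
            vr = sum(
                van_rossum(out_raster[j], spike_target[j], 10.0, lif.dt)
                for j in range(topo.n_out)
            )
            spike_counts = out_raster.sum(axis=1)
            rows.append(
                {"epoch": epoch, "pattern": idx, "label": label,
                 "van_rossum": vr,
                 "spike_counts": "|".join(map(str, spike_counts.tolist()))}
            )
    auto.w_prime = w_prime
    return auto, pd.DataFrame(rows)


def predict_single(
    auto: AutoNetwork,
    spike_input: np.ndarray,
    n_steps: int = 300,
) -> tuple[int, np.ndarray]:
    """Classify one spike stream: argmax of readout spike counts over the
    trial; ties resolve to the lowest class index."""
    if not np.any(auto.w_prime):
        warnings.warn("readout w' is all zero (untrained); counts will be zero",
                      RuntimeWarning)
    _, out_raster, _ = run_auto(auto, spike_input, n_steps)
    counts = out_raster.sum(axis=1)
    return int(np.argmax(counts)), counts
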