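"""Leaky integrate-and-fire dynamics, synaptic traces and sparse random topology.

These primitives are shared by the driven (rate-readout) and autonomous
(fully spiking) reservoir models.  All time constants are in milliseconds,
all voltages in millivolt; the integration step ``dt`` defaults to 1 ms so
that one video spike frame maps onto one simulation step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "LIFParams",
    "SynapseParams",
    "Topology",
    "ReservoirState",
    "build_topology",
    "lif_step",
    "update_traces",
    "exp_filter",
    "run_reservoir",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron constants.

    Defaults: membrane time constant 20 ms, rest/reset at -70 mV, threshold
    -50 mV, 5 ms absolute refractory period, 1 ms step.
    """

    tau_mem: float = 20.0
    v_rest: float = -70.0
    v_th: float = -50.0
    v_reset: float = -70.0
    t_ref: float = 5.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.v_rest < self.v_th):
            raise ValueError(
                f"require v_reset <= v_rest < v_th, got "
                f"{self.v_reset}, {self.v_rest}, {self.v_th}"
            )
        if self.tau_mem <= 0:
            raise ValueError("tau_mem must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Fast/slow synaptic trace time constants.

    ``tau_pre`` is the presynaptic trace constant used by the supervised-STDP
    readout rule; by convention it equals ``tau_fast`` unless set explicitly.
    """

    tau_fast: float = 5.0
    tau_slow: float = 100.0
    tau_pre: float | None = None

    def __post_init__(self) -> None:
        if not (self.tau_slow > self.tau_fast > 0):
            raise ValueError("require tau_slow > tau_fast > 0")
        if self.tau_pre is None:
            object.__setattr__(self, "tau_pre", self.tau_fast)
        elif self.tau_pre <= 0:
            raise ValueError("tau_pre must be positive")


@dataclass
class Topology:
    """Reservoir wiring: sizes plus the fixed fast recurrent matrix."""

    n_res: int
    n_in: int
    n_out: int
    p_conn: float
    j_fast: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.j_fast.shape != (self.n_res, self.n_res):
            raise ValueError("j_fast must be n_res x n_res")


@dataclass
class ReservoirState:
    """Per-neuron dynamical variables advanced by :func:`lif_step`."""

    v: np.ndarray
    ref_left: np.ndarray
    f_trace: np.ndarray
    s_trace: np.ndarray
    spikes_t: np.ndarray

    @classmethod
    def rest(cls, n: int, lif: LIFParams) -> "ReservoirState":
        return cls(
            v=np.full(n, lif.v_rest, dtype=float),
            ref_left=np.zeros(n, dtype=float),
            f_trace=np.zeros(n, dtype=float),
            s_trace=np.zeros(n, dtype=float),
            spikes_t=np.zeros(n, dtype=np.uint8),
        )

    def reset(self, lif: LIFParams, zero_traces: bool = True) -> None:
        """Return membrane potentials to rest before a new pattern.

        Traces are zeroed as well by default so no activity leaks between
        patterns; pass ``zero_traces=False`` to keep them.
        """
        self.v[:] = lif.v_rest
        self.ref_left[:] = 0.0
        self.spikes_t[:] = 0
        if zero_traces:
            self.f_trace[:] = 0.0
            self.s_trace[:] = 0.0


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def build_topology(
    n_res: int,
    n_in: int,
    n_out: int,
    p_conn: float,
    weight_scale: float = 50.0,
    seed: int = 0,
) -> Topology:
    """Draw a sparse random recurrent matrix J_fast.

    Connections exist off-diagonal with probability ``p_conn`` (no
    self-connections); nonzero weights are i.i.d. N(0, g^2/(p N)) with
    g = ``weight_scale``.  The default g = 50 makes single-spike recurrent
    currents a sizeable fraction of the 20 mV threshold distance, so the
    recurrence genuinely shapes the dynamics at millivolt scale.
    """
    if min(n_res, n_in, n_out) < 1:
        raise ValueError("n_res, n_in and n_out must all be >= 1")
    if not (0.0 < p_conn <= 1.0):
        raise ValueError(f"p_conn must be in (0, 1], got {p_conn}")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_res, n_res)) < p_conn
    np.fill_diagonal(mask, False)
    sigma = weight_scale / math.sqrt(p_conn * n_res)
    weights = rng.normal(0.0, sigma, size=(n_res, n_res))
    j_fast = np.where(mask, weights, 0.0)
    return Topology(n_res=n_res, n_in=n_in, n_out=n_out, p_conn=p_conn,
                    j_fast=j_fast, seed=seed)


# ---------------------------------------------------------------------------
# single-step dynamics
# ---------------------------------------------------------------------------

def lif_step(
    state: ReservoirState,
    input_current: np.ndarray,
    lif: LIFParams,
    method: str = "exp_euler",
) -> tuple[ReservoirState, np.ndarray]:
    """Advance membrane potentials one step and emit spikes.

    ``exp_euler`` integrates tau dV/dt = (v_rest - V) + I exactly over dt for
    piecewise-constant I; ``euler`` is plain forward Euler.  Neurons at or
    above threshold spike, reset, and are clamped at ``v_reset`` while their
    refractory clock runs down.
    """
    current = np.asarray(input_current, dtype=float)
    if not np.all(np.isfinite(current)):
        bad = np.flatnonzero(~np.isfinite(current))
        raise FloatingPointError(
            f"non-finite input current at neuron indices {bad[:10].tolist()}"
        )
    # refractory clocks run down first, so a neuron that spiked at step t can
    # spike again at step t + t_ref (with t_ref = 5, dt = 1: not at t+1..t+4)
    np.maximum(state.ref_left - lif.dt, 0.0, out=state.ref_left)
    refractory = state.ref_left > 0.0
    active = ~refractory
    v_inf = lif.v_rest + current
    if method == "exp_euler":
        decay = math.exp(-lif.dt / lif.tau_mem)
        state.v[active] = v_inf[active] + (state.v[active] - v_inf[active]) * decay
    elif method == "euler":
        state.v[active] += (lif.dt / lif.tau_mem) * (v_inf[active] - state.v[active])
    else:
        raise ValueError(f"unknown integration method {method!r}")

    # reflecting floor at v_reset: strong net-negative recurrent input cannot
    # hyperpolarize below the reset potential
    np.maximum(state.v, lif.v_reset, out=state.v)

    spikes = (active & (state.v >= lif.v_th)).astype(np.uint8)
    fired = spikes.astype(bool)
    state.v[fired] = lif.v_reset
    state.ref_left[fired] = lif.t_ref
    state.v[refractory] = lif.v_reset
    state.spikes_t = spikes
    return state, spikes


def update_traces(
    state: ReservoirState,
    spikes: np.ndarray,
    syn: SynapseParams,
    dt: float = 1.0,
) -> ReservoirState:
    """Exponentially decay fast/slow traces, then increment by 1 where spiked."""
    state.f_trace *= math.exp(-dt / syn.tau_fast)
    state.s_trace *= math.exp(-dt / syn.tau_slow)
    if spikes.any():
        state.f_trace += spikes
        state.s_trace += spikes
    return state


def exp_filter(spikes: np.ndarray, tau: float, dt: float = 1.0) -> np.ndarray:
    """Causal exponential trace of a spike array along its last axis.

    y[t] = y[t-1] * exp(-dt/tau) + spikes[t]; this is the same decay-then
    -increment convention as :func:`update_traces`.
    """
    a = math.exp(-dt / tau)
    return lfilter([1.0], [1.0, -a], np.asarray(spikes, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# trial runner
# ---------------------------------------------------------------------------

def run_reservoir(
    network,
    input_stream: np.ndarray,
    n_steps: int = 300,
    record: bool = True,
    zero_traces: bool = True,
):
    """Run one trial of a driven or autonomous network.

    ``network`` is a :class:`~dareservoir.driven.DrivenNetwork` (per-step
    current J_fast f(t) + u_D f_D(t)) or an
    :class:`~dareservoir.autonomous.AutoNetwork`
    (J_fast f(t) + J_slow s(t) + u_r u f_in(t)).  For the driven model the
    input stream is the continuous drive f_D (X x T); for the autonomous
    model it is a binary spike stream whose fast trace carries the input
    current.  Streams shorter than ``n_steps`` are zero-padded: the network
    keeps running on its recurrent activity alone.

    Returns ``(raster, history)`` where raster is (N, n_steps) uint8 and
    history maps 'f', 's', 'v' to (N, n_steps) float arrays when recording.
    """
    topo = network.topology
    stream = np.asarray(input_stream, dtype=float)
    if stream.ndim != 2 or stream.shape[0] != topo.n_in:
        raise ValueError(
            f"input stream must be (n_in={topo.n_in}, T), got {stream.shape}"
        )
    drive = network.input_drive(stream, n_steps)  # (N, n_steps)

    lif, syn = network.lif, network.syn
    state = ReservoirState.rest(topo.n_res, lif)
    state.reset(lif, zero_traces=zero_traces)
    raster = np.zeros((topo.n_res, n_steps), dtype=np.uint8)
    history = (
        {k: np.zeros((topo.n_res, n_steps)) for k in ("f", "s", "v")}
        if record
        else None
    )
    j_fast = topo.j_fast
    slow = getattr(network, "j_slow_factors", None)
    for t in range(n_steps):
        current = j_fast @ state.f_trace + drive[:, t]
        if slow is not None:
            left, right = slow
            current += left @ (right @ state.s_trace)
        _, spikes = lif_step(state, current, lif)
        update_traces(state, spikes, syn, lif.dt)
        raster[:, t] = spikes
        if record:
            history["f"][:, t] = state.f_trace
            history["s"][:, t] = state.s_trace
            history["v"][:, t] = state.v
    return raster, history


def pad_stream(stream: np.ndarray, n_steps: int) -> np.ndarray:
    """Zero-pad (or truncate) a (C, T) stream along time to n_steps."""
    stream = np.asarray(stream)
    c, t = stream.shape
    if t >= n_steps:
        return stream[:, :n_steps]
    out = np.zeros((c, n_steps), dtype=stream.dtype)
    out[:, :t] = stream
    return out
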