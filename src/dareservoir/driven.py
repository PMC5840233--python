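"""The driven network: delay-apportioned drive construction and RLS readout.

The driven model is a reservoir whose input is a filtered copy of the desired
output, f_D = f_out + tau_fast * d f_out/dt.  With X input and Y output
neurons the single tau_fast is apportioned into per-input parts tau^k
(sum_k tau^k = tau_fast) so that variable input/output sizes are possible:

    (f_D^k)_j = (f_out)_j + tau^k * d(f_out)_j/dt

A linear rate readout w is trained by recursive least squares on the
reservoir's fast traces so that w x(t) ~ f_out(t).  The trained driven
network supplies both the recurrent matrix and the target statistics for
autonomous (fully spiking) networks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    LIFParams,
    ReservoirState,
    SynapseParams,
    Topology,
    build_topology,
    lif_step,
    pad_stream,
    update_traces,
)

__all__ = [
    "BumpSpec",
    "TargetPattern",
    "DelayApportionment",
    "DrivenNetwork",
    "make_one_hot_target",
    "channel_output_map",
    "derive_driven_input",
    "build_driven",
    "train_driven",
    "readout_nrmse",
]


# ---------------------------------------------------------------------------
# one-hot targets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BumpSpec:
    """Shape of the per-class desired-activity bump.

    The bump occupies [t0, t0 + dur) of the trial.  ``amplitude`` is the
    rate-domain height (it sets the scale of the drive currents, mV);
    ``spike_period`` spaces the periodic spike target and must exceed the
    readout refractory period for the target to be attainable.  ``shape`` is
    'hann' (smooth raised-cosine, differentiable) or 'rect'.
    """

    t0: float = 30.0
    dur: float = 240.0
    amplitude: float = 30.0
    spike_period: float = 6.0
    shape: str = "hann"


@dataclass
class TargetPattern:
    """One-hot desired output: rate bump + periodic spike target on one row."""

    f_out: np.ndarray        # (Y, T) float
    class_id: int
    spike_target: np.ndarray  # (Y, T) uint8


def make_one_hot_target(
    class_id: int,
    n_classes: int,
    bump: BumpSpec | None = None,
    n_steps: int = 300,
    dt: float = 1.0,
) -> TargetPattern:
    """Build the one-hot target for ``class_id``: high bump on its own output
    row, zeros elsewhere, plus a periodic spike-train target in the window."""
    if not 0 <= class_id < n_classes:
        raise ValueError(f"class_id {class_id} outside [0, {n_classes})")
    bump = bump or BumpSpec()
    i0 = int(round(bump.t0 / dt))
    n_dur = int(round(bump.dur / dt))
    if i0 < 0 or i0 + n_dur > n_steps:
        raise ValueError(
            f"bump window [{bump.t0}, {bump.t0 + bump.dur}) exceeds trial of "
            f"{n_steps * dt} ms"
        )
    f_out = np.zeros((n_classes, n_steps))
    tloc = np.arange(n_dur)
    if bump.shape == "hann":
        profile = bump.amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * (tloc + 0.5) / n_dur))
    elif bump.shape == "rect":
        profile = np.full(n_dur, bump.amplitude)
    else:
        raise ValueError(f"unknown bump shape {bump.shape!r}")
    f_out[class_id, i0:i0 + n_dur] = profile
    spike_target = np.zeros((n_classes, n_steps), dtype=np.uint8)
    step = max(1, int(round(bump.spike_period / dt)))
    spike_target[class_id, i0:i0 + n_dur:step] = 1
    return TargetPattern(f_out=f_out, class_id=class_id, spike_target=spike_target)


# ---------------------------------------------------------------------------
# delay apportionment
# ---------------------------------------------------------------------------

def _fix_last(parts: np.ndarray, total: float) -> np.ndarray:
    # nudge the last part so the float sum equals `total` exactly
    for _ in range(4):
        r = math.fsum(parts) - total
        if r == 0.0:
            break
        parts[-1] -= r
    return parts


@dataclass
class DelayApportionment:
    """Per-input delay constants tau^k that sum exactly to tau_fast."""

    tau_parts: np.ndarray
    total: float

    def __post_init__(self) -> None:
        self.tau_parts = np.asarray(self.tau_parts, dtype=float)
        if np.any(self.tau_parts <= 0):
            raise ValueError("all apportioned delays must be positive")
        if math.fsum(self.tau_parts) != self.total:
            raise ValueError("apportioned delays do not sum to tau_fast")

    def __len__(self) -> int:
        return len(self.tau_parts)

    @classmethod
    def equal(cls, tau_fast: float, n_in: int) -> "DelayApportionment":
        parts = np.full(n_in, tau_fast / n_in)
        return cls(_fix_last(parts, tau_fast), tau_fast)

    @classmethod
    def random(cls, tau_fast: float, n_in: int, seed: int = 0) -> "DelayApportionment":
        """Random positive split (Dirichlet(1,...,1) fractions of tau_fast)."""
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(n_in))
        parts = w * tau_fast
        return cls(_fix_last(parts, tau_fast), tau_fast)


def channel_output_map(n_in: int, n_out: int) -> np.ndarray:
    """Assign each input channel to an output row.

    Contiguous blocks of ~n_in/n_out channels per output; remainder channels
    are spread round-robin over the first outputs.
    """
    base = n_in // n_out
    sizes = np.full(n_out, base, dtype=int)
    sizes[: n_in % n_out] += 1
    return np.repeat(np.arange(n_out), sizes)


def derive_driven_input(
    target: TargetPattern,
    apportionment: DelayApportionment,
    mapping: np.ndarray | None = None,
    dt: float = 1.0,
) -> np.ndarray:
    """Construct the X x T driven drive f_D from a target pattern.

    Channel k mapped to output j carries (f_out)_j + tau^k d(f_out)_j/dt,
    the derivative taken by central finite differences.
    """
    f_out = target.f_out
    n_out = f_out.shape[0]
    n_in = len(apportionment)
    if mapping is None:
        mapping = channel_output_map(n_in, n_out)
    mapping = np.asarray(mapping, dtype=int)
    if mapping.shape != (n_in,):
        raise ValueError("mapping must assign one output row per input channel")
    dfdt = np.gradient(f_out, dt, axis=1)
    taus = apportionment.tau_parts[:, None]
    return f_out[mapping] + taus * dfdt[mapping]


# ---------------------------------------------------------------------------
# driven network + RLS
# ---------------------------------------------------------------------------

@dataclass
class DrivenNetwork:
    """Reservoir with continuous-drive input and a rate readout trained by RLS."""

    topology: Topology
    u_d: np.ndarray           # (N, X)
    w: np.ndarray             # (Y, N)
    p_inv: np.ndarray         # RLS inverse-correlation matrix (N, N)
    alpha: float
    lif: LIFParams
    syn: SynapseParams
    apportionment: DelayApportionment
    seed: int

    @property
    def is_trained(self) -> bool:
        return bool(np.any(self.w))

    def input_drive(self, stream: np.ndarray, n_steps: int) -> np.ndarray:
        """Continuous drive current u_D f_D, zero-padded to the trial length."""
        return self.u_d @ pad_stream(stream, n_steps)


def build_driven(
    n_res: int,
    n_in: int,
    n_out: int,
    p_conn: float = 0.10,
    weight_scale: float = 50.0,
    u_scale: float = 1.0,
    alpha: float = 1.0,
    lif: LIFParams | None = None,
    syn: SynapseParams | None = None,
    apportionment: DelayApportionment | None = None,
    apportion_over: str = "inputs",
    seed: int = 0,
) -> DrivenNetwork:
    """Assemble an untrained driven network.

    Input weights u_D are i.i.d. N(0, u_scale^2/X).  ``apportion_over``
    selects how tau_fast is split across drive channels: 'inputs' (default;
    the X parts sum to tau_fast) or 'reservoir' (each channel uses tau_fast/N).
    """
    lif = lif or LIFParams()
    syn = syn or SynapseParams()
    topo = build_topology(n_res, n_in, n_out, p_conn, weight_scale, seed)
    rng = np.random.default_rng(seed + 1)
    u_d = rng.normal(0.0, u_scale / math.sqrt(n_in), size=(n_res, n_in))
    if apportionment is None:
        if apportion_over == "inputs":
            apportionment = DelayApportionment.equal(syn.tau_fast, n_in)
        elif apportion_over == "reservoir":
            part = syn.tau_fast / n_res
            apportionment = DelayApportionment(
                np.full(n_in, part), total=part * n_in
            )
        else:
            raise ValueError(f"unknown apportion_over {apportion_over!r}")
    if len(apportionment) != n_in:
        raise ValueError("apportionment length must equal n_in")
    return DrivenNetwork(
        topology=topo,
        u_d=u_d,
        w=np.zeros((n_out, n_res)),
        p_inv=np.eye(n_res) / alpha,
        alpha=alpha,
        lif=lif,
        syn=syn,
        apportionment=apportionment,
        seed=seed,
    )


def rls_update(
    w: np.ndarray, p_inv: np.ndarray, x: np.ndarray, y_target: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One recursive-least-squares step toward w x = y_target.

    Returns (w', P', a-priori error).  Standard FORCE bookkeeping: P tracks
    the running inverse correlation matrix of the basis x, no forgetting.
    """
    k = p_inv @ x
    denom = 1.0 + x @ k
    c = 1.0 / denom
    err = w @ x - y_target
    w = w - c * np.outer(err, k)
    p_inv = p_inv - c * np.outer(k, k)
    return w, p_inv, err


def train_driven(
    driven: DrivenNetwork,
    targets: list[TargetPattern],
    n_epochs: int = 15,
    n_steps: int = 300,
) -> tuple[DrivenNetwork, list[float]]:
    """Train the rate readout with RLS against the one-hot rate targets.

    Each epoch presents every target once (class order).  The returned log is
    the per-epoch normalized RMSE (RMS a-priori error / target range), which
    decreases as the readout locks on.
    """
    if not targets:
        raise ValueError("need at least one target pattern")
    targets = sorted(targets, key=lambda t: t.class_id)
    lif, syn = driven.lif, driven.syn
    topo = driven.topology
    span = max(t.f_out.max() - t.f_out.min() for t in targets)
    drives = [
        driven.input_drive(
            derive_driven_input(t, driven.apportionment, dt=lif.dt), n_steps
        )
        for t in targets
    ]
    w, p_inv = driven.w, driven.p_inv
    history: list[float] = []
    for epoch in range(n_epochs):
        sq_sum = 0.0
        n_err = 0
        for tgt, drive in zip(targets, drives):
            f_out = pad_stream(tgt.f_out, n_steps)
            state = ReservoirState.rest(topo.n_res, lif)
            for t in range(n_steps):
                current = topo.j_fast @ state.f_trace + drive[:, t]
                _, spikes = lif_step(state, current, lif)
                update_traces(state, spikes, syn, lif.dt)
                w, p_inv, err = rls_update(w, p_inv, state.f_trace, f_out[:, t])
                if not np.all(np.isfinite(p_inv[0, :1])):
                    warnings.warn(
                        f"RLS inverse-correlation matrix lost conditioning at "
                        f"epoch {epoch}; resetting P",
                        RuntimeWarning,
                    )
                    p_inv = np.eye(topo.n_res) / driven.alpha
                sq_sum += float(err @ err)
                n_err += err.size
        history.append(math.sqrt(sq_sum / n_err) / span)
    driven.w, driven.p_inv = w, p_inv
    return driven, history


def readout_nrmse(
    driven: DrivenNetwork,
    targets: list[TargetPattern],
    n_steps: int = 300,
) -> float:
    """Normalized RMSE of the frozen readout over fresh passes of the targets."""
    lif, syn = driven.lif, driven.syn
    topo = driven.topology
    span = max(t.f_out.max() - t.f_out.min() for t in targets)
    sq_sum, n_err = 0.0, 0
    for tgt in targets:
        drive = driven.input_drive(
            derive_driven_input(tgt, driven.apportionment, dt=lif.dt), n_steps
        )
        f_out = pad_stream(tgt.f_out, n_steps)
        state = ReservoirState.rest(topo.n_res, lif)
        for t in range(n_steps):
            current = topo.j_fast @ state.f_trace + drive[:, t]
            _, spikes = lif_step(state, current, lif)
            update_traces(state, spikes, syn, lif.dt)
            err = driven.w @ state.f_trace - f_out[:, t]
            sq_sum += float(err @ err)
            n_err += err.size
    return math.sqrt(sq_sum / n_err) / span
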