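"""Dynamical diagnostics: eigenvalue spectra and trajectory distances.

The eigenvalue spectrum of a recurrent weight matrix summarizes the linear
modes of the reservoir: eigenvalues with real part above 1 mark modes whose
activity is self-sustaining (long-lasting oscillation or chaos), while a
spectrum concentrated near the origin marks a single fixed point.  Because
J_slow = u_D B w is a product of rank-<=Y factors, its nonzero eigenvalues
never number more than Y, and their radius grows with the range of B.

Trajectory distances compare per-neuron firing-rate traces of two trials:
d(t) = sqrt(1/N * sum_i (r_i1(t) - r_i2(t))^2).  A discriminative reservoir
shows large inter-class and small intra-class distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import exp_filter

__all__ = [
    "SpectrumResult",
    "EVReport",
    "TrajectoryRecord",
    "ev_spectrum",
    "ev_report",
    "rates_from_raster",
    "trajectory_distance",
    "class_trajectory_distances",
]


@dataclass
class SpectrumResult:
    eigenvalues: np.ndarray
    n_unstable: int          # count of Re(EV) > 1
    spectral_radius: float


@dataclass
class EVReport:
    eigenvalues_fast: np.ndarray
    eigenvalues_slow: np.ndarray
    n_modes_fast: int
    n_modes_slow: int
    spectral_radius_fast: float
    spectral_radius_slow: float


@dataclass
class TrajectoryRecord:
    rates: np.ndarray    # (N, T) spikes/s
    label: object = None


def ev_spectrum(weight_matrix: np.ndarray) -> SpectrumResult:
    """Full complex spectrum of a square weight matrix, with the count of
    modes whose real part exceeds 1 and the spectral radius."""
    m = np.asarray(weight_matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"weight matrix must be square, got {m.shape}")
    ev = np.linalg.eigvals(m)
    return SpectrumResult(
        eigenvalues=ev,
        n_unstable=int(np.sum(ev.real > 1.0)),
        spectral_radius=float(np.abs(ev).max()) if ev.size else 0.0,
    )


def ev_report(auto) -> EVReport:
    """Spectra of an autonomous network's J_fast and J_slow matrices."""
    fast = ev_spectrum(auto.topology.j_fast)
    slow = ev_spectrum(auto.j_slow)
    return EVReport(
        eigenvalues_fast=fast.eigenvalues,
        eigenvalues_slow=slow.eigenvalues,
        n_modes_fast=fast.n_unstable,
        n_modes_slow=slow.n_unstable,
        spectral_radius_fast=fast.spectral_radius,
        spectral_radius_slow=slow.spectral_radius,
    )


def rates_from_raster(
    spike_raster: np.ndarray,
    smoothing_tau: float = 20.0,
    dt: float = 1.0,
    label=None,
) -> TrajectoryRecord:
    """Causal exponential rate estimate, in spikes/s.

    The filter kernel has unit area (each spike contributes 1 - exp(-dt/tau)
    per step, summing to exactly 1 over time), so for a stationary train the
    time-mean filtered value equals the per-step spike probability; the
    1000/dt factor converts to spikes/s.
    """
    raster = np.asarray(spike_raster, dtype=float)
    gain = 1.0 - np.exp(-dt / smoothing_tau)
    filtered = gain * exp_filter(raster, smoothing_tau, dt)
    return TrajectoryRecord(rates=filtered * (1000.0 / dt), label=label)


def trajectory_distance(
    rec1: TrajectoryRecord | np.ndarray,
    rec2: TrajectoryRecord | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-step RMS distance between two rate trajectories, plus its mean.

    d(t) = sqrt(1/N sum_i (r_i1(t) - r_i2(t))^2)
    """
    r1 = rec1.rates if isinstance(rec1, TrajectoryRecord) else np.asarray(rec1)
    r2 = rec2.rates if isinstance(rec2, TrajectoryRecord) else np.asarray(rec2)
    if r1.shape != r2.shape:
        raise ValueError(f"trajectory shapes differ: {r1.shape} vs {r2.shape}")
    d_t = np.sqrt(np.mean((r1 - r2) ** 2, axis=0))
    return d_t, float(d_t.mean())


def class_trajectory_distances(
    records: list[TrajectoryRecord],
) -> tuple[float, float]:
    """Mean intra-class and inter-class time-mean trajectory distance over
    all pairs of labelled records."""
    intra, inter = [], []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            _, mean_d = trajectory_distance(records[i], records[j])
            (intra if records[i].label == records[j].label else inter).append(mean_d)
    if not intra or not inter:
        raise ValueError("need at least one intra-class and one inter-class pair")
    return float(np.mean(intra)), float(np.mean(inter))
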