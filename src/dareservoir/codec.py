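"""Microsaccade-inspired video-to-spike encoding and CRLTB scan extraction.

Consecutive grayscale frames are differenced, thresholded at a ladder of
increasing levels eps_i, and fused into a weighted spike map

    WSpike(x, y) = sum_i eps_i * [P_diff(x, y) >= eps_i] / sum_i eps_i

which is binarized to the spike frame for that frame pair.  Per spike frame
a 41x41 bounding box is placed at the center of gravity of the active
pixels (the C scan) and shifted left/right/up/down by a stride (~half the
box half-width), giving the five C/R/L/T/B fixation windows per frame.
Frames dominated by whole-frame flashes (camera jitter) and scan windows
whose activity departs too far from the center window are deleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EncoderParams",
    "SpikeVideo",
    "ScanSet",
    "SCAN_KEYS",
    "to_grayscale",
    "weighted_spike_frame",
    "encode_video",
    "center_of_gravity",
    "extract_scans",
    "delete_bad_frames",
    "encode_to_scans",
]

SCAN_KEYS = ("C", "R", "L", "T", "B")


@dataclass(frozen=True)
class EncoderParams:
    """Encoder and scan-filter settings.

    thresholds: the increasing ladder of intensity-difference levels eps_i;
    binarize_theta: fraction of the full weighted sum required for a spike
    (default 0.1, i.e. a difference of at least 4 grey levels with the
    default ladder); bb_size: odd bounding-box side in pixels; stride:
    fixation shift in pixels (~half the distance from CoG to box edge);
    min/max_active_frac: whole-frame activity bounds of deletion rule 1.
    """

    thresholds: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    binarize_theta: float = 0.1
    bb_size: int = 41
    stride: int = 10
    min_active_frac: float = 0.08
    max_active_frac: float = 0.75

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing and positive")
        if not (0.0 < self.binarize_theta <= 1.0):
            raise ValueError("binarize_theta must be in (0, 1]")
        if self.bb_size % 2 == 0 or self.bb_size < 1:
            raise ValueError("bb_size must be odd and positive")
        if not (0.0 < self.min_active_frac < self.max_active_frac <= 1.0):
            raise ValueError("require 0 < min_active_frac < max_active_frac <= 1")


@dataclass
class SpikeVideo:
    """Binary spike frames over time, (T, H, W) with values in {0, 1}."""

    frames: np.ndarray
    fps_note: str = "one spike frame per 1 ms simulation step"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.frames.max(initial=0) > 1:
            raise ValueError("spike frames must be binary")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ScanSet:
    """The five CRLTB spike-window streams extracted from one video.

    scans maps each key to a (T_key, bb, bb) uint8 stack; frame_indices maps
    each key to the original spike-frame index of every surviving window;
    deleted_frames records removed indices per scan; cog_track holds the
    per-frame (row, col) center of gravity.
    """

    scans: dict[str, np.ndarray]
    frame_indices: dict[str, np.ndarray]
    deleted_frames: dict[str, list[int]]
    cog_track: np.ndarray
    bb_size: int

    def as_input(self, key: str) -> np.ndarray:
        """Flatten one scan stream to the (bb*bb, T_key) reservoir input."""
        s = self.scans[key]
        return s.reshape(s.shape[0], -1).T.astype(np.uint8)


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Convert an RGB frame stack (T, H, W, 3) to grayscale (ITU-R 601)."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("expected (T, H, W, 3) RGB frames")
    w = np.array([0.299, 0.587, 0.114])
    return (frames.astype(float) @ w).astype(frames.dtype if
                                             frames.dtype == np.uint8 else float)


def _check_gray(frame: np.ndarray, name: str) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        raise ValueError(
            f"{name} looks like a color image; convert with to_grayscale() first"
        )
    if frame.ndim != 2:
        raise ValueError(f"{name} must be a 2-D grayscale frame")
    return frame


def weighted_spike_frame(
    frame_prev: np.ndarray,
    frame_curr: np.ndarray,
    params: EncoderParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference two frames and fuse the multi-threshold spike maps.

    Returns (binary spike frame, weighted WSpike map).  The difference is
    signed (brightening edges spike); pass both frame orders or use the
    absolute difference upstream if darkening edges should also count.
    """
    params = params or EncoderParams()
    prev = _check_gray(frame_prev, "frame_prev")
    curr = _check_gray(frame_curr, "frame_curr")
    if prev.shape != curr.shape:
        raise ValueError(f"frame shapes differ: {prev.shape} vs {curr.shape}")
    p_diff = curr.astype(np.float64) - prev.astype(np.float64)
    eps = np.asarray(params.thresholds, dtype=float)
    wspike = np.zeros_like(p_diff)
    for e in eps:
        wspike += e * (p_diff >= e)
    wspike /= eps.sum()
    spike = (wspike >= params.binarize_theta).astype(np.uint8)
    return spike, wspike


def encode_video(
    frames: np.ndarray,
    params: EncoderParams | None = None,
    absolute_diff: bool = False,
) -> SpikeVideo:
    """Encode a (T, H, W) grayscale stack into T-1 binary spike frames."""
    params = params or EncoderParams()
    frames = np.asarray(frames)
    if frames.ndim == 4:
        raise ValueError("color input: convert with to_grayscale() first")
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    diff = frames[1:].astype(np.float64) - frames[:-1].astype(np.float64)
    if absolute_diff:
        diff = np.abs(diff)
    eps = np.asarray(params.thresholds, dtype=float)
    wspike = np.zeros_like(diff)
    for e in eps:
        wspike += e * (diff >= e)
    wspike /= eps.sum()
    return SpikeVideo((wspike >= params.binarize_theta).astype(np.uint8))


def center_of_gravity(spike_frame: np.ndarray) -> tuple[int, int]:
    """Mean active-pixel location (row, col), rounded to the nearest pixel.

    An empty frame falls back to the frame center — the first fixation sits
    at the center of the image.
    """
    frame = np.asarray(spike_frame)
    rows, cols = np.nonzero(frame)
    if rows.size == 0:
        return frame.shape[0] // 2, frame.shape[1] // 2
    return int(np.rint(rows.mean())), int(np.rint(cols.mean()))


def _window(frame: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    """bb x bb crop centered at ``center``, zero-padded beyond the borders."""
    half = size // 2
    h, w = frame.shape
    out = np.zeros((size, size), dtype=frame.dtype)
    r0, c0 = center[0] - half, center[1] - half
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = frame[rs:re, cs:ce]
    return out


def extract_scans(
    spike_video: SpikeVideo,
    params: EncoderParams | None = None,
) -> ScanSet:
    """Cut the five CRLTB fixation windows out of every spike frame.

    Per frame the C window sits at that frame's CoG and the four directional
    windows at the CoG shifted by +-stride along columns (R/L) or rows
    (B/T); every window is bb x bb, zero-padded at image borders.
    """
    params = params or EncoderParams()
    bb, s = params.bb_size, params.stride
    n = spike_video.n_frames
    scans = {k: np.zeros((n, bb, bb), dtype=np.uint8) for k in SCAN_KEYS}
    cog_track = np.zeros((n, 2), dtype=int)
    offsets = {"C": (0, 0), "R": (0, s), "L": (0, -s), "T": (-s, 0), "B": (s, 0)}
    for i, frame in enumerate(spike_video.frames):
        cog = center_of_gravity(frame)
        cog_track[i] = cog
        for key, (dr, dc) in offsets.items():
            scans[key][i] = _window(frame, (cog[0] + dr, cog[1] + dc), bb)
    idx = np.arange(n)
    return ScanSet(
        scans=scans,
        frame_indices={k: idx.copy() for k in SCAN_KEYS},
        deleted_frames={k: [] for k in SCAN_KEYS},
        cog_track=cog_track,
        bb_size=bb,
    )


def delete_bad_frames(
    scan_set: ScanSet,
    spike_video: SpikeVideo,
    params: EncoderParams | None = None,
) -> ScanSet:
    """Apply the two jitter-filtering deletion rules.

    Rule 1 (whole frame, applied to all five streams): drop frames whose
    active-pixel fraction lies outside [min_active_frac, max_active_frac] —
    flashes from camera shake, or empty frames.  Rule 2 (per directional
    scan): for surviving frame i and S in {R, L, T, B}, drop frame i from
    stream S if |count(C_i) - count(S_i)| exceeds the mean active count of
    the C stream.  The C stream is never touched by rule 2.
    """
    params = params or EncoderParams()
    frames = spike_video.frames
    n = frames.shape[0]
    if any(len(scan_set.frame_indices[k]) != n for k in SCAN_KEYS):
        raise ValueError("scan_set is inconsistent with spike_video")
    frac = frames.reshape(n, -1).mean(axis=1)
    keep1 = np.flatnonzero(
        (frac >= params.min_active_frac) & (frac <= params.max_active_frac)
    )
    rule1_deleted = sorted(set(range(n)) - set(keep1.tolist()))

    counts = {
        k: scan_set.scans[k].reshape(n, -1).sum(axis=1).astype(float)
        for k in SCAN_KEYS
    }
    mean_c = counts["C"][keep1].mean() if keep1.size else 0.0

    scans: dict[str, np.ndarray] = {}
    frame_indices: dict[str, np.ndarray] = {}
    deleted: dict[str, list[int]] = {}
    scans["C"] = scan_set.scans["C"][keep1]
    frame_indices["C"] = keep1.copy()
    deleted["C"] = list(rule1_deleted)
    for k in ("R", "L", "T", "B"):
        bad2 = np.abs(counts["C"][keep1] - counts[k][keep1]) > mean_c
        keep_k = keep1[~bad2]
        scans[k] = scan_set.scans[k][keep_k]
        frame_indices[k] = keep_k
        deleted[k] = sorted(set(rule1_deleted) | set(keep1[bad2].tolist()))
    return ScanSet(
        scans=scans,
        frame_indices=frame_indices,
        deleted_frames=deleted,
        cog_track=scan_set.cog_track.copy(),
        bb_size=scan_set.bb_size,
    )


def encode_to_scans(
    frames: np.ndarray,
    params: EncoderParams | None = None,
) -> ScanSet:
    """Full pipeline: encode -> extract CRLTB scans -> deletion rules."""
    params = params or EncoderParams()
    spikes = encode_video(frames, params)
    scan_set = extract_scans(spikes, params)
    return delete_bad_frames(scan_set, spikes, params)
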