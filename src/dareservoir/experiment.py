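"""End-to-end experiment orchestration: encode -> train -> evaluate -> analyze.

Datasets live on disk as directories of grayscale PNG/PGM frames::

    data/train/<class>/<clip>/frame_0000.png
    data/test/<class>/<clip>/frame_0000.png

Every stage writes its artifact under the output directory and is skipped on
rerun if the artifact already exists, so a run is resumable.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .codec import encode_to_scans, to_grayscale
from .config import ExperimentConfig
from .dynamics import ev_report
from .ensemble import evaluate, train_ensemble
from .io import load_ensemble, load_scan_set, save_ensemble, save_scan_set
from .synth import Clip

__all__ = ["load_frames_dir", "write_clip_dir", "write_dataset",
           "encode_directory", "run_experiment", "da_reconstruction_demo",
           "fewshot_experiment", "b_contrast_experiment",
           "trajectory_separation_experiment"]

_FRAME_SUFFIXES = (".png", ".pgm")


def load_frames_dir(path: str | Path) -> np.ndarray:
    """Load a clip directory of frames (lexicographic order) as (T, H, W)."""
    files = sorted(p for p in Path(path).iterdir()
                   if p.suffix.lower() in _FRAME_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no frame images in {path}")
    frames = np.stack([iio.imread(f) for f in files])
    if frames.ndim == 4:
        frames = to_grayscale(frames)
    return frames


def write_clip_dir(clip: Clip, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(clip.frames):
        iio.imwrite(out / f"frame_{i:04d}.png", frame)
    return out


def write_dataset(train: list[Clip], test: list[Clip],
                  out_dir: str | Path) -> None:
    """Write train/test clips as PNG frame directories plus labels.csv."""
    out = Path(out_dir)
    rows = []
    for split, clips in (("train", train), ("test", test)):
        counter: dict[str, int] = {}
        for clip in clips:
            n = counter.get(clip.label, 0)
            counter[clip.label] = n + 1
            rel = Path(split) / clip.label / f"clip_{n:03d}"
            write_clip_dir(clip, out / rel)
            rows.append({"split": split, "label": clip.label,
                         "path": str(rel)})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def _iter_clips(split_dir: Path):
    for class_dir in sorted(p for p in split_dir.iterdir() if p.is_dir()):
        for clip_dir in sorted(p for p in class_dir.iterdir() if p.is_dir()):
            yield class_dir.name, clip_dir


def encode_directory(split_dir: str | Path, config: ExperimentConfig,
                     cache_dir: str | Path | None = None):
    """Encode every clip of a split into a labelled scan set (cached)."""
    split_dir = Path(split_dir)
    params = config.encoder()
    items = []
    for label, clip_dir in _iter_clips(split_dir):
        cache = (Path(cache_dir) / f"{label}__{clip_dir.name}.h5"
                 if cache_dir else None)
        if cache is not None and cache.exists():
            scan_set, _ = load_scan_set(cache)
        else:
            frames = load_frames_dir(clip_dir)
            scan_set = encode_to_scans(frames, params)
            if cache is not None:
                cache.parent.mkdir(parents=True, exist_ok=True)
                save_scan_set(cache, scan_set, label=label)
        items.append((scan_set, label))
    return items


def run_experiment(config_path: str | Path, data_dir: str | Path,
                   out_dir: str | Path) -> dict:
    """Full pipeline on a prepared dataset directory; returns the metrics."""
    config = ExperimentConfig.from_json(Path(config_path))
    data_dir, out = Path(data_dir), Path(out_dir)
    if not data_dir.exists():
        raise FileNotFoundError(f"data directory {data_dir} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "resolved_config.json")

    train_items = encode_directory(data_dir / "train", config,
                                   cache_dir=out / "scans" / "train")
    test_items = encode_directory(data_dir / "test", config,
                                  cache_dir=out / "scans" / "test")

    model_path = out / "model.h5"
    if model_path.exists():
        model = load_ensemble(model_path)
    else:
        model, logs = train_ensemble(train_items, config)
        save_ensemble(model_path, model)
        for name, log in logs.items():
            log.to_csv(out / f"log_{name}.csv", index=False)

    metrics = evaluate(model, test_items, n_repeats=config.eval_repeats,
                       noise=config.eval_noise,
                       seed=config.stage_seed("evaluate"))
    metrics["confusion"].to_csv(out / "confusion.csv")
    metrics["per_item"].to_csv(out / "per_item.csv", index=False)
    summary = {
        "top1": metrics["top1"], "top1_sd": metrics["top1_sd"],
        **{f"top{k}": v for k, v in metrics["topk"].items()},
    }
    pd.DataFrame([summary]).to_csv(out / "metrics.csv", index=False)

    rows = []
    for key, auto in model.autos.items():
        rep = ev_report(auto)
        for kind, evs in (("J_fast", rep.eigenvalues_fast),
                          ("J_slow", rep.eigenvalues_slow)):
            rows.extend({"model": key, "matrix": kind,
                         "re": float(e.real), "im": float(e.imag)}
                        for e in evs)
    pd.DataFrame(rows).to_csv(out / "spectra.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(summary, indent=2) + "\n")
    return metrics


# ---------------------------------------------------------------------------
# canned experiments
# ---------------------------------------------------------------------------
# These are the package's reference experiments: the driven->autonomous
# reconstruction demo, the few-shot synthetic-video benchmark, the slow-loop
# memory contrast, and the trajectory-separation analysis.  They are used by
# the test suite and by scripts/acceptance.py, and are sized to run on one
# CPU in minutes.

from .autonomous import StdpParams, derive_auto, run_auto, train_auto, van_rossum
from .driven import BumpSpec, build_driven, make_one_hot_target, readout_nrmse, train_driven
from .dynamics import class_trajectory_distances, rates_from_raster
from .synth import default_class_specs, generate_dataset


def da_reconstruction_demo(seed: int = 1) -> dict:
    """Drive a 2 x 400 x 1 network to its one-hot target, then teach the
    derived spiking network to emit the spike target from random input.

    Returns the driven readout's normalized RMSE and the trained autonomous
    readout's van Rossum distance to the spike target (tau = 10 ms),
    expressed as a fraction of the target-vs-silence distance.
    """
    rng = np.random.default_rng(seed)
    bump = BumpSpec()
    target = make_one_hot_target(0, 1, bump)
    driven = build_driven(400, 2, 1, weight_scale=300.0, alpha=1.0,
                          seed=int(rng.integers(2**31)))
    driven, _ = train_driven(driven, [target], n_epochs=15)
    nrmse = readout_nrmse(driven, [target])

    spikes = (rng.random((2, 300)) < 0.3).astype(np.uint8)
    auto = derive_auto(driven, b_max=0.15, seed=int(rng.integers(2**31)),
                       u_r=20.0)
    auto, _ = train_auto(auto, [(spikes, 0)], {0: target}, n_epochs=30,
                         stdp=StdpParams(eta=3.0, eta_decay=0.9, tau_pre=3.0))
    _, out_raster, _ = run_auto(auto, spikes)
    baseline = van_rossum(target.spike_target[0], np.zeros(300))
    distance = van_rossum(out_raster[0], target.spike_target[0])
    return {"nrmse": float(nrmse), "vr_ratio": float(distance / baseline),
            "vr_distance": float(distance), "vr_baseline": float(baseline)}


def fewshot_experiment(seed: int = 0, n_train: int = 8, n_test: int = 20,
                       config: ExperimentConfig | None = None):
    """Train and evaluate the five-scan ensemble on the three-class
    synthetic motion task; returns (metrics, model, test_items)."""
    config = config or ExperimentConfig(seed=seed)
    specs = default_class_specs()
    train, test = generate_dataset(specs, n_train, n_test, seed=seed)
    params = config.encoder()
    train_items = [(encode_to_scans(c.frames, params), c.label) for c in train]
    test_items = [(encode_to_scans(c.frames, params), c.label) for c in test]
    from .ensemble import evaluate as evaluate_fn
    from .ensemble import train_ensemble as train_fn
    model, _logs = train_fn(train_items, config)
    metrics = evaluate_fn(model, test_items, n_repeats=config.eval_repeats,
                          noise=config.eval_noise,
                          seed=config.stage_seed("evaluate"))
    return metrics, model, test_items


def _memory_task_config(seed: int, b_max: float) -> ExperimentConfig:
    # scaled-down task in which the readout window lies entirely after the
    # clip ends, so classification hinges on slow-synapse memory; the RLS
    # ridge is set so the slow loop decays instead of saturating, keeping
    # the post-stimulus activity stimulus-dependent within ~tau_slow
    return ExperimentConfig(n_res=200, b_max=b_max, alpha=1e3, eta=0.2,
                            bump_t0=70.0, bump_dur=90.0, seed=seed)


def _encode_all(clips, params):
    return [(encode_to_scans(c.frames, params), c.label) for c in clips]


def b_contrast_experiment(seed: int = 0, b_low: float = 0.005,
                          b_high: float = 0.15, n_seeds: int = 3) -> dict:
    """Ensemble accuracy with a weak vs. a moderate slow-synapse range.

    Short clips (60 frames) and a readout window that lies entirely after
    the stimulus make the task memory-limited: with B ~ 0 the reservoir
    falls silent before the readout window opens and the classifier cannot
    beat chance, while B in [0, 0.15] sustains stimulus-driven activity into
    the window.  Averages over ``n_seeds`` independent datasets/networks.
    """
    from dataclasses import replace as dc_replace

    from .ensemble import evaluate as evaluate_fn
    from .ensemble import train_ensemble as train_fn

    rng = np.random.default_rng(seed)
    accs: dict[float, list[float]] = {b_low: [], b_high: []}
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        specs = {k: dc_replace(v, image_size=(64, 64), object_size=36,
                               n_frames=60)
                 for k, v in default_class_specs().items()}
        train, test = generate_dataset(specs, 3, 5, seed=s)
        params = _memory_task_config(s, b_low).encoder()
        train_items = _encode_all(train, params)
        test_items = _encode_all(test, params)
        for b in (b_low, b_high):
            model, _ = train_fn(train_items, _memory_task_config(s, b))
            metrics = evaluate_fn(model, test_items, n_repeats=1)
            accs[b].append(metrics["top1"])
    return {"acc_low": float(np.mean(accs[b_low])),
            "acc_high": float(np.mean(accs[b_high])),
            "per_seed_low": accs[b_low], "per_seed_high": accs[b_high]}


def trajectory_separation_experiment(seed: int = 0, n_seeds: int = 3) -> dict:
    """Inter- vs. intra-class reservoir trajectory distance on a trained
    two-class model (horizontal oscillation vs. vertical translation).

    For each of ``n_seeds`` independently generated datasets a center-scan
    autonomous model is trained, test clips are run through its reservoir,
    firing rates are estimated by causal exponential smoothing, and the
    time-mean RMS distances between trajectories of the same and of
    different classes are averaged over all pairs.
    """
    from .ensemble import train_ensemble as train_fn

    rng = np.random.default_rng(seed)
    intra_all, inter_all = [], []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        specs = {k: v for k, v in default_class_specs().items()
                 if k in ("oscillate_x", "translate_y")}
        train, test = generate_dataset(specs, 4, 3, seed=s)
        config = ExperimentConfig(n_res=200, seed=s)
        params = config.encoder()
        train_items = _encode_all(train, params)
        test_items = _encode_all(test, params)
        model, _ = train_fn(train_items, config, scan_keys=("C",))
        auto = model.autos["C"]
        records = []
        for scan_set, label in test_items:
            raster, _, _ = run_auto(auto, scan_set.as_input("C"),
                                    n_steps=config.trial_steps)
            records.append(rates_from_raster(raster, label=label))
        intra, inter = class_trajectory_distances(records)
        intra_all.append(intra)
        inter_all.append(inter)
    return {"intra_mean": float(np.mean(intra_all)),
            "inter_mean": float(np.mean(inter_all)),
            "separation_ratio": float(np.mean(inter_all) / np.mean(intra_all)),
            "per_seed_intra": intra_all, "per_seed_inter": inter_all}
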