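"""Five-scan ensemble: one driven network, five autonomous models, majority vote.

Training first fits the driven network's rate readout to the one-hot
targets, then derives one autonomous model per CRLTB scan from that single
driven network (they all share J_fast) and trains each on its own scan
stream with supervised STDP.  At inference every model votes with the class
of its most active readout neuron; the plurality wins, ties resolve by the
largest summed spike count over the tied classes and then the lowest class
index.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autonomous import AutoNetwork, derive_auto, predict_single, train_auto
from .codec import SCAN_KEYS, ScanSet
from .config import ExperimentConfig
from .driven import DrivenNetwork, build_driven, make_one_hot_target, train_driven
from .driven import TargetPattern

__all__ = ["EnsembleModel", "Prediction", "train_ensemble", "predict",
           "vote", "evaluate"]


@dataclass
class EnsembleModel:
    driven: DrivenNetwork
    autos: dict[str, AutoNetwork]
    classes: list[str]
    config: ExperimentConfig
    targets: dict[int, TargetPattern] = field(default_factory=dict)

    def class_index(self, label: str) -> int:
        return self.classes.index(label)


@dataclass
class Prediction:
    per_model_votes: dict[str, int]
    final_class: int
    vote_margin: int
    per_model_counts: dict[str, np.ndarray]

    @property
    def summed_counts(self) -> np.ndarray:
        return np.sum(list(self.per_model_counts.values()), axis=0)


def train_ensemble(
    train_videos_with_labels: list[tuple[ScanSet, str]],
    config: ExperimentConfig,
    scan_keys: tuple[str, ...] = SCAN_KEYS,
) -> tuple[EnsembleModel, dict[str, pd.DataFrame]]:
    """Train the full D/A ensemble on pre-encoded scan sets.

    Returns the model and per-stage training logs ('driven' is the per-epoch
    readout NRMSE, each scan key the STDP van Rossum log).
    """
    if not scan_keys:
        raise ValueError("ensemble requires at least the five CRLTB scans")
    classes = sorted({label for _, label in train_videos_with_labels})
    for cls in classes:
        if not any(lbl == cls for _, lbl in train_videos_with_labels):
            raise ValueError(f"class {cls} has no training video")
    if not classes:
        raise ValueError("no training videos")
    n_classes = len(classes)
    n_in = config.bb_size * config.bb_size

    driven = build_driven(
        n_res=config.n_res, n_in=n_in, n_out=n_classes,
        p_conn=config.p_conn, weight_scale=config.weight_scale,
        u_scale=config.u_scale, alpha=config.alpha,
        lif=config.lif(), syn=config.syn(),
        apportion_over=config.apportion_over,
        seed=config.stage_seed("driven"),
    )
    targets = {
        i: make_one_hot_target(i, n_classes, config.bump(),
                               n_steps=config.trial_steps, dt=config.dt)
        for i in range(n_classes)
    }
    logs: dict[str, pd.DataFrame] = {}
    driven, nrmse_log = train_driven(driven, list(targets.values()),
                                     n_epochs=config.epochs_driven,
                                     n_steps=config.trial_steps)
    logs["driven"] = pd.DataFrame(
        {"epoch": range(len(nrmse_log)), "nrmse": nrmse_log}
    )

    autos: dict[str, AutoNetwork] = {}
    for key in scan_keys:
        inputs = []
        for scan_set, label in train_videos_with_labels:
            if key not in scan_set.scans or scan_set.scans[key].shape[0] == 0:
                warnings.warn(
                    f"training video of class {label} has no usable {key} "
                    f"scan; skipping it for this model", UserWarning)
                continue
            inputs.append((scan_set.as_input(key), classes.index(label)))
        auto = derive_auto(
            driven, b_max=config.b_max,
            seed=config.stage_seed(f"auto_{key}"),
            u_r=config.u_r, w_init_scale=config.w_init_scale,
        )
        auto, log = train_auto(auto, inputs, targets,
                               n_epochs=config.epochs_auto,
                               stdp=config.stdp(),
                               n_steps=config.trial_steps)
        autos[key] = auto
        logs[key] = log
    model = EnsembleModel(driven=driven, autos=autos, classes=classes,
                          config=config, targets=targets)
    return model, logs


def vote(
    per_model_votes: dict[str, int],
    per_model_counts: dict[str, np.ndarray],
) -> tuple[int, int]:
    """Resolve the ensemble decision from individual votes.

    Plurality of votes; ties broken by the largest spike count summed over
    all models for the tied classes, then by the lowest class index.
    Returns (final_class, vote_margin).
    """
    tally = Counter(per_model_votes.values())
    top = max(tally.values())
    tied = sorted(c for c, n in tally.items() if n == top)
    if len(tied) == 1:
        return tied[0], top
    summed = np.sum(list(per_model_counts.values()), axis=0)
    best = max(tied, key=lambda c: (summed[c], -c))
    return int(best), top


def predict(ensemble: EnsembleModel, scan_set: ScanSet) -> Prediction:
    """Classify one video's scan set with the five-model majority vote."""
    votes: dict[str, int] = {}
    counts: dict[str, np.ndarray] = {}
    n_classes = len(ensemble.classes)
    for key, auto in ensemble.autos.items():
        if key in scan_set.scans and scan_set.scans[key].shape[0] > 0:
            stream = scan_set.as_input(key)
        else:
            stream = np.zeros((auto.topology.n_in, 1), dtype=np.uint8)
        cls, cnt = predict_single(auto, stream,
                                  n_steps=ensemble.config.trial_steps)
        votes[key] = cls
        counts[key] = np.asarray(cnt, dtype=float)[:n_classes]
    final, margin = vote(votes, counts)
    return Prediction(per_model_votes=votes, final_class=final,
                      vote_margin=margin, per_model_counts=counts)


def _noisy_scan_set(scan_set: ScanSet, drop_prob: float,
                    rng: np.random.Generator) -> ScanSet:
    scans = {}
    for k, s in scan_set.scans.items():
        keep = rng.random(s.shape) >= drop_prob
        scans[k] = (s.astype(bool) & keep).astype(np.uint8)
    return ScanSet(scans=scans, frame_indices=scan_set.frame_indices,
                   deleted_frames=scan_set.deleted_frames,
                   cog_track=scan_set.cog_track, bb_size=scan_set.bb_size)


def evaluate(
    ensemble: EnsembleModel,
    test_set: list[tuple[ScanSet, str]],
    k_list: tuple[int, ...] = (1, 3, 5),
    n_repeats: int = 10,
    noise: float = 0.0,
    seed: int = 0,
) -> dict:
    """Top-k metrics, vote accuracy and confusion matrix on a labelled test set.

    Top-1 follows the majority-vote rule; Top-k for k > 1 ranks classes by
    readout spike counts summed across the five models.  Inference is
    deterministic, so with ``noise`` = 0 a single pass stands in for all
    ``n_repeats`` evaluation passes (sd = 0); with spike-deletion noise
    enabled each pass drops input spikes independently with that probability.
    """
    if not test_set:
        raise ValueError("empty test set")
    n_classes = len(ensemble.classes)
    rng = np.random.default_rng(seed)
    passes = n_repeats if noise > 0 else 1
    acc_per_pass: list[dict] = []
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    per_item_rows = []
    for p in range(passes):
        top1_hits = 0
        topk_hits = {k: 0 for k in k_list}
        for scan_set, label in test_set:
            ss = scan_set if noise == 0 else _noisy_scan_set(scan_set, noise, rng)
            pred = predict(ensemble, ss)
            true = ensemble.class_index(label)
            summed = pred.summed_counts
            # rank classes by summed counts, stable toward lower index
            order = np.lexsort((np.arange(n_classes), -summed))
            rank_of_true = int(np.where(order == true)[0][0])
            top1_hits += pred.final_class == true
            for k in k_list:
                if k == 1:
                    topk_hits[k] += pred.final_class == true
                else:
                    topk_hits[k] += rank_of_true < k
            if p == 0:
                confusion[true, pred.final_class] += 1
                per_item_rows.append(
                    {"label": label, "true": true,
                     "predicted": pred.final_class,
                     "vote_margin": pred.vote_margin,
                     **{f"count_{c}": summed[c] for c in range(n_classes)}}
                )
        n = len(test_set)
        acc_per_pass.append(
            {"top1": 100.0 * top1_hits / n,
             **{f"top{k}": 100.0 * topk_hits[k] / n for k in k_list}}
        )
    df = pd.DataFrame(acc_per_pass)
    if passes == 1 and n_repeats > 1:
        df = pd.concat([df] * n_repeats, ignore_index=True)
    metrics = {
        "top1": float(df["top1"].mean()),
        "top1_sd": float(df["top1"].std(ddof=0)),
        "topk": {k: float(df[f"top{k}"].mean()) for k in k_list},
        "topk_sd": {k: float(df[f"top{k}"].std(ddof=0)) for k in k_list},
        "confusion": pd.DataFrame(confusion, index=ensemble.classes,
                                  columns=ensemble.classes),
        "per_item": pd.DataFrame(per_item_rows),
        "n_repeats": n_repeats,
    }
    return metrics
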