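"""Regression metrics and the multi-seed three-model comparison protocol.

Metrics: root mean square error (RMSE, degrees), Pearson correlation
coefficient (CC), and the coefficient of determination

    R2 = 1 - sum (theta - theta_hat)^2 / sum (theta - mean(theta))^2

with the mean taken over the actual series.  The comparison protocol
splits a subject's recording chronologically 70/30, trains each model
variant repeatedly with distinct seeds on the training portion, evaluates
on the held-out portion, and reports per-metric mean and standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pipeline import PipelineConfig, predict, train_pipeline
from .preprocess import FeatureDataset, build_dataset
from .simulate import SyntheticRecording

__all__ = [
    "EvaluationReport",
    "rmse",
    "cc",
    "r2",
    "evaluate_series",
    "split_recording",
    "subject_datasets",
    "compare_models",
]


def _check_pair(actual, estimated) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float).ravel()
    e = np.asarray(estimated, dtype=float).ravel()
    if a.size != e.size:
        raise ValueError("series lengths differ")
    if a.size == 0:
        raise ValueError("empty series")
    return a, e


def rmse(actual, estimated) -> float:
    """Root mean square error, in the units of the series (degrees)."""
    a, e = _check_pair(actual, estimated)
    return float(np.sqrt(np.mean((a - e) ** 2)))


def cc(actual, estimated) -> float:
    """Pearson correlation coefficient; undefined for constant series."""
    a, e = _check_pair(actual, estimated)
    if a.size < 2:
        raise ValueError("need at least two samples")
    if np.std(a) == 0.0 or np.std(e) == 0.0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(a, e)[0, 1])


def r2(actual, estimated) -> float:
    """Coefficient of determination against the mean of the actual series."""
    a, e = _check_pair(actual, estimated)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R2 undefined for a constant actual series")
    return 1.0 - float(np.sum((a - e) ** 2)) / ss_tot


@dataclass
class EvaluationReport:
    """Metrics for one evaluation, or mean +- std across repeats."""

    rmse: float
    cc: float
    r2: float
    n_windows: int
    rmse_std: float = 0.0
    cc_std: float = 0.0
    r2_std: float = 0.0
    per_repeat: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rmse < 0 or abs(self.cc) > 1 + 1e-12:
            raise ValueError("invalid metric values")

    def summary(self) -> str:
        return (
            f"RMSE {self.rmse:.2f} ± {self.rmse_std:.2f} deg, "
            f"CC {self.cc:.3f} ± {self.cc_std:.3f}, "
            f"R² {self.r2:.3f} ± {self.r2_std:.3f} (n={self.n_windows})"
        )


def evaluate_series(actual, estimated) -> EvaluationReport:
    a, e = _check_pair(actual, estimated)
    return EvaluationReport(rmse=rmse(a, e), cc=cc(a, e), r2=r2(a, e), n_windows=a.size)


def split_recording(
    recording: SyntheticRecording, fraction: float = 0.7
) -> Tuple[Tuple[np.ndarray, np.ndarray], Tuple[np.ndarray, np.ndarray]]:
    """Chronological split of raw EMG + angle into (train, test) pairs."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    cfg = recording.config
    k_ang = int(round(fraction * recording.angle.size))
    t_split = k_ang / cfg.fs_angle
    k_emg = int(round(t_split * cfg.fs_emg))
    return (
        (recording.emg[:, :k_emg], recording.angle[:k_ang]),
        (recording.emg[:, k_emg:], recording.angle[k_ang:]),
    )


def subject_datasets(
    recording: SyntheticRecording,
    fraction: float = 0.7,
    config: PipelineConfig = PipelineConfig(),
) -> Tuple[FeatureDataset, FeatureDataset]:
    """Train/test feature datasets; normalization is fitted on train only."""
    (emg_tr, ang_tr), (emg_te, ang_te) = split_recording(recording, fraction)
    cfg = recording.config
    train = build_dataset(
        emg_tr, ang_tr, cfg.fs_emg, cfg.fs_angle, config.filter_spec, config.window_spec
    )
    test = build_dataset(
        emg_te,
        ang_te,
        cfg.fs_emg,
        cfg.fs_angle,
        config.filter_spec,
        config.window_spec,
        norm_params=train.norm_params,
    )
    return train, test


def _aggregate(per_repeat: List[dict], n_windows: int) -> EvaluationReport:
    arr = {k: np.array([r[k] for r in per_repeat]) for k in ("rmse", "cc", "r2")}
    return EvaluationReport(
        rmse=float(arr["rmse"].mean()),
        cc=float(arr["cc"].mean()),
        r2=float(arr["r2"].mean()),
        n_windows=n_windows,
        rmse_std=float(arr["rmse"].std(ddof=1)) if len(per_repeat) > 1 else 0.0,
        cc_std=float(arr["cc"].std(ddof=1)) if len(per_repeat) > 1 else 0.0,
        r2_std=float(arr["r2"].std(ddof=1)) if len(per_repeat) > 1 else 0.0,
        per_repeat=per_repeat,
    )


def compare_models(
    recording: SyntheticRecording,
    variants: Sequence[str] = ("pso_dbn_bp", "dbn_bp_fixed", "bpnn_plain"),
    n_repeats: int = 15,
    seeds: Optional[Sequence[int]] = None,
    config: PipelineConfig = PipelineConfig(),
    train_fraction: float = 0.7,
) -> Dict[str, EvaluationReport]:
    """Train each variant ``n_repeats`` times and evaluate on the test split.

    ``seeds`` defaults to ``range(n_repeats)``; each repeat reseeds every
    pipeline stage, so repeats with one shared seed are identical.
    """
    if n_repeats < 2:
        raise ValueError("need at least two repeats")
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("seeds must have n_repeats entries")

    train, test = subject_datasets(recording, train_fraction, config)
    results: Dict[str, EvaluationReport] = {}
    for variant in variants:
        per_repeat = []
        for seed in seeds:
            model = train_pipeline(train, variant, config.reseed(int(seed)))
            _, est = predict(model, features=test)
            per_repeat.append(
                {
                    "seed": int(seed),
                    "rmse": rmse(test.labels, est),
                    "cc": cc(test.labels, est),
                    "r2": r2(test.labels, est),
                }
            )
        results[variant] = _aggregate(per_repeat, len(test))
    return results
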