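"""Pipeline glue shared by the CLI, tests and the acceptance script.

Normalization policy: by default the pooled mean/SD are fitted on the
training-fold windows only and reused on the test fold (leakage-safe);
``paper_exact=True`` pools every window of the stressor instead, which is
how the normalization is described for the original corpora.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import WindowedDataset, slice_windows
from .evaluation import EvalReport, FoldPlan, compute_metrics, make_folds
from .io import resample
from .model import ModelConfig, StressNet, build_model, he_initialize, predict
from .synthetic import (BeatParams, ProtocolSpec, REST_PARAMS, STRESS_PARAMS,
                        simulate_cohort)
from .training import TrainConfig, TrainLog, prepare_transfer, train


def windows_from_records(records, window_s: int,
                         target_fs: int = 256) -> WindowedDataset:
    """Resample to the common rate and slice (no normalization applied)."""
    resampled = [resample(r, target_fs) if r.fs != target_fs else r
                 for r in records]
    return slice_windows(resampled, window_s, fs=target_fs)


def simulate_windows(protocol: ProtocolSpec, n_subjects: int,
                     window_s: int, cohort_seed: int,
                     rest_params: BeatParams = REST_PARAMS,
                     stress_params: BeatParams = STRESS_PARAMS
                     ) -> WindowedDataset:
    cohort = simulate_cohort(protocol, n_subjects, rest_params, stress_params,
                             cohort_seed)
    return windows_from_records(cohort.records, window_s)


def normalize_split(train_ds: WindowedDataset, test_ds: WindowedDataset,
                    paper_exact: bool = False
                    ) -> tuple[WindowedDataset, WindowedDataset]:
    """Z-score both folds with stats from the training fold (or pooled)."""
    if train_ds.norm_stats is not None:
        return train_ds, test_ds
    if paper_exact:
        pooled = np.concatenate([train_ds.windows.ravel(),
                                 test_ds.windows.ravel()])
    else:
        pooled = train_ds.windows.ravel()
    mu = float(pooled.mean())
    sigma = float(pooled.std())
    if sigma == 0:
        raise ValueError("constant signal: pooled SD is zero")
    return train_ds.normalized(mu, sigma), test_ds.normalized(mu, sigma)


@dataclass
class FitResult:
    net: StressNet
    log: TrainLog
    metrics: object
    test_probs: np.ndarray
    test_labels: np.ndarray


def fit_split(ds: WindowedDataset, train_subjects, test_subjects,
              regime: str, init_seed: int = 0, train_seed: int = 0,
              pretrained=None, channel_mode: str = "equations",
              max_epochs: int = 10, paper_exact: bool = False) -> FitResult:
    """Train one regime on a subject split and evaluate on the test fold."""
    train_ds, test_ds = normalize_split(ds.subset(train_subjects),
                                        ds.subset(test_subjects),
                                        paper_exact)
    cfg = ModelConfig(window_s=ds.window_s, fs=ds.fs,
                      channel_mode=channel_mode)
    if regime == "III":
        if pretrained is None:
            raise ValueError("regime III requires a pretrained checkpoint")
        net = prepare_transfer(pretrained, seed=init_seed, target_cfg=cfg)
    else:
        net = he_initialize(build_model(cfg), seed=init_seed)
    tcfg = TrainConfig(regime=regime, seed=train_seed, max_epochs=max_epochs)
    net, log = train(net, train_ds, tcfg, test_ds)
    probs, _ = predict(net, test_ds.windows)
    metrics = compute_metrics(probs, test_ds.labels)
    return FitResult(net=net, log=log, metrics=metrics,
                     test_probs=probs, test_labels=test_ds.labels)


def cross_validate(ds: WindowedDataset, regime: str, k: int = 10,
                   fold_seed: int = 0, init_seed: int = 0,
                   train_seed: int = 0, pretrained=None,
                   max_epochs: int = 10, paper_exact: bool = False,
                   channel_mode: str = "equations") -> EvalReport:
    """Subject-wise k-fold cross-validation of one training regime."""
    plan = make_folds(ds.subjects(), k=k, seed=fold_seed)
    report = EvalReport(fold_metrics=[], regime=regime, window_s=ds.window_s)
    for i, (train_subj, test_subj) in enumerate(plan.splits()):
        res = fit_split(ds, train_subj, test_subj, regime,
                        init_seed=init_seed + i, train_seed=train_seed + i,
                        pretrained=pretrained, max_epochs=max_epochs,
                        paper_exact=paper_exact, channel_mode=channel_mode)
        report.fold_metrics.append(res.metrics)
        report.curves.append({"fold": i,
                              "scores": res.test_probs[:, 1],
                              "labels": res.test_labels})
    return report
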