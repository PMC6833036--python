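"""Subject-wise cross-validation, metrics, curves, statistics, baselines.

ROC/PR construction and AUC are implemented directly (exhaustive sweep
over distinct score thresholds, trapezoidal area) so they can be checked
against independent oracles (Mann-Whitney U, brute-force recounts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .dataset import WindowedDataset
from .model import StressNet, stage_output_shape


# -- fold plans ------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint subject-id folds covering the whole cohort."""

    folds: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def split(self, i: int) -> tuple[set[str], set[str]]:
        """(train_subjects, test_subjects) for fold ``i``."""
        test = set(self.folds[i])
        train = {s for j, f in enumerate(self.folds) if j != i for s in f}
        return train, test

    def splits(self):
        for i in range(self.k):
            yield self.split(i)


def make_folds(subject_ids, k: int = 10, seed: int = 0) -> FoldPlan:
    """Randomly deal subjects into ``k`` folds of near-equal size."""
    subjects = sorted(set(map(str, subject_ids)))
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(subjects) < k:
        warnings.warn(
            f"only {len(subjects)} subjects; reducing k from {k}",
            stacklevel=2)
        k = len(subjects)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(subjects[idx])
    return FoldPlan(folds=tuple(tuple(sorted(f)) for f in folds), seed=seed)


# -- metrics ---------------------------------------------------------------


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc_roc: float | None     # None when only one class is present

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "precision": self.precision,
                "f1": self.f1, "auc_roc": self.auc_roc}


def _positive_scores(probabilities: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(stress score, predicted label) from [n,2] probabilities or [n] scores."""
    p = np.asarray(probabilities, np.float64)
    if p.ndim == 2:
        return p[:, 1], p.argmax(axis=1)
    return p, (p > 0.5).astype(int)


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int,
                        auc: float | None = None) -> Metrics:
    total = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * prec * sens / (prec + sens)) if prec + sens else 0.0
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn,
                   accuracy=(tp + tn) / total if total else 0.0,
                   sensitivity=sens, specificity=spec, precision=prec, f1=f1,
                   auc_roc=auc)


def roc_curve(scores: np.ndarray, labels: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) across every distinct score threshold.

    Predict positive when score >= threshold; the curve starts at (0,0)
    (threshold above max) and ends at (1,1).
    """
    scores = np.asarray(scores, np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    return fpr, tpr, thresholds


def auc_from_roc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def pr_curve(scores: np.ndarray, labels: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(recall, precision, thresholds) across every distinct threshold."""
    scores = np.asarray(scores, np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("PR curve needs at least one positive label")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y == 1)
    preds = np.arange(1, len(s) + 1)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    recall = tps[distinct] / n_pos
    precision = tps[distinct] / preds[distinct]
    return recall, precision, s[distinct]


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray) -> Metrics:
    """Threshold-0.5/argmax confusion metrics plus trapezoidal ROC AUC."""
    scores, pred = _positive_scores(probabilities)
    labels = np.asarray(labels)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: AUC undefined", stacklevel=2)
        auc = None
    else:
        fpr, tpr, _ = roc_curve(scores, labels)
        auc = auc_from_roc(fpr, tpr)
    return metrics_from_counts(tp, fp, tn, fn, auc)


# -- aggregate reports -----------------------------------------------------


@dataclass
class EvalReport:
    """Per-fold metrics with arithmetic-mean aggregation."""

    fold_metrics: list[Metrics]
    regime: str | None = None
    window_s: int | None = None
    curves: list[dict] = field(default_factory=list)

    def mean_sd(self, name: str) -> tuple[float, float]:
        vals = np.array([getattr(m, name) for m in self.fold_metrics],
                        np.float64)
        return float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1
                                         else 0.0)

    def summary(self) -> dict:
        out = {"regime": self.regime, "window_s": self.window_s,
               "k": len(self.fold_metrics)}
        for name in ("accuracy", "auc_roc", "f1", "sensitivity",
                     "specificity", "precision"):
            vals = [getattr(m, name) for m in self.fold_metrics]
            if any(v is None for v in vals):
                out[name] = None
                continue
            mean, sd = self.mean_sd(name)
            out[name] = {"mean": mean, "sd": sd}
        return out


# -- cross-regime statistics ----------------------------------------------


@dataclass(frozen=True)
class PairResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    significant_05: bool
    significant_001: bool


@dataclass(frozen=True)
class RegimeComparison:
    f_stat: float
    p_value: float
    pairs: tuple[PairResult, ...]
    degenerate: bool = False


def compare_regimes(acc_by_group: dict[str, list[float]]) -> RegimeComparison:
    """One-way ANOVA plus Tukey HSD over per-fold accuracies."""
    groups = {k: np.asarray(v, np.float64) for k, v in acc_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs >= 2 fold values")
    values = list(groups.values())
    pooled = np.concatenate(values)
    degenerate = bool(np.allclose(pooled.var(), 0.0))
    if degenerate:
        warnings.warn("degenerate (zero) variance across all folds",
                      stacklevel=2)
        pairs = tuple(
            PairResult(a, b, float(groups[b].mean() - groups[a].mean()),
                       1.0, False, False)
            for i, a in enumerate(groups) for b in list(groups)[i + 1:])
        return RegimeComparison(0.0, 1.0, pairs, degenerate=True)
    f_stat, p_value = sps.f_oneway(*values)
    data = np.concatenate(values)
    labels = np.concatenate([[name] * len(v) for name, v in groups.items()])
    tk = pairwise_tukeyhsd(data, labels, alpha=0.05)
    pairs = []
    for row in tk.summary().data[1:]:
        a, b, diff, p_adj = str(row[0]), str(row[1]), float(row[2]), \
            float(row[3])
        pairs.append(PairResult(a, b, diff, p_adj,
                                significant_05=p_adj < 0.05,
                                significant_001=p_adj < 0.001))
    return RegimeComparison(float(f_stat), float(p_value), tuple(pairs))


# -- conventional baselines ------------------------------------------------


@dataclass
class BaselineResult:
    per_fold: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_fold, ddof=1)) if len(self.per_fold) > 1 \
            else 0.0


def _baseline_factories(seed: int) -> dict:
    return {
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "logistic_regression": lambda: LogisticRegression(
            max_iter=1000, random_state=seed),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed),
        "svm": lambda: SVC(random_state=seed),
    }


def run_baselines(ds: WindowedDataset, folds: FoldPlan,
                  seed: int = 0,
                  classifiers: list[str] | None = None
                  ) -> dict[str, BaselineResult]:
    """Fit conventional classifiers on flattened raw windows, per fold."""
    factories = _baseline_factories(seed)
    names = classifiers or list(factories)
    flat = ds.windows.reshape(len(ds), -1)
    results = {name: BaselineResult([]) for name in names}
    for train_subj, test_subj in folds.splits():
        tr = np.isin(ds.subject_ids, list(train_subj))
        te = np.isin(ds.subject_ids, list(test_subj))
        if not te.any():
            continue
        for name in names:
            clf = make_pipeline(StandardScaler(), factories[name]())
            clf.fit(flat[tr], ds.labels[tr])
            acc = float((clf.predict(flat[te]) == ds.labels[te]).mean())
            results[name].per_fold.append(acc)
    return results


# -- feature inspection ----------------------------------------------------


def extract_stage_features(net: StressNet, windows: np.ndarray,
                           n: int, batch_size: int = 128) -> np.ndarray:
    """Flattened stage-``n`` feature vectors, one row per window."""
    if not 1 <= n <= net.cfg.n_stages:
        raise ValueError(f"stage {n} out of range 1..{net.cfg.n_stages}")
    width, channels = stage_output_shape(net.cfg, n)
    windows = np.asarray(windows, np.float32)
    out = np.empty((windows.shape[0], width * channels), np.float32)
    for i in range(0, windows.shape[0], batch_size):
        net.forward(windows[i:i + batch_size], training=False, collect=True)
        feats = net.stage_outputs[n - 1]
        out[i:i + batch_size] = feats.reshape(feats.shape[0], -1)
    return out


def embed_2d(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D stochastic-neighbor embedding of feature vectors (plotting aid)."""
    from sklearn.manifold import TSNE
    n = features.shape[0]
    perplexity = max(2.0, min(30.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="random")
    return tsne.fit_transform(np.asarray(features, np.float64))
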