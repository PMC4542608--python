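"""Resampled evaluation of PLS-DA decision algorithms.

The evaluation mirrors a class-balanced, site-grouped resampling design:
each iteration downsamples every class to the smallest class's site
count, splits sites 60/40 per class into train/test (no site ever on
both sides), fits PLS-DA on the training spectra and scores the held-out
spectra; per-class correct rates are averaged over (by default) 100
iterations. A permutation negative control reruns the identical pipeline
with class labels shuffled across sites each iteration, which must
collapse performance to the 1/n_classes chance level. Binary tasks
additionally report PPV/NPV/sensitivity/specificity/overall accuracy and
a pooled ROC curve with trapezoid AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import SpectralDataset
from .plsda import PLSDAClassifier, select_n_components_cv


@dataclass
class ResamplingPlan:
    """Design of the resampled evaluation."""

    n_iterations: int = 100
    train_fraction: float = 0.6
    balance: bool = True
    split_unit: str = "site"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.split_unit not in ("site", "spectrum"):
            raise ValueError("split_unit must be 'site' or 'spectrum'")


@dataclass
class BinaryMetrics:
    """Diagnostic metrics of a 2x2 confusion matrix (fractions).

    Ratios with zero denominators are NaN and named in ``undefined``.
    """

    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    accuracy: float
    undefined: list[str] = field(default_factory=list)

    def as_percent(self) -> dict[str, float]:
        return {
            k: round(100.0 * v, 2)
            for k, v in {
                "PPV": self.ppv,
                "NPV": self.npv,
                "SE": self.sensitivity,
                "SP": self.specificity,
                "OA": self.accuracy,
            }.items()
        }


@dataclass
class EvaluationReport:
    """Outcome of a resampled evaluation."""

    class_order: list[str]
    confusions: np.ndarray  # (n_iterations, c, c), rows = truth
    mean_class_rates: dict[str, float]
    overall_rate: float
    n_components_used: int
    site_splits: list[tuple[frozenset, frozenset]]
    binary: Optional[BinaryMetrics] = None
    roc_points: Optional[np.ndarray] = None
    auc: Optional[float] = None

    @property
    def total_confusion(self) -> np.ndarray:
        return self.confusions.sum(axis=0)


def _site_table(dataset: SpectralDataset, labels) -> tuple[np.ndarray, np.ndarray, dict]:
    """Unique sites, their class label, and site -> spectrum-row indices."""
    labels = np.asarray(labels)
    if labels.shape[0] != dataset.n_spectra:
        raise ValueError("labels must align with dataset rows")
    sites = dataset.site_ids.astype(str)
    uniq, first = np.unique(sites, return_index=True)
    site_labels = labels[first]
    # spectra of one site must agree on the label
    for s, lab in zip(uniq, site_labels):
        if not np.all(labels[sites == s] == lab):
            raise ValueError(f"site {s!r} carries conflicting class labels")
    rows = {s: np.flatnonzero(sites == s) for s in uniq}
    return uniq, site_labels, rows


def _resample_evaluate(
    dataset: SpectralDataset,
    labels,
    plan: ResamplingPlan,
    n_components: Optional[int],
    permute: bool,
    positive_class: Optional[str],
) -> EvaluationReport:
    sites, site_labels, rows = _site_table(dataset, labels)
    classes = np.unique(site_labels)
    if classes.size < 2:
        raise ValueError("at least two classes required")
    for cls in classes:
        if np.sum(site_labels == cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 sites")
    class_index = {c: i for i, c in enumerate(classes)}

    split_rng = np.random.default_rng([plan.rng_seed, 0])
    perm_rng = np.random.default_rng([plan.rng_seed, 1])
    cv_rng = np.random.default_rng([plan.rng_seed, 2])

    X = dataset.intensities
    confusions = []
    splits = []
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    a_used = n_components

    for _ in range(plan.n_iterations):
        labels_iter = perm_rng.permutation(site_labels) if permute else site_labels

        per_class_sites = {c: sites[labels_iter == c] for c in classes}
        if plan.balance:
            m = min(len(v) for v in per_class_sites.values())
            per_class_sites = {
                c: split_rng.choice(v, size=m, replace=False)
                for c, v in per_class_sites.items()
            }
        train_sites: list[str] = []
        test_sites: list[str] = []
        for c in classes:
            chosen = np.asarray(per_class_sites[c])
            order = split_rng.permutation(chosen.size)
            n_train = int(round(plan.train_fraction * chosen.size))
            n_train = min(max(n_train, 1), chosen.size - 1)
            train_sites.extend(chosen[order[:n_train]])
            test_sites.extend(chosen[order[n_train:]])
        train_set, test_set = frozenset(train_sites), frozenset(test_sites)
        assert not train_set & test_set, "train/test site overlap"
        splits.append((train_set, test_set))

        lab_of = dict(zip(sites, labels_iter))
        tr_idx = np.concatenate([rows[s] for s in train_sites])
        te_idx = np.concatenate([rows[s] for s in test_sites])
        y_tr = np.asarray(
            [lab_of[s] for s in train_sites for _ in rows[s]], dtype=classes.dtype
        )
        y_te = np.asarray(
            [lab_of[s] for s in test_sites for _ in rows[s]], dtype=classes.dtype
        )

        if a_used is None:
            a_used = select_n_components_cv(X[tr_idx], y_tr, rng=cv_rng)
        model = PLSDAClassifier(a_used).fit(X[tr_idx], y_tr)
        pred = model.predict(X[te_idx])

        cm = np.zeros((classes.size, classes.size), dtype=int)
        for t, p in zip(y_te, pred):
            cm[class_index[t], class_index[p]] += 1
        confusions.append(cm)

        if positive_class is not None:
            pooled_scores.append(model.positive_scores(X[te_idx], positive_class))
            pooled_truth.append(y_te == positive_class)

    confusions = np.asarray(confusions)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = confusions.diagonal(axis1=1, axis2=2) / confusions.sum(axis=2)
    mean_class_rates = {
        str(c): float(np.nanmean(rates[:, i])) for i, c in enumerate(classes)
    }
    overall = float(
        np.mean(confusions.diagonal(axis1=1, axis2=2).sum(axis=1) / confusions.sum(axis=(1, 2)))
    )

    report = EvaluationReport(
        class_order=[str(c) for c in classes],
        confusions=confusions,
        mean_class_rates=mean_class_rates,
        overall_rate=overall,
        n_components_used=int(a_used),
        site_splits=splits,
    )
    if positive_class is not None:
        pos = str(positive_class)
        neg = [c for c in report.class_order if c != pos]
        if len(neg) != 1:
            raise ValueError("binary metrics require exactly two classes")
        total = report.total_confusion
        i_pos, i_neg = report.class_order.index(pos), report.class_order.index(neg[0])
        tp = int(total[i_pos, i_pos])
        fn = int(total[i_pos, i_neg])
        fp = int(total[i_neg, i_pos])
        tn = int(total[i_neg, i_neg])
        report.binary = binary_metrics(tp=tp, fp=fp, fn=fn, tn=tn)
        scores = np.concatenate(pooled_scores)
        truth = np.concatenate(pooled_truth)
        report.roc_points, report.auc = roc_curve(scores, truth)
    return report


def balanced_resample_evaluate(
    dataset: SpectralDataset,
    labels,
    plan: ResamplingPlan | None = None,
    n_components: Optional[int] = None,
    positive_class: Optional[str] = None,
) -> EvaluationReport:
    """Class-balanced, site-grouped 60/40 resampling evaluation.

    ``labels`` is the per-spectrum class vector. ``n_components=None``
    selects the latent-variable count by 5-fold CV on the first
    iteration's training split and reuses it. For binary tasks pass
    ``positive_class`` to obtain PPV/NPV/SE/SP/OA and the pooled ROC/AUC.
    """
    plan = plan or ResamplingPlan()
    return _resample_evaluate(dataset, labels, plan, n_components, False, positive_class)


def negative_control(
    dataset: SpectralDataset,
    labels,
    plan: ResamplingPlan | None = None,
    n_components: Optional[int] = None,
    positive_class: Optional[str] = None,
    _permutation: str = "random",
) -> EvaluationReport:
    """Random-label negative control.

    Class labels are permuted uniformly across sites each iteration
    (class sizes preserved) before the identical balanced evaluation; the
    mean overall correct rate must collapse to ~1/n_classes.
    ``_permutation='identity'`` is a debug hook that skips the shuffle,
    reproducing :func:`balanced_resample_evaluate` exactly.
    """
    plan = plan or ResamplingPlan()
    permute = _permutation != "identity"
    return _resample_evaluate(dataset, labels, plan, n_components, permute, positive_class)


def binary_task(dataset: SpectralDataset, labels, positive: str, negatives) -> tuple[SpectralDataset, np.ndarray]:
    """Restrict a dataset to a binary contrast.

    ``negatives`` is a label or list of labels pooled into one
    ``'rest'``-style negative class named by joining the labels.
    """
    labels = np.asarray(labels)
    if isinstance(negatives, str):
        negatives = [negatives]
    neg_name = "+".join(negatives)
    mask = (labels == positive) | np.isin(labels, negatives)
    sub = dataset.subset(mask)
    y = np.where(labels[mask] == positive, positive, neg_name)
    return sub, y


def roc_curve(scores, truth) -> tuple[np.ndarray, float]:
    """ROC points (1-specificity, sensitivity) and trapezoid AUC.

    Thresholds sweep the unique score values (ties grouped); endpoints
    (0,0) and (1,1) are always included. Raises if only one class is
    present in ``truth``.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes in the truth vector")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    tps = np.cumsum(t)
    fps = np.cumsum(~t)
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    idx = np.r_[distinct, s.size - 1]
    tpr = np.r_[0.0, tps[idx] / n_pos]
    fpr = np.r_[0.0, fps[idx] / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def binary_metrics(tp: int, fp: int, fn: int, tn: int) -> BinaryMetrics:
    """PPV/NPV/SE/SP/OA from 2x2 counts; zero-denominator ratios are NaN
    and listed in ``undefined``."""
    for name, v in {"tp": tp, "fp": fp, "fn": fn, "tn": tn}.items():
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    se = ratio(tp, tp + fn, "sensitivity")
    sp = ratio(tn, tn + fp, "specificity")
    oa = ratio(tp + tn, tp + fp + fn + tn, "accuracy")
    return BinaryMetrics(ppv, npv, se, sp, oa, undefined)
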