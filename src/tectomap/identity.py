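"""How well transcriptomic identity is reflected in function and position.

Three analyses over t-type-labelled, functionally recorded ROIs:

* within- vs between-t-type pairwise Pearson correlation of raw calcium
  traces, with a per-type paired t-test (Bonferroni over types);
* per-t-type mean scaled response scores (t x 8 summary table);
* an SVM comparison asking whether scaled response vectors, 3D cell-body
  positions, or both predict t-type best (RBF kernel, C=1, gamma by the
  scale heuristic, training classes upsampled with replacement, repeated
  stratified 90/10 splits, shuffled-label negative controls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .scoring import TraceMatrix
from .stimulus import STIM_CLASSES


@dataclass
class CorrelationSummary:
    per_roi: pd.DataFrame   # roi, t_type, mean_within_r, mean_between_r
    per_type: pd.DataFrame  # t_type, t_stat, p, p_bonferroni, n
    corr_matrix: np.ndarray


def trace_correlation_summary(
    traces: TraceMatrix, t_labels: np.ndarray
) -> CorrelationSummary:
    """Within- vs between-type mean pairwise trace correlations.

    All-pairs Pearson r on raw traces; per ROI the mean r to same-type
    ROIs (excluding self) and to all other-type ROIs; per type a paired
    two-sided t-test of within vs between means across its ROIs,
    Bonferroni-corrected over the number of types. Constant traces are
    excluded with a warning.
    """
    t_labels = np.asarray(t_labels)
    values = traces.values
    keep = np.ptp(values, axis=1) > 0  # exactly constant traces have no spread
    if not keep.all():
        warnings.warn(f"excluding {np.sum(~keep)} constant trace(s)")
    values = values[keep]
    labels = t_labels[keep]
    roi_ids = np.asarray(traces.roi_ids)[keep]

    corr = np.corrcoef(values)
    n = len(values)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    other = labels[:, None] != labels[None, :]

    def _masked_mean(mask: np.ndarray) -> np.ndarray:
        counts = mask.sum(axis=1)
        sums = np.where(mask, corr, 0.0).sum(axis=1)
        out = np.full(n, np.nan)
        np.divide(sums, counts, out=out, where=counts > 0)
        return out

    within = _masked_mean(same)
    between = _masked_mean(other)
    per_roi = pd.DataFrame(
        {
            "roi_id": roi_ids,
            "t_type": labels,
            "mean_within_r": within,
            "mean_between_r": between,
        }
    )

    types = np.unique(labels)
    rows = []
    for t in types:
        sel = labels == t
        w = within[sel]
        b = between[sel]
        ok = np.isfinite(w) & np.isfinite(b)
        if ok.sum() < 2:
            rows.append((t, np.nan, np.nan, np.nan, int(ok.sum())))
            continue
        stat, p = stats.ttest_rel(w[ok], b[ok])
        rows.append((t, float(stat), float(p), float(min(1.0, p * len(types))), int(ok.sum())))
    per_type = pd.DataFrame(
        rows, columns=["t_type", "t_stat", "p", "p_bonferroni", "n"]
    )
    return CorrelationSummary(per_roi=per_roi, per_type=per_type, corr_matrix=corr)


def ttype_response_summary(
    scaled_scores: np.ndarray, t_labels: np.ndarray
) -> pd.DataFrame:
    """Per-t-type mean scaled response score for each stimulus (t x 8)."""
    df = pd.DataFrame(np.asarray(scaled_scores, dtype=float), columns=list(STIM_CLASSES))
    df["t_type"] = np.asarray(t_labels)
    return df.groupby("t_type").mean()


@dataclass
class ClassifierReport:
    feature_set: str
    accuracies: np.ndarray
    shuffled_accuracies: np.ndarray
    confusion: pd.DataFrame  # true-positive-rate matrix averaged over repeats
    real_vs_shuffled_p: float


def _upsample(
    X: np.ndarray, y: np.ndarray, per_class: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample training rows with replacement to ``per_class`` per type."""
    Xs, ys = [], []
    for t in np.unique(y):
        idx = np.flatnonzero(y == t)
        pick = rng.choice(idx, size=per_class, replace=True)
        Xs.append(X[pick])
        ys.append(y[pick])
    return np.vstack(Xs), np.concatenate(ys)


def _run_svm(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int,
    test_frac: float,
    upsample_to: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated stratified-split SVM; returns accuracies and mean confusion."""
    types = np.unique(y)
    t_index = {t: i for i, t in enumerate(types)}
    accs = np.empty(n_repeats)
    confusion = np.zeros((len(types), len(types)))
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_frac, stratify=y, random_state=split_seed
        )
        X_up, y_up = _upsample(X_tr, y_tr, upsample_to, rng)
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
        clf.fit(X_up, y_up)
        pred = clf.predict(X_te)
        accs[rep] = float(np.mean(pred == y_te))
        for yt, yp in zip(y_te, pred):
            confusion[t_index[yt], t_index[yp]] += 1
    row_sums = confusion.sum(axis=1, keepdims=True)
    tpr = np.zeros_like(confusion)
    np.divide(confusion, row_sums, out=tpr, where=row_sums > 0)
    return accs, tpr


def svm_type_comparison(
    scaled_scores: np.ndarray,
    positions: np.ndarray,
    t_labels: np.ndarray,
    n_repeats: int = 20,
    test_frac: float = 0.1,
    upsample_to: int = 1000,
    seed: int | None = None,
    standardize_positions: bool = False,
) -> tuple[dict[str, ClassifierReport], pd.DataFrame]:
    """Predict t-type from response vectors, positions, or both.

    For each feature set an RBF-kernel SVM (C=1, gamma='scale') is trained
    on a stratified 90% split with the training rows upsampled with
    replacement to ``upsample_to`` per type, and evaluated on the held-out
    10%; this is repeated ``n_repeats`` times, and once more per feature
    set with globally shuffled labels as a negative control. Positions are
    used in raw µm by default (``standardize_positions`` exists because
    RBF kernels are scale-sensitive).

    Returns per-feature-set reports and a pairwise Mann–Whitney comparison
    table between feature sets.
    """
    X_resp = np.asarray(scaled_scores, dtype=float)
    X_pos = np.asarray(positions, dtype=float)
    y = np.asarray(t_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 t-types")
    if standardize_positions:
        X_pos = (X_pos - X_pos.mean(axis=0)) / X_pos.std(axis=0)
    feature_sets = {
        "response": X_resp,
        "position": X_pos,
        "combined": np.hstack([X_resp, X_pos]),
    }
    ss = np.random.SeedSequence(seed)
    reports: dict[str, ClassifierReport] = {}
    types = np.unique(y)
    for (name, X), child in zip(feature_sets.items(), ss.spawn(len(feature_sets))):
        s1, s2, s3 = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in child.spawn(3))
        accs, tpr = _run_svm(X, y, n_repeats, test_frac, upsample_to, s1)
        y_shuf = np.random.default_rng(s2).permutation(y)
        shuf_accs, _ = _run_svm(X, y_shuf, n_repeats, test_frac, upsample_to, s3)
        _, p = stats.mannwhitneyu(accs, shuf_accs, alternative="two-sided")
        reports[name] = ClassifierReport(
            feature_set=name,
            accuracies=accs,
            shuffled_accuracies=shuf_accs,
            confusion=pd.DataFrame(tpr, index=types, columns=types),
            real_vs_shuffled_p=float(p),
        )
    rows = []
    names = list(feature_sets)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            _, p = stats.mannwhitneyu(
                reports[names[i]].accuracies,
                reports[names[j]].accuracies,
                alternative="two-sided",
            )
            rows.append((names[i], names[j], float(p)))
    comparisons = pd.DataFrame(rows, columns=["feature_a", "feature_b", "p"])
    return reports, comparisons
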