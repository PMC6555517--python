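"""Word-level evaluation harness.

Words are segmented from the silence gaps in the front-end stream, each
word is summarised by summing activity over its frames (front-end
magnitudes, or per-unit firing counts for the encoder), and a linear SVM
with a swept C parameter is trained under stratified 5-fold
cross-validation.  Robustness is measured by scoring the already-trained
classifiers on features from degraded corpora, and paired two-tailed
t-tests with a Holm-Bonferroni step-down (fixed correction factor) compare
the two feature sources across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

__all__ = [
    "ClassificationResult",
    "detect_word_boundaries",
    "marks_from_track",
    "aggregate_frame_vectors",
    "aggregate_activation_vectors",
    "scale_features",
    "svm_crossval",
    "evaluate_variants",
    "paired_tests",
    "holm_bonferroni",
    "write_libsvm",
]

DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))


@dataclass
class ClassificationResult:
    accuracy: float  # best cross-validated accuracy, percent
    best_c: float
    per_c: dict[float, float]  # C -> CV accuracy (percent)
    fold_seed: int
    scaler: MinMaxScaler | None = None
    model: SVC | None = None


def detect_word_boundaries(
    stream, min_gap_frames: int = 10, silent: np.ndarray | None = None
) -> list[tuple[int, int]]:
    """Find word segments as maximal non-silent frame runs.

    A frame is silent when every element of its pre-normalization magnitude
    is negligible (the stream's undetermined mask).  Runs separated by
    fewer than ``min_gap_frames`` silent frames are merged, so brief
    intra-word dips do not split a word.  Returns [start, end) frame marks.
    """
    if silent is None:
        silent = stream.frame_undetermined
    nonsilent = ~np.asarray(silent)
    if not nonsilent.any():
        return []
    edges = np.diff(nonsilent.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if nonsilent[0]:
        starts.insert(0, 0)
    if nonsilent[-1]:
        ends.append(len(nonsilent))
    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def marks_from_track(
    track: list[dict], sample_rate: int, frame_period: float
) -> tuple[list[tuple[int, int]], list[str]]:
    """Convert a sample-accurate boundary track to frame marks + labels."""
    hop = sample_rate * frame_period
    marks, labels = [], []
    for seg in track:
        marks.append((int(seg["start"] / hop), max(int(np.ceil(seg["end"] / hop)), 1)))
        labels.append(seg["label"])
    return marks, labels


def aggregate_frame_vectors(stream, marks: list[tuple[int, int]]) -> np.ndarray:
    """One vector per word: front-end activity summed over the word's frames."""
    _check_marks(marks, len(stream))
    flat = stream.values.reshape(len(stream), -1)
    return np.stack([flat[s:e].sum(axis=0) for s, e in marks]) if marks else np.zeros((0, flat.shape[1]))


def aggregate_activation_vectors(
    activations: list, marks: list[tuple[int, int]]
) -> scipy.sparse.csr_matrix:
    """One sparse vector per word: per-unit firing counts over the word's frames."""
    _check_marks(marks, len(activations))
    if not activations:
        return scipy.sparse.csr_matrix((len(marks), 0))
    n_feat = activations[0].active_mask.size
    rows = []
    for s, e in marks:
        acc = np.zeros(n_feat, dtype=np.float64)
        for t in range(s, e):
            acc += activations[t].active_mask.reshape(-1)
        rows.append(scipy.sparse.csr_matrix(acc))
    return scipy.sparse.vstack(rows, format="csr")


def _check_marks(marks, n_frames):
    last_end = 0
    for s, e in marks:
        if s < last_end:
            raise ValueError("overlapping word marks")
        if e > n_frames or s < 0:
            raise ValueError("word mark outside the stream")
        last_end = e if e > last_end else last_end


def scale_features(train, test=None):
    """Map each component of the training data linearly onto [0, 1].

    The identical (unclamped) map is applied to the test data, so test
    values may fall outside [0, 1]; constant components map to 0.  Returns
    (scaled train, scaled test or None, fitted scaler).
    """
    scaler = MinMaxScaler(clip=False)
    train = np.asarray(train.todense()) if scipy.sparse.issparse(train) else np.asarray(train)
    train_s = scaler.fit_transform(train)
    test_s = None
    if test is not None:
        test = np.asarray(test.todense()) if scipy.sparse.issparse(test) else np.asarray(test)
        test_s = scaler.transform(test)
    return train_s, test_s, scaler


def svm_crossval(
    X,
    y,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    folds: int = 5,
    seed: int = 0,
) -> ClassificationResult:
    """Linear-kernel SVM accuracy under stratified k-fold cross-validation.

    Scaling is fit inside each fold on the training partition only, so no
    information leaks from the held-out fold.  The best C is refit on all
    data (with a full-data scaler) for subsequent variant scoring.
    """
    X = np.asarray(X.todense()) if scipy.sparse.issparse(X) else np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} samples per class for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    per_c: dict[float, float] = {}
    for C in c_grid:
        correct = 0
        for tr, te in splits:
            Xtr, Xte, _ = scale_features(X[tr], X[te])
            clf = SVC(kernel="linear", C=C)
            clf.fit(Xtr, y[tr])
            correct += int((clf.predict(Xte) == y[te]).sum())
        per_c[C] = 100.0 * correct / len(y)
    best_c = max(per_c, key=lambda c: (per_c[c], -c))
    Xs, _, scaler = scale_features(X)
    model = SVC(kernel="linear", C=best_c)
    model.fit(Xs, y)
    return ClassificationResult(
        accuracy=per_c[best_c],
        best_c=best_c,
        per_c=per_c,
        fold_seed=seed,
        scaler=scaler,
        model=model,
    )


def evaluate_variants(
    results: dict[str, ClassificationResult],
    variant_features: dict[str, dict[str, tuple]],
) -> dict[str, dict[str, float]]:
    """Score already-trained classifiers on degraded-corpus features.

    ``results`` maps feature source (e.g. "mrstsa", "encoder") to a trained
    ClassificationResult; ``variant_features`` maps variant name -> source
    -> (X, y).  Returns accuracy (percent) per variant x source, without
    any retraining.
    """
    table: dict[str, dict[str, float]] = {}
    for variant, by_source in variant_features.items():
        table[variant] = {}
        for source, (X, y) in by_source.items():
            res = results[source]
            X = np.asarray(X.todense()) if scipy.sparse.issparse(X) else np.asarray(X)
            if X.shape[1] != res.scaler.n_features_in_:
                raise ValueError(f"{variant}/{source}: feature dimension mismatch")
            pred = res.model.predict(res.scaler.transform(X))
            table[variant][source] = 100.0 * float(np.mean(pred == np.asarray(y)))
    return table


def holm_bonferroni(pvalues, m: int = 7, alpha: float = 0.05):
    """Holm step-down with an externally fixed correction factor ``m``.

    The i-th smallest p-value is compared against alpha / (m - i); the
    step-down stops at the first failure.  Returns (adjusted p, reject).
    """
    p = np.asarray(pvalues, dtype=float)
    if m < len(p):
        raise ValueError("correction factor smaller than the number of tests")
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min((m - rank) * p[idx], 1.0))
        adj[idx] = running
    reject = np.zeros(len(p), dtype=bool)
    for rank, idx in enumerate(order):
        if adj[idx] < alpha:
            reject[idx] = True
        else:
            break
    return adj, reject


def paired_tests(
    condition_pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    m: int = 7,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Two-tailed paired t-tests per condition with Holm-Bonferroni flags.

    Each condition supplies paired accuracy samples (e.g. encoder vs
    front-end over vocabularies).  Zero-variance differences are degenerate
    for the t statistic: identical pairs give p = 1 (no effect), while a
    constant nonzero difference is reported significant by convention and
    flagged ``degenerate`` in the output.
    """
    names = list(condition_pairs)
    stats: dict[str, dict] = {}
    pvals = []
    for name in names:
        a, b = (np.asarray(v, dtype=float) for v in condition_pairs[name])
        if len(a) != len(b) or len(a) < 2:
            raise ValueError(f"{name}: need paired samples with n >= 2")
        diff = a - b
        degenerate = bool(np.ptp(diff) == 0)
        if degenerate:
            p = 1.0 if diff[0] == 0 else 0.0
            t = np.nan if diff[0] == 0 else np.inf * np.sign(diff[0])
        else:
            t, p = scipy.stats.ttest_rel(a, b)
        stats[name] = {"t": float(t), "p": float(p), "degenerate": degenerate,
                       "mean_difference": float(diff.mean())}
        pvals.append(p)
    adj, reject = holm_bonferroni(pvals, m=m, alpha=alpha)
    for i, name in enumerate(names):
        stats[name]["p_adjusted"] = float(adj[i])
        stats[name]["significant"] = bool(reject[i])
    return stats


def write_libsvm(path, X, y) -> None:
    """Write a feature matrix in LIBSVM sparse text format."""
    X = scipy.sparse.csr_matrix(X)
    with open(path, "w") as fh:
        for i in range(X.shape[0]):
            row = X.getrow(i)
            feats = " ".join(f"{j + 1}:{v:.10g}" for j, v in zip(row.indices, row.data))
            fh.write(f"{y[i]} {feats}\n")
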