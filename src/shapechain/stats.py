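"""Stepwise linear discriminant analysis with canonical components and LOOCV.

Forward selection with backward removal on the partial F statistic derived
from Wilks' lambda: a variable enters when its partial F is at least
``f_enter`` and leaves when it drops below ``f_remove`` (the classic 3.84 /
2.71 defaults).  The classifier is a linear discriminant with pooled
within-group covariance and equal priors; canonical components come from the
generalized eigenproblem of the between- and within-group scatter matrices
(``g`` groups yield ``g − 1`` components).  Leave-one-out cross-validation
refits the classifier on each n−1 subset with the variable set held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import CollinearityError, ConfigurationError

__all__ = ["DAResult", "stepwise_da", "loocv", "wilks_lambda"]


@dataclass
class DAResult:
    """Outcome of a stepwise discriminant analysis."""

    selected: list[str]
    wilks_path: list[float]  # Wilks' lambda after each entry step
    canonical_loadings: pd.DataFrame | None
    scores: pd.DataFrame | None
    confusion: pd.DataFrame | None
    accuracy: float | None  # resubstitution, percent
    loocv_confusion: pd.DataFrame | None
    loocv_accuracy: float | None  # percent
    groups: list[str] = field(default_factory=list)
    empty: bool = False


# ---------------------------------------------------------------------------
# Wilks' lambda machinery
# ---------------------------------------------------------------------------

def _scatter(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group and total scatter matrices."""
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        cg = Xg.mean(axis=0)
        W += (Xg - cg).T @ (Xg - cg)
    return W, T


def wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for the given variables; 1.0 for an empty
    variable set."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        return 1.0
    W, T = _scatter(X, y)
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0 or sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def _partial_f(
    lam_small: float, lam_big: float, n: int, g: int, p_small: int
) -> float:
    """Partial F for adding one variable to ``p_small`` already-selected ones."""
    df2 = n - g - p_small
    if df2 <= 0 or lam_big <= 0:
        return 0.0
    return (df2 / (g - 1)) * (lam_small / lam_big - 1.0)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def _select_variables(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    f_enter: float,
    f_remove: float,
) -> tuple[list[int], list[float]]:
    n = len(y)
    g = len(np.unique(y))
    selected: list[int] = []
    lam_path: list[float] = []
    lam_current = 1.0
    max_steps = 4 * X.shape[1]
    for _ in range(max_steps):
        # forward: best candidate by partial F, ties to the smaller index
        p0 = len(selected)
        if n - g - p0 - 1 <= 0:
            break  # guard: keep more samples than variables
        best_f, best_idx, best_lam = -np.inf, None, None
        for idx in range(X.shape[1]):
            if idx in selected:
                continue
            lam_new = wilks_lambda(X[:, selected + [idx]], y)
            f = _partial_f(lam_current, lam_new, n, g, p0)
            if f > best_f + 1e-12:
                best_f, best_idx, best_lam = f, idx, lam_new
        if best_idx is None or best_f < f_enter:
            break
        selected.append(best_idx)
        lam_current = best_lam
        lam_path.append(lam_current)
        # backward: drop any variable whose partial F fell below f_remove
        changed = True
        while changed and len(selected) > 1:
            changed = False
            worst_f, worst_pos = np.inf, None
            for pos, idx in enumerate(selected):
                rest = selected[:pos] + selected[pos + 1 :]
                lam_rest = wilks_lambda(X[:, rest], y)
                f = _partial_f(lam_rest, lam_current, n, g, len(rest))
                if f < worst_f:
                    worst_f, worst_pos = f, pos
            if worst_pos is not None and worst_f < f_remove:
                selected.pop(worst_pos)
                lam_current = wilks_lambda(X[:, selected], y)
                changed = True
    return selected, lam_path


def _canonical(
    X: np.ndarray, y: np.ndarray, names: list[str], groups: list[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Canonical components from the between/within generalized eigenproblem."""
    W, T = _scatter(X, y)
    B = T - W
    n_comp = len(groups) - 1
    try:
        w, v = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise CollinearityError(
            f"singular pooled covariance for variables {names}"
        ) from exc
    order = np.argsort(w)[::-1][:n_comp]
    loadings = v[:, order]
    # sign convention: largest-magnitude loading positive
    for c in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[k, c] < 0:
            loadings[:, c] = -loadings[:, c]
    frame = pd.DataFrame(
        loadings,
        index=names,
        columns=[f"can_{i + 1}" for i in range(loadings.shape[1])],
    )
    scores = (X - X.mean(axis=0)) @ loadings
    return frame, scores


def _fit_lda(X: np.ndarray, y: np.ndarray, groups: list[str]) -> LinearDiscriminantAnalysis:
    priors = np.full(len(groups), 1.0 / len(groups))
    clf = LinearDiscriminantAnalysis(priors=priors)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            clf.fit(X, y)
        except UserWarning as exc:  # "Variables are collinear"
            raise CollinearityError(str(exc)) from exc
    return clf


def _confusion(
    y_true: np.ndarray, y_pred: np.ndarray, groups: list[str]
) -> tuple[pd.DataFrame, float]:
    mat = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    acc = 100.0 * float(np.mean(y_true == y_pred))
    return mat, acc


def stepwise_da(
    features: pd.DataFrame,
    groups: pd.Series | np.ndarray | str = "group",
    f_enter: float = 3.84,
    f_remove: float = 2.71,
) -> DAResult:
    """Stepwise linear discriminant analysis of a feature table.

    ``features`` is a numeric table (one row per specimen); ``groups`` is a
    label per row, or the name of a column of ``features`` holding the
    labels.  Returns the selection path, canonical components and scores,
    resubstitution and leave-one-out confusion matrices and accuracies.  If
    no variable reaches ``f_enter`` an explicit empty-model result is
    returned rather than an exception.
    """
    if isinstance(groups, str):
        if groups not in features.columns:
            raise ConfigurationError(f"no group column {groups!r} in the table")
        y = features[groups].to_numpy()
        X_frame = features.drop(columns=[groups])
    else:
        y = np.asarray(groups)
        X_frame = features
    X_frame = X_frame.select_dtypes(include=[np.number])
    names = list(X_frame.columns)
    X = X_frame.to_numpy(dtype=float)
    group_names = sorted(set(map(str, y)))
    y = np.asarray([str(v) for v in y])
    if len(group_names) < 2:
        raise ConfigurationError("need at least 2 groups")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ConfigurationError(
            f"every group needs >= 2 samples; got {counts.to_dict()}"
        )

    sel_idx, lam_path = _select_variables(X, y, names, f_enter, f_remove)
    if not sel_idx:
        return DAResult(
            selected=[],
            wilks_path=[],
            canonical_loadings=None,
            scores=None,
            confusion=None,
            accuracy=None,
            loocv_confusion=None,
            loocv_accuracy=None,
            groups=group_names,
            empty=True,
        )
    sel_names = [names[i] for i in sel_idx]
    Xs = X[:, sel_idx]

    loadings, score_vals = _canonical(Xs, y, sel_names, group_names)
    scores = pd.DataFrame(score_vals, index=features.index, columns=loadings.columns)
    scores.insert(0, "group", y)

    clf = _fit_lda(Xs, y, group_names)
    pred = clf.predict(Xs)
    confusion, accuracy = _confusion(y, pred, group_names)

    cv_conf, cv_acc = loocv(X_frame, y, sel_names)

    return DAResult(
        selected=sel_names,
        wilks_path=lam_path,
        canonical_loadings=loadings,
        scores=scores,
        confusion=confusion,
        accuracy=accuracy,
        loocv_confusion=cv_conf,
        loocv_accuracy=cv_acc,
        groups=group_names,
    )


def loocv(
    features: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    selected: list[str],
) -> tuple[pd.DataFrame, float]:
    """Leave-one-out cross-validation with a fixed variable set.

    For each specimen the classifier is refitted on the other n−1 and the
    held-out specimen classified; folds that would leave a group with fewer
    than 2 training samples are skipped with a warning.
    """
    y = np.asarray([str(v) for v in np.asarray(groups)])
    group_names = sorted(set(y))
    X = features[selected].to_numpy(dtype=float)
    n = len(y)
    preds: list[str] = []
    truths: list[str] = []
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        counts = pd.Series(y_train).value_counts()
        if counts.min() < 2 or len(counts) < len(group_names):
            skipped += 1
            continue
        clf = _fit_lda(X[mask], y_train, group_names)
        preds.append(str(clf.predict(X[i][None, :])[0]))
        truths.append(y[i])
    if skipped:
        warnings.warn(
            f"LOOCV skipped {skipped} fold(s) that would leave a group with "
            f"fewer than 2 training samples",
            stacklevel=2,
        )
    conf, acc = _confusion(np.asarray(truths), np.asarray(preds), group_names)
    return conf, acc
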