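"""Multivariate discrimination: PCA and from-scratch NIPALS PLS-DA.

The class label is coded 0/1 and modelled with single-response PLS (PLS1):
per component the weight vector is X'y normalized to unit length, scores
t = Xw, and X is deflated by its rank-one reconstruction. Cross-validation
uses the venetian-blind scheme (fold = sample index modulo the fold count
after a seeded rotation per repeat). Two cross-validated summaries are
reported: ``q2`` — the averaged Pearson correlation between the label and
out-of-fold predictions — and ``q2_press`` — the usual 1 - PRESS/TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class PcaModel:
    scores: np.ndarray
    loadings: np.ndarray  # features x k, orthonormal columns
    explained_variance_fraction: np.ndarray
    center: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) @ self.loadings


def fit_pca(X: np.ndarray, k: int) -> PcaModel:
    """Truncated SVD of the column-centered matrix.

    Component signs are fixed so each loading's largest-magnitude entry is
    positive, making the decomposition deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("fit_pca expects a 2-d matrix")
    n, p = X.shape
    max_k = min(n - 1 if n > 1 else 1, p)
    if not 1 <= k <= max_k:
        raise ValidationError(f"k must lie in [1, {max_k}] for a {n}x{p} matrix")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    # sign convention
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    evf = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PcaModel(scores=scores, loadings=loadings, explained_variance_fraction=evf, center=center)


@dataclass
class PlsdaModel:
    n_components: int
    x_weights: np.ndarray  # features x k, unit columns
    x_loadings: np.ndarray  # features x k
    y_loadings: np.ndarray  # k
    scores: np.ndarray  # samples x k
    x_center: np.ndarray
    y_center: float
    coef: np.ndarray  # regression vector on centered X
    class_coding: dict = field(default_factory=lambda: {"normo": 0, "malb": 1})
    q2: float | None = None
    rmscv: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous 0/1-scale prediction for new samples."""
        Xc = np.asarray(X, dtype=float) - self.x_center
        return Xc @ self.coef + self.y_center

    def classify(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict(X) >= threshold).astype(int)


def fit_plsda(X: np.ndarray, y: np.ndarray, k: int) -> PlsdaModel:
    """NIPALS PLS1 on centered X and a centered 0/1 class code."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or len(y) != X.shape[0]:
        raise ValidationError("X must be samples x features and y a matching label vector")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("both classes must be present to fit PLS-DA")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if not 1 <= k <= rank:
        raise ValidationError(f"k must lie in [1, rank(X)={rank}]")
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    E = X - x_center
    f = y - y_center
    n, p = E.shape
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    T = np.zeros((n, k))
    q = np.zeros(k)
    for a in range(k):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValidationError(f"component {a + 1}: no residual covariance with the label")
        w /= norm
        t = E @ w
        tt = float(t @ t)
        p_a = E.T @ t / tt
        q_a = float(f @ t / tt)
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    # regression vector: b = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PlsdaModel(
        n_components=k,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        x_center=x_center,
        y_center=y_center,
        coef=coef,
    )


@dataclass(frozen=True)
class CvPlan:
    """Venetian-blind cross-validation layout."""

    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValidationError("need at least 2 folds")
        if self.n_repeats < 1:
            raise ValidationError("need at least 1 repeat")

    def folds(self, n: int, rotation: int = 0) -> list[np.ndarray]:
        """Partition indices: fold f holds samples with (i + rotation) % n_folds == f."""
        if n < self.n_folds:
            raise ValidationError(f"{n} samples cannot fill {self.n_folds} folds")
        assignment = (np.arange(n) + rotation) % self.n_folds
        return [np.where(assignment == f)[0] for f in range(self.n_folds)]


@dataclass
class CvResult:
    q2: float
    rmscv: float
    q2_press: float
    per_repeat_q2: np.ndarray
    per_repeat_rmscv: np.ndarray
    per_repeat_q2_press: np.ndarray


def cross_validate(X: np.ndarray, y: np.ndarray, plan: CvPlan, k: int) -> CvResult:
    """Venetian-blind cross-validated Q2 / RMSCV of a k-component PLS-DA.

    Each repeat rotates the blind assignment by a seeded offset, refits on
    the training remainder of every fold and predicts the held-out tenth.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(plan.seed)
    rotations = rng.integers(0, plan.n_folds, size=plan.n_repeats)
    q2s, rmses, press_q2s = [], [], []
    tss = float(np.sum((y - y.mean()) ** 2))
    for rep in range(plan.n_repeats):
        y_pred = np.empty(n)
        for test_idx in plan.folds(n, rotation=int(rotations[rep])):
            train = np.ones(n, dtype=bool)
            train[test_idx] = False
            model = fit_plsda(X[train], y[train], k)
            y_pred[test_idx] = model.predict(X[test_idx])
        if np.std(y_pred) < 1e-12 or np.std(y) < 1e-12:
            q2s.append(0.0)
        else:
            q2s.append(float(np.corrcoef(y, y_pred)[0, 1]))
        press = float(np.sum((y - y_pred) ** 2))
        rmses.append(np.sqrt(press / n))
        press_q2s.append(1.0 - press / tss if tss > 0 else float("nan"))
    return CvResult(
        q2=float(np.mean(q2s)),
        rmscv=float(np.mean(rmses)),
        q2_press=float(np.mean(press_q2s)),
        per_repeat_q2=np.array(q2s),
        per_repeat_rmscv=np.array(rmses),
        per_repeat_q2_press=np.array(press_q2s),
    )


def select_components(
    X: np.ndarray, y: np.ndarray, plan: CvPlan, k_max: int = 5
) -> tuple[int, dict[int, CvResult]]:
    """Pick the component count maximizing cross-validated Q2 over 1..k_max."""
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    results = {}
    for k in range(1, min(k_max, rank) + 1):
        results[k] = cross_validate(X, y, plan, k)
    best = max(results, key=lambda k: results[k].q2)
    return best, results


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection; mean square over features is 1."""
    W = model.x_weights
    T = model.scores
    q = model.y_loadings
    p, k = W.shape
    ssy = (q**2) * np.einsum("ij,ij->j", T, T)  # explained y-variance per component
    total = float(ssy.sum())
    if total <= 0:
        raise ValidationError("model explains no label variance; VIP undefined")
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / total)


def rank_features(model: PlsdaModel, feature_names: list[str] | None = None):
    """Features ordered by decreasing VIP score."""
    import pandas as pd

    vip = vip_scores(model)
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(len(vip))]
    out = pd.DataFrame({"feature": names, "vip": vip})
    return out.sort_values("vip", ascending=False, kind="stable").reset_index(drop=True)
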