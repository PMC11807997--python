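"""Projection-to-latent-structures models for discriminant analysis.

Implements, from first principles on top of numpy:

* autoscaling (optional log10 transform, mean-centring, unit-variance
  scaling) with recoverable parameters,
* PLS-DA via NIPALS with deflation and a centred one-hot response,
* OPLS-DA: orthogonal-signal filtering followed by a single predictive
  component, the form whose per-feature VIP is computed on that predictive
  component alone,
* stratified k-fold cross-validated Q2,
* the label-permutation test that builds empirical nulls for R2Y and Q2.

Conventions: samples are rows and features are columns throughout this
module; the binary response is the centred 0/1 group indicator, and the
predictive score sign is chosen so the case (later disease stage) group has
a positive mean score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

LOG_OFFSET = 1e-9


@dataclass
class ScaledMatrix:
    """Autoscaled samples x features matrix with invertible parameters."""

    values: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    log_applied: bool
    constant_features: np.ndarray  # boolean flag per feature
    feature_ids: list[str] | None = None
    sample_ids: list[str] | None = None

    def apply_to(self, raw: np.ndarray) -> np.ndarray:
        """Scale new raw data with the stored (training) parameters."""
        x = np.asarray(raw, dtype=float)
        if self.log_applied:
            x = np.log10(x + LOG_OFFSET)
        return (x - self.center) / self.scale

    def inverse(self) -> np.ndarray:
        """Recover the (possibly log-transformed) input values."""
        return self.values * self.scale + self.center


def autoscale(matrix, log_transform: bool = True) -> ScaledMatrix:
    """Mean-centre and unit-variance scale a complete samples x features
    matrix, optionally after a log10(x + 1e-9) transform.

    Scaling uses the sample (n-1) standard deviation. Constant features are
    centred to zero, flagged, and given scale 1 so they carry no weight
    downstream without poisoning the matrix with NaN.
    """
    if isinstance(matrix, pd.DataFrame):
        feature_ids = list(matrix.columns)
        sample_ids = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        feature_ids = sample_ids = None
        x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("autoscale requires a complete matrix (impute first)")
    if log_transform:
        x = np.log10(x + LOG_OFFSET)
    center = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    scale = np.where(constant, 1.0, sd)
    return ScaledMatrix(
        values=(x - center) / scale,
        center=center,
        scale=scale,
        log_applied=log_transform,
        constant_features=constant,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
    )


def encode_binary(y_labels, case_group: str | None = None) -> tuple[np.ndarray, dict]:
    """Centred 0/1 encoding of a two-class label vector.

    ``case_group`` (the class coded 1) defaults to the lexicographically
    later label; for staging comparisons pass the later disease stage.
    """
    labels = np.asarray(y_labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if case_group is None:
        case_group = classes[1]
    if case_group not in classes:
        raise ValueError(f"case_group {case_group!r} not among {classes}")
    raw = (labels == case_group).astype(float)
    encoding = {"case": case_group,
                "reference": [c for c in classes if c != case_group][0],
                "mean": float(raw.mean())}
    return raw - raw.mean(), encoding


@dataclass
class PLSModel:
    n_components: int
    scores: np.ndarray        # T, n x A
    weights: np.ndarray       # W, p x A, unit-norm columns
    x_loadings: np.ndarray    # P, p x A
    y_loadings: np.ndarray    # C, q x A
    r2x: np.ndarray           # cumulative per component
    r2y: np.ndarray
    class_encoding: dict


def _one_hot(y_labels) -> tuple[np.ndarray, dict]:
    labels = np.asarray(y_labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    Y = np.stack([(labels == c).astype(float) for c in classes], axis=1)
    means = Y.mean(axis=0)
    return Y - means, {"classes": classes, "means": means.tolist()}


def fit_plsda(X: ScaledMatrix, y_labels, n_components: int,
              max_iter: int = 500, tol: float = 1e-10) -> PLSModel:
    """PLS-DA by NIPALS with deflation on a centred one-hot response.

    R2X and R2Y are cumulative explained fractions of the scaled X and the
    centred response. Raises if ``n_components`` exceeds the rank of X.
    """
    Xc = X.values.copy()
    Y, encoding = _one_hot(y_labels)
    n, p = Xc.shape
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")
    ssx0 = float(np.sum(Xc ** 2))
    ssy0 = float(np.sum(Y ** 2))
    T = np.empty((n, n_components))
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    C = np.empty((Y.shape[1], n_components))
    r2x = np.empty(n_components)
    r2y = np.empty(n_components)
    Yc = Y.copy()
    for a in range(n_components):
        u = Yc[:, int(np.argmax(np.sum(Yc ** 2, axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xc.T @ u / (u @ u)
            w_new /= np.linalg.norm(w_new)
            t = Xc @ w_new
            c = Yc.T @ t / (t @ t)
            u_new = Yc @ c / (c @ c)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xc @ w
        p_a = Xc.T @ t / (t @ t)
        c = Yc.T @ t / (t @ t)
        Xc -= np.outer(t, p_a)
        Yc -= np.outer(t, c)
        T[:, a], W[:, a], P[:, a], C[:, a] = t, w, p_a, c
        r2x[a] = 1.0 - np.sum(Xc ** 2) / ssx0
        r2y[a] = 1.0 - np.sum(Yc ** 2) / ssy0
    return PLSModel(n_components, T, W, P, C, r2x, r2y, encoding)


@dataclass
class OPLSModel:
    """OPLS-DA decomposition: orthogonal components stripped first, then a
    single predictive component carrying all class-correlated variation."""

    t_pred: np.ndarray          # predictive scores, length n
    p_pred: np.ndarray          # predictive X-loadings, length p
    w_pred: np.ndarray          # predictive weights, unit norm, length p
    c_pred: float               # predictive Y-loading
    orthogonal: list[dict]      # each: {"t", "p", "w"}
    r2y: float
    r2x_pred: float
    r2x_ortho: float
    vip: np.ndarray
    class_encoding: dict
    q2: float | None = None
    feature_ids: list[str] | None = None

    @property
    def n_ortho(self) -> int:
        return len(self.orthogonal)

    def transform(self, x_scaled: np.ndarray) -> np.ndarray:
        """Predictive scores for new (already scaled) data after removing
        the fitted orthogonal components."""
        Xf = np.atleast_2d(np.asarray(x_scaled, dtype=float)).copy()
        for comp in self.orthogonal:
            t_o = Xf @ comp["w"]
            Xf -= np.outer(t_o, comp["p"])
        return Xf @ self.w_pred

    def predict(self, x_scaled: np.ndarray) -> np.ndarray:
        """Predicted centred response (add the training class mean to get a
        0/1-scale score)."""
        return self.transform(x_scaled) * self.c_pred


def fit_oplsda(X: ScaledMatrix, y_labels, n_ortho: int = 1,
               case_group: str | None = None) -> OPLSModel:
    """Fit OPLS-DA for a binary contrast.

    Algorithm: w = X'y/(y'y) normalised; for each orthogonal component,
    p = X't/(t't) with t = Xw, w_o = p - (w'p)w normalised, t_o = X w_o,
    p_o = X't_o/(t_o't_o), X <- X - t_o p_o'; the predictive component is
    then computed on the filtered matrix. R2Y = 1 - RSS/TSS of the centred
    response; VIP_j = sqrt(p) |w_j| / ||w|| on the predictive component, so
    mean(VIP^2) = 1 exactly.
    """
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    y, encoding = encode_binary(y_labels, case_group)
    if np.allclose(y, 0):
        raise ValueError("response is constant; need two classes")
    Xf = X.values.copy()
    ssx0 = float(np.sum(Xf ** 2))
    w = Xf.T @ y / (y @ y)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with the response")
    w /= nw
    orthogonal: list[dict] = []
    for _ in range(n_ortho):
        t = Xf @ w
        p_vec = Xf.T @ t / (t @ t)
        w_o = p_vec - (w @ p_vec) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            raise ValueError(
                f"cannot extract {n_ortho} orthogonal component(s); "
                "matrix rank exhausted"
            )
        w_o /= n_wo
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        orthogonal.append({"t": t_o, "p": p_o, "w": w_o})
    t_p = Xf @ w
    p_p = Xf.T @ t_p / (t_p @ t_p)
    c = float(y @ t_p / (t_p @ t_p))

    # sign convention: case group scores positive on the predictive axis
    if t_p[y > 0].mean() < 0:
        w, t_p, p_p, c = -w, -t_p, -p_p, -c
        for comp in orthogonal:  # orthogonal parts are sign-free; untouched
            pass

    rss = float(np.sum((y - t_p * c) ** 2))
    tss = float(np.sum(y ** 2))
    r2y = 1.0 - rss / tss
    r2x_pred = float(np.sum(np.outer(t_p, p_p) ** 2)) / ssx0
    r2x_ortho = sum(
        float(np.sum(np.outer(o["t"], o["p"]) ** 2)) for o in orthogonal
    ) / ssx0
    p_feat = X.values.shape[1]
    vip = np.sqrt(p_feat) * np.abs(w) / np.linalg.norm(w)
    return OPLSModel(
        t_pred=t_p, p_pred=p_p, w_pred=w, c_pred=c, orthogonal=orthogonal,
        r2y=r2y, r2x_pred=r2x_pred, r2x_ortho=r2x_ortho, vip=vip,
        class_encoding=encoding, feature_ids=X.feature_ids,
    )


def vip_scores(model: OPLSModel) -> np.ndarray:
    """Per-feature VIP on the single predictive component:
    VIP_j = sqrt(p) |w_j| / ||w||, hence mean(VIP^2) = 1."""
    return model.vip.copy()


def q2_cross_validate(raw_matrix, y_labels, n_ortho: int = 1, folds: int = 7,
                      seed: int = 0, log_transform: bool = True,
                      case_group: str | None = None) -> float:
    """Stratified k-fold cross-validated Q2 for the OPLS-DA contrast.

    Scaling parameters and the model are refit inside every training fold;
    held-out samples are scaled with the training parameters and predicted
    on the 0/1 scale via the training class mean. Q2 = 1 - PRESS / TSS with
    TSS the total sum of squares of the overall-centred 0/1 response.
    """
    if isinstance(raw_matrix, pd.DataFrame):
        raw = raw_matrix.to_numpy(dtype=float)
    else:
        raw = np.asarray(raw_matrix, dtype=float)
    labels = np.asarray(y_labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds; "
            "reduce the fold count"
        )
    y01_all, enc = encode_binary(labels, case_group)
    y01_all = y01_all + enc["mean"]  # back to 0/1
    press = 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(raw, labels):
        X_train = autoscale(raw[train_idx], log_transform)
        model = fit_oplsda(X_train, labels[train_idx], n_ortho,
                           case_group=enc["case"])
        x_test = X_train.apply_to(raw[test_idx])
        pred = model.predict(x_test) + model.class_encoding["mean"]
        press += float(np.sum((y01_all[test_idx] - pred) ** 2))
    tss = float(np.sum((y01_all - y01_all.mean()) ** 2))
    return 1.0 - press / tss


@dataclass
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    null_r2y: np.ndarray
    null_q2: np.ndarray
    p_r2: float
    p_q2: float
    n_perm: int
    seed: int


def permutation_test(raw_matrix, y_labels, n_ortho: int = 1,
                     n_perm: int = 200, seed: int = 0, folds: int = 7,
                     log_transform: bool = True,
                     case_group: str | None = None) -> PermutationResult:
    """Label-permutation null for R2Y and Q2 with full refits.

    Labels are permuted uniformly at random ``n_perm`` times; each
    permutation refits the whole model (including cross-validated Q2 with
    the same number of orthogonal components). Empirical p-values carry the
    +1 correction: p = (1 + #{null >= observed}) / (n_perm + 1), so the
    smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(raw_matrix, pd.DataFrame):
        raw = raw_matrix.to_numpy(dtype=float)
    else:
        raw = np.asarray(raw_matrix, dtype=float)
    labels = np.asarray(y_labels)
    X_full = autoscale(raw, log_transform)
    obs_model = fit_oplsda(X_full, labels, n_ortho, case_group=case_group)
    obs_q2 = q2_cross_validate(raw, labels, n_ortho, folds, seed,
                               log_transform, case_group)
    rng = np.random.default_rng(seed)
    null_r2 = np.empty(n_perm)
    null_q2 = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(labels))
        y_perm = labels[perm]
        m = fit_oplsda(X_full, y_perm, n_ortho, case_group=case_group)
        null_r2[b] = m.r2y
        null_q2[b] = q2_cross_validate(raw, y_perm, n_ortho, folds,
                                       int(rng.integers(2 ** 31)),
                                       log_transform, case_group)
    p_r2 = (1 + int(np.sum(null_r2 >= obs_model.r2y))) / (n_perm + 1)
    p_q2 = (1 + int(np.sum(null_q2 >= obs_q2))) / (n_perm + 1)
    return PermutationResult(
        observed_r2y=obs_model.r2y, observed_q2=obs_q2,
        null_r2y=null_r2, null_q2=null_q2,
        p_r2=p_r2, p_q2=p_q2, n_perm=n_perm, seed=seed,
    )
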