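"""Latent-variable discrimination models.

Three estimators, all scikit-learn compatible (``fit`` / ``predict`` /
``get_params``), all deterministic:

* :class:`PLSDAClassifier` — PLS regression against a class encoding
  (two-class: one +1/-1 column; multi-class: dummy matrix), fitted by NIPALS
  with deflation, class assignment by sign / column-of-maximum.
* :class:`MultilevelPLSDA` — PLS-DA on the *within-subject* part of a paired
  design: each sample is replaced by its deviation from its subject's mean,
  which removes between-subject variation and isolates the paired treatment
  effect.
* :class:`OPLSDAClassifier` — PLS-DA preceded by orthogonal signal
  correction: components of X-variation uncorrelated with the class encoding
  are estimated and removed before the predictive components are fitted.

Only column mean-centering is applied inside the fits (the bucket data are
already total-area normalized); unit-variance scaling is available as an
option but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .containers import FeatureMatrix, SampleMetadata

_TOL = 1e-10
_MAX_ITER = 500


# ---------------------------------------------------------------------------
# NIPALS core


@dataclass
class PLSFit:
    """Raw NIPALS PLS parameters (X and Y assumed centered by the caller)."""

    W: np.ndarray          # X-weights, (p, A)
    P: np.ndarray          # X-loadings, (p, A)
    Q: np.ndarray          # Y-loadings, (q, A)
    T: np.ndarray          # X-scores, (n, A)
    x_mean: np.ndarray
    y_mean: np.ndarray

    @property
    def coef(self) -> np.ndarray:
        """Regression form B so that Yhat = (X - x_mean) @ B + y_mean."""
        R = self.W @ np.linalg.inv(self.P.T @ self.W)
        return R @ self.Q.T

    @property
    def rotations(self) -> np.ndarray:
        """R with T = (X - x_mean) @ R."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)


def _sign_fix(w: np.ndarray) -> float:
    """Sign convention: the largest-magnitude element of w is positive."""
    i = int(np.argmax(np.abs(w)))
    return -1.0 if w[i] < 0 else 1.0


def nipals_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    center: bool = True,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> PLSFit:
    """Fit PLS by NIPALS with X- and Y-deflation.

    Score columns come out mutually orthogonal; weight-vector iteration runs
    to ``tol`` convergence (single-response Y converges in one step). Raises
    if a component fails to converge or exceeds the rank of X.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    x_mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    y_mean = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    Xc = X - x_mean
    Yc = Y - y_mean
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds rank(X)={rank}"
        )
    n, p = Xc.shape
    q = Yc.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    for a in range(n_components):
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))]
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = Xc.T @ u
            nw = np.linalg.norm(w_new)
            if nw == 0:
                raise ValueError(f"component {a + 1}: degenerate weight vector")
            w_new = w_new / nw
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
            t = Xc @ w
            tt = t @ t
            if tt == 0:
                raise ValueError(f"component {a + 1}: zero score vector")
            qv = Yc.T @ t / tt
            qq = qv @ qv
            if qq == 0:
                break  # Y fully explained; w converged
            u = Yc @ qv / qq
        else:
            raise ValueError(
                f"NIPALS did not converge for component {a + 1} "
                f"within {max_iter} iterations"
            )
        s = _sign_fix(w)
        w = s * w
        t = Xc @ w
        tt = t @ t
        p_load = Xc.T @ t / tt
        qv = Yc.T @ t / tt
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, qv, t
        Xc = Xc - np.outer(t, p_load)
        Yc = Yc - np.outer(t, qv)
    return PLSFit(W, P, Q, T, x_mean, y_mean)


# ---------------------------------------------------------------------------
# multilevel (paired) decomposition


@dataclass
class MultilevelSplit:
    """Within/between decomposition of a repeated-measures matrix:
    X = grand_mean + between(subject) + within, with the within rows of each
    subject summing to zero (for a B/AT pair they are +-d/2 where d is the
    paired difference)."""

    X_within: np.ndarray
    X_between: np.ndarray
    grand_mean: np.ndarray
    subject_order: list[str]
    sample_ids: list[str] = field(default_factory=list)


def within_between(
    X: np.ndarray, subjects: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Array-level within/between split; errors on single-sample subjects."""
    X = np.asarray(X, dtype=float)
    subjects = np.asarray(subjects, dtype=object)
    grand = X.mean(axis=0)
    order = list(dict.fromkeys(subjects))
    within = np.empty_like(X)
    between = np.empty((len(order), X.shape[1]))
    for k, subj in enumerate(order):
        idx = np.flatnonzero(subjects == subj)
        if idx.size < 2:
            raise ValueError(f"subject {subj!r} has a single sample")
        mu = X[idx].mean(axis=0)
        within[idx] = X[idx] - mu
        between[k] = mu - grand
    return within, between, grand, [str(s) for s in order]


def multilevel_decompose(fm: FeatureMatrix, md: SampleMetadata) -> MultilevelSplit:
    """Within/between split of a feature matrix using the metadata pairing."""
    subj = md.subjects
    subjects = np.asarray([subj[s] for s in fm.sample_ids], dtype=object)
    within, between, grand, order = within_between(fm.values, subjects)
    return MultilevelSplit(within, between, grand, order, list(fm.sample_ids))


# ---------------------------------------------------------------------------
# estimators


def _encode_labels(y: np.ndarray, class_order: list | None) -> tuple[list, np.ndarray]:
    classes = list(class_order) if class_order else sorted(set(map(str, y)))
    y = np.asarray([str(v) for v in y], dtype=object)
    unknown = sorted(set(y) - set(classes))
    if unknown:
        raise ValueError(f"labels not in class order: {unknown}")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if len(classes) == 2:
        enc = np.where(y == classes[0], 1.0, -1.0)[:, None]
    else:
        enc = np.zeros((len(y), len(classes)))
        for j, c in enumerate(classes):
            enc[y == c, j] = 1.0
    return classes, enc


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS discriminant analysis.

    Two classes are encoded as one +1/-1 column (+1 = first class of
    ``class_order``) and predicted by the sign of the regression output
    (boundary ties go to the first class); three or more classes use a dummy
    matrix and the class of the maximal predicted column.

    Parameters
    ----------
    n_components : int
        Number of predictive latent components.
    scale : bool
        If True, divide columns by their (ddof=1) standard deviation after
        centering. Off by default.
    class_order : list or None
        Explicit class ordering; defaults to sorted label order.
    """

    def __init__(self, n_components: int = 2, scale: bool = False,
                 class_order: list | None = None):
        self.n_components = n_components
        self.scale = scale
        self.class_order = class_order

    # encoding + NIPALS on (optionally scaled) X
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, Yenc = _encode_labels(np.asarray(y), self.class_order)
        self.x_std_ = (
            np.where((s := X.std(axis=0, ddof=1)) > 0, s, 1.0)
            if self.scale else np.ones(X.shape[1])
        )
        fit = nipals_pls(X / self.x_std_, Yenc, self.n_components)
        self.pls_ = fit
        self.x_mean_ = fit.x_mean * self.x_std_
        self.x_weights_ = fit.W
        self.x_loadings_ = fit.P
        self.y_loadings_ = fit.Q
        self.x_scores_ = fit.T
        self.coef_ = fit.coef
        self.n_features_in_ = X.shape[1]
        return self

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        return X

    def decision_function(self, X):
        X = self._check_X(X) / self.x_std_
        return (X - self.pls_.x_mean) @ self.pls_.coef + self.pls_.y_mean

    def transform(self, X):
        """Predictive scores for new samples."""
        X = self._check_X(X) / self.x_std_
        return (X - self.pls_.x_mean) @ self.pls_.rotations

    def predict(self, X):
        yhat = self.decision_function(X)
        if len(self.classes_) == 2:
            idx = np.where(yhat[:, 0] >= 0, 0, 1)
        else:
            idx = np.argmax(yhat, axis=1)
        return np.asarray([self.classes_[i] for i in idx], dtype=object)


class MultilevelPLSDA(PLSDAClassifier):
    """Multilevel (paired) PLS-DA: PLS-DA fitted on within-subject variation.

    ``fit``/``predict`` take a ``subjects`` vector; each subject must
    contribute at least two samples (here the B/AT pair), and a new subject's
    within-part is computed from its own samples, so prediction never uses
    training-set subject means.
    """

    requires_subjects = True

    def __init__(self, n_components: int = 2, scale: bool = False,
                 class_order: list | None = None):
        super().__init__(n_components, scale, class_order)

    def _resolve_order(self, y) -> list:
        if self.class_order:
            return list(self.class_order)
        labels = sorted(set(map(str, y)))
        # paired convention: baseline encoded +1
        return ["B", "AT"] if set(labels) == {"B", "AT"} else labels

    def fit(self, X, y, subjects=None):
        if subjects is None:
            raise ValueError("MultilevelPLSDA.fit requires subjects")
        X = np.asarray(X, dtype=float)
        within, between, grand, order = within_between(X, np.asarray(subjects))
        self.between_ = between          # diagnostics only
        self.grand_mean_ = grand
        self.subject_order_ = order
        resolved = self._resolve_order(y)
        fitted = PLSDAClassifier(
            self.n_components, self.scale, resolved
        ).fit(within, y)
        # adopt the inner fit's state
        self.__dict__.update(
            {k: v for k, v in fitted.__dict__.items() if k.endswith("_")}
        )
        return self

    def _within(self, X, subjects) -> np.ndarray:
        within, _, _, _ = within_between(self._check_X(X), np.asarray(subjects))
        return within

    def decision_function(self, X, subjects=None):
        if subjects is None:
            raise ValueError("MultilevelPLSDA requires subjects")
        return super().decision_function(self._within(X, subjects))

    def transform(self, X, subjects=None):
        if subjects is None:
            raise ValueError("MultilevelPLSDA requires subjects")
        return super().transform(self._within(X, subjects))

    def predict(self, X, subjects=None):
        yhat = self.decision_function(X, subjects)
        idx = (
            np.where(yhat[:, 0] >= 0, 0, 1)
            if len(self.classes_) == 2 else np.argmax(yhat, axis=1)
        )
        return np.asarray([self.classes_[i] for i in idx], dtype=object)


class OPLSDAClassifier(PLSDAClassifier):
    """OPLS-DA: orthogonal signal correction followed by PLS-DA.

    Each orthogonal component is built from the X-loading of a provisional
    PLS component with its projection onto the span of X'Y removed, so its
    scores are exactly uncorrelated with every class-encoding column; X is
    deflated by the component and the predictive PLS model is fitted on the
    filtered matrix. With ``n_orthogonal=0`` this reduces to plain PLS-DA.
    """

    def __init__(self, n_components: int = 2, n_orthogonal: int = 1,
                 scale: bool = False, class_order: list | None = None):
        super().__init__(n_components, scale, class_order)
        self.n_orthogonal = n_orthogonal

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, Yenc = _encode_labels(np.asarray(y), self.class_order)
        self.x_std_ = (
            np.where((s := X.std(axis=0, ddof=1)) > 0, s, 1.0)
            if self.scale else np.ones(X.shape[1])
        )
        Xs = X / self.x_std_
        x_mean = Xs.mean(axis=0)
        Xc = Xs - x_mean
        Yc = Yenc - Yenc.mean(axis=0)
        rank = np.linalg.matrix_rank(Xc)
        if self.n_orthogonal + self.n_components > rank:
            raise ValueError(
                f"{self.n_orthogonal} orthogonal + {self.n_components} "
                f"predictive components exceed rank(X)={rank}"
            )
        p = Xc.shape[1]
        W_o = np.zeros((p, self.n_orthogonal))
        P_o = np.zeros((p, self.n_orthogonal))
        T_o = np.zeros((Xc.shape[0], self.n_orthogonal))
        for a in range(self.n_orthogonal):
            # basis of the Y-correlated weight space of the current X
            C = Xc.T @ Yc
            U, sv, _ = np.linalg.svd(C, full_matrices=False)
            V = U[:, sv > sv.max() * 1e-12] if sv.size and sv.max() > 0 else U[:, :0]
            comp = nipals_pls(Xc, Yc, 1, center=False)
            p_load = comp.P[:, 0]
            w_o = p_load - V @ (V.T @ p_load)
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:
                raise ValueError(
                    f"no Y-orthogonal variation left for orthogonal "
                    f"component {a + 1}"
                )
            w_o = w_o / norm * _sign_fix(w_o)
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
        self.orth_weights_ = W_o
        self.orth_loadings_ = P_o
        self.orth_scores_ = T_o
        fit = nipals_pls(Xc + x_mean, Yenc, self.n_components)
        self.pls_ = fit
        self.x_mean_ = x_mean * self.x_std_
        self.x_weights_ = fit.W
        self.x_loadings_ = fit.P
        self.y_loadings_ = fit.Q
        self.x_scores_ = fit.T
        self.coef_ = fit.coef
        self.n_features_in_ = X.shape[1]
        return self

    def _filter(self, X) -> np.ndarray:
        """Remove the fitted orthogonal variation from new samples."""
        Xs = self._check_X(X) / self.x_std_
        Xc = Xs - (self.x_mean_ / self.x_std_)
        for a in range(self.n_orthogonal):
            t_o = Xc @ self.orth_weights_[:, a]
            Xc = Xc - np.outer(t_o, self.orth_loadings_[:, a])
        return Xc + (self.x_mean_ / self.x_std_)

    def decision_function(self, X):
        Xf = self._filter(X)
        return (Xf - self.pls_.x_mean) @ self.pls_.coef + self.pls_.y_mean

    def transform(self, X):
        Xf = self._filter(X)
        return (Xf - self.pls_.x_mean) @ self.pls_.rotations

    def orthogonal_scores(self, X) -> np.ndarray:
        Xs = self._check_X(X) / self.x_std_
        Xc = Xs - (self.x_mean_ / self.x_std_)
        out = np.zeros((Xc.shape[0], self.n_orthogonal))
        for a in range(self.n_orthogonal):
            t_o = Xc @ self.orth_weights_[:, a]
            out[:, a] = t_o
            Xc = Xc - np.outer(t_o, self.orth_loadings_[:, a])
        return out


# ---------------------------------------------------------------------------
# functional wrappers and serialization


def fit_pls(X, Y, n_components: int) -> PLSFit:
    """NIPALS PLS on raw (uncentered) X against an encoding matrix Y."""
    return nipals_pls(X, Y, n_components)


def fit_mpls_paired(
    fm: FeatureMatrix, md: SampleMetadata, n_components: int = 2
) -> MultilevelPLSDA:
    """Multilevel PLS-DA of the paired B/AT samples of a feature matrix."""
    groups = md.group_of(fm.sample_ids)
    keep = np.isin(groups, ["B", "AT"])
    ids = [s for s, k in zip(fm.sample_ids, keep) if k]
    sub = fm.subset(ids)
    subj = md.subjects
    subjects = np.asarray([subj[s] for s in ids], dtype=object)
    model = MultilevelPLSDA(n_components=n_components)
    model.fit(sub.values, md.group_of(ids), subjects=subjects)
    return model


def fit_oplsda(
    X, labels, n_predictive: int = 2, n_orthogonal: int = 1
) -> OPLSDAClassifier:
    return OPLSDAClassifier(
        n_components=n_predictive, n_orthogonal=n_orthogonal
    ).fit(X, labels)


def model_to_dict(model: PLSDAClassifier) -> dict:
    """JSON-serializable dump of a fitted model (arrays as nested lists)."""
    kind = type(model).__name__
    out = {"kind": kind, "params": model.get_params()}
    for key, val in model.__dict__.items():
        if not key.endswith("_") or key in ("pls_",):
            continue
        out[key] = val.tolist() if isinstance(val, np.ndarray) else val
    f = model.pls_
    out["pls"] = {
        k: getattr(f, k).tolist() for k in ("W", "P", "Q", "T", "x_mean", "y_mean")
    }
    return out


def model_from_dict(d: dict) -> PLSDAClassifier:
    cls = {
        "PLSDAClassifier": PLSDAClassifier,
        "MultilevelPLSDA": MultilevelPLSDA,
        "OPLSDAClassifier": OPLSDAClassifier,
    }[d["kind"]]
    model = cls(**d["params"])
    for key, val in d.items():
        if key in ("kind", "params", "pls"):
            continue
        model.__dict__[key] = (
            np.asarray(val) if isinstance(val, list) and key != "classes_" else val
        )
    p = d["pls"]
    model.pls_ = PLSFit(
        *(np.asarray(p[k]) for k in ("W", "P", "Q", "T", "x_mean", "y_mean"))
    )
    return model
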