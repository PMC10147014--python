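"""PLS-DA: PLS regression on dummy-coded classes with LDA on the predictions.

The classification problem is turned into a regression by dummy-coding class
membership: for two classes y is a 0/1 vector, for k > 2 classes Y is an
n × k indicator matrix with a single 1 per row.  NIPALS PLS (PLS2 for the
multiclass case, with response deflation) projects the autoscaled predictor
matrix X onto orthogonal latent variables through a weight matrix R chosen
so that successive score directions maximize covariance with the (deflated)
response:

    T = X R            (scores)
    Y_hat = T q + mean (regression of the response on the scores)

Linear discriminant analysis is then fitted on the predicted responses of
the training samples to produce the final class assignment; its discriminant
directions, pulled back to the original variables through R q, are the
canonical variates whose weights identify the discriminating analytes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "DummyResponse",
    "PLSModel",
    "CanonicalProjection",
    "encode_classes",
    "fit_pls",
    "predict_response",
    "fit_canonical_discriminant",
    "classify",
    "PLSDiscriminantAnalysis",
    "PLSDAResults",
    "PLSDAError",
]

_TIE_TOL = 1e-12


class PLSDAError(ValueError):
    pass


@dataclass(frozen=True)
class DummyResponse:
    """Dummy-coded class membership.

    ``Y`` has one indicator column per class in ``class_order``; with exactly
    two classes it collapses to a single 0/1 column (1 for the first class).
    """

    class_order: tuple[str, ...]
    Y: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.class_order)


def encode_classes(
    labels: Sequence[str], class_order: Sequence[str]
) -> DummyResponse:
    """Dummy-code ``labels`` following ``class_order``."""
    order = tuple(class_order)
    index = {c: j for j, c in enumerate(order)}
    unknown = [lab for lab in labels if lab not in index]
    if unknown:
        raise PLSDAError(f"label {unknown[0]!r} not in class_order {order}")
    n, k = len(labels), len(order)
    if k == 2:
        Y = np.array([[1.0] if lab == order[0] else [0.0] for lab in labels])
    else:
        Y = np.zeros((n, k))
        for i, lab in enumerate(labels):
            Y[i, index[lab]] = 1.0
    return DummyResponse(class_order=order, Y=Y)


def labels_to_indices(labels: Sequence[str], class_order: Sequence[str]) -> np.ndarray:
    index = {c: j for j, c in enumerate(class_order)}
    try:
        return np.array([index[lab] for lab in labels], dtype=int)
    except KeyError as exc:
        raise PLSDAError(f"label {exc.args[0]!r} not in class_order") from None


@dataclass
class PLSModel:
    """Fitted NIPALS PLS decomposition.

    ``R`` (variables × LV) maps the centered/scaled predictors to scores,
    ``T = X R``; ``q`` (LV × responses) regresses the response on the scores;
    ``P`` holds the predictor loadings used in deflation.  ``y_mean`` is the
    response intercept (training column means).
    """

    R: np.ndarray
    T: np.ndarray
    P: np.ndarray
    W: np.ndarray
    q: np.ndarray
    y_mean: np.ndarray
    n_lv: int

    @property
    def coef(self) -> np.ndarray:
        """variables × responses regression coefficients R q."""
        return self.R @ self.q


def fit_pls(X: np.ndarray, Y, n_lv: int, tol: float = 1e-10,
            max_iter: int = 500) -> PLSModel:
    """NIPALS PLS with response deflation (PLS1/PLS2).

    ``X`` must already be column-centered (autoscaled upstream); the response
    is centered internally and its column means stored as the intercept.
    Extraction stops early if the residual predictor-response covariance
    vanishes (e.g. Y orthogonal to X), in which case fewer than ``n_lv``
    components are returned.
    """
    X = np.asarray(X, dtype=float)
    Yarr = Y.Y if isinstance(Y, DummyResponse) else np.asarray(Y, dtype=float)
    if Yarr.ndim == 1:
        Yarr = Yarr[:, None]
    n, p = X.shape
    if Yarr.shape[0] != n:
        raise PLSDAError("X and Y row mismatch")
    max_rank = min(n - 1, p)
    if not 1 <= n_lv <= max_rank:
        raise PLSDAError(f"n_lv must be in [1, {max_rank}] for this matrix")

    y_mean = Yarr.mean(axis=0)
    E = X.copy()
    F = Yarr - y_mean
    Ws, Ts, Ps, Qs = [], [], [], []
    for _ in range(n_lv):
        # The NIPALS inner iteration is a power method converging to the
        # dominant left singular vector of the cross-covariance E'F; with a
        # handful of response columns that vector is computed directly,
        # which is exact where power iteration can stall on near-degenerate
        # covariance directions.
        M = E.T @ F                       # p × n_responses
        if np.linalg.norm(M) < tol:
            break
        if M.shape[1] == 1:
            w = M[:, 0]
        else:
            U, _, _ = np.linalg.svd(M, full_matrices=False)
            w = U[:, 0]
        w = w / np.linalg.norm(w)
        if w[np.argmax(np.abs(w))] < 0:   # deterministic sign
            w = -w
        t = E @ w
        tt = t @ t
        if tt < tol:
            break
        c = F.T @ t / tt
        p_load = E.T @ t / tt
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, c)
        Ws.append(w)
        Ts.append(t)
        Ps.append(p_load)
        Qs.append(c)

    if not Ws:
        # degenerate: no covariance between X and Y; constant-mean model
        R = np.zeros((p, 1))
        return PLSModel(R=R, T=np.zeros((n, 1)), P=np.zeros((p, 1)),
                        W=np.zeros((p, 1)), q=np.zeros((1, Yarr.shape[1])),
                        y_mean=y_mean, n_lv=0)

    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.vstack(Qs)  # (n_lv, n_responses)
    # R maps the *original* (undeflated) X to the scores: T = X R
    R = W @ np.linalg.inv(P.T @ W)
    T = X @ R
    return PLSModel(R=R, T=T, P=P, W=W, q=q, y_mean=y_mean, n_lv=W.shape[1])


def truncate_pls(model: PLSModel, n_lv: int) -> PLSModel:
    """Sub-model using only the first ``n_lv`` latent variables.

    NIPALS components are nested, so truncation reproduces the model that a
    fresh fit at the smaller complexity would give.
    """
    if n_lv >= model.n_lv:
        return model
    if n_lv < 1:
        raise PLSDAError("n_lv must be >= 1")
    W = model.W[:, :n_lv]
    P = model.P[:, :n_lv]
    R = W @ np.linalg.inv(P.T @ W)
    return PLSModel(R=R, T=model.T[:, :n_lv], P=P, W=W, q=model.q[:n_lv],
                    y_mean=model.y_mean, n_lv=n_lv)


def predict_response(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted responses ``X_new R q + intercept`` (raw regression outputs;
    multiclass rows need not sum to 1)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.R.shape[0]:
        raise PLSDAError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.R.shape[0]}"
        )
    return model.y_mean + X_new @ model.R @ model.q


@dataclass
class CanonicalProjection:
    """LDA fitted on training predicted responses.

    Multiclass dummy predictions vary only inside a (k−1)-dimensional plane
    of the response space, so the discriminant is fitted in the
    rank-revealing subspace of the training predictions (``_basis``); the
    pooled covariance there is generically nonsingular.  ``directions`` are
    the discriminant directions expressed back in predicted-response space
    (d × n_cv); ``cv_weights`` are those directions pulled back to the
    original variables through the PLS coefficients (variables × n_cv),
    unit-norm with the largest-magnitude entry positive.
    """

    class_order: tuple[str, ...]
    class_means: np.ndarray          # k × d, in predicted-response space
    priors: np.ndarray
    directions: np.ndarray           # d × n_cv
    cv_weights: np.ndarray | None    # p × n_cv
    class_centers_cv: np.ndarray     # k × n_cv
    ridged: bool
    _grand: np.ndarray               # reference point in response space
    _basis: np.ndarray               # d × d' subspace of prediction variation
    _means_z: np.ndarray             # k × d'
    _icov_z: np.ndarray              # d' × d'
    pooled_cov: np.ndarray           # d' × d' (possibly ridge-regularized)

    @property
    def n_cv(self) -> int:
        return self.directions.shape[1]

    def cv_scores(self, predicted: np.ndarray) -> np.ndarray:
        predicted = np.atleast_2d(predicted)
        return (predicted - self._grand) @ self.directions

    def discriminant_scores(self, predicted: np.ndarray) -> np.ndarray:
        predicted = np.atleast_2d(predicted)
        Z = (predicted - self._grand) @ self._basis
        a = self._icov_z @ self._means_z.T                    # d' × k
        b = -0.5 * np.einsum("kd,dk->k", self._means_z, a) \
            + np.log(self.priors)
        return Z @ a + b


def _first_argmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise argmax with near-ties resolved to the lowest index
    (class_order precedence)."""
    mx = scores.max(axis=1, keepdims=True)
    near = scores >= mx - _TIE_TOL * (1.0 + np.abs(mx))
    return near.argmax(axis=1)


def fit_canonical_discriminant(
    predicted: np.ndarray,
    labels: Sequence[str],
    class_order: Sequence[str],
    priors: str = "frequency",
    pls_coef: np.ndarray | None = None,
    ridge: float = 1e-8,
) -> CanonicalProjection:
    """Fit LDA (pooled within-class covariance) on predicted responses.

    ``priors`` is ``"frequency"`` (proportional to training class counts,
    the default) or ``"equal"``.  A singular pooled covariance is ridge
    regularized with a warning.  If ``pls_coef`` (variables × responses,
    i.e. R q) is given, canonical-variate weights in the original variable
    space are computed and sign/norm normalized.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    order = tuple(class_order)
    k = len(order)
    if k < 2:
        raise PLSDAError("need >= 2 classes")
    idx = labels_to_indices(labels, order)
    n, d = predicted.shape
    counts = np.bincount(idx, minlength=k)
    if np.any(counts < 2):
        raise PLSDAError("need >= 2 samples per class for LDA")
    pri = counts / n if priors == "frequency" else np.full(k, 1.0 / k)

    # restrict to the subspace the predictions actually span
    grand = predicted.mean(axis=0)
    Zc = predicted - grand
    _, S, Vt = np.linalg.svd(Zc, full_matrices=False)
    tol = max(n, d) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    keep = S > tol
    if not keep.any():
        # all predictions identical: classification falls back to priors
        keep = np.zeros(len(S), dtype=bool)
        keep[0] = True
    basis = Vt[keep].T                                   # d × d'
    Z = Zc @ basis
    dz = Z.shape[1]

    means_z = np.vstack([Z[idx == j].mean(axis=0) for j in range(k)])
    Sw = np.zeros((dz, dz))
    for j in range(k):
        W = Z[idx == j] - means_z[j]
        Sw += W.T @ W
    Sw /= n - k

    eigmin = np.linalg.eigvalsh(Sw).min() if dz else 0.0
    scale = np.trace(Sw) / max(dz, 1)
    ridged = False
    if eigmin <= ridge * max(scale, 1.0):
        warnings.warn(
            "singular within-class scatter; ridge-regularizing LDA",
            stacklevel=2,
        )
        Sw = Sw + ridge * max(scale, 1.0) * np.eye(dz)
        ridged = True
    icov_z = np.linalg.inv(Sw)

    grand_z = pri @ means_z
    Sb = np.zeros((dz, dz))
    for j in range(k):
        diff = means_z[j] - grand_z
        Sb += pri[j] * np.outer(diff, diff)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    n_cv = min(k - 1, dz)
    order_ix = np.argsort(evals)[::-1][:n_cv]
    dirs_z = evecs[:, order_ix]
    directions = basis @ dirs_z                          # back to d-space
    # deterministic sign: largest-|.| entry of each direction positive
    for j in range(directions.shape[1]):
        col = directions[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            directions[:, j] = -col

    cv_weights = None
    if pls_coef is not None:
        cv_weights = np.asarray(pls_coef) @ directions
        for j in range(cv_weights.shape[1]):
            col = cv_weights[:, j]
            nrm = np.linalg.norm(col)
            if nrm > 0:
                col = col / nrm
            if col[np.argmax(np.abs(col))] < 0:
                col = -col
            cv_weights[:, j] = col

    class_means = grand + means_z @ basis.T
    centers_cv = (class_means - grand) @ directions
    return CanonicalProjection(
        class_order=order,
        class_means=class_means,
        priors=pri,
        directions=directions,
        cv_weights=cv_weights,
        class_centers_cv=centers_cv,
        ridged=ridged,
        _grand=grand,
        _basis=basis,
        _means_z=means_z,
        _icov_z=icov_z,
        pooled_cov=Sw,
    )


def classify(
    model: PLSModel, projection: CanonicalProjection, X_new: np.ndarray
) -> np.ndarray:
    """Assign each row of ``X_new`` (scaled space) to the class with the
    largest LDA discriminant score; ties go to the earliest class in
    ``class_order``."""
    predicted = predict_response(model, X_new)
    scores = projection.discriminant_scores(predicted)
    idx = _first_argmax(scores)
    return np.array([projection.class_order[j] for j in idx])


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------


class PLSDiscriminantAnalysis:
    """PLS-DA model bound to a data matrix and class labels.

    Parameters
    ----------
    X : array-like or DataFrame, samples × variables
        Concentration matrix.  Autoscaled internally by default (train-set
        mean/sd); pass ``scale=False`` if ``X`` is already scaled.
    labels : sequence of str
        Class label per sample.
    class_order : sequence of str, optional
        Dummy-coding order; defaults to order of first appearance.
    priors : "frequency" or "equal"
        LDA priors.
    """

    def __init__(self, X, labels, class_order=None, priors="frequency",
                 scale=True):
        self.var_names = list(getattr(X, "columns", range(np.shape(X)[1])))
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(list(labels))
        if class_order is None:
            class_order = list(dict.fromkeys(self.labels))
        self.class_order = tuple(class_order)
        self.priors = priors
        self.scale = scale
        if scale:
            from .preprocess import fit_scale_arrays, scale_matrix

            self._center, self._spread = fit_scale_arrays(self.X)
            self._Xs = scale_matrix(self.X, self._center, self._spread)
        else:
            self._center = np.zeros(self.X.shape[1])
            self._spread = np.ones(self.X.shape[1])
            self._Xs = self.X

    def fit(self, n_lv: int) -> "PLSDAResults":
        Y = encode_classes(self.labels, self.class_order)
        pls = fit_pls(self._Xs, Y, n_lv)
        fitted = predict_response(pls, self._Xs)
        projection = fit_canonical_discriminant(
            fitted, self.labels, self.class_order,
            priors=self.priors, pls_coef=pls.coef,
        )
        return PLSDAResults(self, pls, projection, fitted)


class PLSDAResults:
    """Fitted PLS-DA model: decomposition, canonical projection, prediction."""

    def __init__(self, model, pls: PLSModel, projection: CanonicalProjection,
                 fittedvalues: np.ndarray):
        self.model = model
        self.pls = pls
        self.projection = projection
        self.fittedvalues = fittedvalues
        self.n_lv = pls.n_lv

    # decomposition accessors (training data)
    @property
    def weights(self) -> np.ndarray:
        return self.pls.R

    @property
    def scores(self) -> np.ndarray:
        return self.pls.T

    @property
    def loadings(self) -> np.ndarray:
        return self.pls.P

    @property
    def coef(self) -> np.ndarray:
        return self.pls.coef

    @property
    def cv_weights(self) -> np.ndarray:
        return self.projection.cv_weights

    @property
    def cv_weights_raw(self) -> np.ndarray:
        """Canonical-variate weights without unit-norm/sign normalization,
        sign-consistent with ``cv_scores`` and ``class_centers_cv`` (an
        analyte elevated in a class points toward that class's side)."""
        return self.pls.coef @ self.projection.directions

    def _scale(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return (X_new - self.model._center) / self.model._spread

    def predict_response(self, X_new) -> np.ndarray:
        return predict_response(self.pls, self._scale(X_new))

    def classify(self, X_new) -> np.ndarray:
        return classify(self.pls, self.projection, self._scale(X_new))

    def cv_scores(self, X_new=None) -> np.ndarray:
        pred = self.fittedvalues if X_new is None else self.predict_response(X_new)
        return self.projection.cv_scores(pred)

    def training_accuracy(self) -> float:
        pred = classify(self.pls, self.projection, self.model._Xs)
        return float(np.mean(pred == self.model.labels))

    def summary(self) -> str:
        k = len(self.model.class_order)
        lines = [
            "PLS-DA fit",
            "==========",
            f"classes:          {', '.join(self.model.class_order)}",
            f"samples:          {self.model.X.shape[0]}",
            f"variables:        {self.model.X.shape[1]}",
            f"latent variables: {self.n_lv}",
            f"canonical variates: {k - 1}",
            f"training accuracy: {100 * self.training_accuracy():.1f}%",
        ]
        return "\n".join(lines)
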