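"""SIMCA class modeling: one PCA model per category, membership by distance.

Each class is modeled by a PCA fitted only on that class's (autoscaled)
training rows.  A sample's conformity with the class is summarized by two
statistics: T², the Mahalanobis distance of its projection from the center
of the PCA score space, and Q, the squared orthogonal residual of the sample
to the PCA subspace.  Both are normalized ("reduced") by their respective
95th percentiles on the class training data and combined into a single
distance to the model

    d = sqrt( (T² / T²₉₅)² + (Q / Q₉₅)² )

A sample is accepted by the class model iff d < 2 (strict); sensitivity is
the acceptance rate of true class members, specificity the rejection rate of
members of other classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import fit_scale_arrays, scale_matrix
from .validation import (
    DCVConfig,
    ValidationError,
    _stratified_folds,
    select_complexity,
)
from .plsda import labels_to_indices

__all__ = [
    "SIMCAClassModel",
    "SIMCAReport",
    "fit_simca",
    "distance_to_model",
    "reduced_statistics",
    "accept",
    "simca_evaluate",
    "select_components_cv",
    "simca_dcv",
    "SIMCADCVResult",
    "SIMCA",
    "SIMCAResults",
    "SIMCAError",
]

DEFAULT_THRESHOLD = 2.0
_EPS = 1e-12


class SIMCAError(ValueError):
    pass


@dataclass
class SIMCAClassModel:
    """One-class PCA model with 95th-percentile distance normalizers."""

    class_name: str
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray       # p × A, orthonormal columns
    score_var: np.ndarray      # (A,) training score variances (n-1)
    n_components: int
    t2_p95: float
    q_p95: float
    train_t2: np.ndarray = field(repr=False, default=None)
    train_q: np.ndarray = field(repr=False, default=None)


def _statistics(Xs: np.ndarray, loadings: np.ndarray,
                score_var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = Xs @ loadings
    t2 = np.sum(scores**2 / score_var, axis=1)
    resid = Xs - scores @ loadings.T
    q = np.sum(resid**2, axis=1)
    return t2, q


def fit_simca(class_rows, n_components: int,
              class_name: str = "", scale: bool = True) -> SIMCAClassModel:
    """Fit a one-class PCA model on ``class_rows`` (samples of one class).

    Rows are autoscaled with the class's own mean/sd (classical SIMCA);
    T² uses the training score variances (Mahalanobis in score space),
    Q is the squared orthogonal residual norm.
    """
    X = np.asarray(class_rows, dtype=float)
    n, p = X.shape
    if n < n_components + 2:
        raise SIMCAError(
            f"need >= n_components + 2 rows ({n_components + 2}), got {n}"
        )
    if scale:
        center, spread = fit_scale_arrays(X)
    else:
        center, spread = X.mean(axis=0), np.ones(p)
    Xs = scale_matrix(X, center, spread)
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    rank = int(np.sum(S > max(n, p) * np.finfo(float).eps * S[0]))
    if n_components > rank:
        raise SIMCAError(
            f"n_components={n_components} exceeds effective rank {rank}"
        )
    loadings = Vt[:n_components].T
    score_var = S[:n_components] ** 2 / (n - 1)
    t2, q = _statistics(Xs, loadings, score_var)
    t2_p95 = float(np.percentile(t2, 95))
    q_p95 = float(np.percentile(q, 95))
    return SIMCAClassModel(
        class_name=class_name,
        center=center,
        scale=spread,
        loadings=loadings,
        score_var=score_var,
        n_components=n_components,
        t2_p95=t2_p95,
        q_p95=q_p95,
        train_t2=t2,
        train_q=q,
    )


def _reduce(stat: np.ndarray, p95: float) -> np.ndarray:
    if p95 > _EPS:
        return stat / p95
    # degenerate normalizer (e.g. data exactly in the PCA span): a vanishing
    # statistic is perfectly conforming, a non-vanishing one infinitely far
    return np.where(stat <= _EPS, 0.0, np.inf)


def reduced_statistics(model: SIMCAClassModel,
                       samples) -> tuple[np.ndarray, np.ndarray]:
    """Reduced (percentile-normalized) T² and Q of ``samples``."""
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[1] != len(model.center):
        raise SIMCAError(
            f"samples have {X.shape[1]} variables, model expects "
            f"{len(model.center)}"
        )
    Xs = scale_matrix(X, model.center, model.scale)
    t2, q = _statistics(Xs, model.loadings, model.score_var)
    return _reduce(t2, model.t2_p95), _reduce(q, model.q_p95)


def distance_to_model(model: SIMCAClassModel, samples) -> np.ndarray:
    """Combined distance d = sqrt(T²_red² + Q_red²)."""
    t2r, qr = reduced_statistics(model, samples)
    return np.hypot(t2r, qr)


def accept(model: SIMCAClassModel, samples,
           threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Accept iff d < threshold (strict inequality; d == threshold rejects)."""
    return distance_to_model(model, samples) < threshold


@dataclass
class SIMCAReport:
    """Sensitivity/specificity of a set of class models on labeled samples."""

    class_order: tuple[str, ...]
    sensitivity: dict[str, float]                  # percent
    specificity: dict[str, dict[str, float]]       # model -> other class -> %
    overall_specificity: dict[str, float]          # percent
    distances: pd.DataFrame                        # samples × models
    accepted: pd.DataFrame
    n_by_class: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "sensitivity_pct": dict(self.sensitivity),
            "specificity_pct": {c: dict(v) for c, v in self.specificity.items()},
            "overall_specificity_pct": dict(self.overall_specificity),
            "n_by_class": dict(self.n_by_class),
        }

    def summary(self) -> str:
        lines = ["SIMCA class models", "------------------"]
        for c in self.class_order:
            lines.append(
                f"{c}: sensitivity {self.sensitivity[c]:.1f} %, overall "
                f"specificity {self.overall_specificity[c]:.1f} %"
            )
            for other, sp in self.specificity[c].items():
                lines.append(f"    vs {other}: {sp:.1f} %")
        return "\n".join(lines)


def simca_evaluate(
    models: Mapping[str, SIMCAClassModel],
    samples,
    labels,
    threshold: float = DEFAULT_THRESHOLD,
) -> SIMCAReport:
    """Sensitivity and specificity of each class model on labeled rows.

    Sensitivity of model c: % of class-c rows accepted by model c.
    Specificity of model c vs c': % of class-c' rows rejected.  Overall
    specificity pools all non-c rows.
    """
    labels = np.asarray(list(labels))
    classes = tuple(models.keys())
    missing = set(labels) - set(classes)
    if missing:
        raise SIMCAError(f"no model for class(es) {sorted(missing)}")
    ids = getattr(samples, "index", pd.RangeIndex(np.shape(samples)[0]))
    X = np.asarray(samples, dtype=float)
    dist = pd.DataFrame(
        {c: distance_to_model(models[c], X) for c in classes}, index=ids
    )
    acc = dist < threshold
    sens, spec, overall, n_by = {}, {}, {}, {}
    for c in classes:
        own = labels == c
        n_by[c] = int(own.sum())
        sens[c] = 100.0 * float(acc.loc[own, c].mean()) if own.any() else np.nan
        spec[c] = {}
        rej_all, n_all = 0, 0
        for other in classes:
            if other == c:
                continue
            rows = labels == other
            if rows.any():
                rej = int((~acc.loc[rows, c]).sum())
                spec[c][other] = 100.0 * rej / rows.sum()
                rej_all += rej
                n_all += int(rows.sum())
        overall[c] = 100.0 * rej_all / n_all if n_all else np.nan
    return SIMCAReport(
        class_order=classes,
        sensitivity=sens,
        specificity=spec,
        overall_specificity=overall,
        distances=dist,
        accepted=acc,
        n_by_class=n_by,
    )


# ---------------------------------------------------------------------------
# Component selection / double cross-validation
# ---------------------------------------------------------------------------


def _balanced_score(model: SIMCAClassModel, Xval: np.ndarray,
                    own_mask: np.ndarray, threshold: float) -> float:
    """(sensitivity + specificity) / 2 on a validation split."""
    acc = accept(model, Xval, threshold)
    sens = acc[own_mask].mean() if own_mask.any() else 0.0
    spec = (~acc[~own_mask]).mean() if (~own_mask).any() else 0.0
    return 0.5 * (sens + spec)


def select_components_cv(
    X,
    labels,
    target_class: str,
    max_components: int = 12,
    n_folds: int = 5,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    rng: np.random.Generator | None = None,
) -> int:
    """Choose the PCA complexity of one class model by cross-validation,
    maximizing balanced sensitivity/specificity; ties go to the smallest
    number of components."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(list(labels))
    own = labels == target_class
    if own.sum() < 4:
        raise SIMCAError(f"too few samples of class {target_class!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    strat = labels_to_indices(labels, tuple(dict.fromkeys(labels)))
    folds = _stratified_folds(strat, n_folds, rng)
    cap = max_components
    score = np.zeros(cap)
    weight = np.zeros(cap)
    for f in range(n_folds):
        vmask = folds == f
        tr_own = np.nonzero(own & ~vmask)[0]
        val = np.nonzero(vmask)[0]
        if len(val) == 0 or len(tr_own) < 4:
            continue
        fold_cap = min(cap, len(tr_own) - 2, X.shape[1])
        last = 0.0
        for a in range(1, fold_cap + 1):
            m = fit_simca(X[tr_own], a, class_name=target_class)
            last = _balanced_score(m, X[val], own[val], threshold)
            score[a - 1] += last * len(val)
            weight[a - 1] += len(val)
        # complexities beyond this fold's cap behave like the cap
        for a in range(fold_cap + 1, cap + 1):
            score[a - 1] += last * len(val)
            weight[a - 1] += len(val)
    rates = 1.0 - score / np.maximum(weight, 1)  # turn into loss for argmin
    return select_complexity(rates)


@dataclass
class SIMCADCVResult:
    """Outer-loop SIMCA figures for one class model under repeated DCV."""

    class_name: str
    chosen_components: np.ndarray      # (reps, outer_folds)
    sensitivity: np.ndarray            # (reps,) percent
    specificity_vs: dict[str, np.ndarray]
    overall_specificity: np.ndarray
    reduced_table: pd.DataFrame        # pooled outer-loop (T2_red, Q_red, d)

    @property
    def complexity_mean(self) -> float:
        return float(self.chosen_components.mean())

    @property
    def complexity_sd(self) -> float:
        v = self.chosen_components.ravel()
        return float(np.std(v, ddof=1)) if v.size > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "class_name": self.class_name,
            "complexity_mean": self.complexity_mean,
            "complexity_sd": self.complexity_sd,
            "sensitivity_mean_pct": float(self.sensitivity.mean()),
            "sensitivity_sd_pct": float(np.std(self.sensitivity, ddof=1))
            if self.sensitivity.size > 1 else 0.0,
            "overall_specificity_mean_pct": float(
                self.overall_specificity.mean()
            ),
            "specificity_vs_mean_pct": {
                c: float(v.mean()) for c, v in self.specificity_vs.items()
            },
        }


def simca_dcv(
    X,
    labels,
    target_class: str,
    config: DCVConfig | None = None,
    max_components: int = 12,
    threshold: float = DEFAULT_THRESHOLD,
) -> SIMCADCVResult:
    """Repeated double cross-validation of one SIMCA class model.

    Outer folds are stratified over all samples; the inner loop selects the
    PCA complexity on the outer-training portion (balanced sensitivity/
    specificity); the model refitted on the outer-training rows of the target
    class scores the held-out fold.  Sensitivity/specificity are pooled per
    repetition over the outer folds.
    """
    if config is None:
        config = DCVConfig()
    ids = np.asarray(getattr(X, "index", np.arange(np.shape(X)[0])))
    X = np.asarray(X, dtype=float)
    labels = np.asarray(list(labels))
    classes = tuple(dict.fromkeys(labels))
    if target_class not in classes:
        raise SIMCAError(f"unknown target class {target_class!r}")
    idx = labels_to_indices(labels, classes)
    own = labels == target_class
    others = [c for c in classes if c != target_class]

    reps = config.n_repetitions
    chosen = np.empty((reps, config.outer_folds), dtype=int)
    sens = np.empty(reps)
    overall = np.empty(reps)
    spec_vs = {c: np.empty(reps) for c in others}
    rows = []
    streams = np.random.SeedSequence([config.seed, 0x51CA]).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        folds = _stratified_folds(idx, config.outer_folds, rng)
        accepted = np.zeros(len(labels), dtype=bool)
        for f in range(config.outer_folds):
            vmask = folds == f
            tr = ~vmask
            a = select_components_cv(
                X[tr], labels[tr], target_class,
                max_components=max_components,
                n_folds=config.inner_folds,
                threshold=threshold,
                rng=rng,
            )
            tr_own = np.nonzero(own & tr)[0]
            a = min(a, len(tr_own) - 2, X.shape[1])
            model = fit_simca(X[tr_own], a, class_name=target_class)
            chosen[r, f] = a
            te = np.nonzero(vmask)[0]
            t2r, qr = reduced_statistics(model, X[te])
            d = np.hypot(t2r, qr)
            accepted[te] = d < threshold
            if r == 0:
                for i, t2v, qv, dv in zip(te, t2r, qr, d):
                    rows.append((ids[i], labels[i], t2v, qv, dv, dv < threshold))
        sens[r] = 100.0 * accepted[own].mean()
        overall[r] = 100.0 * (~accepted[~own]).mean()
        for c in others:
            rows_c = labels == c
            spec_vs[c][r] = 100.0 * (~accepted[rows_c]).mean()
    table = pd.DataFrame(
        rows, columns=["sample_id", "class", "t2_red", "q_red", "d", "accepted"]
    ).set_index("sample_id")
    return SIMCADCVResult(
        class_name=target_class,
        chosen_components=chosen,
        sensitivity=sens,
        specificity_vs=spec_vs,
        overall_specificity=overall,
        reduced_table=table,
    )


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------


class SIMCA:
    """SIMCA multi-class model bound to a data matrix and labels."""

    def __init__(self, X, labels, class_order: Sequence[str] | None = None):
        self.ids = getattr(X, "index", pd.RangeIndex(np.shape(X)[0]))
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(list(labels))
        if class_order is None:
            class_order = list(dict.fromkeys(self.labels))
        self.class_order = tuple(class_order)

    def fit(self, n_components: int | Mapping[str, int] | str = "cv",
            max_components: int = 12, seed: int = 0) -> "SIMCAResults":
        """Fit one PCA model per class.

        ``n_components`` may be an int (same for all classes), a mapping
        class -> int, or ``"cv"`` to select per class by cross-validated
        balanced sensitivity/specificity.
        """
        models = {}
        for j, c in enumerate(self.class_order):
            rows = self.X[self.labels == c]
            if n_components == "cv":
                a = select_components_cv(
                    self.X, self.labels, c,
                    max_components=max_components, seed=seed + j,
                )
                a = min(a, rows.shape[0] - 2)
            elif isinstance(n_components, Mapping):
                a = n_components[c]
            else:
                a = int(n_components)
            models[c] = fit_simca(rows, a, class_name=c)
        return SIMCAResults(self, models)


class SIMCAResults:
    def __init__(self, model: SIMCA, class_models: dict[str, SIMCAClassModel]):
        self.model = model
        self.class_models = class_models

    def distances(self, X=None) -> pd.DataFrame:
        X = self.model.X if X is None else X
        return pd.DataFrame(
            {c: distance_to_model(m, X) for c, m in self.class_models.items()}
        )

    def evaluate(self, X=None, labels=None,
                 threshold: float = DEFAULT_THRESHOLD) -> SIMCAReport:
        if X is None:
            X, labels = self.model.X, self.model.labels
        return simca_evaluate(self.class_models, X, labels, threshold)

    def summary(self) -> str:
        rep = self.evaluate()
        comp = ", ".join(
            f"{c}: {m.n_components}" for c, m in self.class_models.items()
        )
        return rep.summary() + f"\ncomponents: {comp}"
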