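"""Repeated double cross-validation (DCV) and permutation testing.

DCV arranges the samples in two nested cross-validation loops.  The inner
loop, run on the training portion of each outer fold, selects the model
complexity (number of latent variables) minimizing the inner classification
error; a model refitted at that complexity on the whole outer-training set
then predicts the held-out outer fold, which therefore mimics an external
test set.  The whole procedure is repeated (50 times by default), reshuffling
the fold assignment each time, and the spread of the figures of merit over
repetitions quantifies their uncertainty.

All parameter estimation — scaling included — is confined to training rows,
so outer-fold predictions are free of information leakage.

Significance is assessed non-parametrically: class labels are permuted, the
full DCV is rerun per permutation (with a reduced repetition count for
tractability), and the p-value is the fraction of null draws at least as
good as the observed figure, with the +1 correction
p = (1 + #{null >= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import fit_scale_arrays, scale_matrix
from .plsda import (
    DummyResponse,
    PLSDAError,
    _first_argmax,
    fit_canonical_discriminant,
    fit_pls,
    labels_to_indices,
    predict_response,
    truncate_pls,
)

__all__ = [
    "DCVConfig",
    "DCVResult",
    "FiguresOfMerit",
    "PermutationTestResult",
    "run_dcv",
    "select_complexity",
    "permutation_test",
    "summarize_dcv",
    "ValidationError",
]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class DCVConfig:
    """Settings of the repeated double cross-validation."""

    n_repetitions: int = 50
    outer_folds: int = 7
    inner_folds: int = 5
    max_lv: int = 15
    stratified: bool = True
    seed: int = 0
    priors: str = "frequency"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValidationError("fold counts must be >= 2")
        if self.max_lv < 1:
            raise ValidationError("max_lv must be >= 1")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")


@dataclass
class DCVResult:
    """Per-repetition outer-loop predictions and chosen complexities."""

    class_order: tuple[str, ...]
    sample_ids: np.ndarray
    true_idx: np.ndarray               # (n,)
    predictions: np.ndarray            # (reps, n) predicted class indices
    fold_ids: np.ndarray               # (reps, n) outer-fold assignment
    chosen_lv: np.ndarray              # (reps, outer_folds)
    accuracies: np.ndarray             # (reps,) fractions in [0, 1]
    class_rates: np.ndarray            # (reps, k) fractions
    config: DCVConfig

    @property
    def n_repetitions(self) -> int:
        return self.predictions.shape[0]

    def confusion(self) -> np.ndarray:
        """Confusion counts pooled over repetitions (true × predicted)."""
        k = len(self.class_order)
        cm = np.zeros((k, k), dtype=int)
        for r in range(self.n_repetitions):
            np.add.at(cm, (self.true_idx, self.predictions[r]), 1)
        return cm

    def summary(self) -> str:
        return summarize_dcv(self).summary()


@dataclass
class FiguresOfMerit:
    """Accuracy / per-class rates / complexity as mean ± sd over repetitions,
    on the percent scale, plus the pooled confusion table."""

    class_order: tuple[str, ...]
    accuracy_mean: float
    accuracy_sd: float
    class_rate_mean: np.ndarray
    class_rate_sd: np.ndarray
    complexity_mean: float
    complexity_sd: float
    confusion: np.ndarray
    n_repetitions: int
    p_values: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "accuracy_mean_pct": self.accuracy_mean,
            "accuracy_sd_pct": self.accuracy_sd,
            "class_rate_mean_pct": {
                c: float(v) for c, v in zip(self.class_order, self.class_rate_mean)
            },
            "class_rate_sd_pct": {
                c: float(v) for c, v in zip(self.class_order, self.class_rate_sd)
            },
            "complexity_mean": self.complexity_mean,
            "complexity_sd": self.complexity_sd,
            "confusion": self.confusion.tolist(),
            "n_repetitions": self.n_repetitions,
            "p_values": dict(self.p_values),
        }

    def summary(self) -> str:
        lines = [
            "Double cross-validation figures of merit",
            "----------------------------------------",
            f"repetitions: {self.n_repetitions}",
            f"complexity:  {self.complexity_mean:.0f} ± "
            f"{self.complexity_sd:.0f} latent variables",
            f"accuracy:    {self.accuracy_mean:.1f} ± "
            f"{self.accuracy_sd:.1f} %",
        ]
        for c, m, s in zip(self.class_order, self.class_rate_mean,
                           self.class_rate_sd):
            lines.append(f"  {c}: {m:.1f} ± {s:.1f} %")
        for name, p in self.p_values.items():
            lines.append(f"p({name}) = {p:.4g}")
        return "\n".join(lines)


def select_complexity(errors: Sequence[float]) -> int:
    """Number of latent variables minimizing the inner-loop error.

    Candidates are understood as 1..len(errors); ties resolve to the
    smallest (most parsimonious) complexity.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValidationError("empty candidate list")
    return int(np.argmin(errors)) + 1


def _stratified_folds(idx: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Round-robin fold assignment after a per-class shuffle."""
    folds = np.empty(len(idx), dtype=int)
    start = int(rng.integers(n_folds))
    for j in np.unique(idx):
        members = np.nonzero(idx == j)[0]
        rng.shuffle(members)
        folds[members] = (start + np.arange(len(members))) % n_folds
    return folds


def _plain_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def _check_fold_feasibility(idx: np.ndarray, n_folds: int, k: int) -> None:
    counts = np.bincount(idx, minlength=k)
    for j, c in enumerate(counts):
        # every training fold must retain >= 2 members of each class
        if c - int(np.ceil(c / n_folds)) < 2:
            raise ValidationError(
                f"class index {j} has only {c} samples: a training fold would "
                f"keep fewer than 2; use fewer folds"
            )


class _FoldModel:
    """Scaler + full-complexity PLS fitted on one training fold; evaluates
    any truncated complexity on held-out rows without refitting."""

    def __init__(self, Xtr: np.ndarray, ytr: np.ndarray, class_order,
                 max_lv: int, priors: str):
        self.class_order = tuple(class_order)
        self.k = len(self.class_order)
        self.ytr = ytr
        self.center, self.spread = fit_scale_arrays(Xtr)
        Xs = scale_matrix(Xtr, self.center, self.spread)
        cap = min(max_lv, Xtr.shape[0] - 1, Xtr.shape[1])
        Y = _dummy_from_indices(ytr, self.k)
        self.pls_full = fit_pls(Xs, Y, cap)
        self.cap = max(self.pls_full.n_lv, 1)
        self.priors = priors
        self._proj_cache: dict[int, object] = {}

    def _labels(self) -> list[str]:
        return [self.class_order[j] for j in self.ytr]

    def _projection(self, a: int):
        if a not in self._proj_cache:
            sub = truncate_pls(self.pls_full, a)
            fitted = sub.y_mean + sub.T @ sub.q
            with warnings.catch_warnings():
                warnings.filterwarnings(
                    "ignore", message="singular within-class scatter.*"
                )
                proj = fit_canonical_discriminant(
                    fitted, self._labels(), self.class_order,
                    priors=self.priors,
                )
            self._proj_cache[a] = (sub, proj)
        return self._proj_cache[a]

    def predict_indices(self, Xnew: np.ndarray, a: int) -> np.ndarray:
        sub, proj = self._projection(a)
        Xs = scale_matrix(Xnew, self.center, self.spread)
        pred = predict_response(sub, Xs)
        return _first_argmax(proj.discriminant_scores(pred))


def _dummy_from_indices(idx: np.ndarray, k: int) -> DummyResponse:
    order = tuple(str(j) for j in range(k))
    n = len(idx)
    if k == 2:
        Y = (idx == 0).astype(float)[:, None]
    else:
        Y = np.zeros((n, k))
        Y[np.arange(n), idx] = 1.0
    return DummyResponse(class_order=order, Y=Y)


def run_dcv(X, labels, config: DCVConfig,
            class_order: Sequence[str] | None = None) -> DCVResult:
    """Repeated double cross-validation of the PLS-DA pipeline.

    ``X`` is the post-substitution, *unscaled* concentration matrix; scaling
    is refitted inside every training fold.  Returns per-repetition outer
    predictions, chosen complexities and figures of merit.
    """
    sample_ids = np.asarray(
        getattr(X, "index", np.arange(np.shape(X)[0]))
    )
    X = np.asarray(X, dtype=float)
    labels = np.asarray(list(labels))
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    class_order = tuple(class_order)
    k = len(class_order)
    idx = labels_to_indices(labels, class_order)
    n = len(idx)
    _check_fold_feasibility(idx, config.outer_folds, k)

    reps = config.n_repetitions
    predictions = np.empty((reps, n), dtype=int)
    fold_ids = np.empty((reps, n), dtype=int)
    chosen_lv = np.empty((reps, config.outer_folds), dtype=int)
    accuracies = np.empty(reps)
    class_rates = np.empty((reps, k))

    streams = np.random.SeedSequence(config.seed).spawn(reps)
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        if config.stratified:
            outer = _stratified_folds(idx, config.outer_folds, rng)
        else:
            outer = _plain_folds(n, config.outer_folds, rng)
        fold_ids[r] = outer
        for f in range(config.outer_folds):
            test_mask = outer == f
            tr = np.nonzero(~test_mask)[0]
            te = np.nonzero(test_mask)[0]
            a_star = _inner_select(X[tr], idx[tr], class_order, config, rng)
            fold_model = _FoldModel(X[tr], idx[tr], class_order,
                                    a_star, config.priors)
            a_eff = min(a_star, fold_model.cap)
            chosen_lv[r, f] = a_eff
            predictions[r, te] = fold_model.predict_indices(X[te], a_eff)
        correct = predictions[r] == idx
        accuracies[r] = correct.mean()
        for j in range(k):
            class_rates[r, j] = correct[idx == j].mean()

    return DCVResult(
        class_order=class_order,
        sample_ids=sample_ids,
        true_idx=idx,
        predictions=predictions,
        fold_ids=fold_ids,
        chosen_lv=chosen_lv,
        accuracies=accuracies,
        class_rates=class_rates,
        config=config,
    )


def _inner_select(Xtr: np.ndarray, ytr: np.ndarray, class_order,
                  config: DCVConfig, rng: np.random.Generator) -> int:
    """Inner CV over 1..max_lv on the outer-training portion; returns the
    complexity minimizing the pooled inner misclassification error."""
    k = len(class_order)
    _check_fold_feasibility(ytr, config.inner_folds, k)
    if config.stratified:
        inner = _stratified_folds(ytr, config.inner_folds, rng)
    else:
        inner = _plain_folds(len(ytr), config.inner_folds, rng)
    cap = config.max_lv
    errors = np.zeros(cap)
    counts = np.zeros(cap)
    for f in range(config.inner_folds):
        vmask = inner == f
        fit_ix = np.nonzero(~vmask)[0]
        val_ix = np.nonzero(vmask)[0]
        if len(val_ix) == 0:
            continue
        fm = _FoldModel(Xtr[fit_ix], ytr[fit_ix], class_order, cap,
                        config.priors)
        fold_cap = min(cap, fm.cap)
        for a in range(1, fold_cap + 1):
            pred = fm.predict_indices(Xtr[val_ix], a)
            errors[a - 1] += np.sum(pred != ytr[val_ix])
            counts[a - 1] += len(val_ix)
        # complexities beyond this fold's cap behave like the cap
        for a in range(fold_cap + 1, cap + 1):
            pred = fm.predict_indices(Xtr[val_ix], fold_cap)
            errors[a - 1] += np.sum(pred != ytr[val_ix])
            counts[a - 1] += len(val_ix)
    rates = errors / np.maximum(counts, 1)
    return select_complexity(rates)


def summarize_dcv(result: DCVResult,
                  p_values: dict[str, float] | None = None) -> FiguresOfMerit:
    """Means and n-1 standard deviations over repetitions, on the percent
    scale; complexity pooled over all outer folds and repetitions."""
    acc = 100.0 * result.accuracies
    rates = 100.0 * result.class_rates
    reps = result.n_repetitions
    sd = (lambda v: float(np.std(v, ddof=1))) if reps > 1 else (lambda v: 0.0)
    lv = result.chosen_lv.ravel().astype(float)
    return FiguresOfMerit(
        class_order=result.class_order,
        accuracy_mean=float(acc.mean()),
        accuracy_sd=sd(acc),
        class_rate_mean=rates.mean(axis=0),
        class_rate_sd=np.array([sd(rates[:, j]) for j in range(rates.shape[1])]),
        complexity_mean=float(lv.mean()),
        complexity_sd=float(np.std(lv, ddof=1)) if lv.size > 1 else 0.0,
        confusion=result.confusion(),
        n_repetitions=reps,
        p_values=dict(p_values or {}),
    )


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """Add-one permutation p-value (1 + #{null >= observed}) / (1 + B)."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


@dataclass
class PermutationTestResult:
    """Observed figures of merit with their permutation null distribution."""

    observed: FiguresOfMerit
    null_accuracy: np.ndarray          # (B,) percent
    null_class_rates: np.ndarray       # (B, k) percent
    p_accuracy: float
    p_class_rates: dict[str, float]
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "p_accuracy": self.p_accuracy,
            "p_class_rates": dict(self.p_class_rates),
            "n_permutations": self.n_permutations,
            "observed_accuracy_pct": self.observed.accuracy_mean,
            "null_accuracy_pct": self.null_accuracy.tolist(),
        }


def permutation_test(
    X,
    labels,
    config: DCVConfig,
    n_permutations: int = 999,
    null_repetitions: int = 5,
    class_order: Sequence[str] | None = None,
    observed: DCVResult | None = None,
) -> PermutationTestResult:
    """Permutation test of the DCV figures of merit.

    Labels are permuted ``n_permutations`` times and the full DCV is rerun
    per permutation with ``null_repetitions`` repetitions (a documented
    reduction of the observed run's repetition count).  p-values use the
    add-one estimator p = (1 + #{null >= observed}) / (1 + B).
    """
    if n_permutations < 19:
        raise ValidationError("need n_permutations >= 19")
    labels = np.asarray(list(labels))
    if class_order is None:
        class_order = list(dict.fromkeys(labels))
    class_order = tuple(class_order)
    if observed is None:
        observed = run_dcv(X, labels, config, class_order=class_order)
    obs_fom = summarize_dcv(observed)

    from dataclasses import replace

    null_cfg_base = replace(config, n_repetitions=null_repetitions)
    perm_ss = np.random.SeedSequence([config.seed, 0x5EED]).spawn(n_permutations)
    k = len(class_order)
    null_acc = np.empty(n_permutations)
    null_rates = np.empty((n_permutations, k))
    for b in range(n_permutations):
        rng = np.random.default_rng(perm_ss[b])
        perm_labels = labels[rng.permutation(len(labels))]
        cfg = replace(null_cfg_base,
                      seed=int(rng.integers(2**31 - 1)))
        res = run_dcv(X, perm_labels, cfg, class_order=class_order)
        fom = summarize_dcv(res)
        null_acc[b] = fom.accuracy_mean
        null_rates[b] = fom.class_rate_mean

    p_acc = permutation_pvalue(obs_fom.accuracy_mean, null_acc)
    p_rates = {
        c: permutation_pvalue(obs_fom.class_rate_mean[j], null_rates[:, j])
        for j, c in enumerate(class_order)
    }
    obs_fom.p_values = {"accuracy": p_acc,
                        **{f"rate_{c}": p for c, p in p_rates.items()}}
    return PermutationTestResult(
        observed=obs_fom,
        null_accuracy=null_acc,
        null_class_rates=null_rates,
        p_accuracy=p_acc,
        p_class_rates=p_rates,
        n_permutations=n_permutations,
    )
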