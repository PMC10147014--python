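"""LLOQ-based analyte exclusion, censored-value substitution and autoscaling.

The modeling pipeline is strictly ordered: filter the panel on censoring
fractions, substitute the remaining censored cells, then scale — with scaling
parameters always estimated on training rows only so cross-validation folds
never leak test information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "RetainedPanel",
    "ScalingParams",
    "Scaler",
    "lloq_filter",
    "substitute_censored",
    "fit_scaling",
    "apply_scaling",
    "PreprocessingError",
    "SUBSTITUTION_POLICIES",
]

SUBSTITUTION_POLICIES = ("half_lloq", "lloq", "drop_sample")


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class RetainedPanel:
    """Outcome of LLOQ filtering: analytes kept for modeling and the ones
    dropped, with the censored fraction that excluded them."""

    kept: tuple[str, ...]
    dropped: dict[str, float]

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_dict(self) -> dict:
        return {"kept": list(self.kept), "dropped": dict(self.dropped)}


def lloq_filter(
    cohort: CohortTable, max_censored_fraction: float = 0.5
) -> RetainedPanel:
    """Drop analytes whose censored fraction exceeds ``max_censored_fraction``.

    Keeps panel order.  An analyte is retained iff its fraction of
    below-LLOQ samples is <= the threshold.
    """
    if not 0 <= max_censored_fraction < 1:
        raise PreprocessingError("max_censored_fraction must lie in [0, 1)")
    frac = cohort.censored_fraction()
    kept = tuple(a for a in cohort.analyte_names if frac[a] <= max_censored_fraction)
    dropped = {a: float(frac[a]) for a in cohort.analyte_names if a not in kept}
    if not kept:
        raise PreprocessingError("LLOQ filter removed every analyte")
    return RetainedPanel(kept=kept, dropped=dropped)


def substitute_censored(
    cohort: CohortTable,
    panel: RetainedPanel,
    policy: str = "half_lloq",
) -> pd.DataFrame:
    """Return a fully numeric samples × kept-analytes matrix.

    Policies: ``half_lloq`` replaces a censored cell by LLOQ/2 (the targeted
    metabolomics convention), ``lloq`` by the LLOQ itself, ``drop_sample``
    removes any sample with a censored cell among the kept analytes.
    """
    if policy not in SUBSTITUTION_POLICIES:
        raise PreprocessingError(
            f"unknown policy {policy!r}; expected one of {SUBSTITUTION_POLICIES}"
        )
    kept = list(panel.kept)
    values = cohort.concentrations[kept].copy()
    cens = cohort.censored[kept]
    if policy == "drop_sample":
        keep_rows = ~cens.any(axis=1)
        out = values.loc[keep_rows]
        remaining = cohort.class_labels.loc[keep_rows]
        lost = set(cohort.class_labels.unique()) - set(remaining.unique())
        if lost:
            raise PreprocessingError(
                f"drop_sample removed every sample of class(es) {sorted(lost)}"
            )
        return out
    fill = cohort.lloq[kept]
    if policy == "half_lloq":
        fill = fill / 2.0
    for a in kept:
        values.loc[cens[a], a] = fill[a]
    return values


@dataclass(frozen=True)
class ScalingParams:
    """Per-analyte center (mean) and spread (n-1 standard deviation)
    estimated on training rows."""

    center: pd.Series
    spread: pd.Series

    def __post_init__(self) -> None:
        bad = self.spread[~(self.spread > 0)]
        if len(bad):
            raise PreprocessingError(
                f"constant column(s): {list(bad.index)} (zero spread)"
            )


def fit_scaling(train: pd.DataFrame) -> ScalingParams:
    """Estimate autoscaling parameters (column mean, n-1 sd) on training rows."""
    if len(train) < 2:
        raise PreprocessingError("need >= 2 training rows to estimate scaling")
    return ScalingParams(center=train.mean(axis=0), spread=train.std(axis=0, ddof=1))


def apply_scaling(matrix: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Autoscale ``matrix`` with previously fitted training parameters."""
    return (matrix - params.center) / params.spread


def invert_scaling(scaled: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    return scaled * params.spread + params.center


class Scaler:
    """Stateful convenience wrapper around fit/apply scaling."""

    def __init__(self) -> None:
        self.params: ScalingParams | None = None

    def fit(self, train: pd.DataFrame) -> "Scaler":
        self.params = fit_scaling(train)
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if self.params is None:
            raise PreprocessingError("Scaler not fitted")
        return apply_scaling(matrix, self.params)

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)

    def inverse_transform(self, scaled: pd.DataFrame) -> pd.DataFrame:
        if self.params is None:
            raise PreprocessingError("Scaler not fitted")
        return invert_scaling(scaled, self.params)


def scale_matrix(
    X: np.ndarray, center: np.ndarray, spread: np.ndarray
) -> np.ndarray:
    """ndarray fast path used by the cross-validation engine."""
    return (X - center) / spread


def fit_scale_arrays(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    spread = X.std(axis=0, ddof=1)
    if np.any(spread <= 0):
        bad = np.nonzero(spread <= 0)[0]
        raise PreprocessingError(f"constant column(s) at indices {bad.tolist()}")
    return center, spread
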