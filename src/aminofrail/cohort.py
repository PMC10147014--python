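"""Synthetic serum amino-acid cohort generator.

Emulates a targeted UPLC/MS panel of 37 amino acids and derivatives measured
in three groups of older adults: robust non-diabetic controls, participants
with physical frailty & sarcopenia (PF&S), and pre-frail/frail participants
with type 2 diabetes (F-T2DM).  Concentrations are drawn from a multivariate
log-normal model with exchangeable correlation on the log scale — amino-acid
panels are positive, right-skewed and mutually correlated, which is exactly
the ill-conditioning PLS-based classifiers are designed to handle.

Values below an analyte's lower limit of quantitation (LLOQ) are censored:
the table stores a censoring flag carrying the LLOQ bound rather than an
imputed number; substitution policy is a preprocessing decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteSpec",
    "CohortConfig",
    "CohortTable",
    "replica_config",
    "generate_cohort",
    "CLASS_CONTROL",
    "CLASS_PFS",
    "CLASS_FT2DM",
]

CLASS_CONTROL = "controls"
CLASS_PFS = "PF&S"
CLASS_FT2DM = "F-T2DM"

#: default replica class order: controls first (dummy code [1 0 0]), then
#: PF&S ([0 1 0]), then F-T2DM ([0 0 1]).
REPLICA_CLASS_ORDER = (CLASS_CONTROL, CLASS_PFS, CLASS_FT2DM)
REPLICA_GROUP_SIZES = {CLASS_CONTROL: 40, CLASS_PFS: 94, CLASS_FT2DM: 66}


class ConfigError(ValueError):
    """Invalid cohort or analysis configuration."""


@dataclass(frozen=True)
class AnalyteSpec:
    """Distributional specification of one analyte.

    Parameters
    ----------
    name : str
        Analyte name, unique within a panel.
    lloq : float
        Lower limit of quantitation in µmol/L; draws below it are censored.
    log_mean : mapping of class name to float
        Mean of log-concentration (log µmol/L) per class.
    log_sd : float
        Log-scale standard deviation (shared across classes).
    fully_censored : bool
        If True every sample is reported below the LLOQ regardless of the
        draw (analyte sits entirely under the quantitation limit).
    """

    name: str
    lloq: float
    log_mean: Mapping[str, float]
    log_sd: float
    fully_censored: bool = False

    def __post_init__(self) -> None:
        if not self.lloq > 0:
            raise ConfigError(f"analyte {self.name!r}: lloq must be > 0")
        if not self.log_sd > 0:
            raise ConfigError(f"analyte {self.name!r}: log_sd must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort draw."""

    class_names: tuple[str, ...]
    group_sizes: Mapping[str, int]
    panel: tuple[AnalyteSpec, ...]
    correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise ConfigError("class names must be distinct")
        names = [a.name for a in self.panel]
        if len(set(names)) != len(names):
            raise ConfigError("panel analyte names must be unique")
        for c in self.class_names:
            if self.group_sizes.get(c, 0) < 2:
                raise ConfigError(f"group size for {c!r} must be >= 2")
            for a in self.panel:
                if c not in a.log_mean:
                    raise ConfigError(
                        f"analyte {a.name!r} missing log_mean for class {c!r}"
                    )
        if not 0 <= self.correlation < 1:
            raise ConfigError("correlation must lie in [0, 1)")

    @property
    def analyte_names(self) -> list[str]:
        return [a.name for a in self.panel]

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes[c] for c in self.class_names)


class CohortTable:
    """Labeled samples × analytes concentration table with censoring flags.

    Censored cells hold ``NaN`` in :attr:`concentrations` and ``True`` in
    :attr:`censored`; the per-analyte LLOQ bound is kept in :attr:`lloq`.
    """

    def __init__(
        self,
        concentrations: pd.DataFrame,
        censored: pd.DataFrame,
        class_labels: pd.Series,
        lloq: pd.Series,
    ):
        if not concentrations.index.is_unique:
            raise ValueError("sample ids must be unique")
        if concentrations.shape != censored.shape:
            raise ValueError("concentrations/censored shape mismatch")
        if (concentrations.lt(0)).any().any():
            raise ValueError("negative concentrations")
        self.concentrations = concentrations
        self.censored = censored.astype(bool)
        self.class_labels = class_labels
        self.lloq = lloq.reindex(concentrations.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.concentrations.index

    @property
    def analyte_names(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def n_samples(self) -> int:
        return len(self.concentrations)

    def censored_fraction(self) -> pd.Series:
        """Per-analyte fraction of samples below the LLOQ."""
        return self.censored.mean(axis=0)

    def class_counts(self) -> pd.Series:
        return self.class_labels.value_counts()

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.concentrations.equals(other.concentrations)
            and self.censored.equals(other.censored)
            and self.class_labels.equals(other.class_labels)
            and self.lloq.equals(other.lloq)
        )


# ---------------------------------------------------------------------------
# Replica panel
# ---------------------------------------------------------------------------

# Control-group median serum concentrations (µmol/L), order defines the panel.
_BASELINE_MEDIAN = {
    "alanine": 350.0,
    "arginine": 80.0,
    "asparagine": 50.0,
    "aspartic acid": 10.0,
    "citrulline": 35.0,
    "cystine": 50.0,
    "glutamic acid": 60.0,
    "glutamine": 600.0,
    "glycine": 230.0,
    "histidine": 80.0,
    "isoleucine": 60.0,
    "leucine": 120.0,
    "lysine": 180.0,
    "methionine": 25.0,
    "phenylalanine": 60.0,
    "proline": 180.0,
    "serine": 110.0,
    "taurine": 60.0,
    "threonine": 130.0,
    "tryptophan": 55.0,
    "tyrosine": 65.0,
    "valine": 230.0,
    "ornithine": 70.0,
    "cysteine": 30.0,
    "ethanolamine": 10.0,
    "hydroxyproline": 12.0,
    "sarcosine": 2.0,
    "1-methylhistidine": 8.0,
    "3-methylhistidine": 5.0,
    "beta-aminobutyric acid": 2.0,
    "aminoadipic acid": 1.5,
    # fully below the quantitation limit in serum at this assay's LLOQ
    "anserine": 0.1,
    "carnosine": 0.1,
    "cystathionine": 0.1,
    "gamma-aminobutyric acid": 0.1,
    "phosphoethanolamine": 0.1,
    "phosphoserine": 0.1,
}

FULLY_CENSORED_ANALYTES = (
    "anserine",
    "carnosine",
    "cystathionine",
    "gamma-aminobutyric acid",
    "phosphoethanolamine",
    "phosphoserine",
)

# Analytes that drive each phenotype's signature.  "Primary" analytes are the
# headline discriminators (largest shifts); "secondary" ones contribute with
# smaller shifts.  Shifts are additive on the log scale relative to controls.
FT2DM_PRIMARY = (
    "3-methylhistidine",
    "alanine",
    "arginine",
    "ethanolamine",
    "glutamic acid",
)
FT2DM_SECONDARY = (
    "beta-aminobutyric acid",
    "isoleucine",
    "methionine",
    "1-methylhistidine",
    "sarcosine",
)
PFS_PRIMARY = (
    "aminoadipic acid",
    "aspartic acid",
    "cystine",
    "taurine",
    "tryptophan",
)
PFS_SECONDARY = (
    "asparagine",
    "citrulline",
)

# Log-scale effect sizes (log-units), chosen to emulate the observed
# separability pattern: F-T2DM well separated from both other groups, PF&S
# and controls overlapping substantially.
EFFECT_FT2DM_PRIMARY = 0.50
EFFECT_FT2DM_SECONDARY = 0.25
EFFECT_PFS_PRIMARY = 0.30
EFFECT_PFS_SECONDARY = 0.15

DEFAULT_LOG_SD = 0.35
DEFAULT_LLOQ = 0.5
CYSTINE_LLOQ = 1.0  # cystine is calibrated on a higher-range standard curve


def replica_config(seed: int = 0, correlation: float = 0.3) -> CohortConfig:
    """Default three-class frailty cohort configuration.

    Returns a 37-analyte panel with group sizes 40 controls, 94 PF&S and
    66 F-T2DM; six analytes (anserine, carnosine, cystathionine,
    gamma-aminobutyric acid, phosphoethanolamine, phosphoserine) sit fully
    below the LLOQ; class-specific log-mean shifts elevate the F-T2DM and
    PF&S signature analytes above control levels.
    """
    panel = []
    for name, median in _BASELINE_MEDIAN.items():
        base = float(np.log(median))
        shift_pfs = 0.0
        shift_ft2dm = 0.0
        if name in FT2DM_PRIMARY:
            shift_ft2dm = EFFECT_FT2DM_PRIMARY
        elif name in FT2DM_SECONDARY:
            shift_ft2dm = EFFECT_FT2DM_SECONDARY
        if name in PFS_PRIMARY:
            shift_pfs = EFFECT_PFS_PRIMARY
        elif name in PFS_SECONDARY:
            shift_pfs = EFFECT_PFS_SECONDARY
        panel.append(
            AnalyteSpec(
                name=name,
                lloq=CYSTINE_LLOQ if name == "cystine" else DEFAULT_LLOQ,
                log_mean={
                    CLASS_CONTROL: base,
                    CLASS_PFS: base + shift_pfs,
                    CLASS_FT2DM: base + shift_ft2dm,
                },
                log_sd=DEFAULT_LOG_SD,
                fully_censored=name in FULLY_CENSORED_ANALYTES,
            )
        )
    return CohortConfig(
        class_names=REPLICA_CLASS_ORDER,
        group_sizes=dict(REPLICA_GROUP_SIZES),
        panel=tuple(panel),
        correlation=correlation,
        seed=seed,
    )


def _correlation_cholesky(p: int, rho: float) -> np.ndarray:
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rho<1 guards this
        raise ConfigError("correlation matrix is not positive definite") from exc


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Draw a :class:`CohortTable` from the configured log-normal model.

    One master seed drives the draw; per-class streams are spawned
    deterministically from it, so the table is byte-identical across runs
    with the same config.
    """
    p = len(config.panel)
    chol = _correlation_cholesky(p, config.correlation)
    sds = np.array([a.log_sd for a in config.panel])
    lloqs = np.array([a.lloq for a in config.panel])
    fully = np.array([a.fully_censored for a in config.panel])

    streams = np.random.SeedSequence(config.seed).spawn(len(config.class_names))
    blocks, labels, ids = [], [], []
    offset = 0
    for ci, cname in enumerate(config.class_names):
        n = config.group_sizes[cname]
        rng = np.random.default_rng(streams[ci])
        mu = np.array([a.log_mean[cname] for a in config.panel])
        z = rng.standard_normal((n, p))
        log_conc = mu + (z @ chol.T) * sds
        blocks.append(np.exp(log_conc))
        labels.extend([cname] * n)
        ids.extend(f"S{offset + i + 1:04d}" for i in range(n))
        offset += n

    values = np.vstack(blocks)
    censored = (values < lloqs) | fully
    values = np.where(censored, np.nan, values)

    cols = config.analyte_names
    conc = pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=cols)
    cens = pd.DataFrame(censored, index=conc.index, columns=cols)
    lab = pd.Series(labels, index=conc.index, name="class")
    lloq = pd.Series(lloqs, index=pd.Index(cols), name="lloq")
    return CohortTable(conc, cens, lab, lloq)
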