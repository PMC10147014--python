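"""Cohort CSV dialect, group summaries and the end-to-end analysis workflow.

The cohort CSV has the header ``sample_id,class,<analyte names...>``;
censored (below-LLOQ) cells are written as the literal ``<LLOQ`` (e.g.
``<0.5``), so the table round-trips losslessly including censoring flags.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from .cohort import CohortConfig, CohortTable, generate_cohort, replica_config
from .preprocess import lloq_filter, substitute_censored
from .plsda import PLSDiscriminantAnalysis
from .validation import DCVConfig, permutation_test, run_dcv, summarize_dcv
from .simca import simca_dcv

__all__ = [
    "DataError",
    "RunConfig",
    "GroupSummary",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_panel_sidecar",
    "group_summary",
    "run_full_analysis",
]

log = logging.getLogger("aminofrail")


class DataError(ValueError):
    """Malformed input data (exit code 1 at the CLI)."""


# ---------------------------------------------------------------------------
# cohort CSV dialect
# ---------------------------------------------------------------------------


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write the cohort in the ``sample_id,class,...`` dialect; censored
    cells become ``<LLOQ`` literals."""
    out = table.concentrations.astype(object).copy()
    for a in table.analyte_names:
        mask = table.censored[a]
        if mask.any():
            out.loc[mask, a] = f"<{table.lloq[a]:g}"
    out.insert(0, "class", table.class_labels)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_cohort_csv(path) -> CohortTable:
    """Parse the cohort CSV dialect back into a :class:`CohortTable`.

    Raises :class:`DataError` naming the offending row/column on malformed
    cells, and on a missing ``class`` column.
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "sample_id" or "class" not in df.columns[:2]:
        raise DataError(
            f"{path}: header must start with 'sample_id,class', got "
            f"{list(df.columns[:2])}"
        )
    df = df.set_index("sample_id")
    labels = df["class"]
    analytes = [c for c in df.columns if c != "class"]
    values = np.empty((len(df), len(analytes)))
    censored = np.zeros_like(values, dtype=bool)
    lloq = {}
    for j, a in enumerate(analytes):
        for i, cell in enumerate(df[a]):
            cell = "" if cell is None or cell != cell else str(cell).strip()
            if cell.startswith("<"):
                try:
                    bound = float(cell[1:])
                except ValueError:
                    raise DataError(
                        f"{path}: malformed censored cell {cell!r} at row "
                        f"{df.index[i]!r}, column {a!r}"
                    ) from None
                censored[i, j] = True
                values[i, j] = np.nan
                prev = lloq.setdefault(a, bound)
                if prev != bound:
                    raise DataError(
                        f"{path}: inconsistent LLOQ bounds for {a!r}: "
                        f"{prev} vs {bound}"
                    )
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise DataError(
                        f"{path}: malformed cell {cell!r} at row "
                        f"{df.index[i]!r}, column {a!r}"
                    ) from None
    conc = pd.DataFrame(values, index=df.index, columns=analytes)
    cens = pd.DataFrame(censored, index=df.index, columns=analytes)
    lloq_s = pd.Series({a: lloq.get(a, np.nan) for a in analytes}, name="lloq")
    return CohortTable(conc, cens, labels.rename("class"), lloq_s)


def write_panel_sidecar(config: CohortConfig, path) -> None:
    """Panel definition (names, LLOQ, per-class log-means) as JSON."""
    payload = {
        "class_names": list(config.class_names),
        "group_sizes": {c: int(config.group_sizes[c]) for c in config.class_names},
        "correlation": config.correlation,
        "panel": [
            {
                "name": a.name,
                "lloq": a.lloq,
                "log_mean": dict(a.log_mean),
                "log_sd": a.log_sd,
                "fully_censored": a.fully_censored,
            }
            for a in config.panel
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# group summaries (Table-1 style arithmetic)
# ---------------------------------------------------------------------------


@dataclass
class GroupSummary:
    """Per-class n, mean, sd and all pairwise mean differences."""

    class_order: tuple[str, ...]
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    differences: dict[tuple[str, str], float]

    def difference(self, a: str, b: str) -> float:
        return self.differences[(a, b)]

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "n": dict(self.n),
            "mean": dict(self.mean),
            "sd": dict(self.sd),
            "differences": {f"{a} - {b}": v
                            for (a, b), v in self.differences.items()},
        }

    def summary(self) -> str:
        lines = ["group        n    mean (sd)"]
        for c in self.class_order:
            lines.append(f"{c:<12} {self.n[c]:<4} {self.mean[c]:.1f} "
                         f"({self.sd[c]:.1f})")
        for (a, b), v in self.differences.items():
            lines.append(f"mean difference {a} - {b} = {v:.1f}")
        return "\n".join(lines)


def group_summary(values_by_class: Mapping[str, Sequence[float]],
                  class_order: Sequence[str] | None = None) -> GroupSummary:
    """Mean (n-1 sd) per class and antisymmetric pairwise mean differences."""
    if class_order is None:
        class_order = list(values_by_class)
    order = tuple(class_order)
    n, mean, sd = {}, {}, {}
    for c in order:
        v = np.asarray(values_by_class[c], dtype=float)
        if v.size == 0:
            raise DataError(f"class {c!r} has no values")
        n[c] = int(v.size)
        mean[c] = float(v.mean())
        sd[c] = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    diffs = {}
    for a, b in itertools.permutations(order, 2):
        diffs[(a, b)] = mean[a] - mean[b]
    return GroupSummary(class_order=order, n=n, mean=mean, sd=sd,
                        differences=diffs)


# ---------------------------------------------------------------------------
# full analysis workflow
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end analysis configuration.

    If ``cohort_csv`` is None a replica cohort is simulated from the seed.
    The strong two-class comparison (PF&S vs F-T2DM) and the three-class
    model are both run under DCV; permutation tests and per-class SIMCA DCV
    follow.
    """

    output_dir: str = "aminofrail_run"
    cohort_csv: str | None = None
    class_order: tuple[str, ...] = _cohort.REPLICA_CLASS_ORDER
    two_class_pair: tuple[str, str] = (_cohort.CLASS_PFS, _cohort.CLASS_FT2DM)
    max_censored_fraction: float = 0.5
    substitution_policy: str = "half_lloq"
    dcv: DCVConfig = field(default_factory=DCVConfig)
    n_permutations: int = 999
    permutation_repetitions: int = 5
    simca_max_components: int = 12
    simca_repetitions: int = 20
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        dcv_raw = raw.pop("dcv", {})
        try:
            cfg = cls(**raw)
            if dcv_raw:
                cfg = replace(cfg, dcv=DCVConfig(**dcv_raw))
        except TypeError as exc:
            raise _cohort.ConfigError(f"{path}: {exc}") from None
        return cfg

    def digest(self) -> str:
        # digest covers the analysis-relevant settings, not output locations
        payload = {k: str(v) for k, v in asdict(self).items()
                   if k not in ("output_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole pipeline and write the report bundle.

    Stages: simulate/ingest -> LLOQ filter -> substitution -> two-class
    PLS-DA DCV -> three-class PLS-DA DCV -> permutation tests -> per-class
    SIMCA DCV -> group summary -> serialized bundle.  Every artifact is a
    deterministic function of (config, seed).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    bundle: dict = {"config_digest": config.digest(), "seed": config.seed}

    # --- stage: cohort ----------------------------------------------------
    try:
        if config.cohort_csv is None:
            cconf = replica_config(seed=config.seed)
            table = generate_cohort(cconf)
            write_cohort_csv(table, out / "cohort.csv")
            write_panel_sidecar(cconf, out / "panel.json")
        else:
            table = read_cohort_csv(config.cohort_csv)
    except Exception as exc:
        raise DataError(f"stage cohort: {exc}") from exc
    log.info("cohort: %d samples, %d analytes", table.n_samples,
             len(table.analyte_names))

    # --- stage: preprocessing --------------------------------------------
    try:
        panel = lloq_filter(table, config.max_censored_fraction)
        matrix = substitute_censored(table, panel, config.substitution_policy)
    except Exception as exc:
        raise DataError(f"stage preprocessing: {exc}") from exc
    _json_dump(
        {**panel.to_dict(),
         "censored_fraction": {
             a: float(f) for a, f in table.censored_fraction().items()
         }},
        out / "retained_panel.json",
    )
    labels = table.class_labels
    bundle["n_analytes_retained"] = panel.n_kept

    # --- stage: two-class PLS-DA DCV --------------------------------------
    pair = config.two_class_pair
    pair_mask = labels.isin(pair)
    X2, y2 = matrix.loc[pair_mask], labels.loc[pair_mask]
    dcv2_cfg = replace(config.dcv, seed=config.seed)
    res2 = run_dcv(X2, y2, dcv2_cfg, class_order=pair)
    perm2 = permutation_test(
        X2, y2, dcv2_cfg, n_permutations=config.n_permutations,
        null_repetitions=config.permutation_repetitions,
        class_order=pair, observed=res2,
    )
    fom2 = perm2.observed
    _json_dump(fom2.to_dict(), out / "plsda_two_class.json")
    _json_dump(perm2.to_dict(), out / "permutation_two_class.json")
    bundle["two_class"] = fom2.to_dict()

    # --- stage: three-class PLS-DA DCV -------------------------------------
    dcv3_cfg = replace(config.dcv, seed=config.seed + 1)
    res3 = run_dcv(matrix, labels, dcv3_cfg, class_order=config.class_order)
    perm3 = permutation_test(
        matrix, labels, dcv3_cfg, n_permutations=config.n_permutations,
        null_repetitions=config.permutation_repetitions,
        class_order=config.class_order, observed=res3,
    )
    fom3 = perm3.observed
    _json_dump(fom3.to_dict(), out / "plsda_three_class.json")
    _json_dump(perm3.to_dict(), out / "permutation_three_class.json")
    bundle["three_class"] = fom3.to_dict()

    # canonical scores/weights of the full-data three-class model
    n_lv_full = max(1, int(round(fom3.complexity_mean)))
    full = PLSDiscriminantAnalysis(
        matrix, labels, class_order=config.class_order
    ).fit(n_lv_full)
    cv_scores = pd.DataFrame(
        full.cv_scores(),
        index=matrix.index,
        columns=[f"CV{j + 1}" for j in range(full.cv_scores().shape[1])],
    )
    cv_scores.insert(0, "class", labels)
    cv_scores.to_csv(out / "cv_scores_three_class.csv")
    pd.DataFrame(
        full.cv_weights, index=matrix.columns,
        columns=[f"CV{j + 1}" for j in range(full.cv_weights.shape[1])],
    ).to_csv(out / "cv_weights_three_class.csv")

    # --- stage: SIMCA -----------------------------------------------------
    simca_cfg = replace(
        config.dcv, n_repetitions=config.simca_repetitions,
        seed=config.seed + 2,
    )
    bundle["simca"] = {}
    for c in config.class_order:
        res = simca_dcv(
            matrix, labels, c, config=simca_cfg,
            max_components=config.simca_max_components,
        )
        res.reduced_table.to_csv(out / f"simca_distances_{_slug(c)}.csv")
        bundle["simca"][c] = res.to_dict()
    _json_dump(bundle["simca"], out / "simca.json")

    # --- stage: group summary ---------------------------------------------
    first = panel.kept[0]
    gs = group_summary(
        {c: matrix.loc[labels == c, first].to_numpy()
         for c in config.class_order},
        class_order=config.class_order,
    )
    _json_dump(gs.to_dict(), out / "group_summary.json")
    bundle["group_summary_analyte"] = first

    _json_dump(bundle, out / "report.json")
    (out / "run.log").write_text(
        f"seed={config.seed}\nconfig_digest={config.digest()}\n"
    )
    return bundle


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name).strip("_")
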