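"""End-to-end analysis pipeline and report bundle.

``run_pipeline`` takes raw records (from a file or the synthetic
generator), applies exclusions, derives measures, classifies
metabolic-syndrome status, computes census post-stratification weights and
emits the full report surface as delimited text plus JSON:

* ``cohort_analyzed.csv`` / ``exclusions.csv`` — analyzable cohort with
  derived columns, and the per-record exclusion log;
* ``assessment.csv`` — component flags, counts, MetS labels, stratum;
* ``cohort_characteristics.csv`` — weighted mean +/- SEM by sex, with the
  unweighted versions alongside;
* ``percentiles_<definition>_<stratum>.csv`` — score thresholds at the
  percentile grid with sensitivity/specificity/PLR (thresholds only for a
  single-class stratum);
* ``criterion_curves_<definition>_<stratum>.csv`` — sensitivity,
  specificity, Youden (both scales), squared distance and PLR at every
  candidate threshold (the criterion-vs-threshold curves);
* ``cutpoints.csv`` and ``summary.json`` — selected cut-offs per stratum x
  definition x criterion with AUC and bootstrap CI;
* ``manifest.json`` — config echo, seed, versions, record accounting.

All randomness (generator, bootstrap) derives from the single top-level
seed; a rerun with the same config writes byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __about__
from . import clinical_records, mets_classification, survey_weighting
from .errors import DegenerateLabelsError, HomacutError
from .roc_cutpoint import (
    auc,
    auc_bootstrap_ci,
    empirical_roc,
    optimal_cutpoint,
    percentile_table,
)
from .survey_weighting import (
    CensusStrata,
    poststratification_weights,
    weighted_mean_sem,
    weighted_pearson,
    weighted_prevalence,
)
from .synthetic_survey import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

#: Variables summarized in the cohort characteristics table.
CHARACTERISTIC_VARS = [
    "age",
    "bmi",
    "waist",
    "sbp",
    "dbp",
    "fpg",
    "insulin",
    "homa_ir",
    "tg",
    "hdl",
    "tc",
    "ldl",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``input_path`` (a raw cohort file) or ``generator``
    (synthetic preset) feeds the pipeline. ``score_column`` selects the
    diagnostic score (``homa_ir`` default; ``insulin`` runs the fasting-
    insulin variant through the identical machinery).
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    census_path: str | Path | None = None
    criteria: tuple[str, ...] = ("atpiii", "idf")
    score_column: str = "homa_ir"
    strata: tuple[str, ...] = ("nondiabetic", "diabetic", "normal")
    diabetes_rule: str = "history_or_fpg126"
    percentile_grid: tuple[float, ...] = tuple(range(50, 100, 5))
    n_boot: int = 2000
    seed: int = 1

    def __post_init__(self):
        if (self.input_path is None) == (self.generator is None):
            raise HomacutError("provide exactly one of input_path or generator")
        bad = [c for c in self.criteria if c not in ("atpiii", "idf")]
        if bad:
            raise HomacutError(f"unknown criteria: {bad}")
        if any(not 0 <= p <= 100 for p in self.percentile_grid):
            raise HomacutError("percentile grid must lie within [0, 100]")


def _stratum_mask(assessment: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum in ("nondiabetic", "diabetic"):
        return (assessment["stratum"] == stratum).to_numpy()
    if stratum == "normal":
        return assessment["metabolically_normal"].to_numpy()
    raise HomacutError(f"unknown analysis stratum {stratum!r}")


def _characteristics(derived: pd.DataFrame, assessment: pd.DataFrame, weights) -> pd.DataFrame:
    rows = []
    groups = [("all", np.ones(len(derived), dtype=bool))] + [
        (s, (derived["sex"] == s).to_numpy()) for s in ("male", "female")
    ]
    for group, mask in groups:
        w = weights[mask]
        for var in CHARACTERISTIC_VARS:
            x = derived.loc[mask, var].to_numpy(dtype=float)
            keep = ~np.isnan(x)
            if keep.sum() < 2:
                continue
            mean, sem = weighted_mean_sem(x[keep], w[keep])
            u_mean, u_sem = weighted_mean_sem(x[keep], None)
            rows.append(
                {
                    "group": group,
                    "variable": var,
                    "weighted_mean": mean,
                    "weighted_sem": sem,
                    "unweighted_mean": u_mean,
                    "unweighted_sem": u_sem,
                    "n": int(keep.sum()),
                }
            )
        for definition in ("atpiii", "idf"):
            lab = assessment.loc[mask, f"mets_{definition}"].to_numpy()
            rows.append(
                {
                    "group": group,
                    "variable": f"mets_{definition}_prevalence",
                    "weighted_mean": weighted_prevalence(lab, w),
                    "weighted_sem": np.nan,
                    "unweighted_mean": float(lab.mean()),
                    "unweighted_sem": np.nan,
                    "n": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def _criterion_curves(roc) -> pd.DataFrame:
    se, sp = roc.sensitivity, roc.specificity
    with np.errstate(divide="ignore"):
        plr_col = np.where(sp < 1.0, se / np.where(sp < 1.0, 1.0 - sp, 1.0), np.inf)
    return pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": se,
            "specificity": sp,
            "youden_j": se + sp - 1.0,
            "youden_plus_one": se + sp,
            "distance_sq": (1 - se) ** 2 + (1 - sp) ** 2,
            "plr": plr_col,
            "score_percentile": 100.0 * roc.score_cdf,
        }
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; write the report bundle; return the summary.

    Deterministic: identical config (including seed) reproduces every
    output file byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    # documented substream derivation: one child seed per stochastic stage
    boot_seeds = {}

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=int(rng.integers(2**31)))
        cohort = generate_cohort(gen)
        source = {"generator": _jsonable(dataclasses.asdict(gen))}
    else:
        cohort = clinical_records.read_cohort(config.input_path)
        source = {"input_path": str(config.input_path)}
    n_raw = len(cohort)
    logger.info("ingest: %d raw records", n_raw)

    retained, exclusion_log = clinical_records.apply_exclusions(cohort)
    logger.info(
        "exclusions: retained %d, excluded %d (%s)",
        len(retained),
        len(exclusion_log),
        exclusion_log["reason"].value_counts().to_dict(),
    )
    derived = clinical_records.derive_measures(retained)
    assessment = mets_classification.assess_cohort(derived, config.diabetes_rule)

    census = (
        CensusStrata.from_file(config.census_path) if config.census_path else CensusStrata()
    )
    weights = poststratification_weights(derived, census)

    clinical_records.write_cohort(derived, out / "cohort_analyzed.csv")
    clinical_records.write_cohort(exclusion_log, out / "exclusions.csv")
    clinical_records.write_cohort(assessment, out / "assessment.csv")
    _characteristics(derived, assessment, weights).to_csv(
        out / "cohort_characteristics.csv", index=False, float_format=_FLOAT_FMT
    )

    scores = derived[config.score_column].to_numpy(dtype=float)
    insulin = derived["insulin"].to_numpy(dtype=float)
    homa = derived["homa_ir"].to_numpy(dtype=float)

    summary: dict = {
        "score_column": config.score_column,
        "n_raw": n_raw,
        "n_analyzed": len(derived),
        "mets_prevalence_weighted": {},
        "homa_insulin_correlation": weighted_pearson(homa, insulin, weights),
        "cutpoints": [],
        "skipped_strata": [],
    }
    for definition in config.criteria:
        labels_all = assessment[f"mets_{definition}"].to_numpy()
        summary["mets_prevalence_weighted"][definition] = weighted_prevalence(
            labels_all, weights
        )

    for stratum in config.strata:
        mask = _stratum_mask(assessment, stratum)
        if mask.sum() == 0:
            logger.warning("stratum %s: empty, skipped", stratum)
            summary["skipped_strata"].append({"stratum": stratum, "reason": "empty"})
            continue
        for definition in config.criteria:
            labels = assessment.loc[mask, f"mets_{definition}"].to_numpy()
            tag = f"{definition}_{stratum}"
            try:
                roc = empirical_roc(scores[mask], labels, weights[mask])
            except DegenerateLabelsError:
                logger.warning(
                    "stratum %s / %s: single outcome class, ROC outputs skipped",
                    stratum,
                    definition,
                )
                summary["skipped_strata"].append(
                    {"stratum": stratum, "definition": definition, "reason": "single-class"}
                )
                thr = survey_weighting.weighted_percentile(
                    scores[mask], weights[mask], np.asarray(config.percentile_grid)
                )
                pd.DataFrame(
                    {"percentile": config.percentile_grid, "threshold": np.atleast_1d(thr)}
                ).to_csv(out / f"percentiles_{tag}.csv", index=False, float_format=_FLOAT_FMT)
                continue

            table = percentile_table(
                scores[mask], labels, weights[mask], config.percentile_grid
            )
            table.to_csv(out / f"percentiles_{tag}.csv", index=False, float_format=_FLOAT_FMT)
            _criterion_curves(roc).to_csv(
                out / f"criterion_curves_{tag}.csv", index=False, float_format=_FLOAT_FMT
            )

            boot_seed = int(rng.integers(2**31))
            boot_seeds[tag] = boot_seed
            ci_lo, ci_hi = auc_bootstrap_ci(
                scores[mask],
                labels,
                weights[mask],
                n_boot=config.n_boot,
                seed=boot_seed,
            )
            area = auc(roc)
            for method in ("youden", "distance"):
                cp = optimal_cutpoint(roc, method)
                summary["cutpoints"].append(
                    {
                        "stratum": stratum,
                        "definition": definition,
                        "method": method,
                        "threshold": cp.threshold,
                        "sensitivity": cp.sensitivity,
                        "specificity": cp.specificity,
                        "youden_j": cp.youden_j,
                        "youden_plus_one": cp.youden_plus_one,
                        "distance_sq": cp.distance_sq,
                        "plr": cp.plr,
                        "percentile_of_threshold": cp.percentile_of_threshold,
                        "plateau_low": cp.plateau[0],
                        "plateau_high": cp.plateau[1],
                        "auc": area,
                        "auc_ci95_low": ci_lo,
                        "auc_ci95_high": ci_hi,
                        "n_stratum": int(mask.sum()),
                    }
                )

    cut_df = pd.DataFrame(summary["cutpoints"])
    cut_df.to_csv(out / "cutpoints.csv", index=False, float_format=_FLOAT_FMT)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "package": "homacut",
        "version": __about__.__version__,
        "seed": config.seed,
        "source": source,
        "config": _jsonable(
            {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("generator", "out_dir")
            }
        ),
        "bootstrap_seeds": boot_seeds,
        "records": {
            "raw": n_raw,
            "analyzed": len(derived),
            "excluded": len(exclusion_log),
            "excluded_by_reason": exclusion_log["reason"].value_counts().to_dict(),
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and paths for json.dump."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj
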