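"""End-to-end analysis: ingest -> per-item per-cohort fits -> report tables.

Produces, per run: a long-format ``fit_results.csv`` (one row per item x
cohort), two wide presentation tables (pi* with SE, and the dissimilarity
index with non-convergent cells marked), and a machine-readable JSON run
summary.  Output is deterministic given input and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .fit import DEFAULT_DI_CUTOFF, DEFAULT_PI_CUTOFF, FitResult, fit_item
from .ingest import (
    DEFAULT_MISSING_CODES,
    POOLED_LABEL,
    EligibilityFlags,
    EmptyTableError,
    RecodingRule,
    assess_item_eligibility,
    build_pattern_table,
    item_vectors,
    pool_tables,
    raw_missing_fraction,
    read_responses,
)

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "load_config",
    "run_analysis",
    "write_fit_tables",
    "format_value",
    "DI_NONCONVERGED_MARKER",
]

logger = logging.getLogger(__name__)

DI_NONCONVERGED_MARKER = "*"


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible analysis run depends on."""

    input_path: str
    out_dir: str
    T: int = 4
    pi_cutoff: float = DEFAULT_PI_CUTOFF
    di_cutoff: float = DEFAULT_DI_CUTOFF
    error_model: str = "proctor"
    pooled: bool = True
    seed: Optional[int] = None
    columns: Optional[Mapping[str, str]] = None
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES
    recoding: Mapping[str, RecodingRule] = field(default_factory=dict)
    missing_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name, c in (("pi_cutoff", self.pi_cutoff), ("di_cutoff", self.di_cutoff)):
            if not 0.0 < c < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {c}")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def load_config(path) -> dict:
    """Read a YAML or JSON analysis config (YAML is a JSON superset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def rules_from_config(cfg: Mapping) -> Dict[str, RecodingRule]:
    """Build per-item recoding rules from the config's ``recoding`` section.

    Each entry maps an item label to ``{mode, max_score}``; items without an
    entry are assumed already binary.
    """
    rules: Dict[str, RecodingRule] = {}
    for item, spec in (cfg.get("recoding") or {}).items():
        spec = spec or {}
        rules[item] = RecodingRule(
            item=item,
            mode=spec.get("mode", "dichotomize_perfect"),
            max_score=spec.get("max_score"),
        )
    return rules


@dataclass(frozen=True)
class AnalysisReport:
    """Outcome of one analysis run."""

    results: Tuple[FitResult, ...]
    exclusions: Tuple[Tuple[str, str], ...]  # (item, reason)
    summary: Dict

    @property
    def items(self) -> Tuple[str, ...]:
        return tuple(sorted({r.item for r in self.results}))


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Run the full pipeline on a long-format response file.

    Per eligible item, fits every cohort separately and (optionally) the
    pooled sample; ineligible items are listed with their exclusion reason.
    Raises :class:`EmptyTableError` if no item is eligible.
    """
    df = read_responses(config.input_path, columns=config.columns, missing_codes=config.missing_codes)
    items = sorted(df["item"].unique())
    cohorts = sorted(df["cohort"].unique())
    results: List[FitResult] = []
    exclusions: List[Tuple[str, str]] = []

    for item in items:
        rule = config.recoding.get(item, RecodingRule(item=item, mode="already_binary"))
        miss_frac = raw_missing_fraction(df, item, config.T)
        cohort_tables = []
        for cohort in cohorts:
            vectors = item_vectors(df, item, rule, config.T, cohort=cohort)
            try:
                cohort_tables.append(
                    build_pattern_table(vectors.values(), item=item, cohort=cohort, T=config.T)
                )
            except EmptyTableError:
                logger.warning("item %s: no complete cases in cohort %s", item, cohort)
        if not cohort_tables:
            exclusions.append((item, "no_complete_cases"))
            continue
        pooled_table = pool_tables(cohort_tables, cohort=POOLED_LABEL)
        flags = assess_item_eligibility(pooled_table, miss_frac, config.missing_threshold)
        if not flags.eligible:
            logger.info("item %s excluded: %s (missing fraction %.3f)", item, flags.reason, miss_frac)
            exclusions.append((item, flags.reason))
            continue
        tables = list(cohort_tables) + ([pooled_table] if config.pooled else [])
        for table in tables:
            results.append(
                fit_item(
                    table,
                    pi_cutoff=config.pi_cutoff,
                    di_cutoff=config.di_cutoff,
                    error_model=config.error_model,
                )
            )

    if not results:
        raise EmptyTableError("no eligible items in the input")

    summary = _summarize(results, exclusions, cohorts, config)
    return AnalysisReport(results=tuple(results), exclusions=tuple(exclusions), summary=summary)


def _summarize(results, exclusions, cohorts, config: RunConfig) -> Dict:
    labels = list(cohorts) + ([POOLED_LABEL] if config.pooled else [])
    per_cohort = {}
    for label in labels:
        rs = [r for r in results if r.cohort == label]
        per_cohort[label] = {
            "items_analyzed": len(rs),
            "items_fitting_pi": sum(1 for r in rs if r.fits_pi),
            "items_fitting_di": sum(1 for r in rs if r.fits_di),
            "di_nonconverged": sum(1 for r in rs if not r.di_converged),
        }
    return {
        "package_version": __version__,
        "parameters": {
            "T": config.T,
            "pi_cutoff": config.pi_cutoff,
            "di_cutoff": config.di_cutoff,
            "error_model": config.error_model,
            "pooled": config.pooled,
            "seed": config.seed,
            "missing_threshold": config.missing_threshold,
        },
        "cohorts": per_cohort,
        "exclusions": [{"item": i, "reason": r} for i, r in exclusions],
        "em_iterations": {
            f"{r.item}/{r.cohort}": r.em_iterations for r in results
        },
    }


def format_value(x: Optional[float]) -> str:
    """Report formatting: three decimals, matching the result tables."""
    if x is None:
        return DI_NONCONVERGED_MARKER
    return f"{x:.3f}"


def _wide_table(results: Sequence[FitResult], value) -> pd.DataFrame:
    items = sorted({r.item for r in results})
    cohorts = sorted({r.cohort for r in results})
    if POOLED_LABEL in cohorts:  # pooled column first, like a headline column
        cohorts = [POOLED_LABEL] + [c for c in cohorts if c != POOLED_LABEL]
    by_key = {(r.item, r.cohort): r for r in results}
    data = {
        cohort: [
            value(by_key[(item, cohort)]) if (item, cohort) in by_key else ""
            for item in items
        ]
        for cohort in cohorts
    }
    return pd.DataFrame(data, index=pd.Index(items, name="item"))


def write_fit_tables(results: Sequence[FitResult], out: Path) -> Dict[str, Path]:
    """Write the result CSVs for one run; returns the paths written."""
    if not results:
        raise ValueError("no results to write")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    long_rows = [
        {
            "item": r.item,
            "cohort": r.cohort,
            "N": r.N,
            "pi_star": r.pi_star,
            "pi_star_se": r.pi_star_se,
            "di": r.di if r.di is not None else "",
            "di_converged": r.di_converged,
            "fits_pi": r.fits_pi,
            "fits_di": r.fits_di if r.fits_di is not None else "",
            "em_iterations": r.em_iterations,
        }
        for r in sorted(results, key=lambda r: (r.item, r.cohort))
    ]
    paths = {}
    long_path = out / "fit_results.csv"
    pd.DataFrame(long_rows).to_csv(long_path, index=False)
    paths["fit_results"] = long_path

    pi_table = _wide_table(
        results, lambda r: f"{format_value(r.pi_star)} ({format_value(r.pi_star_se)})"
    )
    pi_path = out / "pi_star_table.csv"
    pi_table.to_csv(pi_path)
    paths["pi_star_table"] = pi_path

    di_table = _wide_table(results, lambda r: format_value(r.di))
    di_path = out / "di_table.csv"
    di_table.to_csv(di_path)
    paths["di_table"] = di_path
    return paths


def write_run_summary(report: AnalysisReport, out: Path) -> Path:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "run_summary.json"
    with open(path, "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
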