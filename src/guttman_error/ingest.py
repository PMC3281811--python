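"""Reading long-format item responses, recoding to 0/1, and tabulating patterns.

Input is a long-format table with one row per (subject, item, visit):
``subject_id, cohort, item, visit, score``.  Raw scores are dichotomized so
that perfect performance is "correct" (1) and anything less is 0, then each
subject's per-item responses over the ``T`` visits are tallied into a
:class:`PatternTable` of counts over the canonical pattern order.  Analysis
is complete-case per item: a subject missing any of the ``T`` responses for
an item is dropped from that item's table only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .patterns import GuttmanPatternSet, ResponseVector, enumerate_patterns

__all__ = [
    "DataValidationError",
    "DataIntegrityError",
    "EmptyTableError",
    "RecodingRule",
    "PatternTable",
    "EligibilityFlags",
    "read_responses",
    "dichotomize_item",
    "build_pattern_table",
    "pool_tables",
    "assess_item_eligibility",
    "item_vectors",
    "raw_missing_fraction",
    "DEFAULT_COLUMNS",
    "DEFAULT_MISSING_CODES",
    "POOLED_LABEL",
]

logger = logging.getLogger(__name__)

DEFAULT_COLUMNS: Mapping[str, str] = {
    "subject_id": "subject_id",
    "cohort": "cohort",
    "item": "item",
    "visit": "visit",
    "score": "score",
}
DEFAULT_MISSING_CODES: Tuple[str, ...] = ("", "NA", "N/A", "NaN", "nan", ".")

#: Cohort label used for tables pooled over all cohorts.
POOLED_LABEL = "all"

RECODING_MODES = ("dichotomize_perfect", "already_binary", "split_points")


class DataValidationError(ValueError):
    """Malformed input file: missing columns, bad cells, duplicate rows."""


class DataIntegrityError(ValueError):
    """Data contradicts its recoding rule (e.g. score above the stated maximum)."""


class EmptyTableError(ValueError):
    """No complete-case subjects remain for an item."""


def read_responses(
    path,
    columns: Optional[Mapping[str, str]] = None,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
) -> pd.DataFrame:
    """Read a long-format response CSV into a normalized DataFrame.

    Parameters
    ----------
    path : path-like
        CSV with one row per (subject, item, visit).
    columns : mapping, optional
        Maps canonical names (``subject_id``, ``cohort``, ``item``,
        ``visit``, ``score``) to the file's column names.
    missing_codes : sequence of str
        Score cells equal to any of these (after stripping whitespace) are
        treated as missing.

    Returns a DataFrame with canonical column names, integer ``visit`` and
    float ``score`` (NaN = missing).  Duplicate (subject, item, visit) rows
    and unparseable cells raise :class:`DataValidationError` naming the
    offending data rows (1-based, excluding the header).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [src for src in colmap.values() if src not in raw.columns]
    if missing_cols:
        raise DataValidationError(
            f"input file {path} lacks required column(s): {', '.join(missing_cols)}"
        )
    df = pd.DataFrame(
        {canon: raw[src].astype(str).str.strip() for canon, src in colmap.items()}
    )

    codes = {str(c).strip() for c in missing_codes}
    score_raw = df["score"].where(~df["score"].isin(codes), other=np.nan)
    score = pd.to_numeric(score_raw, errors="coerce")
    bad_score = score.isna() & score_raw.notna()
    if bad_score.any():
        rows = _row_numbers(bad_score)
        raise DataValidationError(f"unparseable score values at data row(s) {rows}")

    visit = pd.to_numeric(df["visit"], errors="coerce")
    bad_visit = visit.isna() | (visit != visit.round()) | (visit < 1)
    if bad_visit.any():
        rows = _row_numbers(bad_visit)
        raise DataValidationError(
            f"visit must be an integer >= 1; bad values at data row(s) {rows}"
        )

    out = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "cohort": df["cohort"],
            "item": df["item"],
            "visit": visit.astype(int),
            "score": score.astype(float),
        }
    )
    dup = out.duplicated(subset=["subject_id", "item", "visit"], keep=False)
    if dup.any():
        rows = _row_numbers(dup)
        raise DataValidationError(
            f"duplicate (subject, item, visit) rows at data row(s) {rows}"
        )
    return out


def _row_numbers(mask: pd.Series, limit: int = 20) -> str:
    rows = [str(i + 1) for i in np.flatnonzero(mask.to_numpy())][:limit]
    suffix = ", ..." if int(mask.sum()) > limit else ""
    return ", ".join(rows) + suffix


@dataclass(frozen=True)
class RecodingRule:
    """How to turn one item's raw scores into 0/1.

    ``dichotomize_perfect``: ``score == max_score`` -> 1, anything below -> 0
    (perfect performance counts as correct).  ``already_binary`` passes 0/1
    through unchanged.  ``split_points`` marks an item whose points were
    split upstream into separate item labels; responses must already be 0/1.
    """

    item: str
    mode: str = "dichotomize_perfect"
    max_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in RECODING_MODES:
            raise ValueError(f"unknown recoding mode {self.mode!r}; expected one of {RECODING_MODES}")
        if self.mode == "dichotomize_perfect":
            if self.max_score is None or self.max_score < 1:
                raise ValueError("dichotomize_perfect requires max_score >= 1")


def dichotomize_item(scores: Sequence, rule: RecodingRule) -> ResponseVector:
    """Recode one subject's raw per-visit scores for one item to 0/1.

    Missing scores stay missing.  A score above ``rule.max_score`` raises
    :class:`DataIntegrityError`.
    """
    values = []
    for s in scores:
        if s is None or (isinstance(s, float) and np.isnan(s)):
            values.append(None)
            continue
        x = float(s)
        if rule.mode == "dichotomize_perfect":
            if x > rule.max_score:  # type: ignore[operator]
                raise DataIntegrityError(
                    f"item {rule.item!r}: score {x} exceeds declared maximum {rule.max_score}"
                )
            if x < 0:
                raise DataIntegrityError(f"item {rule.item!r}: negative score {x}")
            values.append(1 if x == rule.max_score else 0)
        else:
            if x not in (0.0, 1.0):
                raise DataIntegrityError(
                    f"item {rule.item!r}: expected 0/1 responses, got {x}"
                )
            values.append(int(x))
    return ResponseVector(tuple(values))


@dataclass(frozen=True, eq=False)
class PatternTable:
    """Counts of complete-case response patterns for one item in one cohort.

    ``counts`` is indexed against ``enumerate_patterns(T).all_patterns`` and
    sums to ``N``, the complete-case sample size.
    """

    item: str
    cohort: str
    T: int
    counts: np.ndarray
    N: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64).copy()
        if counts.ndim != 1 or counts.shape[0] != 2**self.T:
            raise ValueError(f"counts must have length 2**T = {2**self.T}")
        if (counts < 0).any():
            raise ValueError("pattern counts must be non-negative")
        if counts.sum() != self.N:
            raise ValueError(f"counts sum to {counts.sum()} but N = {self.N}")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def pattern_set(self) -> GuttmanPatternSet:
        return enumerate_patterns(self.T)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.N

    @property
    def n_distinct_patterns(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def forbidden_count(self) -> int:
        return int(self.counts[~self.pattern_set.permitted_mask].sum())


def build_pattern_table(
    vectors: Iterable,
    item: str = "item",
    cohort: str = POOLED_LABEL,
    T: Optional[int] = None,
) -> PatternTable:
    """Tally complete-case response vectors into a pattern table.

    Subjects with any missing entry are excluded (complete-case per item).
    Raises :class:`EmptyTableError` if no complete vector remains.
    """
    vecs = [v if isinstance(v, ResponseVector) else ResponseVector(tuple(v)) for v in vectors]
    if T is None:
        if not vecs:
            raise EmptyTableError(f"item {item!r}, cohort {cohort!r}: no subjects supplied")
        T = vecs[0].T
    lengths = {v.T for v in vecs}
    if lengths and lengths != {T}:
        raise ValueError(f"mixed vector lengths {sorted(lengths)}; expected T={T}")
    ps = enumerate_patterns(T)
    counts = np.zeros(ps.n_patterns, dtype=np.int64)
    dropped = 0
    for v in vecs:
        if v.is_complete:
            counts[ps.index(v.pattern())] += 1
        else:
            dropped += 1
    N = int(counts.sum())
    if N == 0:
        raise EmptyTableError(
            f"item {item!r}, cohort {cohort!r}: no complete-case subjects over {T} visits"
        )
    if dropped:
        logger.info(
            "item %s cohort %s: dropped %d incomplete subject(s), kept %d", item, cohort, dropped, N
        )
    return PatternTable(item=item, cohort=cohort, T=T, counts=counts, N=N)


def pool_tables(tables: Sequence[PatternTable], cohort: str = POOLED_LABEL) -> PatternTable:
    """Elementwise sum of per-cohort tables for the same item (pooled analysis)."""
    if not tables:
        raise EmptyTableError("no tables to pool")
    item = tables[0].item
    T = tables[0].T
    if any(t.item != item or t.T != T for t in tables):
        raise ValueError("can only pool tables for the same item and visit count")
    counts = np.sum([t.counts for t in tables], axis=0)
    return PatternTable(item=item, cohort=cohort, T=T, counts=counts, N=int(counts.sum()))


@dataclass(frozen=True)
class EligibilityFlags:
    """Screening outcome for one item before model fitting."""

    excluded_missing: bool
    insufficient_variability: bool

    @property
    def eligible(self) -> bool:
        return not (self.excluded_missing or self.insufficient_variability)

    @property
    def reason(self) -> str:
        if self.excluded_missing:
            return "excluded_missing"
        if self.insufficient_variability:
            return "insufficient_variability"
        return "eligible"


def assess_item_eligibility(
    table: PatternTable,
    raw_missing_fraction: float,
    missing_threshold: float = 0.05,
) -> EligibilityFlags:
    """Screen an item for analysis.

    Items with ``raw_missing_fraction >= missing_threshold`` (default 5%,
    computed on raw responses before complete-case filtering) are excluded;
    items whose table shows fewer than two distinct patterns cannot support
    a fit and are flagged ``insufficient_variability``.
    """
    return EligibilityFlags(
        excluded_missing=bool(raw_missing_fraction >= missing_threshold),
        insufficient_variability=table.n_distinct_patterns < 2,
    )


# ---------------------------------------------------------------------------
# DataFrame helpers used by the pipeline / CLI


def item_vectors(
    df: pd.DataFrame,
    item: str,
    rule: RecodingRule,
    T: int,
    cohort: Optional[str] = None,
) -> Dict[str, ResponseVector]:
    """Per-subject recoded response vectors for one item (visits 1..T).

    Visits absent from the file count as missing.  Subject order is sorted
    for determinism.
    """
    sub = df[df["item"] == item]
    if cohort is not None:
        sub = sub[sub["cohort"] == cohort]
    out: Dict[str, ResponseVector] = {}
    scores_by_subject: Dict[str, Dict[int, float]] = {}
    for row in sub.itertuples(index=False):
        if 1 <= row.visit <= T:
            scores_by_subject.setdefault(row.subject_id, {})[row.visit] = row.score
    for subject in sorted(scores_by_subject):
        visits = scores_by_subject[subject]
        scores = [visits.get(t, np.nan) for t in range(1, T + 1)]
        out[subject] = dichotomize_item(scores, rule)
    return out


def raw_missing_fraction(df: pd.DataFrame, item: str, T: int) -> float:
    """Fraction of missing raw responses for an item over visits 1..T.

    Denominator is (subjects appearing for the item) x T; absent visit rows
    and blank score cells both count as missing.  Computed before any
    complete-case filtering.
    """
    sub = df[(df["item"] == item) & (df["visit"] >= 1) & (df["visit"] <= T)]
    subjects = sub["subject_id"].unique()
    if len(subjects) == 0:
        return 1.0
    slots = len(subjects) * T
    observed = int(sub["score"].notna().sum())
    return (slots - observed) / slots
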