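"""Enumeration and classification of binary response patterns over repeated visits.

A test item followed over ``T`` visits yields a length-``T`` vector of 0/1
responses.  Under a longitudinal Guttman ("real loss") model the latent
ability probed by the item, once lost, is never regained: an incorrect
response at one visit rules out a correct response at any later visit.  The
only error-free observable patterns are therefore the monotone
non-increasing ones, ``1...1 0...0``.  For ``T`` visits there are exactly
``T + 1`` such *permitted* patterns among the ``2**T`` possibilities; every
other pattern shows a correct answer after an incorrect one and is
*forbidden* — its observed mass is what this package treats as measurement
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Pattern",
    "ResponseVector",
    "GuttmanPatternSet",
    "enumerate_patterns",
    "is_guttman_consistent",
    "format_pattern",
]

Pattern = Tuple[int, ...]


def format_pattern(pattern: Sequence[int]) -> str:
    """Render a 0/1 pattern as a compact string such as ``"1110"``."""
    return "".join("1" if int(b) else "0" for b in pattern)


def _coerce_entry(value) -> Optional[int]:
    """Normalize one response entry to 0, 1 or ``None`` (missing)."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    try:
        as_float = float(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"response entry {value!r} is not 0, 1 or missing") from exc
    if math.isnan(as_float):
        return None
    if as_float not in (0.0, 1.0):
        raise ValueError(f"response entry {value!r} is not 0, 1 or missing")
    return int(as_float)


@dataclass(frozen=True)
class ResponseVector:
    """One subject's 0/1 answers to one item over ``T`` visits.

    Entries are 0, 1 or ``None`` (missing); ``float('nan')`` is accepted and
    normalized to ``None`` on construction.
    """

    values: Tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        values = tuple(_coerce_entry(v) for v in self.values)
        if len(values) == 0:
            raise ValueError("a response vector needs at least one visit")
        object.__setattr__(self, "values", values)

    @property
    def T(self) -> int:
        return len(self.values)

    @property
    def is_complete(self) -> bool:
        return all(v is not None for v in self.values)

    def pattern(self) -> Pattern:
        """Return the complete 0/1 tuple; error if any entry is missing."""
        if not self.is_complete:
            raise ValueError("response vector has missing entries")
        return tuple(int(v) for v in self.values)  # type: ignore[arg-type]

    def __str__(self) -> str:  # pragma: no cover - display helper
        return "".join("." if v is None else str(v) for v in self.values)


@dataclass(frozen=True, eq=False)
class GuttmanPatternSet:
    """All ``2**T`` binary patterns for ``T`` visits, split into the
    permitted (monotone non-increasing) and forbidden subsets.

    Patterns are kept in a fixed canonical order — descending lexicographic,
    1 sorting before 0 — so that count vectors, fitted probabilities and
    reports index identically everywhere.
    """

    T: int
    all_patterns: Tuple[Pattern, ...]
    permitted: Tuple[Pattern, ...]
    forbidden: Tuple[Pattern, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {p: i for i, p in enumerate(self.all_patterns)}
        )
        mask = np.zeros(len(self.all_patterns), dtype=bool)
        for p in self.permitted:
            mask[self._index[p]] = True
        mask.setflags(write=False)
        object.__setattr__(self, "_permitted_mask", mask)

    @property
    def n_patterns(self) -> int:
        return len(self.all_patterns)

    @property
    def permitted_mask(self) -> np.ndarray:
        """Boolean mask over ``all_patterns`` marking the permitted subset."""
        return self._permitted_mask  # type: ignore[attr-defined]

    def index(self, pattern: Sequence[int]) -> int:
        """Canonical position of ``pattern`` within ``all_patterns``."""
        key = tuple(int(b) for b in pattern)
        try:
            return self._index[key]  # type: ignore[attr-defined]
        except KeyError as exc:
            raise KeyError(f"{format_pattern(key)} is not a length-{self.T} pattern") from exc


def _is_monotone_nonincreasing(pattern: Sequence[int]) -> bool:
    seen_zero = False
    for bit in pattern:
        if bit == 0:
            seen_zero = True
        elif seen_zero:
            return False
    return True


@lru_cache(maxsize=None)
def enumerate_patterns(T: int) -> GuttmanPatternSet:
    """Enumerate all binary response patterns for ``T`` visits.

    Returns the full set of ``2**T`` patterns in canonical (descending
    lexicographic) order together with the ``T + 1`` permitted patterns,
    ordered by decreasing total score, and their forbidden complement.

    Raises
    ------
    TypeError
        if ``T`` is not an integer.
    ValueError
        if ``T < 1``.
    """
    if isinstance(T, bool) or not isinstance(T, (int, np.integer)):
        raise TypeError(f"visit count T must be an integer, got {T!r}")
    if T < 1:
        raise ValueError(f"visit count T must be >= 1, got {T}")
    T = int(T)
    all_patterns = tuple(
        tuple((m >> (T - 1 - i)) & 1 for i in range(T)) for m in range(2**T - 1, -1, -1)
    )
    permitted = tuple(p for p in all_patterns if _is_monotone_nonincreasing(p))
    forbidden = tuple(p for p in all_patterns if not _is_monotone_nonincreasing(p))
    return GuttmanPatternSet(T=T, all_patterns=all_patterns, permitted=permitted, forbidden=forbidden)


def is_guttman_consistent(v) -> bool:
    """Whether a complete response vector fits the "once lost, never
    regained" model, i.e. has no 0 followed by a later 1.

    ``v`` may be a :class:`ResponseVector` or any 0/1 sequence.  Missing
    entries are a caller error: apply complete-case filtering first.
    """
    if isinstance(v, ResponseVector):
        values = v.values
    else:
        values = tuple(_coerce_entry(x) for x in v)
    if any(x is None for x in values):
        raise ValueError("response vector has missing entries; filter to complete cases first")
    return _is_monotone_nonincreasing(values)
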