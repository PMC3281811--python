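"""Synthetic cohorts with latent monotone loss plus response error.

Each subject's latent ability for an item follows a discrete-time absorbing
loss process: intact at visit 1 with probability ``p0``, and an intact
ability is lost between consecutive visits with hazard ``h`` (never
regained).  The observed 0/1 response flips the latent state independently
at each visit with probability ``eps``, and single responses go missing
completely at random with probability ``missing_rate``.  With ``eps = 0``
every observed pattern is permitted, so all measured error is attributable
to the response-error channel.

The module also provides the exact distribution over observed patterns
implied by ``(p0, h, eps)`` — the oracle the simulator and the model-fitting
code are tested against — and preset three-cohort scenarios emulating a
cognitively normal group, a converter group, and an impaired (AD-like)
group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .patterns import enumerate_patterns

__all__ = [
    "ItemParams",
    "CohortSimSpec",
    "exact_pattern_distribution",
    "forbidden_mass",
    "simulate_cohort",
    "preset_cohort_specs",
    "SCENARIOS",
]


def _check_prob(name: str, value: float, upper: float = 1.0) -> float:
    value = float(value)
    if not 0.0 <= value <= upper:
        raise ValueError(f"{name} must lie in [0, {upper}], got {value}")
    return value


@dataclass(frozen=True)
class ItemParams:
    """Generator parameters for one item.

    p0: probability the ability is intact at visit 1.
    h: per-visit loss hazard given intact (absorbing).
    eps: response-error rate — probability an observed response flips the
         latent state, independently per visit (must be <= 0.5).
    """

    name: str
    p0: float
    h: float
    eps: float

    def __post_init__(self) -> None:
        _check_prob("p0", self.p0)
        _check_prob("h", self.h)
        _check_prob("eps", self.eps, upper=0.5)


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters for one simulated cohort."""

    n: int
    T: int
    items: Tuple[ItemParams, ...]
    cohort_label: str
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.T < 1:
            raise ValueError("n and T must be positive")
        _check_prob("missing_rate", self.missing_rate)
        object.__setattr__(self, "items", tuple(self.items))

    def to_dict(self) -> Dict:
        """Plain-dict form, serializable to the YAML/JSON config dialect."""
        return {
            "n": self.n,
            "T": self.T,
            "cohort_label": self.cohort_label,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "items": [
                {"name": i.name, "p0": i.p0, "h": i.h, "eps": i.eps} for i in self.items
            ],
        }


def _loss_time_weights(p0: float, h: float, T: int) -> np.ndarray:
    """P(latent pattern = intact through visit k) for k = 0..T.

    k = 0 is "lost before visit 1" (probability 1 - p0); k = T is "intact
    throughout" (p0 (1-h)^(T-1)); in between, p0 (1-h)^(k-1) h.
    """
    w = np.empty(T + 1)
    w[0] = 1.0 - p0
    for k in range(1, T):
        w[k] = p0 * (1.0 - h) ** (k - 1) * h
    w[T] = p0 * (1.0 - h) ** (T - 1)
    return w


def exact_pattern_distribution(p0: float, h: float, eps: float, T: int) -> np.ndarray:
    """Exact probability of each observed pattern (canonical order).

    Marginalizes the loss time and the independent per-visit response flips:
    P(y) = sum_k  P(loss time k) * eps**d(y, s_k) * (1-eps)**(T - d(y, s_k)),
    where s_k is the latent pattern intact through visit k.
    """
    _check_prob("p0", p0)
    _check_prob("h", h)
    _check_prob("eps", eps, upper=0.5)
    ps = enumerate_patterns(T)
    Y = np.asarray(ps.all_patterns)               # (P, T)
    # permitted patterns are in decreasing-score order; reorder to k = 0..T
    S = np.asarray(ps.permitted)[::-1]            # (T+1, T), row k has score k
    w = _loss_time_weights(p0, h, T)
    d = (Y[:, None, :] != S[None, :, :]).sum(axis=2)   # (P, T+1)
    probs = (w[None, :] * eps**d * (1.0 - eps) ** (T - d)).sum(axis=1)
    return probs


def forbidden_mass(p0: float, h: float, eps: float, T: int) -> float:
    """Total probability of forbidden (non-monotone) observed patterns."""
    probs = exact_pattern_distribution(p0, h, eps, T)
    mask = enumerate_patterns(T).permitted_mask
    return float(probs[~mask].sum())


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw one cohort as a long-format response table.

    Returns a DataFrame with columns ``subject_id, cohort, item, visit,
    score`` (score is 0/1, NaN where the response went missing).  Identical
    specs, including the seed, give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    subjects = np.array([f"{spec.cohort_label}-{i:05d}" for i in range(1, spec.n + 1)])
    for item in spec.items:
        intact = rng.random(spec.n) < item.p0
        latent = np.empty((spec.n, spec.T), dtype=np.int64)
        state = intact.copy()
        latent[:, 0] = state
        for t in range(1, spec.T):
            state &= rng.random(spec.n) >= item.h
            latent[:, t] = state
        flips = rng.random((spec.n, spec.T)) < item.eps
        observed = np.where(flips, 1 - latent, latent).astype(float)
        if spec.missing_rate > 0:
            observed[rng.random((spec.n, spec.T)) < spec.missing_rate] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subjects, spec.T),
                    "cohort": spec.cohort_label,
                    "item": item.name,
                    "visit": np.tile(np.arange(1, spec.T + 1), spec.n),
                    "score": observed.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Preset scenarios

#: Base per-item response-error rates, loosely spanning the range seen in
#: item-level analyses of brief cognitive batteries: orientation and command
#: items are nearly error-free, delayed recall and serial tasks are noisy.
_BASE_ITEM_EPS: Tuple[Tuple[str, float], ...] = (
    ("orient_year", 0.003),
    ("orient_season", 0.035),
    ("orient_date", 0.080),
    ("naming_pencil", 0.002),
    ("recall_3word", 0.130),
    ("spell_world", 0.080),
    ("read_command", 0.009),
    ("write_sentence", 0.012),
)

#: Cohort-level latent-process parameters: (p0, h, eps multiplier).  The
#: error multiplier rises with impairment, encoding the phenomenon the
#: method is designed to detect (error not independent of ability level);
#: the "constant_error" scenario sets all multipliers to 1 as the classical
#: test theory null.
_COHORT_PROFILES: Tuple[Tuple[str, float, float, float], ...] = (
    ("nc", 0.995, 0.005, 1.0),
    ("converter", 0.98, 0.03, 1.6),
    ("ad", 0.85, 0.12, 3.0),
)

#: Default cohort sizes (complete-case scale of typical ageing registries).
_DEFAULT_NS: Tuple[int, int, int] = (149, 133, 78)

SCENARIOS = ("default", "constant_error", "error_free")


def preset_cohort_specs(
    scenario: str = "default",
    seed: int = 0,
    n: Tuple[int, int, int] = _DEFAULT_NS,
    T: int = 4,
    missing_rate: float = 0.01,
) -> Tuple[CohortSimSpec, CohortSimSpec, CohortSimSpec]:
    """Three-cohort presets: stable NC-like, slowly declining converter-like,
    steeply declining AD-like.

    Scenarios: ``default`` (error rate grows with impairment),
    ``constant_error`` (same per-item error in every cohort), and
    ``error_free`` (eps = 0 and no missingness everywhere, so every fitted
    item is error-free by construction).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    seeds = [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(3)]
    specs = []
    for (label, p0, h, mult), n_c, s_c in zip(_COHORT_PROFILES, n, seeds):
        if scenario == "error_free":
            items = tuple(ItemParams(name, p0, h, 0.0) for name, _ in _BASE_ITEM_EPS)
            miss = 0.0
        else:
            m = 1.0 if scenario == "constant_error" else mult
            items = tuple(
                ItemParams(name, p0, h, min(eps * m, 0.45)) for name, eps in _BASE_ITEM_EPS
            )
            miss = missing_rate
        specs.append(
            CohortSimSpec(
                n=n_c, T=T, items=items, cohort_label=label, missing_rate=miss, seed=s_c
            )
        )
    return tuple(specs)  # type: ignore[return-value]
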