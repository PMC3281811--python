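# Methods

## The longitudinal Guttman model and what "error" means here

Each item is modeled separately, as a unidimensional measure of one ability
followed over `T` consecutive visits. The model is deterministic and
maximally restrictive: the ability is either present or absent, and once
absent it never returns. A subject's error-free response vector is therefore
`1` up to some visit and `0` afterwards — one of the `T + 1` monotone
non-increasing ("permitted") patterns, including the two stable ones (all
correct, all incorrect). Any observed pattern with a 0 followed by a later 1
("forbidden") cannot reflect real loss and is counted as measurement error.
The method deliberately does not distinguish error in the item from
fluctuation in the person; both break the "consistent signal" the model
demands.

## Statistics computed

**Mixture index of fit (π\*).** The general definition — represent the
population as a mixture `(1 − π) · model + π · anything`, and take the
smallest feasible `π` — reduces, for a deterministic family supported on the
permitted patterns, to the observed forbidden-pattern proportion. We compute
that closed form, and retain the defining optimization as a linear program
(maximize retainable mass `q(y) ≤ p_obs(y)` supported on permitted patterns,
solved with HiGHS through `scipy.optimize.linprog`) as an independent oracle;
the two agree to 1e−12 on randomized tables in the test suite.

**Standard error of π\*.** The binomial form `sqrt(π*(1 − π*)/N)` on the
complete-case `N`. A more elaborate asymptotic estimator exists in the
mixture-index literature; the binomial form is the package default because
the forbidden-pattern proportion is exactly a binomial proportion under this
family. It reproduces published item-level SEs computed at known cohort
sizes to printed precision (asserted in the acceptance tests). `π* = 0`
yields SE 0; the SE is symmetric in `π* ↔ 1 − π*` and maximal at 0.5.

**Restricted latent class model.** `T + 1` latent classes, one per permitted
pattern `s_c`, with a single misclassification rate `α` applied
independently at every visit (the fully constrained, Proctor-type scaling
model): `P(y) = Σ_c ω_c α^{d(y,s_c)} (1 − α)^{T − d(y,s_c)}`. The exact
historical parameterization used alongside the published tables is not
recoverable (the describing appendix is not in the available text), so this
canonical fully-constrained scaling model was chosen; it reproduces the
qualitative convergence behaviour reported there (single-pattern items
cannot be fit; homogeneous cohorts give boundary solutions). A per-visit
variant (`α_t`, `error_model="per_visit"`) is available but not the default.

*Estimation.* EM on pattern counts. E-step: posterior class
responsibilities. M-step, closed form: `ω_c` = mean responsibility; `α` =
responsibility-weighted mean Hamming mismatch per response
(`Σ n(y) r_{yc} d(y, s_c) / (N·T)`), clipped to `[1e−10, 0.5]`.
Initialization is deterministic — uniform `ω`, `α = 0.1` — so fits are
reproducible without seeds. Convergence: relative log-likelihood change
below 1e−8, cap 5000 iterations. The log-likelihood trace is recorded and
asserted non-decreasing. Flagged non-converged: iteration-cap hits;
single-pattern tables (no information to separate classes — reported as a
result, not an exception, since real analyses report such items); and
boundary solutions where `α` collapses to the floor while forbidden patterns
were observed (those observations would get essentially zero fitted
probability). Data supported entirely on permitted patterns converge
legitimately to `α = 0` with `ω` equal to the observed proportions.

**Dissimilarity index.** `DI = ½ Σ_y |p_obs(y) − p_fit(y)|` over all `2^T`
patterns — the fraction of observations that would need reallocating for
perfect agreement. Not computable (reported as a marker, `*` in tables) when
the latent class fit did not converge.

**Classification.** `π* < 0.10` and `DI < 0.05`, both strict inequalities
(so a printed 0.101 does not pass at 0.10) and both configurable. The
cutoffs are conventional rules of thumb, not inference tests.

## Ingest and screening

Input is long-format CSV (`subject_id, cohort, item, visit, score`), with
configurable column mapping and missing-value codes (blank, `NA`, ... at
read time). Recoding is per item: `dichotomize_perfect` scores only perfect
performance as 1 (a score above the declared maximum is a data-integrity
error, not silently clipped); `already_binary` passes 0/1 through; items
whose points are analyzed separately are split upstream into separate item
labels rather than by a transform. Missingness is handled per item,
complete-case over the `T` visits: a subject missing any response for an
item is dropped from that item's table only, which is why per-item `N` can
differ within a cohort. Screening happens before fitting: items with ≥5%
missing raw responses (computed per item over all subjects, before
complete-case filtering; the denominator is subjects-appearing-for-the-item
× `T`) are excluded, as are items with a single observed pattern. Pooled
("over all groups") analysis concatenates subjects before counting, so the
pooled π* is exactly the subject-weighted combination of cohort forbidden
counts.

## The synthetic-data generator

Real item-level registry data of this kind are not publicly deposited, so
the generator produces the statistical structure the method assumes plus the
one violation it measures:

- **Latent process**: discrete-time absorbing loss. Intact at visit 1 with
  probability `p0`; an intact ability is lost between consecutive visits
  with hazard `h`; never regained (geometric onset — the simplest process
  with the "once lost, never regained" semantics).
- **Response error**: each visit's observed response flips the latent state
  independently with probability `eps ≤ 0.5`, symmetric by default (the
  field distinguishes systematic from random error without parameterizing
  either; an asymmetric variant would be a trivial extension of
  `ItemParams`).
- **Missingness**: completely at random per response, because the
  complete-case machinery is the object under test, not missingness
  mechanisms.

`exact_pattern_distribution(p0, h, eps, T)` marginalizes loss time × flip
set in closed form and is the oracle the simulator and the EM are validated
against: Monte-Carlo forbidden mass agrees within binomial error, and EM on
model-generated data recovers `α` within ±0.02 at n = 5000.

**Preset scenarios.** Three cohorts mimic an ageing study: stable `nc`
(`p0 = 0.995, h = 0.005`), slowly declining `converter` (`0.98, 0.03`),
steeply declining `ad` (`0.85, 0.12`), with default sizes 149/133/78
(complete-case scale typical of such registries) and 1% missingness. Item
base error rates span 0.002–0.13, near-zero for naming/orientation-to-year
type items and high for delayed recall and serial tasks. In the `default`
scenario the error rate additionally rises with impairment (multipliers 1.0
/ 1.6 / 3.0, capped at 0.45) — the phenomenon the method exists to detect. A
deliberate modeling point: with `eps` held constant across cohorts the exact
forbidden mass *decreases* slightly with decline, because interior latent
patterns (e.g. `1100`) have only two forbidden Hamming-1 neighbours where
the stable patterns have three (≈2ε vs 3ε to first order). The
`constant_error` scenario keeps that constant-ε structure as the
classical-test-theory null; `error_free` sets `eps = 0` everywhere, making
every observed pattern permitted by construction. What passing tests on
these data do **not** show: robustness to practice effects, recovery or
fluctuation, informative dropout, or within-cohort heterogeneity in `eps` —
none of which the generator produces.

## Numerical and design choices

- Patterns are tuples of ints in a fixed canonical order (descending
  lexicographic, 1 before 0) so count vectors and reports are bit-stable;
  display formatting (`"1110"`) is a single routine.
- Class weights are floored at 1e−300 inside logs only (no renormalization);
  `α` lives in `[1e−10, 0.5]`.
- Reported tables round to 3 decimals; full precision is kept internally and
  in `fit_results.csv`.
- The CLI is deterministic given input and configuration: stable item/cohort
  ordering, no timestamps in outputs, seeded simulation; re-runs are
  byte-identical (asserted in tests).
- Problem sizes in the test and acceptance suites (n = 5000 for recovery,
  n = 10000 for simulator agreement, 200 randomized tables for the LP
  sweep) are chosen so the statistical tolerances (±0.02 on `α`, 3 binomial
  SEs) are comfortably informative while the whole suite runs in seconds.

## Known limitations

- The model is intentionally restrictive; π* conflates item error with
  genuine within-person fluctuation and says nothing about recovery.
- The latent class parameterization is one defensible reconstruction of the
  fully-constrained scaling model; DI values from other restrictions (e.g.
  intrusion/omission error structures) would differ, so DI should be read as
  ancillary to π*.
- The binomial SE ignores the (deterministic-family) estimation of the
  permitted set; it is exact for the forbidden-proportion interpretation
  but not the general mixture-index asymptotics.
- Per-cohort tables with a single observed pattern yield π* but no DI;
  heavily homogeneous cohorts will show many `*` cells.
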