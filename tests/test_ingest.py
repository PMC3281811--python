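"""Reading long-format responses, recoding, and pattern tabulation."""

import numpy as np
import pandas as pd
import pytest

from guttman_error.ingest import (
    DataIntegrityError,
    DataValidationError,
    EmptyTableError,
    RecodingRule,
    assess_item_eligibility,
    build_pattern_table,
    dichotomize_item,
    item_vectors,
    pool_tables,
    raw_missing_fraction,
    read_responses,
)
from guttman_error.patterns import enumerate_patterns
from guttman_error.synth import preset_cohort_specs, simulate_cohort


def write_csv(tmp_path, rows, header="subject_id,cohort,item,visit,score"):
    path = tmp_path / "responses.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadResponses:
    def test_basic_parse(self, tmp_path):
        path = write_csv(
            tmp_path,
            [f"s1,nc,year,{t},{s}" for t, s in zip(range(1, 5), (1, 1, 0, 0))],
        )
        df = read_responses(path)
        assert len(df) == 4
        assert df["visit"].tolist() == [1, 2, 3, 4]
        assert df["score"].tolist() == [1.0, 1.0, 0.0, 0.0]

    def test_blank_and_sentinel_scores_become_missing(self, tmp_path):
        path = write_csv(tmp_path, ["s1,nc,year,1,", "s1,nc,year,2,NA", "s1,nc,year,3,1"])
        df = read_responses(path)
        assert df["score"].isna().tolist() == [True, True, False]

    def test_duplicate_rows_error_names_rows(self, tmp_path):
        path = write_csv(tmp_path, ["s1,nc,year,1,1", "s1,nc,year,1,0"])
        with pytest.raises(DataValidationError, match=r"row\(s\) 1, 2"):
            read_responses(path)

    def test_missing_column_error(self, tmp_path):
        path = write_csv(tmp_path, ["s1,nc,1,1"], header="subject_id,cohort,visit,score")
        with pytest.raises(DataValidationError, match="item"):
            read_responses(path)

    def test_unparseable_score_error(self, tmp_path):
        path = write_csv(tmp_path, ["s1,nc,year,1,oops"])
        with pytest.raises(DataValidationError, match="unparseable"):
            read_responses(path)

    def test_column_mapping(self, tmp_path):
        path = write_csv(tmp_path, ["s1,nc,year,1,1"], header="id,grp,q,wave,pts")
        df = read_responses(
            path,
            columns={"subject_id": "id", "cohort": "grp", "item": "q", "visit": "wave", "score": "pts"},
        )
        assert df.loc[0, "subject_id"] == "s1" and df.loc[0, "score"] == 1.0

    def test_synthetic_roundtrip(self, tmp_path):
        """A simulated cohort written to CSV reads back to identical records."""
        spec = preset_cohort_specs("default", seed=7)[1]
        df = simulate_cohort(spec)
        path = tmp_path / "sim.csv"
        df.to_csv(path, index=False)
        back = read_responses(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["subject_id", "item", "visit"]).reset_index(drop=True),
            df.sort_values(["subject_id", "item", "visit"]).reset_index(drop=True),
        )


class TestDichotomize:
    def test_perfect_score_recoding(self):
        rule = RecodingRule("spell_world", "dichotomize_perfect", max_score=5)
        assert dichotomize_item((5, 5, 4, 5), rule).values == (1, 1, 0, 1)

    def test_all_perfect(self):
        rule = RecodingRule("recall", "dichotomize_perfect", max_score=3)
        assert dichotomize_item((3, 3, 3, 3), rule).values == (1, 1, 1, 1)

    def test_missing_propagates(self):
        rule = RecodingRule("x", "dichotomize_perfect", max_score=2)
        assert dichotomize_item((2, np.nan, 0, 0), rule).values == (1, None, 0, 0)

    def test_score_above_max_is_integrity_error(self):
        rule = RecodingRule("x", "dichotomize_perfect", max_score=2)
        with pytest.raises(DataIntegrityError, match="exceeds"):
            dichotomize_item((3, 1, 1, 1), rule)

    def test_already_binary_passthrough_and_idempotence(self):
        rule = RecodingRule("x", "already_binary")
        v = dichotomize_item((1, 0, 1, 0), rule)
        assert v.values == (1, 0, 1, 0)
        assert dichotomize_item(v.values, rule).values == v.values
        with pytest.raises(DataIntegrityError):
            dichotomize_item((2, 0, 1, 1), rule)

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            RecodingRule("x", "dichotomize_perfect", max_score=None)
        with pytest.raises(ValueError):
            RecodingRule("x", "no_such_mode")


class TestPatternTable:
    def test_direct_tally(self):
        vectors = [(1, 1, 1, 1)] * 3 + [(1, 1, 0, 0)]
        table = build_pattern_table(vectors, item="year", cohort="nc")
        ps = enumerate_patterns(4)
        assert table.N == 4
        assert table.counts[ps.index((1, 1, 1, 1))] == 3
        assert table.counts[ps.index((1, 1, 0, 0))] == 1
        assert table.counts.sum() == 4

    def test_complete_case_drop(self):
        vectors = [(1, None, 0, 0), (1, 1, 1, 1), (1, 1, 1, 1)]
        table = build_pattern_table(vectors)
        assert table.N == 2

    def test_empty_table_error(self):
        with pytest.raises(EmptyTableError):
            build_pattern_table([(1, None, 0, 0)], item="x")
        with pytest.raises(EmptyTableError):
            build_pattern_table([], item="x")

    def test_invariant_under_subject_reordering(self, rng):
        vectors = [tuple(rng.integers(0, 2, 4)) for _ in range(50)]
        t1 = build_pattern_table(vectors)
        perm = rng.permutation(len(vectors))
        t2 = build_pattern_table([vectors[i] for i in perm])
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_pooled_equals_sum_of_cohorts(self, rng):
        """Pooling is concatenation of subjects before counting."""
        groups = {
            label: [tuple(rng.integers(0, 2, 4)) for _ in range(n)]
            for label, n in (("nc", 40), ("converter", 30), ("ad", 20))
        }
        tables = [build_pattern_table(v, item="x", cohort=c) for c, v in groups.items()]
        pooled = pool_tables(tables)
        concat = build_pattern_table(sum(groups.values(), []), item="x", cohort="all")
        np.testing.assert_array_equal(pooled.counts, concat.counts)
        assert pooled.N == sum(t.N for t in tables)


class TestEligibility:
    def test_high_missingness_excluded(self):
        table = build_pattern_table([(1, 1, 1, 1), (1, 1, 0, 0)])
        flags = assess_item_eligibility(table, raw_missing_fraction=0.10)
        assert flags.excluded_missing and not flags.eligible
        assert flags.reason == "excluded_missing"

    def test_single_pattern_insufficient_variability(self):
        table = build_pattern_table([(1, 1, 1, 1)] * 20)
        flags = assess_item_eligibility(table, raw_missing_fraction=0.0)
        assert flags.insufficient_variability and not flags.eligible

    def test_eligible(self):
        table = build_pattern_table([(1, 1, 1, 1), (1, 1, 0, 0)])
        flags = assess_item_eligibility(table, raw_missing_fraction=0.0)
        assert flags.eligible and flags.reason == "eligible"

    def test_threshold_is_inclusive(self):
        table = build_pattern_table([(1, 1, 1, 1), (1, 1, 0, 0)])
        assert assess_item_eligibility(table, 0.05).excluded_missing
        assert not assess_item_eligibility(table, 0.049).excluded_missing


def test_frame_helpers_missing_accounting(tmp_path):
    """Complete-case N plus dropped subjects equals total (conservation)."""
    rows = []
    for s, scores in (("a", (1, 1, 0, 0)), ("b", (1, None, 0, 0)), ("c", (1, 1, 1, 1))):
        for t, x in enumerate(scores, start=1):
            rows.append(f"{s},nc,year,{t},{'' if x is None else x}")
    path = write_csv(tmp_path, rows)
    df = read_responses(path)
    rule = RecodingRule("year", "already_binary")
    vectors = item_vectors(df, "year", rule, T=4)
    assert len(vectors) == 3
    table = build_pattern_table(vectors.values(), item="year")
    assert table.N + sum(1 for v in vectors.values() if not v.is_complete) == 3
    assert raw_missing_fraction(df, "year", 4) == pytest.approx(1 / 12)
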