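"""Hierarchical disagreement scoring: schema rules, penalties, the paired test."""

from itertools import product

import numpy as np
import pytest

from eegpress import concordance
from eegpress.concordance import (
    ScoreRecord,
    compare_to_baseline,
    disagreement,
    load_schema,
    numeric_disagree,
    pairwise_disagreements,
    summarize_disagreements,
    uniform_record,
)
from eegpress.exceptions import ParameterError, SchemaError, ScoringError


class TestSchema:
    def test_default_template_anchors(self, schema):
        assert schema.leaf_count == 45
        assert schema.total_max == 60
        assert schema.node("hx.seizure").penalty == 14
        assert schema.node("hx.seizure.location").penalty == 1
        assert schema.node("foc.slowing").penalty == 4
        assert schema.node("foc.slowing.lateralization").penalty == 3

    def test_default_template_has_three_categories(self, schema):
        assert set(schema.categories) == {
            "background", "focal", "hyperexcitability"
        }
        # sub-category counts: I.A-D, II.A-B, III.A-C
        assert [len(schema.categories[c]) for c in
                ("background", "focal", "hyperexcitability")] == [4, 2, 3]

    def test_cap_rule_violation_rejected(self):
        text = """
categories:
  - name: focal
    majors:
      - id: x.major
        response: binary
        penalty: 3
        children:
          - {id: x.a, response: binary, penalty: 2}
          - {id: x.b, response: binary, penalty: 2}
"""
        with pytest.raises(SchemaError, match="cap rule"):
            load_schema(text, require_standard=False)

    def test_wrong_leaf_count_rejected_when_standard_required(self):
        text = """
categories:
  - name: focal
    majors:
      - id: x.major
        response: binary
        penalty: 60
"""
        with pytest.raises(SchemaError, match="leaf"):
            load_schema(text)

    def test_duplicate_ids_rejected(self):
        text = """
categories:
  - name: focal
    majors:
      - {id: x, response: binary, penalty: 2}
      - {id: x, response: binary, penalty: 2}
"""
        with pytest.raises(SchemaError, match="duplicate"):
            load_schema(text, require_standard=False)


class TestNumericRule:
    def test_equal_values_agree(self):
        assert not numeric_disagree(5.0, 5.0)
        assert not numeric_disagree(0.0, 0.0)

    def test_twenty_percent_threshold_boundary(self):
        # symmetric relative difference: |x-y| / ((|x|+|y|)/2)
        assert numeric_disagree(100.0, 125.0)      # 25/112.5 ~ 0.222 > 0.2
        assert not numeric_disagree(100.0, 120.0)  # 20/110 ~ 0.182 < 0.2

    def test_symmetry(self):
        assert numeric_disagree(100.0, 125.0) == numeric_disagree(125.0, 100.0)

    def test_threshold_domain(self):
        with pytest.raises(ParameterError):
            numeric_disagree(1.0, 2.0, threshold=0.0)


class TestDisagreement:
    def test_identical_records_score_zero(self, schema):
        a = uniform_record(schema)
        assert disagreement(a, a, schema).omnibus == 0

    def test_all_major_disagreement_scores_sixty(self, schema):
        a = uniform_record(schema, binary=1, nominal_index=0, numeric=100.0)
        b = uniform_record(schema, binary=0, nominal_index=1, numeric=200.0)
        res = disagreement(a, b, schema)
        assert res.omnibus == 60
        # truncation stopped at the nine major features only
        assert sorted(res.truncated_at) == sorted(
            m.id for m in schema.majors()
        )

    @pytest.mark.parametrize(
        "feature, flip, expected",
        [
            ("hx.seizure", 0, 14),
            ("hx.seizure.location", "temporal", 1),
            ("foc.slowing", 0, 4),
            ("foc.slowing.lateralization", "left", 3),
        ],
    )
    def test_single_branch_flip_penalties(self, schema, feature, flip, expected):
        a = uniform_record(schema)
        b = uniform_record(schema, overrides={feature: flip})
        res = disagreement(a, b, schema)
        assert res.omnibus == expected
        assert res.per_feature_penalties == {feature: expected}

    def test_major_disagreement_suppresses_qualifier_penalties(self, schema):
        # records that disagree on seizure presence AND all its qualifiers
        # still score only the major's 14 for that branch
        overrides = {"hx.seizure": 0}
        for child in schema.node("hx.seizure").children:
            if child.response_type == "numeric":
                overrides[child.id] = 999.0
            elif child.response_type == "nominal":
                overrides[child.id] = child.nominal_levels[-1]
            else:
                overrides[child.id] = 0
        a = uniform_record(schema)
        b = uniform_record(schema, overrides=overrides)
        assert disagreement(a, b, schema).omnibus == 14

    def test_missing_response_names_the_feature(self, schema):
        a = uniform_record(schema)
        b = uniform_record(schema)
        del b.responses["bg.continuity"]
        with pytest.raises(ScoringError, match="bg.continuity"):
            disagreement(a, b, schema)

    def test_symmetric_and_bounded_on_random_records(self, schema, rng):
        nodes = list(schema.iter_nodes())
        for _ in range(25):
            def random_record():
                responses = {}
                for node in nodes:
                    if node.response_type == "binary":
                        responses[node.id] = int(rng.integers(2))
                    elif node.response_type == "nominal":
                        responses[node.id] = str(
                            rng.choice(node.nominal_levels)
                        )
                    else:
                        responses[node.id] = float(rng.choice([50, 100, 130]))
                return ScoreRecord(responses)

            a, b = random_record(), random_record()
            ab = disagreement(a, b, schema)
            ba = disagreement(b, a, schema)
            assert ab.omnibus == ba.omnibus
            assert 0 <= ab.omnibus <= 60


class TestToySchemaOracle:
    """Brute-force enumeration against a literal restatement of the rules."""

    @staticmethod
    def _oracle(ra, rb):
        def num_differs(x, y):
            if x == y:
                return False
            denom = (abs(x) + abs(y)) / 2.0
            return denom > 0 and abs(x - y) / denom > 0.20

        if ra["t.major"] != rb["t.major"]:
            return 6
        if not (ra["t.major"] == 1 and rb["t.major"] == 1):
            return 0
        total = 0
        if ra["t.q1"] != rb["t.q1"]:
            total += 2  # branch truncated: nested numeric never reached
        elif num_differs(ra["t.q1.sub"], rb["t.q1.sub"]):
            total += 1
        if num_differs(ra["t.q2"], rb["t.q2"]):
            total += 2
        return total

    def test_exhaustive_patterns_match_oracle(self, toy_schema):
        majors = (0, 1)
        q1s = ("a", "b")
        subs = (100.0, 130.0)   # 30/115 ~ 0.26: disagree
        q2s = (100.0, 105.0, 200.0)
        space = list(product(majors, q1s, subs, q2s))
        for pa in space:
            for pb in space:
                ra = dict(zip(("t.major", "t.q1", "t.q1.sub", "t.q2"), pa))
                rb = dict(zip(("t.major", "t.q1", "t.q1.sub", "t.q2"), pb))
                got = disagreement(
                    ScoreRecord(ra), ScoreRecord(rb), toy_schema
                ).omnibus
                assert got == self._oracle(ra, rb), (pa, pb)

    def test_branch_never_exceeds_major_penalty(self, toy_schema):
        a = ScoreRecord({"t.major": 1, "t.q1": "a", "t.q1.sub": 100.0,
                         "t.q2": 100.0})
        b = ScoreRecord({"t.major": 1, "t.q1": "b", "t.q1.sub": 999.0,
                         "t.q2": 999.0})
        assert disagreement(a, b, toy_schema).omnibus <= 6


class TestPairwiseTable:
    def _scores(self, schema, n_subjects, comp_overrides=None):
        out = {}
        for i in range(n_subjects):
            base = uniform_record(schema)
            comp = uniform_record(schema, overrides=comp_overrides or {})
            out[f"S{i}"] = {
                "ORIG1": base, "ORIG2": base, "COMP1": comp, "COMP2": comp
            }
        return out

    def test_all_identical_records_give_zero_table(self, schema):
        table = pairwise_disagreements(self._scores(schema, 4), schema)
        assert table.shape == (4, 5)
        assert list(table.columns) == ["O11", "D11", "D12", "D21", "D22"]
        assert (table.values == 0).all()

    def test_five_scores_per_subject(self, schema):
        table = pairwise_disagreements(self._scores(schema, 50), schema)
        assert table.size == 250

    def test_seizure_flip_in_reconstructions_raises_d_columns_by_14(self, schema):
        table = pairwise_disagreements(
            self._scores(schema, 6, comp_overrides={"hx.seizure": 0}), schema
        )
        med = table.median()
        assert med["O11"] == 0
        for col in ("D11", "D12", "D21", "D22"):
            assert med[col] == med["O11"] + 14

    def test_incomplete_subject_skipped_with_warning(self, schema):
        scores = self._scores(schema, 3)
        del scores["S1"]["COMP2"]
        with pytest.warns(UserWarning, match="S1"):
            table = pairwise_disagreements(scores, schema)
        assert len(table) == 2

    def test_summary_reports_median_and_iqr(self, schema):
        table = pairwise_disagreements(
            self._scores(schema, 5, comp_overrides={"foc.slowing": 0}), schema
        )
        summary = summarize_disagreements(table)
        assert summary.loc["D11", "median"] == 4
        assert summary.loc["O11", "IQR"] == 0


class TestWilcoxon:
    def test_statistic_and_p_match_exhaustive_enumeration(self):
        o11 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        dxy = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        res = compare_to_baseline(o11, dxy)
        diffs = o11 - dxy
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = float(np.sum(ranks[diffs > 0]))
        assert res.statistic == w_obs
        # exact null: enumerate all 2^5 sign assignments of the ranks
        w_all = [
            float(np.sum(ranks[np.array(signs, bool)]))
            for signs in product([0, 1], repeat=5)
        ]
        p_exact = np.mean([w <= w_obs for w in w_all])
        assert res.pvalue == pytest.approx(p_exact)
        assert res.n_effective == 5 and not res.degenerate

    def test_identical_samples_degenerate_p_one(self):
        res = compare_to_baseline([3.0, 4.0], [3.0, 4.0])
        assert res.pvalue == 1.0 and res.degenerate

    def test_single_informative_pair_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = compare_to_baseline([1.0, 2.0], [1.0, 5.0])
        assert res.degenerate

    def test_baseline_larger_gives_large_p(self):
        res = compare_to_baseline([10.0, 11.0, 12.0, 13.0], [1.0, 2.0, 3.0, 4.0])
        assert res.pvalue > 0.9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            compare_to_baseline([1.0, 2.0], [1.0])
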