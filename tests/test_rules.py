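"""Rule engine: parsing, evaluation, threshold derivation, pair search."""

import json

import numpy as np
import pandas as pd
import pytest

from pulseqc.errors import ConfigurationError, InputError
from pulseqc.rules import (Boundary, Rule, RuleSet, apply_rule, apply_ruleset,
                           pair_search, parse_ruleset, serialize_ruleset,
                           threshold_percentile, threshold_search)

EXAMPLE = {
    "rules": {
        "kurtosis_sqi": {"boundaries": [{"op": ">", "value": 5.0,
                                         "decision": "reject"}],
                         "na_decision": "reject"},
        "skewness_sqi": {"boundaries": [{"op": "<", "value": -2.0,
                                         "decision": "reject"},
                                        {"op": ">", "value": 2.0,
                                         "decision": "reject"}],
                         "na_decision": "reject"},
        "entropy_sqi": {"boundaries": [{"op": "<", "value": 5.0,
                                        "decision": "reject"}],
                        "na_decision": "accept"},
    },
    "order": ["kurtosis_sqi", "skewness_sqi", "entropy_sqi"],
}


class TestParsing:
    def test_three_rule_example(self):
        rs = parse_ruleset(json.dumps(EXAMPLE))
        assert rs.order == ["kurtosis_sqi", "skewness_sqi", "entropy_sqi"]
        assert len(rs.rules) == 3
        assert rs.rules["entropy_sqi"].na_decision == "accept"

    def test_empty_rules_rejected(self):
        with pytest.raises(ConfigurationError):
            parse_ruleset('{"rules": {}}')

    def test_unknown_operator_path_reported(self):
        bad = {"rules": {"x": {"boundaries": [{"op": "!=", "value": 1,
                                               "decision": "reject"}]}}}
        with pytest.raises(ConfigurationError, match=r"rules\.x\.boundaries\[0\]"):
            parse_ruleset(json.dumps(bad))

    def test_order_must_reference_rules(self):
        bad = dict(EXAMPLE, order=["kurtosis_sqi", "missing"])
        with pytest.raises(ConfigurationError):
            parse_ruleset(json.dumps(bad))

    def test_round_trip(self):
        rs = parse_ruleset(json.dumps(EXAMPLE))
        again = parse_ruleset(serialize_ruleset(rs))
        assert again.order == rs.order
        assert serialize_ruleset(again) == serialize_ruleset(rs)


class TestEvaluation:
    rule = Rule("x", [Boundary("<", 2.0, "reject")], na_decision="reject")

    def test_boundary_semantics(self):
        assert apply_rule(self.rule, 3.5) == "accept"
        assert apply_rule(self.rule, 1.0) == "reject"
        assert apply_rule(self.rule, float("nan")) == "reject"
        assert apply_rule(Rule("x", [Boundary("<", 2.0, "reject")],
                               na_decision="accept"), None) == "accept"

    def test_first_matching_boundary_wins(self):
        rule = Rule("x", [Boundary(">", 0.0, "accept"),
                          Boundary(">", 10.0, "reject")])
        assert apply_rule(rule, 20.0) == "accept"

    def test_ruleset_short_circuit(self):
        rs = parse_ruleset(json.dumps(EXAMPLE))
        ok = apply_ruleset(rs, {"kurtosis_sqi": 3.0, "skewness_sqi": 0.1,
                                "entropy_sqi": 7.0}, segment_id=0)
        assert ok.label == "accept" and ok.triggered_rule is None
        bad = apply_ruleset(rs, {"kurtosis_sqi": 3.0, "skewness_sqi": 4.0,
                                 "entropy_sqi": 7.0}, segment_id=1)
        assert bad.label == "reject" and bad.triggered_rule == "skewness_sqi"

    def test_missing_column_is_config_error(self):
        rs = parse_ruleset(json.dumps(EXAMPLE))
        with pytest.raises(ConfigurationError):
            apply_ruleset(rs, {"kurtosis_sqi": 3.0})

    def test_hand_crafted_table_matches_enumerated_truth(self):
        """Decisions on a 10-row table equal the independently
        enumerated per-row truth."""
        rs = parse_ruleset(json.dumps(EXAMPLE))
        rows = [
            {"kurtosis_sqi": 3.0, "skewness_sqi": 0.0, "entropy_sqi": 7.0},
            {"kurtosis_sqi": 6.0, "skewness_sqi": 0.0, "entropy_sqi": 7.0},
            {"kurtosis_sqi": 3.0, "skewness_sqi": -3.0, "entropy_sqi": 7.0},
            {"kurtosis_sqi": 3.0, "skewness_sqi": 3.0, "entropy_sqi": 7.0},
            {"kurtosis_sqi": 3.0, "skewness_sqi": 0.0, "entropy_sqi": 4.0},
            {"kurtosis_sqi": float("nan"), "skewness_sqi": 0.0,
             "entropy_sqi": 7.0},
            {"kurtosis_sqi": 3.0, "skewness_sqi": float("nan"),
             "entropy_sqi": 7.0},
            {"kurtosis_sqi": 3.0, "skewness_sqi": 0.0,
             "entropy_sqi": float("nan")},  # entropy NA accepts
            {"kurtosis_sqi": 5.0, "skewness_sqi": 2.0, "entropy_sqi": 5.0},
            {"kurtosis_sqi": 6.0, "skewness_sqi": 3.0, "entropy_sqi": 1.0},
        ]
        expected = [("accept", None), ("reject", "kurtosis_sqi"),
                    ("reject", "skewness_sqi"), ("reject", "skewness_sqi"),
                    ("reject", "entropy_sqi"), ("reject", "kurtosis_sqi"),
                    ("reject", "skewness_sqi"), ("accept", None),
                    ("accept", None), ("reject", "kurtosis_sqi")]
        for row, (label, trig) in zip(rows, expected):
            d = apply_ruleset(rs, row)
            assert (d.label, d.triggered_rule) == (label, trig), row

    def test_monotonicity_over_random_rulesets(self):
        """Adding a rule never converts a reject into an accept
        (all-accept conjunction), over 1000 random rulesets."""
        rng = np.random.default_rng(47)
        names = [f"s{i}" for i in range(5)]
        for _ in range(1000):
            k = int(rng.integers(1, 5))
            chosen = list(rng.choice(names, size=k, replace=False))
            rules = {}
            for nm in chosen:
                op = str(rng.choice(["<", "<=", ">", ">=", "=="]))
                rules[nm] = Rule(nm, [Boundary(op, float(rng.normal()),
                                               "reject")])
            rs = RuleSet(rules, chosen)
            row = {nm: float(rng.normal()) for nm in names}
            base = apply_ruleset(rs, row).label
            extra_name = str(rng.choice(names))
            extra = Rule("extra", [Boundary(str(rng.choice(["<", ">"])),
                                            float(rng.normal()), "reject")])
            bigger = RuleSet({**rules, "extra": extra}, chosen + ["extra"])
            row["extra"] = row[extra_name]
            grown = apply_ruleset(bigger, row).label
            if base == "reject":
                assert grown == "reject"

    def test_rule_order_never_changes_label(self):
        """Under all-accept semantics the label is order-independent."""
        rng = np.random.default_rng(53)
        rules = {f"s{i}": Rule(f"s{i}", [Boundary("<", 0.0, "reject")])
                 for i in range(4)}
        names = list(rules)
        for _ in range(100):
            row = {nm: float(rng.normal()) for nm in names}
            perm = list(rng.permutation(names))
            a = apply_ruleset(RuleSet(rules, names), row).label
            b = apply_ruleset(RuleSet(rules, perm), row).label
            assert a == b


class TestThresholds:
    def test_percentile_linear_interpolation(self):
        """Values 1..100 at q=95 → 95.05 (linear interpolation)."""
        values = np.arange(1, 101, dtype=float)
        assert threshold_percentile(values, 95.0) == pytest.approx(95.05)
        assert threshold_percentile(np.full(25, 7.0), 95.0) == 7.0
        sym = np.arange(-50, 51, dtype=float)
        assert threshold_percentile(sym, 50.0) == pytest.approx(0.0)
        with pytest.raises(InputError):
            threshold_percentile(np.arange(5.0), 95.0)

    def test_search_separable_classes(self):
        """Disjoint uniform classes yield balanced accuracy 1.0 with the
        correct rejection direction."""
        rng = np.random.default_rng(59)
        accept = rng.uniform(0, 1, 200)
        reject = rng.uniform(2, 3, 200)
        thr, direction, ba = threshold_search(accept, reject)
        assert ba == 1.0
        assert direction == "reject_above"
        assert 1.0 <= thr <= 2.0

    def test_search_identical_distributions_chance_level(self):
        """Same-distribution classes stay near chance over 20 seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal(150)
            b = rng.standard_normal(150)
            _, _, ba = threshold_search(a, b)
            assert ba <= 0.6

    def test_search_degenerate_input(self):
        with pytest.raises(InputError):
            threshold_search(np.full(30, 1.0), np.full(30, 1.0))
        with pytest.raises(InputError):
            threshold_search(np.arange(5.0), np.arange(30.0))


class TestPairSearch:
    @staticmethod
    def make_table(seed=61, n=200):
        rng = np.random.default_rng(seed)
        y = np.array(["accept"] * n + ["reject"] * n)
        # sqi_a separates perfectly; sqi_b partially; sqi_c is noise
        a = np.concatenate([rng.uniform(0, 1, n), rng.uniform(2, 3, n)])
        b = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        c = rng.standard_normal(2 * n)
        return pd.DataFrame({"sqi_a": a, "sqi_b": b, "sqi_c": c}), y

    def test_pair_count(self):
        table, y = self.make_table()
        assert len(pair_search(table, y, ["sqi_a", "sqi_b"])) == 1
        assert len(pair_search(table, y, ["sqi_a", "sqi_b", "sqi_c"])) == 3

    def test_perfect_member_dominates(self):
        """An AND-pair containing a perfectly separating SQI reaches at
        least the balanced accuracy of the other member alone."""
        table, y = self.make_table()
        results = pair_search(table, y, ["sqi_a", "sqi_b", "sqi_c"])
        singles = {}
        for name in ("sqi_b", "sqi_c"):
            v = table[name].to_numpy()
            _, _, singles[name] = threshold_search(v[y == "accept"],
                                                   v[y == "reject"])
        for res in results:
            pair = res["sqi_pair"]
            if "sqi_a" in pair:
                other = pair[0] if pair[1] == "sqi_a" else pair[1]
                assert res["metrics"]["balanced_accuracy"] >= singles[other] - 1e-12

    def test_ranked_by_auc(self):
        table, y = self.make_table()
        results = pair_search(table, y, ["sqi_a", "sqi_b", "sqi_c"])
        aucs = [r["metrics"]["roc_auc"] for r in results]
        assert aucs == sorted(aucs, reverse=True)

    def test_single_class_rejected(self):
        table, _ = self.make_table()
        with pytest.raises(InputError):
            pair_search(table, ["accept"] * len(table), ["sqi_a", "sqi_b"])
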