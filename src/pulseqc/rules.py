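"""JSON rule/ruleset formalism, decision evaluation and threshold derivation.

A :class:`Rule` attaches an ordered list of threshold boundaries to one
SQI column; a :class:`RuleSet` executes rules in a fixed order with
AND semantics (every rule must accept; the first rejecting rule is
recorded as the trigger). Undefined SQI values are decided by the rule's
``na_decision`` (default reject — quality-control conservatism).

Ruleset JSON schema (pinned)::

    {
      "rules": {
        "<sqi_name>": {
          "boundaries": [{"op": ">=", "value": 3.0, "decision": "accept"}, ...],
          "na_decision": "reject"
        }, ...
      },
      "order": ["<sqi_name>", ...]
    }

Two threshold-derivation procedures are provided: the 95th-percentile
of the accept-class histogram, and a brute-force quantile-grid search
(default step 0.05) maximizing balanced accuracy between the accept and
reject classes; :func:`pair_search` combines two derived single-SQI
rules into an AND-ruleset for every unordered pair and ranks the pairs
by ROC AUC.
"""

from __future__ import annotations

import itertools
import json
import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import fbeta_score, roc_auc_score

from .errors import ConfigurationError, InputError

__all__ = [
    "Boundary",
    "Rule",
    "RuleSet",
    "Decision",
    "parse_ruleset",
    "serialize_ruleset",
    "apply_rule",
    "apply_ruleset",
    "threshold_percentile",
    "threshold_search",
    "pair_search",
]

ACCEPT, REJECT = "accept", "reject"
_OPS = {"<": operator.lt, "<=": operator.le, ">": operator.gt,
        ">=": operator.ge, "==": operator.eq}


@dataclass
class Boundary:
    op: str
    value: float
    decision: str

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ConfigurationError(f"unknown operator {self.op!r}")
        if self.decision not in (ACCEPT, REJECT):
            raise ConfigurationError(f"decision must be accept/reject, "
                                     f"got {self.decision!r}")
        self.value = float(self.value)
        if not np.isfinite(self.value):
            raise ConfigurationError("boundary threshold must be finite")


@dataclass
class Rule:
    sqi_name: str
    boundaries: list[Boundary]
    na_decision: str = REJECT

    def __post_init__(self) -> None:
        if not self.boundaries:
            raise ConfigurationError(f"rule {self.sqi_name!r}: boundaries empty")
        if self.na_decision not in (ACCEPT, REJECT):
            raise ConfigurationError(f"rule {self.sqi_name!r}: bad na_decision")


@dataclass
class RuleSet:
    rules: dict[str, Rule]
    order: list[str]
    combination: str = "all_accept"

    def __post_init__(self) -> None:
        if self.combination != "all_accept":
            raise ConfigurationError(
                f"unknown combination {self.combination!r}")
        for name in self.order:
            if name not in self.rules:
                raise ConfigurationError(f"order references unknown rule {name!r}")
        for name in self.rules:
            if name not in self.order:
                raise ConfigurationError(f"rule {name!r} missing from order")


@dataclass
class Decision:
    segment_id: object
    label: str
    triggered_rule: str | None = None


def apply_rule(rule: Rule, value) -> str:
    """Evaluate one rule: first matching boundary wins; no match →
    accept; NA value → the rule's na_decision."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return rule.na_decision
    try:
        v = float(value)
    except (TypeError, ValueError):
        return rule.na_decision
    if np.isnan(v):
        return rule.na_decision
    for b in rule.boundaries:
        if _OPS[b.op](v, b.value):
            return b.decision
    return ACCEPT


def apply_ruleset(ruleset: RuleSet, sqi_row, segment_id=None) -> Decision:
    """Evaluate rules in order; the first reject short-circuits.

    ``sqi_row`` is any mapping from SQI name to value (a DataFrame row
    works). Missing columns are a configuration error; NA values are
    legal and handled per rule.
    """
    row = dict(sqi_row)
    for name in ruleset.order:
        if name not in row:
            raise ConfigurationError(f"SQI column {name!r} missing from row")
    for name in ruleset.order:
        if apply_rule(ruleset.rules[name], row[name]) == REJECT:
            return Decision(segment_id, REJECT, name)
    return Decision(segment_id, ACCEPT, None)


def parse_ruleset(json_text: str) -> RuleSet:
    """Parse and validate the pinned ruleset JSON schema."""
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"ruleset is not valid JSON: {exc}") from None
    if not isinstance(doc, dict) or "rules" not in doc:
        raise ConfigurationError("ruleset: missing top-level 'rules' object")
    raw_rules = doc["rules"]
    if not isinstance(raw_rules, dict) or not raw_rules:
        raise ConfigurationError("ruleset: 'rules' must be a non-empty object")
    rules: dict[str, Rule] = {}
    for name, body in raw_rules.items():
        path = f"rules.{name}"
        if not isinstance(body, dict) or "boundaries" not in body:
            raise ConfigurationError(f"{path}: missing 'boundaries'")
        bounds = []
        for i, b in enumerate(body["boundaries"]):
            bpath = f"{path}.boundaries[{i}]"
            if not isinstance(b, dict):
                raise ConfigurationError(f"{bpath}: must be an object")
            for key in ("op", "value", "decision"):
                if key not in b:
                    raise ConfigurationError(f"{bpath}: missing {key!r}")
            try:
                bounds.append(Boundary(b["op"], b["value"], b["decision"]))
            except ConfigurationError as exc:
                raise ConfigurationError(f"{bpath}: {exc}") from None
        try:
            rules[name] = Rule(name, bounds, body.get("na_decision", REJECT))
        except ConfigurationError as exc:
            raise ConfigurationError(f"{path}: {exc}") from None
    order = doc.get("order", list(rules))
    if not isinstance(order, list):
        raise ConfigurationError("order: must be a list of SQI names")
    return RuleSet(rules, list(order), doc.get("combination", "all_accept"))


def serialize_ruleset(ruleset: RuleSet) -> str:
    doc = {
        "rules": {
            name: {
                "boundaries": [
                    {"op": b.op, "value": b.value, "decision": b.decision}
                    for b in rule.boundaries
                ],
                "na_decision": rule.na_decision,
            }
            for name, rule in ruleset.rules.items()
        },
        "order": list(ruleset.order),
        "combination": ruleset.combination,
    }
    return json.dumps(doc, indent=2)


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def threshold_percentile(accept_values, q: float = 95.0,
                         side: str = "upper") -> float:
    """Linear-interpolation percentile of the accept-class values.

    ``side`` records which tail the caller intends to reject (upper:
    reject values above the threshold).
    """
    v = _clean(accept_values)
    if v.size < 20:
        raise InputError(f"need >= 20 values, got {v.size}")
    if side not in ("upper", "lower"):
        raise ConfigurationError(f"side must be upper/lower, got {side!r}")
    if side == "lower":
        q = 100.0 - q
    return float(np.percentile(v, q))


def threshold_search(accept_values, reject_values,
                     step_quantile: float = 0.05
                     ) -> tuple[float, str, float]:
    """Brute-force quantile-grid search for the most discriminative
    threshold.

    Candidates are quantiles of the pooled values on the grid
    {step, 2·step, …}; each candidate is tried in both directions
    (``reject_below``: predict reject when value < threshold;
    ``reject_above``: when value > threshold). Returns the
    (threshold, direction, balanced_accuracy) maximizer; ties prefer the
    smallest threshold, then reject_below.
    """
    acc = _clean(accept_values)
    rej = _clean(reject_values)
    if acc.size < 20 or rej.size < 20:
        raise InputError("need >= 20 values in each class")
    pooled = np.concatenate([acc, rej])
    if np.min(pooled) == np.max(pooled):
        raise InputError("degenerate classes: all values identical")
    qs = np.arange(step_quantile, 1.0, step_quantile)
    candidates = np.quantile(pooled, qs)
    best = (-1.0, np.inf, 1)  # (balanced accuracy, threshold, direction rank)
    best_out = None
    for thr in candidates:
        for rank, direction in enumerate(("reject_below", "reject_above")):
            if direction == "reject_below":
                sens = np.mean(acc >= thr)  # accept correctly accepted
                spec = np.mean(rej < thr)
            else:
                sens = np.mean(acc <= thr)
                spec = np.mean(rej > thr)
            ba = (sens + spec) / 2.0
            key = (ba, -thr, -rank)
            if key > (best[0], -best[1], -best[2]):
                best = (ba, thr, rank)
                best_out = (float(thr), direction, float(ba))
    return best_out


def _rule_from_threshold(name: str, threshold: float, direction: str) -> Rule:
    op = "<" if direction == "reject_below" else ">"
    return Rule(name, [Boundary(op, threshold, REJECT)], na_decision=REJECT)


def pair_search(sqi_table: pd.DataFrame, labels, candidate_sqis,
                step_quantile: float = 0.05, beta: float = 1.0) -> list[dict]:
    """Evaluate every unordered pair of candidate SQIs as an AND-ruleset.

    For each member a threshold is derived by :func:`threshold_search`
    on the labeled table; the pair ruleset rejects when either member
    rejects. Reported metrics per pair: per-class accuracies, overall
    accuracy, Brier score of the 0/1 decision, ROC AUC of the combined
    margin score, and F-beta (accept = positive class). Pairs are ranked
    by AUC, descending.
    """
    y = np.asarray([1 if str(v) == ACCEPT or v == 1 else 0 for v in labels])
    if len(y) != len(sqi_table):
        raise InputError("labels length must match table rows")
    if y.min() == y.max():
        raise InputError("labels must contain both classes")
    names = list(candidate_sqis)
    if len(names) < 2:
        raise InputError("need at least 2 candidate SQIs")
    for name in names:
        if name not in sqi_table.columns:
            raise ConfigurationError(f"SQI column {name!r} not in table")

    per_sqi = {}
    for name in names:
        v = sqi_table[name].to_numpy(dtype=float)
        thr, direction, ba = threshold_search(v[y == 1], v[y == 0],
                                              step_quantile)
        scale = float(np.nanstd(v)) or 1.0
        margin = (v - thr) / scale
        if direction == "reject_above":
            margin = -margin
        margin = np.where(np.isfinite(margin), margin, -np.inf)
        per_sqi[name] = (thr, direction, ba, margin)

    results = []
    for a, b in itertools.combinations(names, 2):
        ruleset = RuleSet(
            {a: _rule_from_threshold(a, per_sqi[a][0], per_sqi[a][1]),
             b: _rule_from_threshold(b, per_sqi[b][0], per_sqi[b][1])},
            order=[a, b],
        )
        pred = np.array([
            1 if apply_ruleset(ruleset, row._asdict() if hasattr(row, "_asdict")
                               else dict(row)).label == ACCEPT else 0
            for _, row in sqi_table[[a, b]].iterrows()
        ])
        score = np.minimum(per_sqi[a][3], per_sqi[b][3])
        finite = np.isfinite(score)
        score = np.where(finite, score, np.min(score[finite]) - 1.0
                         if finite.any() else 0.0)
        acc_accept = float(np.mean(pred[y == 1] == 1))
        acc_reject = float(np.mean(pred[y == 0] == 0))
        metrics = {
            "accept_accuracy": acc_accept,
            "reject_accuracy": acc_reject,
            "balanced_accuracy": (acc_accept + acc_reject) / 2.0,
            "accuracy": float(np.mean(pred == y)),
            "brier": float(np.mean((pred - y) ** 2)),
            "roc_auc": float(roc_auc_score(y, score)),
            "fbeta": float(fbeta_score(y, pred, beta=beta)),
        }
        results.append({"sqi_pair": (a, b), "ruleset": ruleset,
                        "metrics": metrics,
                        "thresholds": {a: per_sqi[a][:2], b: per_sqi[b][:2]}})
    results.sort(key=lambda r: -r["metrics"]["roc_auc"])
    return results
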