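"""Interpretable ordered-rule surrogates.

A trained forest is opaque; to summarize what it learned, a sequential
covering rule learner in the RIPPER family (Repeated Incremental Pruning
to Produce Error Reduction) is fitted to the forest's *predictions*,
yielding an ordered list of conjunctive threshold rules such as::

    disorder >= 0.897            -> ambiguous
    disorder >= 0.256 AND backbone <= 0.724 -> ambiguous

Classes are processed from least to most frequent, the most frequent
class becoming the default.  Each rule is grown greedily by FOIL
information gain on a grow split, then pruned on a held-out prune split;
covered examples are removed after each accepted rule.  Induction for a
class stops when a candidate rule's prune-set error exceeds the error
tolerance or its coverage falls below the minimum.

This is a native reimplementation of the grow/prune sequential-covering
scheme: thresholds are restricted to midpoints between adjacent observed
feature values, and the MDL-based stopping rule of the original
algorithm is replaced by an explicit error-tolerance parameter.  Exact
equivalence to other rule learners is not claimed.

The learner is exposed both as a scikit-learn classifier
(:class:`RipperClassifier`) and as functional wrappers
(:func:`induce_rules`, :func:`apply_ruleset`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ambiclass.features import FEATURE_COLUMNS

OPS = ("<=", ">=")


@dataclass(frozen=True)
class Condition:
    """A single threshold test on one feature."""

    feature: str
    op: str  # "<=" or ">="
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise ValueError(f"invalid comparator {self.op!r}")

    def matches(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value >= self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:.3f}"


@dataclass(frozen=True)
class Rule:
    """A conjunction of threshold conditions with a consequent class."""

    conditions: tuple[Condition, ...]
    consequent: str

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise ValueError("a rule needs at least one condition")
        keys = [(c.feature, c.op) for c in self.conditions]
        if len(keys) != len(set(keys)):
            raise ValueError("at most one condition per (feature, comparator)")

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(table), dtype=bool)
        for c in self.conditions:
            if c.feature not in table.columns:
                raise KeyError(f"rule references missing feature {c.feature!r}")
            v = table[c.feature].to_numpy(dtype=float)
            m &= (v <= c.threshold) if c.op == "<=" else (v >= c.threshold)
        return m

    def __str__(self) -> str:
        return " AND ".join(str(c) for c in self.conditions) + f" -> {self.consequent}"


@dataclass
class RuleSet:
    """Ordered rule list with a default class; applied first-match."""

    rules: list[Rule]
    default_class: str
    provenance: dict = field(default_factory=dict)

    def apply(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.default_class, dtype=object)
        unassigned = np.ones(len(table), dtype=bool)
        for rule in self.rules:
            hit = rule.mask(table) & unassigned
            out[hit] = rule.consequent
            unassigned &= ~hit
        return out

    def to_json(self) -> str:
        payload = {
            "rules": [
                {
                    "conditions": [
                        {"feature": c.feature, "op": c.op, "threshold": c.threshold}
                        for c in r.conditions
                    ],
                    "consequent": r.consequent,
                }
                for r in self.rules
            ],
            "default_class": self.default_class,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        payload = json.loads(text)
        rules = [
            Rule(
                conditions=tuple(
                    Condition(c["feature"], c["op"], float(c["threshold"]))
                    for c in r["conditions"]
                ),
                consequent=r["consequent"],
            )
            for r in payload["rules"]
        ]
        return cls(rules, payload["default_class"], payload.get("provenance", {}))

    def to_text(self) -> str:
        lines = [str(r) for r in self.rules]
        lines.append(f"DEFAULT -> {self.default_class}")
        return "\n".join(lines)


def _foil_gain(p, n, P, N):
    """FOIL information gain of covering (p, n) from a rule covering (P, N)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = p * (np.log2(p / (p + n)) - np.log2(P / (P + N)))
    return np.where(p > 0, gain, -np.inf)


def _best_condition(X, is_pos, covered, used):
    """Best (feature index, op, threshold, gain) over midpoint candidates."""
    P = int(np.sum(is_pos & covered))
    N = int(np.sum(~is_pos & covered))
    if P == 0 or N == 0:
        return None
    best = (None, None, None, 0.0)
    for j in range(X.shape[1]):
        v = X[covered, j]
        sp = is_pos[covered]
        order = np.argsort(v, kind="stable")
        sv, spos = v[order], sp[order]
        distinct = np.nonzero(np.diff(sv) > 0)[0]
        if distinct.size == 0:
            continue
        mids = (sv[distinct] + sv[distinct + 1]) / 2.0
        cum_pos = np.cumsum(spos)[distinct]
        cum_all = distinct + 1.0
        # "<=" keeps everything up to the boundary, ">=" everything above it
        for op, p, n in (
            ("<=", cum_pos, cum_all - cum_pos),
            (">=", P - cum_pos, N - (cum_all - cum_pos)),
        ):
            if (j, op) in used:
                continue
            gains = _foil_gain(p, n, P, N)
            k = int(np.argmax(gains))
            if gains[k] > best[3]:
                best = (j, op, float(mids[k]), float(gains[k]))
    return None if best[0] is None else best


def _rule_counts(X, is_pos, mask, conditions, feature_names):
    covered = mask.copy()
    for c in conditions:
        j = feature_names.index(c.feature)
        covered &= (X[:, j] <= c.threshold) if c.op == "<=" else (X[:, j] >= c.threshold)
    p = int(np.sum(covered & is_pos))
    n = int(np.sum(covered & ~is_pos))
    return p, n, covered


class RipperClassifier(BaseEstimator, ClassifierMixin):
    """Sequential-covering rule-list classifier.

    Parameters
    ----------
    grow_fraction:
        Fraction of the remaining examples used to grow each rule; the
        rest form the prune split (default 2/3).
    min_coverage:
        Minimum number of positives a rule must cover to be accepted.
    prune_error_tolerance:
        Induction for a class stops when a candidate rule's prune-split
        error rate exceeds this value (default 0.5, the classical
        better-than-chance cutoff).
    max_conditions:
        Safety cap on conditions per rule.
    seed:
        Seed for the grow/prune splits; fixed seed gives identical rules.
    """

    def __init__(
        self,
        grow_fraction: float = 2.0 / 3.0,
        min_coverage: int = 2,
        prune_error_tolerance: float = 0.5,
        max_conditions: int = 16,
        seed: int = 0,
    ):
        self.grow_fraction = grow_fraction
        self.min_coverage = min_coverage
        self.prune_error_tolerance = prune_error_tolerance
        self.max_conditions = max_conditions
        self.seed = seed

    def _as_matrix(self, X):
        if isinstance(X, pd.DataFrame):
            names = [c for c in X.columns if c in FEATURE_COLUMNS] or [
                c for c in X.columns if pd.api.types.is_numeric_dtype(X[c])
            ]
            return X[names].to_numpy(dtype=float), list(names)
        matrix = np.asarray(X, dtype=float)
        return matrix, [f"f{i}" for i in range(matrix.shape[1])]

    def fit(self, X, y):
        matrix, names = self._as_matrix(X)
        y = np.asarray(y, dtype=object)
        if len(y) == 0:
            raise ValueError("empty training data")
        if not np.isfinite(matrix).all():
            raise ValueError("features contain missing or non-finite values")
        rng = np.random.default_rng(self.seed)
        classes, counts = np.unique(y, return_counts=True)
        # least frequent first; ties broken lexicographically by class name
        order = sorted(range(len(classes)), key=lambda i: (counts[i], str(classes[i])))
        ordered = [str(classes[i]) for i in order]
        default = ordered[-1]
        rules: list[Rule] = []
        remaining = np.ones(len(y), dtype=bool)
        for cls in ordered[:-1]:
            while True:
                rule = self._learn_one_rule(matrix, y, remaining, cls, names, rng)
                if rule is None:
                    break
                rules.append(rule)
                _, _, covered = _rule_counts(
                    matrix, y == cls, remaining, rule.conditions, names
                )
                remaining &= ~covered
        self.ruleset_ = RuleSet(
            rules,
            default,
            provenance={
                "algorithm": "sequential-covering (RIPPER-style)",
                "grow_fraction": self.grow_fraction,
                "min_coverage": self.min_coverage,
                "prune_error_tolerance": self.prune_error_tolerance,
                "seed": self.seed,
            },
        )
        self.classes_ = np.array(sorted(str(c) for c in classes), dtype=object)
        self.feature_names_ = names
        return self

    def _learn_one_rule(self, X, y, remaining, cls, names, rng):
        is_pos = (y == cls) & remaining
        n_pos = int(is_pos.sum())
        if n_pos < self.min_coverage:
            return None
        idx = np.nonzero(remaining)[0]
        # stratified grow/prune split so both carry positives
        pos_idx = idx[y[idx] == cls]
        neg_idx = idx[y[idx] != cls]
        grow_mask = np.zeros(len(y), dtype=bool)
        prune_mask = np.zeros(len(y), dtype=bool)
        for part in (pos_idx, neg_idx):
            perm = rng.permutation(part)
            cut = max(1, int(round(len(perm) * self.grow_fraction)))
            grow_mask[perm[:cut]] = True
            prune_mask[perm[cut:]] = True

        conditions = self._grow(X, y == cls, grow_mask, names)
        if not conditions:
            return None
        conditions = self._prune(X, y == cls, prune_mask, conditions, names)

        # stopping check: prune-split error (grow-split if nothing covered there)
        p, n, _ = _rule_counts(X, y == cls, prune_mask, conditions, names)
        if p + n == 0:
            p, n, _ = _rule_counts(X, y == cls, grow_mask, conditions, names)
        error = n / (p + n) if (p + n) else 1.0
        p_all, _, _ = _rule_counts(X, y == cls, remaining, conditions, names)
        if error > self.prune_error_tolerance or p_all < self.min_coverage:
            return None
        return Rule(tuple(conditions), cls)

    def _grow(self, X, is_pos, grow_mask, names):
        conditions: list[Condition] = []
        covered = grow_mask.copy()
        used: set[tuple[int, str]] = set()
        while len(conditions) < self.max_conditions:
            n_neg = int(np.sum(covered & ~is_pos))
            if n_neg == 0:
                break
            found = _best_condition(X, is_pos, covered, used)
            if found is None:
                break
            j, op, threshold, _ = found
            used.add((j, op))
            conditions.append(Condition(names[j], op, threshold))
            covered &= (X[:, j] <= threshold) if op == "<=" else (X[:, j] >= threshold)
        return conditions

    def _prune(self, X, is_pos, prune_mask, conditions, names):
        def value(conds):
            p, n, _ = _rule_counts(X, is_pos, prune_mask, conds, names)
            return (p - n) / (p + n) if (p + n) else -np.inf

        pruned = list(conditions)
        while len(pruned) > 1 and value(pruned[:-1]) >= value(pruned):
            pruned.pop()
        return pruned

    def predict(self, X):
        check_is_fitted(self, "ruleset_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.feature_names_)
        return self.ruleset_.apply(X)


def induce_rules(
    x: pd.DataFrame,
    y,
    grow_fraction: float = 2.0 / 3.0,
    min_coverage: int = 2,
    prune_error_tolerance: float = 0.5,
    seed: int = 0,
) -> RuleSet:
    """Induce an ordered rule list from labeled feature rows."""
    learner = RipperClassifier(
        grow_fraction=grow_fraction,
        min_coverage=min_coverage,
        prune_error_tolerance=prune_error_tolerance,
        seed=seed,
    )
    learner.fit(x, y)
    return learner.ruleset_


def apply_ruleset(rs: RuleSet, v) -> str | np.ndarray:
    """Apply a rule set to one feature vector (mapping) or a table."""
    if isinstance(v, pd.DataFrame):
        return rs.apply(v)
    table = pd.DataFrame([dict(v)])
    return str(rs.apply(table)[0])


def surrogate_fidelity(rs: RuleSet, model_predictions, x: pd.DataFrame) -> float:
    """Fraction of rows where the rule list agrees with the model's prediction."""
    model_predictions = np.asarray(model_predictions, dtype=object)
    if len(model_predictions) != len(x):
        raise ValueError("predictions and feature rows have different lengths")
    if len(x) == 0:
        raise ValueError("empty input")
    return float(np.mean(rs.apply(x) == model_predictions))


def summarize_rules(rs: RuleSet, reference: pd.DataFrame, labels=None) -> dict:
    """Per-rule first-match coverage (and accuracy when labels are given).

    Coverage counts, including the default bucket, sum to the reference
    size.
    """
    if len(reference) == 0:
        raise ValueError("empty reference set")
    labels = None if labels is None else np.asarray(labels, dtype=object)
    unassigned = np.ones(len(reference), dtype=bool)
    per_rule = []
    for rule in rs.rules:
        hit = rule.mask(reference) & unassigned
        entry = {"rule": str(rule), "coverage": int(hit.sum())}
        if labels is not None and hit.any():
            entry["accuracy"] = float(np.mean(labels[hit] == rule.consequent))
        per_rule.append(entry)
        unassigned &= ~hit
    default_entry = {"coverage": int(unassigned.sum())}
    if labels is not None and unassigned.any():
        default_entry["accuracy"] = float(
            np.mean(labels[unassigned] == rs.default_class)
        )
    return {
        "n_rules": len(rs.rules),
        "rules": per_rule,
        "default": {"class": rs.default_class, **default_entry},
        "n_reference": len(reference),
    }
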