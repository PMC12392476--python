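"""Order-stratified rule tables: sorting, partitioning, rendering.

Mined rules are read as a sequence of tables, one per rule order
(2 = "binary" rules with a single antecedent symptom, 3 = "triple", and
so on). Within a table rows descend by raw support, then raw confidence,
then raw lift, then lexicographic antecedent — display rounding never
participates in ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .miner import Rule

SORT_KEYS = ("support", "confidence", "lift", "lhs")


@dataclass(frozen=True)
class RuleTable:
    """Rules of a single order plus the ordering applied to them."""

    order: int
    rows: tuple[Rule, ...]
    sort_keys: tuple[str, ...] = field(default=SORT_KEYS)

    def __post_init__(self) -> None:
        for r in self.rows:
            if r.order != self.order:
                raise ValueError(
                    f"rule of order {r.order} in an order-{self.order} table"
                )


def stratify_rules(rules) -> dict[int, RuleTable]:
    """Partition rules into per-order tables (keyed by |LHS| + 1)."""
    by_order: dict[int, list[Rule]] = {}
    for r in rules:
        by_order.setdefault(r.order, []).append(r)
    return {
        order: RuleTable(order, tuple(rows)) for order, rows in sorted(by_order.items())
    }


def sort_rules(table: RuleTable) -> RuleTable:
    """Stable-sort a table: support desc, confidence desc, lift desc, lhs asc."""
    ordered = sorted(
        table.rows, key=lambda r: (-r.support, -r.confidence, -r.lift, r.lhs)
    )
    return RuleTable(table.order, tuple(ordered), SORT_KEYS)


def _lhs_text(rule: Rule) -> str:
    return ",".join(rule.lhs)


def _rule_record(rule: Rule) -> dict:
    return {
        "lhs": list(rule.lhs),
        "rhs": rule.rhs,
        "order": rule.order,
        "support": rule.support,
        "confidence": rule.confidence,
        "lift": rule.lift,
        "supp": rule.support_2dp,
        "conf": rule.confidence_2dp,
        "lift_2dp": rule.lift_2dp,
    }


def render_rules_table(table: RuleTable, format: str = "tsv") -> str:
    """Render one table; TSV shows the 2-dp display values, JSON adds raw."""
    if format == "tsv":
        lines = ["LHS\tRHS\tsupp\tconf\tlift"]
        for r in table.rows:
            lines.append(
                f"{_lhs_text(r)}\t{r.rhs}\t{r.support_2dp:.2f}"
                f"\t{r.confidence_2dp:.2f}\t{r.lift_2dp:.2f}"
            )
        return "\n".join(lines) + "\n"
    if format == "json":
        return json.dumps(
            {"order": table.order, "rules": [_rule_record(r) for r in table.rows]},
            indent=2,
        )
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")


def render_rules_json(tables: dict[int, RuleTable]) -> str:
    """Combined JSON document keyed by rule order."""
    doc = {
        str(order): [_rule_record(r) for r in tables[order].rows]
        for order in sorted(tables)
    }
    return json.dumps(doc, indent=2)
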