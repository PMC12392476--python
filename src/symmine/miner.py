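"""From-scratch Apriori frequent-itemset mining and outcome-targeted rules.

The miner operates on a :class:`~symmine.cohort_io.TransactionSet` and
produces association rules ``A -> B`` where the consequent ``B`` is a
single configured target item (the outcome-positive token). Rules are
scored by the three classical metrics:

    support(A -> B)    = |transactions ⊇ A ∪ {B}| / N
    confidence(A -> B) = support(A ∪ {B}) / support(A)
    lift(A -> B)       = confidence(A -> B) / support({B})

Lift > 1 marks positive association, = 1 independence, < 1 negative
association; rules are filtered on support and confidence only — lift is
reported, never thresholded.

Implementation notes. Transactions are represented internally as bitmask
integers (bit j set when transaction j contains the item), so itemset
support is a bitwise AND plus a popcount. Candidate (k)-itemsets are
built by the classical prefix join of frequent (k−1)-itemsets sharing
their first k−2 items under the canonical (sorted) order, pruned when
any (k−1)-subset is infrequent, then support-counted and filtered. A
brute-force enumerator over the full power set doubles as an independent
test oracle on small universes.

Metrics are computed from integer counts (e.g. lift as
``count(A∪B)·N / (count(A)·count(B))``) so algebraically exact values
like 1.625 stay exact in floating point. Display rounding is half-up to
two decimals and never feeds back into filtering or sorting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .cohort_io import TransactionSet
from .errors import MiningError
from .screening import TwoByTwo
from .utils import round_half_up

#: Largest item universe brute_force_rules will enumerate (2^15 subsets).
BRUTE_FORCE_MAX_ITEMS = 15


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and targeting for a mining run.

    ``min_support`` and ``min_confidence`` default to the 3% / 60%
    operating point of the reference analysis. ``target`` fixes the rule
    consequent to one item (``None`` enables the general any-consequent
    mode). ``max_order`` caps the total rule size |LHS| + 1.
    """

    min_support: float = 0.03
    min_confidence: float = 0.60
    target: str | None = "Diabetes=1"
    max_order: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.min_support <= 1.0):
            raise ValueError("min_support must be in (0, 1]")
        if not (0.0 < self.min_confidence <= 1.0):
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_order is not None and self.max_order < 2:
            raise ValueError("max_order must be at least 2 (one LHS item + RHS)")


@dataclass(frozen=True)
class Rule:
    """One association rule with raw metric values.

    ``lhs`` is the canonically sorted antecedent tuple; ``rhs`` a single
    item. Metrics are raw fractions; two-decimal half-up display values
    are exposed as ``support_2dp`` etc. so rounding never contaminates
    comparisons or sorting.
    """

    lhs: tuple[str, ...]
    rhs: str
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if self.rhs in self.lhs:
            raise ValueError("consequent must not appear in the antecedent")
        if tuple(sorted(self.lhs)) != self.lhs:
            raise ValueError("lhs must be canonically sorted")
        if not (0.0 <= self.support <= self.confidence <= 1.0 + 1e-12):
            raise ValueError("expected 0 <= support <= confidence <= 1")

    @property
    def order(self) -> int:
        """Total item count of the rule: |LHS| + 1."""
        return len(self.lhs) + 1

    @property
    def support_2dp(self) -> float:
        return round_half_up(self.support)

    @property
    def confidence_2dp(self) -> float:
        return round_half_up(self.confidence)

    @property
    def lift_2dp(self) -> float:
        return round_half_up(self.lift)


# ---------------------------------------------------------------------------
# bitmask plumbing


def _item_masks(t: TransactionSet) -> dict[str, int]:
    """Per-item transaction bitmasks (bit j set <=> transaction j has item)."""
    masks: dict[str, int] = {}
    for j, trans in enumerate(t.transactions):
        bit = 1 << j
        for item in trans:
            masks[item] = masks.get(item, 0) | bit
    return masks


def _mask_of(items, masks: dict[str, int], full: int) -> int:
    m = full
    for it in items:
        m &= masks.get(it, 0)
        if m == 0:
            break
    return m


# ---------------------------------------------------------------------------
# public operations


def itemset_support(items, t: TransactionSet) -> float:
    """Fraction of transactions containing every item of ``items``.

    The empty itemset is vacuously contained everywhere: support 1.0.
    """
    if t.n == 0:
        raise MiningError("empty transaction set")
    items = frozenset(items)
    if not items:
        return 1.0
    masks = _item_masks(t)
    full = (1 << t.n) - 1
    return _mask_of(items, masks, full).bit_count() / t.n


def frequent_itemsets(
    t: TransactionSet, min_support: float, max_size: int | None = None
) -> dict[int, dict[frozenset[str], float]]:
    """Level-wise Apriori enumeration of all frequent itemsets.

    Returns ``{size: {itemset: support}}`` containing exactly the
    itemsets with support >= ``min_support`` and size <= ``max_size``.
    Single items are counted first and infrequent ones discarded; each
    subsequent level joins frequent (k−1)-sets sharing a (k−2)-prefix,
    prunes candidates with any infrequent (k−1)-subset, and filters the
    survivors by counted support.
    """
    if t.n == 0:
        raise MiningError("empty transaction set")
    if min_support <= 0:
        raise ValueError("min_support must be positive")
    masks = _item_masks(t)
    n = t.n

    # level 1
    level: dict[tuple[str, ...], int] = {}
    for item in sorted(masks):
        m = masks[item]
        if m.bit_count() / n >= min_support:
            level[(item,)] = m
    result: dict[int, dict[frozenset[str], float]] = {}
    if level:
        result[1] = {frozenset(k): m.bit_count() / n for k, m in level.items()}

    k = 2
    while level and (max_size is None or k <= max_size):
        keys = sorted(level)
        prev = set(keys)
        nxt: dict[tuple[str, ...], int] = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted order: no later b shares a's prefix
                cand = a + (b[-1],)
                # subset pruning: every (k-1)-subset must be frequent
                if any(
                    cand[:j] + cand[j + 1 :] not in prev for j in range(len(cand) - 2)
                ):
                    continue
                m = level[a] & masks[b[-1]]
                if m.bit_count() / n >= min_support:
                    nxt[cand] = m
        if nxt:
            result[k] = {frozenset(c): m.bit_count() / n for c, m in nxt.items()}
        level = nxt
        k += 1
    return result


def generate_rules(
    frequent: dict[int, dict[frozenset[str], float]],
    t: TransactionSet,
    config: MiningConfig,
) -> list[Rule]:
    """Turn frequent itemsets into filtered association rules.

    In targeted mode (the default) each frequent itemset containing the
    target yields one candidate rule with the target as consequent; in
    the general mode every item of every frequent itemset takes a turn
    as consequent. Candidates are kept iff support >= min_support (true
    by construction) and confidence >= min_confidence.
    """
    if t.n == 0:
        raise MiningError("empty transaction set")
    if config.target is not None and config.target not in t.item_universe:
        raise MiningError(
            f"target item {config.target!r} absent from every transaction"
        )
    n = t.n
    counts: dict[frozenset[str], int] = {}
    for level in frequent.values():
        for s, supp in level.items():
            counts[s] = round(supp * n)  # supports are exact multiples of 1/n
    # consequent supports counted directly from the transactions so lift is
    # defined even when the consequent itself fell below min_support
    rhs_counts: dict[str, int] = {}

    def rhs_count(item: str) -> int:
        if item not in rhs_counts:
            rhs_counts[item] = sum(1 for trans in t.transactions if item in trans)
        return rhs_counts[item]

    rules: list[Rule] = []
    for s, c_union in counts.items():
        if len(s) < 2:
            continue
        if config.max_order is not None and len(s) > config.max_order:
            continue
        if config.target is not None:
            if config.target not in s:
                continue
            consequents = (config.target,)
        else:
            consequents = tuple(sorted(s))
        for rhs in consequents:
            lhs = s - {rhs}
            c_lhs = counts[lhs] if lhs in counts else None
            if c_lhs is None:  # only possible for size-1 lhs below min_support
                c_lhs = rhs_count(next(iter(lhs)))
            confidence = c_union / c_lhs
            if confidence < config.min_confidence:
                continue
            c_rhs = rhs_count(rhs)
            rules.append(
                Rule(
                    lhs=tuple(sorted(lhs)),
                    rhs=rhs,
                    support=c_union / n,
                    confidence=confidence,
                    lift=(c_union * n) / (c_lhs * c_rhs),
                )
            )
    rules.sort(key=lambda r: (r.order, r.lhs, r.rhs))
    return rules


def mine_rules(t: TransactionSet, config: MiningConfig | None = None) -> list[Rule]:
    """Convenience wrapper: frequent_itemsets + generate_rules."""
    config = config if config is not None else MiningConfig()
    frequent = frequent_itemsets(t, config.min_support, config.max_order)
    return generate_rules(frequent, t, config)


def rule_metrics_from_counts(table: TwoByTwo) -> tuple[float, float, float]:
    """Closed-form support/confidence/lift of ``exposure=1 -> outcome=1``.

    Evaluates the three metrics directly on a 2×2 contingency table, so
    printed counts can be turned into rule metrics without transactions.
    """
    n = table.total
    c_exp = table.c_pn + table.c_pp
    c_out = table.c_ep + table.c_pp
    if c_exp == 0:
        raise MiningError("zero exposure-positive margin; confidence undefined")
    if c_out == 0:
        raise MiningError("zero outcome-positive margin; lift undefined")
    support = table.c_pp / n
    confidence = table.c_pp / c_exp
    lift = (table.c_pp * n) / (c_exp * c_out)
    return support, confidence, lift


def brute_force_rules(t: TransactionSet, config: MiningConfig | None = None) -> list[Rule]:
    """Exhaustive-enumeration rule miner, the independent test oracle.

    Enumerates every subset of the item universe (refusing universes
    over ``BRUTE_FORCE_MAX_ITEMS`` items), computes each candidate
    rule's metrics directly from transaction counts, and applies the
    same thresholds as the Apriori path. Output is set-equal to
    ``generate_rules(frequent_itemsets(...))`` by definition.
    """
    config = config if config is not None else MiningConfig()
    if t.n == 0:
        raise MiningError("empty transaction set")
    universe = sorted(t.item_universe)
    if len(universe) > BRUTE_FORCE_MAX_ITEMS:
        raise MiningError(
            f"{len(universe)} items exceed the brute-force limit of "
            f"{BRUTE_FORCE_MAX_ITEMS}"
        )
    if config.target is not None and config.target not in t.item_universe:
        raise MiningError(
            f"target item {config.target!r} absent from every transaction"
        )
    masks = _item_masks(t)
    full = (1 << t.n) - 1
    n = t.n
    max_order = config.max_order if config.max_order is not None else len(universe)

    rules: list[Rule] = []
    for size in range(2, max_order + 1):
        for combo in combinations(universe, size):
            c_union = _mask_of(combo, masks, full).bit_count()
            if c_union / n < config.min_support:
                continue
            consequents = (
                (config.target,) if config.target is not None else combo
            )
            for rhs in consequents:
                if rhs not in combo:
                    continue
                lhs = tuple(x for x in combo if x != rhs)
                c_lhs = _mask_of(lhs, masks, full).bit_count()
                confidence = c_union / c_lhs
                if confidence < config.min_confidence:
                    continue
                c_rhs = masks[rhs].bit_count()
                rules.append(
                    Rule(
                        lhs=lhs,
                        rhs=rhs,
                        support=c_union / n,
                        confidence=confidence,
                        lift=(c_union * n) / (c_lhs * c_rhs),
                    )
                )
    rules.sort(key=lambda r: (r.order, r.lhs, r.rhs))
    return rules
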