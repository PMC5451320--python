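"""Synchronous Boolean regulatory rules.

A Boolean rule pairs a condition — comparisons of species counts, sums of
species counts, or parameters against constants, combined with AND/OR/NOT —
with an effect: set a named parameter to a value, or enable/disable a
reaction.  All rules in a step are evaluated against the *same* snapshot
(synchronous update), so rule order can never matter; the resulting updates
are applied by the controller at the step boundary and take effect in the
next step's snapshot.  Rules never write species counts directly: request
arbitration remains the sole writer of the global pool.

Condition grammar (case-insensitive keywords)::

    expr       := or_expr
    or_expr    := and_expr ( "or" and_expr )*
    and_expr   := unary ( "and" unary )*
    unary      := "not" unary | "(" expr ")" | comparison
    comparison := sum ("<" | "<=" | ">" | ">=" | "==" | "=" | "!=") number
    sum        := identifier ( "+" identifier )*

Identifiers resolve to species counts first, then to parameters.
Comparison at an exact threshold follows the declared operator strictly —
counts are integers, so there is no epsilon smudging.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .state import StateSnapshot


class RuleError(ValueError):
    """Malformed rule condition or unresolvable identifier."""


class RuleConflictError(RuleError):
    """Two true rules target the same parameter/reaction with different values."""


_TOKEN = re.compile(
    r"\s*(?:(?P<num>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|==|!=|<|>|=|\+|\(|\)))"
)
_KEYWORDS = {"and", "or", "not"}


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise RuleError(f"cannot tokenize condition at: {text[pos:]!r}")
        pos = m.end()
        if m.lastgroup == "ident" and m.group("ident").lower() in _KEYWORDS:
            tokens.append(("kw", m.group("ident").lower()))
        elif m.lastgroup == "num":
            tokens.append(("num", m.group("num")))
        elif m.lastgroup == "ident":
            tokens.append(("ident", m.group("ident")))
        else:
            tokens.append(("op", m.group("op")))
    return tokens


# AST nodes: ("cmp", [idents], op, number) | ("and"/"or", left, right) | ("not", node)
class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect_op(self, op: str) -> None:
        kind, val = self.next()
        if kind != "op" or val != op:
            raise RuleError(f"expected '{op}', got {val!r}")

    def parse(self):
        node = self.or_expr()
        if self.i != len(self.tokens):
            raise RuleError(f"trailing tokens in condition: {self.tokens[self.i:]}")
        return node

    def or_expr(self):
        node = self.and_expr()
        while self.peek() == ("kw", "or"):
            self.next()
            node = ("or", node, self.and_expr())
        return node

    def and_expr(self):
        node = self.unary()
        while self.peek() == ("kw", "and"):
            self.next()
            node = ("and", node, self.unary())
        return node

    def unary(self):
        kind, val = self.peek()
        if (kind, val) == ("kw", "not"):
            self.next()
            return ("not", self.unary())
        if (kind, val) == ("op", "("):
            self.next()
            node = self.or_expr()
            self.expect_op(")")
            return node
        return self.comparison()

    def comparison(self):
        idents = []
        kind, val = self.next()
        if kind != "ident":
            raise RuleError(f"expected identifier, got {val!r}")
        idents.append(val)
        while self.peek() == ("op", "+"):
            self.next()
            kind, val = self.next()
            if kind != "ident":
                raise RuleError(f"expected identifier after '+', got {val!r}")
            idents.append(val)
        kind, op = self.next()
        if kind != "op" or op not in ("<", "<=", ">", ">=", "==", "=", "!="):
            raise RuleError(f"expected comparison operator, got {op!r}")
        kind, num = self.next()
        if kind != "num":
            raise RuleError(f"expected numeric constant, got {num!r}")
        return ("cmp", idents, "==" if op == "=" else op, float(num))


def parse_condition(text: str):
    """Parse a condition string into an AST (raises :class:`RuleError`)."""
    return _Parser(_tokenize(text)).parse()


def _ast_identifiers(node) -> set[str]:
    if node[0] == "cmp":
        return set(node[1])
    if node[0] == "not":
        return _ast_identifiers(node[1])
    return _ast_identifiers(node[1]) | _ast_identifiers(node[2])


def _ast_eval(node, snapshot: StateSnapshot) -> bool:
    kind = node[0]
    if kind == "cmp":
        _, idents, op, const = node
        total = 0.0
        for ident in idents:
            if ident in snapshot.counts:
                total += snapshot.counts[ident]
            elif ident in snapshot.parameters:
                total += snapshot.parameters[ident]
            else:
                raise RuleError(f"unknown identifier '{ident}' in rule condition")
        return {
            "<": total < const,
            "<=": total <= const,
            ">": total > const,
            ">=": total >= const,
            "==": total == const,
            "!=": total != const,
        }[op]
    if kind == "not":
        return not _ast_eval(node[1], snapshot)
    if kind == "and":
        return _ast_eval(node[1], snapshot) and _ast_eval(node[2], snapshot)
    return _ast_eval(node[1], snapshot) or _ast_eval(node[2], snapshot)


@dataclass(frozen=True)
class Effect:
    """What a true rule does: set a parameter, or toggle a reaction.

    ``kind`` is ``"parameter"`` (then ``value`` is the new parameter value)
    or ``"reaction"`` (then ``enabled`` is the new enablement flag).
    """

    kind: str
    target: str
    value: float | None = None
    enabled: bool | None = None


@dataclass
class BooleanRule:
    """condition ⇒ effect; the condition string is parsed once, eagerly."""

    id: str
    condition: str
    effect: Effect
    _ast: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self._ast is None:
            object.__setattr__(self, "_ast", parse_condition(self.condition))

    def referenced_identifiers(self) -> set[str]:
        return _ast_identifiers(self._ast)

    def holds(self, snapshot: StateSnapshot) -> bool:
        return _ast_eval(self._ast, snapshot)


@dataclass(frozen=True)
class ParameterUpdate:
    """An accepted effect, to be applied at the next step boundary."""

    target: str
    kind: str  # "parameter" | "reaction"
    value: float | None = None
    enabled: bool | None = None


def evaluate_rules(
    snapshot: StateSnapshot, rules: Sequence[BooleanRule]
) -> list[ParameterUpdate]:
    """Evaluate every rule against the same snapshot; return effects of true rules.

    Synchronous semantics: conditions see only the snapshot, never each
    other's effects, so permuting rule order cannot change the update set.
    Two true rules targeting the same parameter/reaction with *different*
    values raise :class:`RuleConflictError` (identical values are merged).
    """
    updates: dict[tuple[str, str], tuple[ParameterUpdate, str]] = {}
    out: list[ParameterUpdate] = []
    for rule in rules:
        if not rule.holds(snapshot):
            continue
        eff = rule.effect
        upd = ParameterUpdate(
            target=eff.target, kind=eff.kind, value=eff.value, enabled=eff.enabled
        )
        key = (eff.kind, eff.target)
        if key in updates:
            prior, prior_rule = updates[key]
            if prior != upd:
                raise RuleConflictError(
                    f"rules '{prior_rule}' and '{rule.id}' both target "
                    f"{eff.kind} '{eff.target}' with different effects"
                )
            continue
        updates[key] = (upd, rule.id)
        out.append(upd)
    return out


def rules_from_dicts(entries: Iterable[dict]) -> list[BooleanRule]:
    """Build rules from manifest dictionaries.

    Each entry: ``{"id": ..., "condition": "...", "effect": {...}}`` where the
    effect is either ``{"type": "set_parameter", "target": p, "value": x}`` or
    ``{"type": "set_reaction_enabled", "target": r, "enabled": bool}``.
    """
    rules = []
    for e in entries:
        eff = e["effect"]
        if eff["type"] == "set_parameter":
            effect = Effect(kind="parameter", target=eff["target"], value=float(eff["value"]))
        elif eff["type"] == "set_reaction_enabled":
            effect = Effect(kind="reaction", target=eff["target"], enabled=bool(eff["enabled"]))
        else:
            raise RuleError(f"unknown effect type {eff['type']!r} in rule '{e.get('id')}'")
        rules.append(BooleanRule(id=e["id"], condition=e["condition"], effect=effect))
    return rules


def rules_to_dicts(rules: Sequence[BooleanRule]) -> list[dict]:
    out = []
    for r in rules:
        if r.effect.kind == "parameter":
            eff = {"type": "set_parameter", "target": r.effect.target, "value": r.effect.value}
        else:
            eff = {
                "type": "set_reaction_enabled",
                "target": r.effect.target,
                "enabled": r.effect.enabled,
            }
        out.append({"id": r.id, "condition": r.condition, "effect": eff})
    return out
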