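"""Gene-protein-reaction (GPR) boolean algebra.

A GPR rule links genes to a reaction as a boolean expression: AND nodes
represent enzyme complexes (every subunit required), OR nodes represent
isoenzymes (any one suffices).  The empty rule places no gene requirement
on the reaction, so it evaluates true — orphan and spontaneous reactions
are retained through strain derivation.  Absence of genetic support is
expressed by the distinct ``UNSATISFIABLE`` marker produced by
substitution, never by the empty rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


class GprError(ValueError):
    """Malformed GPR text."""


@dataclass(frozen=True)
class Gpr:
    """Immutable GPR expression tree.

    ``op`` is one of ``"leaf"``, ``"and"``, ``"or"``, ``"empty"``,
    ``"false"`` (the unsatisfiable marker).  Leaves carry a gene id in
    ``gene``; AND/OR nodes carry >= 2 children.
    """

    op: str
    gene: str | None = None
    children: tuple["Gpr", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.op == "leaf":
            if not self.gene:
                raise GprError("leaf without gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise GprError(f"{self.op} node needs >= 2 children")
        elif self.op not in ("empty", "false"):
            raise GprError(f"unknown GPR op {self.op!r}")

    # -- constructors ------------------------------------------------
    @staticmethod
    def leaf(gene: str) -> "Gpr":
        return Gpr("leaf", gene=gene)

    @staticmethod
    def and_(children: Iterable["Gpr"]) -> "Gpr":
        return _nary("and", list(children))

    @staticmethod
    def or_(children: Iterable["Gpr"]) -> "Gpr":
        return _nary("or", list(children))

    # -- predicates --------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    @property
    def is_unsatisfiable(self) -> bool:
        return self.op == "false"

    def genes(self) -> set[str]:
        """All gene ids appearing in the tree."""
        if self.op == "leaf":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience
        return serialize(self)


EMPTY = Gpr("empty")
UNSATISFIABLE = Gpr("false")


def _nary(op: str, children: list[Gpr]) -> Gpr:
    """Build an AND/OR node, flattening same-op children and collapsing
    degenerate arities so trees stay in normal form."""
    flat: list[Gpr] = []
    for c in children:
        if c.op == op:
            flat.extend(c.children)
        else:
            flat.append(c)
    if not flat:
        return EMPTY
    if len(flat) == 1:
        return flat[0]
    return Gpr(op, children=tuple(flat))


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append(("paren", ch, i))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            tokens.append((low, word, i))
        else:
            tokens.append(("gene", word, i))
        i = j
    return tokens


def parse(text: str) -> Gpr:
    """Parse a GPR string ("and"/"or", case-insensitive, parentheses).

    "and" binds tighter than "or".  The empty string parses to the empty
    rule.  Raises :class:`GprError` naming the offending token position.
    """
    tokens = _tokenize(text)
    if not tokens:
        return EMPTY
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or() -> Gpr:
        nonlocal pos
        terms = [parse_and()]
        while (t := peek()) and t[0] == "or":
            pos += 1
            terms.append(parse_and())
        return _nary("or", terms)

    def parse_and() -> Gpr:
        nonlocal pos
        terms = [parse_atom()]
        while (t := peek()) and t[0] == "and":
            pos += 1
            terms.append(parse_atom())
        return _nary("and", terms)

    def parse_atom() -> Gpr:
        nonlocal pos
        t = peek()
        if t is None:
            raise GprError(f"unexpected end of GPR at position {len(text)}")
        kind, word, at = t
        if kind == "gene":
            pos += 1
            return Gpr.leaf(word)
        if kind == "paren" and word == "(":
            pos += 1
            inner = parse_or()
            t2 = peek()
            if t2 is None or t2[1] != ")":
                raise GprError(f"unbalanced '(' opened at position {at}")
            pos += 1
            return inner
        raise GprError(f"unexpected token {word!r} at position {at}")

    result = parse_or()
    if pos != len(tokens):
        kind, word, at = tokens[pos]
        raise GprError(f"unexpected token {word!r} at position {at}")
    return result


def serialize(gpr: Gpr) -> str:
    """Serialize to the conventional "and"/"or" string; inverse of parse."""
    if gpr.is_empty:
        return ""
    if gpr.is_unsatisfiable:
        raise GprError("unsatisfiable GPR has no serial form")
    return _ser(gpr, parent=None)


def _ser(g: Gpr, parent: str | None) -> str:
    if g.op == "leaf":
        return g.gene  # type: ignore[return-value]
    joiner = f" {g.op} "
    body = joiner.join(_ser(c, g.op) for c in g.children)
    # "or" under "and" needs parentheses; same-op nesting never occurs
    # (trees are flattened) but parenthesize defensively.
    if parent == "and" and g.op == "or":
        return f"({body})"
    return body


# ---------------------------------------------------------------------------
# evaluation / substitution
# ---------------------------------------------------------------------------

def evaluate(gpr: Gpr, present: set[str] | frozenset[str]) -> bool:
    """Evaluate a GPR against a set of present genes.

    The empty rule is true (no requirement); the unsatisfiable marker is
    false; AND requires all children, OR any child, a leaf membership.
    """
    if gpr.op == "empty":
        return True
    if gpr.op == "false":
        return False
    if gpr.op == "leaf":
        return gpr.gene in present
    if gpr.op == "and":
        return all(evaluate(c, present) for c in gpr.children)
    return any(evaluate(c, present) for c in gpr.children)


def substitute(gpr: Gpr, mapping: Mapping[str, Iterable[str]]) -> Gpr:
    """Replace each leaf gene by the OR of its replacement genes.

    A gene absent from ``mapping`` is kept as-is.  An empty replacement
    set makes the leaf false; false propagates through AND and is pruned
    from OR; a tree that collapses entirely returns ``UNSATISFIABLE``.
    The empty rule is returned unchanged.
    """
    if gpr.op in ("empty", "false"):
        return gpr
    if gpr.op == "leaf":
        if gpr.gene not in mapping:
            return gpr
        repl = sorted(set(mapping[gpr.gene]))  # type: ignore[index]
        if not repl:
            return UNSATISFIABLE
        return _nary("or", [Gpr.leaf(g) for g in repl])
    subs = [substitute(c, mapping) for c in gpr.children]
    if gpr.op == "and":
        if any(s.is_unsatisfiable for s in subs):
            return UNSATISFIABLE
        return _nary("and", subs)
    live = [s for s in subs if not s.is_unsatisfiable]
    if not live:
        return UNSATISFIABLE
    return _nary("or", live)
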