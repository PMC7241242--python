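"""Boolean gene-association (GPR) expressions: parsing and evaluation.

Grammar (case-insensitive keywords)::

    expr   := term ( OR term )*
    term   := factor ( AND factor )*
    factor := '(' expr ')' | GENE

Gene identifiers are any run of characters other than whitespace and
parentheses that is not ``and``/``or``.
"""

from __future__ import annotations

import re
from typing import Callable, Mapping, Optional, Union

GprNode = Union[str, tuple]  # gene id, or ("and"|"or", [children])

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class GprParseError(ValueError):
    """Raised when a gene-association string cannot be parsed."""


def parse_gpr(rule: str) -> Optional[GprNode]:
    """Parse a boolean gene-association string into an AST.

    Returns ``None`` for an empty/blank rule.
    """
    tokens = _TOKEN.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> GprNode:
        children = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_term())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_term() -> GprNode:
        children = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_factor())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_factor() -> GprNode:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of gene association: {rule!r}")
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in {rule!r}")
        return take()

    node = parse_expr()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in gene association {rule!r}")
    return node


def gpr_genes(node: Optional[GprNode]) -> set:
    """All gene identifiers referenced by an AST."""
    if node is None:
        return set()
    if isinstance(node, str):
        return {node}
    _, children = node
    out: set = set()
    for child in children:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(
    node: Optional[GprNode],
    values: Mapping[str, float],
    and_mode: Callable = min,
    or_mode: Callable = max,
) -> Optional[float]:
    """Evaluate an AST against per-gene values.

    AND combines by ``and_mode`` (default min: limiting complex subunit),
    OR by ``or_mode`` (default max: best isozyme). Genes missing from
    *values* are skipped; a node whose genes are all missing evaluates to
    ``None``.
    """
    if node is None:
        return None
    if isinstance(node, str):
        return values.get(node)
    op, children = node
    resolved = [evaluate_gpr(c, values, and_mode, or_mode) for c in children]
    resolved = [v for v in resolved if v is not None]
    if not resolved:
        return None
    return and_mode(resolved) if op == "and" else or_mode(resolved)


def normalize_gpr(node: Optional[GprNode]) -> Optional[GprNode]:
    """Canonical form used for structural comparison (sorts operands)."""
    if node is None or isinstance(node, str):
        return node
    op, children = node
    norm = sorted((normalize_gpr(c) for c in children), key=repr)
    return (op, norm)


def gpr_to_string(node: Optional[GprNode]) -> str:
    if node is None:
        return ""
    if isinstance(node, str):
        return node
    op, children = node
    sep = f" {op} "
    parts = []
    for child in children:
        text = gpr_to_string(child)
        if isinstance(child, tuple):
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)
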