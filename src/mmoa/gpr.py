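"""Gene-protein-reaction (GPR) boolean expressions.

A GPR rule states which gene products enable a reaction: AND joins the
subunits of an enzymatic complex (all required), OR joins isoenzymes (any
one suffices). Rules are held as small immutable trees with gene-name
leaves; parsing of rule strings is delegated to cobrapy, whose grammar
covers the SBML/fbc conventions.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from typing import Union

from cobra.core.gene import GPR as _CobraGPR

__all__ = ["GeneLeaf", "GprAnd", "GprOr", "GPRExpression", "parse_gpr", "gpr_to_string", "gpr_genes"]


@dataclass(frozen=True)
class GeneLeaf:
    gene: str


@dataclass(frozen=True)
class GprAnd:
    children: tuple["GPRExpression", ...]


@dataclass(frozen=True)
class GprOr:
    children: tuple["GPRExpression", ...]


GPRExpression = Union[GeneLeaf, GprAnd, GprOr]


def _from_ast(node: ast.AST) -> GPRExpression:
    if isinstance(node, ast.Name):
        return GeneLeaf(node.id)
    if isinstance(node, ast.BoolOp):
        children = tuple(_from_ast(v) for v in node.values)
        if isinstance(node.op, ast.And):
            return GprAnd(children)
        if isinstance(node.op, ast.Or):
            return GprOr(children)
    raise ValueError(f"unsupported GPR syntax node: {ast.dump(node)}")


def parse_gpr(rule: str) -> GPRExpression | None:
    """Parse a GPR rule string like ``"(g1 or g2) and g3"``.

    Returns None for an empty rule. Raises ValueError if the rule cannot
    be parsed.
    """
    rule = (rule or "").strip()
    if not rule:
        return None
    cg = _CobraGPR.from_string(rule)
    if cg.body is None:
        return None
    return _from_ast(cg.body)


def gpr_to_string(gpr: GPRExpression | None) -> str:
    if gpr is None:
        return ""
    if isinstance(gpr, GeneLeaf):
        return gpr.gene
    joiner = " and " if isinstance(gpr, GprAnd) else " or "
    return "(" + joiner.join(gpr_to_string(c) for c in gpr.children) + ")"


def gpr_genes(gpr: GPRExpression | None) -> set[str]:
    if gpr is None:
        return set()
    if isinstance(gpr, GeneLeaf):
        return {gpr.gene}
    out: set[str] = set()
    for c in gpr.children:
        out |= gpr_genes(c)
    return out
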