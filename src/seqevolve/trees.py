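"""Newick trees with an optional branch-model flag dialect.

The simulator evolves sequences along a fixed, user-supplied phylogeny.
Beyond standard Newick (names, branch lengths), branches may carry a model
flag written as ``#flagname`` either immediately after the branch length or
immediately after the node name / closing parenthesis:

    (t1:0.5#fast, (t2:0.3, t3:0.3)#slow:0.4);

A flag selects a named substitution model for that branch and, by
inheritance, for every descendant branch until another flag overrides it.
Unflagged branches with no flagged ancestor use the partition's root model.
This dialect is specific to this package; trees without flags are plain
Newick.

Grammar (whitespace ignored)::

    tree     := subtree [';']
    subtree  := internal | leaf
    internal := '(' subtree (',' subtree)* ')' [name] ['#' flag] [':' length ['#' flag]]
    leaf     := name ['#' flag] [':' length ['#' flag]]
    name     := [A-Za-z0-9_.|-]+   (or any text inside single quotes)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset where parsing failed."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)
        self.offset = offset


@dataclass
class TreeNode:
    """A node of a rooted tree.

    ``branch_length`` is in expected substitutions per site (per codon site
    for codon models) and is required on every non-root node.  ``model_flag``
    optionally names the substitution model governing the branch leading to
    this node and, by inheritance, its descendants.
    """

    name: str | None = None
    branch_length: float | None = None
    model_flag: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]

    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def validate(self) -> None:
        names = [t.name for t in self.tips()]
        if any(n is None or n == "" for n in names):
            raise NewickError("every tip must be named")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NewickError(f"duplicate tip names: {dupes}")
        for node in self.preorder():
            if node is not self and node.branch_length is None:
                raise NewickError(f"node {node.name or '(internal)'} has no branch length")

    def to_newick(self, include_flags: bool = True) -> str:
        def fmt(node: TreeNode, is_root: bool) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if not is_root and node.branch_length is not None:
                s += f":{node.branch_length:g}"
            if include_flags and node.model_flag:
                s += f"#{node.model_flag}"
            return s

        return fmt(self, True) + ";"


_NAME_CHARS = set("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789_.|-")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickError:
        return NewickError(msg, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take_name(self) -> str:
        self.skip_ws()
        if self.peek() == "'":
            end = self.text.find("'", self.pos + 1)
            if end < 0:
                raise self.error("unterminated quoted name")
            name = self.text[self.pos + 1 : end]
            self.pos = end + 1
            return name
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] in _NAME_CHARS:
            self.pos += 1
        return self.text[start : self.pos]

    def take_flag_if_present(self, node: TreeNode) -> None:
        if self.peek() == "#":
            self.pos += 1
            flag = self.take_name()
            if not flag:
                raise self.error("empty model flag after '#'")
            node.model_flag = flag

    def take_length_if_present(self, node: TreeNode) -> None:
        if self.peek() == ":":
            self.pos += 1
            self.skip_ws()
            start = self.pos
            while self.pos < len(self.text) and self.text[self.pos] in "0123456789.eE+-":
                self.pos += 1
            tok = self.text[start : self.pos]
            try:
                bl = float(tok)
            except ValueError:
                raise self.error(f"malformed branch length {tok!r}") from None
            if bl < 0:
                raise self.error(f"negative branch length {bl}")
            node.branch_length = bl

    def subtree(self) -> TreeNode:
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            node.children.append(self.subtree())
            while self.peek() == ",":
                self.pos += 1
                node.children.append(self.subtree())
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.pos += 1
            name = self.take_name()
            node.name = name or None
        else:
            name = self.take_name()
            if not name:
                raise self.error("expected a taxon name or '('")
            node.name = name
        self.take_flag_if_present(node)
        self.take_length_if_present(node)
        self.take_flag_if_present(node)
        return node

    def parse(self) -> TreeNode:
        root = self.subtree()
        if self.peek() == ";":
            self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error(f"trailing characters {self.text[self.pos:self.pos+10]!r}")
        return root


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (with the optional ``#flag`` branch-model
    dialect) into a :class:`TreeNode`; the result passes validation."""
    tree = _Parser(text).parse()
    tree.validate()
    return tree


def read_newick(path: str) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read())


def balanced_tree(levels: int, branch_length: float, tip_prefix: str = "t") -> TreeNode:
    """A fully balanced rooted bifurcating tree with 2**levels tips, all
    branch lengths equal (the shape used by the site-heterogeneity
    validation experiments)."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    counter = iter(range(1, 2**levels + 1))

    def grow(depth: int) -> TreeNode:
        if depth == 0:
            return TreeNode(name=f"{tip_prefix}{next(counter)}", branch_length=branch_length)
        return TreeNode(
            branch_length=branch_length,
            children=[grow(depth - 1), grow(depth - 1)],
        )

    root = grow(levels)
    root.branch_length = None
    return root


def resolve_branch_models(tree: TreeNode, root_model: str) -> dict[int, str]:
    """Map id(node) -> model name for every node, applying flag inheritance:
    a branch uses its own flag if present, else the nearest flagged
    ancestor's, else ``root_model``."""
    resolved: dict[int, str] = {}

    def walk(node: TreeNode, inherited: str) -> None:
        model = node.model_flag or inherited
        resolved[id(node)] = model
        for child in node.children:
            walk(child, model)

    walk(tree, root_model)
    return resolved
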