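"""Newick parsing, serialization and leaf-restricted subtrees.

Two support-value dialects are understood:

* ``"internal-label"`` (default, the FastTree/RAxML style): a numeric
  label on an internal node is its support value, e.g.
  ``((A:1,B:1)0.97:0.5,C:2);``.  Non-numeric internal labels are kept
  as node names, never dropped.
* ``"branch-comment"``: a bracketed numeric comment attached to an
  internal node (before or after its branch length) is the support,
  e.g. ``((A:1,B:1):0.5[0.97],C:2);``.  Internal labels are then
  always plain names.

Branch lengths may be absent (cladogram input); downstream path-length
sums treat a missing length as 0.  Trees are used exactly as rooted by
the Newick nesting -- no rerooting is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .errors import NewickParseError, ValidationError

SUPPORT_CONVENTIONS = ("internal-label", "branch-comment")

_UNQUOTED_SAFE = re.compile(r"^[^\s(),:;\[\]']+$")


@dataclass
class TreeNode:
    """A node of a rooted tree.

    ``children`` is empty exactly for leaves.  ``support`` is only ever
    attached to internal nodes; leaf labels are names.
    """

    name: Optional[str] = None
    branch_length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Preorder traversal of the subtree rooted here."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_leaves(self) -> Iterator["TreeNode"]:
        for node in self.walk():
            if node.is_leaf:
                yield node

    def leaf_names(self) -> tuple[str, ...]:
        return tuple(node.name for node in self.iter_leaves())


@dataclass
class Tree:
    """A rooted tree plus the leaf order fixed by its serialization."""

    root: TreeNode
    leaf_order: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        names: list[str] = []
        seen: set[str] = set()
        for node in self.root.walk():
            if node.is_leaf:
                if not node.name:
                    raise ValidationError("leaf with empty name")
                if node.name in seen:
                    raise ValidationError(f"duplicate leaf name: {node.name!r}")
                seen.add(node.name)
                names.append(node.name)
                if node.support is not None:
                    raise ValidationError(
                        f"support value attached to leaf {node.name!r}"
                    )
            if node.branch_length is not None and node.branch_length < 0:
                raise ValidationError(
                    f"negative branch length {node.branch_length} on node "
                    f"{node.name or '<internal>'}"
                )
        if len(names) < 2:
            raise ValidationError("a tree must have at least 2 leaves")
        self.leaf_order = tuple(names)

    def internal_nodes(self) -> list[TreeNode]:
        """All internal nodes in preorder (root first)."""
        return [n for n in self.root.walk() if not n.is_leaf]


class _Parser:
    def __init__(self, text: str, convention: str, underscores_to_spaces: bool):
        self.text = text
        self.pos = 0
        self.convention = convention
        self.underscores = underscores_to_spaces

    def error(self, message: str) -> NewickParseError:
        return NewickParseError(message, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def read_comment(self) -> Optional[str]:
        """Consume one ``[...]`` comment if present, returning its body."""
        if self.peek() != "[":
            return None
        start = self.pos
        self.pos += 1
        depth = 1
        body_start = self.pos
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth -= 1
                if depth == 0:
                    body = self.text[body_start : self.pos]
                    self.pos += 1
                    return body
            self.pos += 1
        self.pos = start
        raise self.error("unterminated '[' comment")

    def read_label(self) -> Optional[str]:
        self.skip_ws()
        ch = self.peek()
        if ch == "'":
            return self._read_quoted()
        chars: list[str] = []
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch in "(),:;[" or ch.isspace():
                break
            chars.append(ch)
            self.pos += 1
        if not chars:
            return None
        label = "".join(chars)
        if self.underscores:
            label = label.replace("_", " ")
        return label

    def _read_quoted(self) -> str:
        self.pos += 1  # opening quote
        chars: list[str] = []
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch == "'":
                if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                    chars.append("'")
                    self.pos += 2
                    continue
                self.pos += 1
                return "".join(chars)
            chars.append(ch)
            self.pos += 1
        raise self.error("unterminated quoted label")

    def read_number(self, what: str) -> float:
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in "(),:;[" \
                and not self.text[self.pos].isspace():
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            return float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"expected a numeric {what}, got {token!r}") from None

    def parse(self) -> TreeNode:
        self.skip_ws()
        root = self.parse_subtree()
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';' terminating the tree")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing content after ';'")
        return root

    def parse_subtree(self) -> TreeNode:
        self.skip_ws()
        if self.peek() == "(":
            return self._parse_internal()
        return self._parse_leaf()

    def _parse_internal(self) -> TreeNode:
        self.pos += 1  # '('
        children = [self.parse_subtree()]
        self.skip_ws()
        while self.peek() == ",":
            self.pos += 1
            children.append(self.parse_subtree())
            self.skip_ws()
        if self.peek() != ")":
            raise self.error("expected ',' or ')'")
        self.pos += 1
        node = TreeNode(children=children)
        self._parse_decorations(node, internal=True)
        return node

    def _parse_leaf(self) -> TreeNode:
        self.skip_ws()
        name = self.read_label()
        if name is None:
            raise self.error("expected a leaf label")
        node = TreeNode(name=name)
        self._parse_decorations(node, internal=False)
        return node

    def _parse_decorations(self, node: TreeNode, internal: bool) -> None:
        """Label, branch length and comments following a node."""
        comments: list[str] = []

        def drain_comments() -> None:
            self.skip_ws()
            while self.peek() == "[":
                body = self.read_comment()
                if body is not None:
                    comments.append(body)
                self.skip_ws()

        drain_comments()
        if internal:
            label = self.read_label()
            if label is not None:
                if self.convention == "internal-label":
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
                else:
                    node.name = label
        drain_comments()
        if self.peek() == ":":
            self.pos += 1
            node.branch_length = self.read_number("branch length")
        drain_comments()
        if internal and self.convention == "branch-comment":
            for body in comments:
                try:
                    node.support = float(body.strip())
                except ValueError:
                    continue
                break


def parse_newick(
    text: str,
    support_convention: str = "internal-label",
    underscores_to_spaces: bool = False,
) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Parameters
    ----------
    text:
        One well-formed Newick statement terminated by ``;``.
    support_convention:
        ``"internal-label"`` or ``"branch-comment"`` (see module docs).
    underscores_to_spaces:
        When true, underscores in unquoted labels are converted to
        spaces per the Newick standard; off by default because modern
        pipelines put literal underscores in sequence identifiers.

    Raises
    ------
    NewickParseError
        On malformed input, naming the character offset.
    ValidationError
        On duplicate leaf names or other semantic violations.
    """
    if support_convention not in SUPPORT_CONVENTIONS:
        raise ValueError(
            f"support_convention must be one of {SUPPORT_CONVENTIONS}, "
            f"got {support_convention!r}"
        )
    root = _Parser(text, support_convention, underscores_to_spaces).parse()
    return Tree(root=root)


def _format_label(name: str) -> str:
    if _UNQUOTED_SAFE.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _format_number(value: float) -> str:
    # str() round-trips floats exactly in Python 3.
    return str(float(value))


def write_newick(
    tree: Tree,
    with_branch_lengths: bool = True,
    with_supports: bool = True,
) -> str:
    """Serialize a tree to one Newick statement ending in ``;``.

    Supports are emitted as internal-node labels.  With
    ``with_branch_lengths=False`` no ``:`` fields are written
    (cladogram output).
    """

    def emit(node: TreeNode) -> str:
        if node.is_leaf:
            out = _format_label(node.name)
        else:
            out = "(" + ",".join(emit(c) for c in node.children) + ")"
            if with_supports and node.support is not None:
                out += _format_number(node.support)
            elif node.name:
                out += _format_label(node.name)
        if with_branch_lengths and node.branch_length is not None:
            out += ":" + _format_number(node.branch_length)
        return out

    return emit(tree.root) + ";"


def restrict_to_leaves(tree: Tree, keep: Sequence[str] | set[str]) -> Tree:
    """Induced topology on a subset of leaves, as a cladogram.

    Pruned leaves are removed; internal nodes left with a single child
    are suppressed (the child is spliced to the grandparent, keeping
    its own support).  All branch lengths are dropped.  The relative
    order of surviving leaves is preserved.
    """
    keep_set = set(keep)
    known = set(tree.leaf_order)
    unknown = keep_set - known
    if unknown:
        raise ValidationError(
            f"unknown leaf name(s) in keep set: {sorted(unknown)!r}"
        )
    if len(keep_set) < 2:
        raise ValidationError("keep set must contain at least 2 leaves")

    def rebuild(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.name in keep_set:
                return TreeNode(name=node.name)
            return None
        kept = [c for c in (rebuild(child) for child in node.children) if c]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return TreeNode(name=node.name, support=node.support, children=kept)

    new_root = rebuild(tree.root)
    assert new_root is not None  # |keep| >= 2 guarantees survival
    return Tree(root=new_root)
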