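"""Phylogenetic tree parsing, dendrogram layout, search, and editing.

Supports the three common interchange formats — Newick, a PhyloXML subset
(clade nesting, names, branch lengths), and Nexus (the TREES block, with
translate tables honored) — and writes Newick back out losslessly.

The layout is a standard rectangular dendrogram: visible leaves occupy
rows 0, 1, 2, ... in traversal order, each internal node sits at the
arithmetic mean of its children's rows, and the x coordinate is the
cumulative branch length from the root (a missing length displays as one
unit but stays ``None`` in the data). Collapsed subtrees are drawn as
single leaves when the layout is asked to respect collapse state.

All traversals are iterative, so trees with tens of thousands of nodes
parse and lay out without recursion-depth limits.
"""

from __future__ import annotations

import os
import re
import warnings
import xml.etree.ElementTree as ET

__all__ = [
    "PhyloError",
    "PhyloNode",
    "TreeLayout",
    "parse_tree",
    "parse_newick",
    "write_newick",
    "layout_tree",
    "search_tree",
    "set_annotation",
    "set_branch_length",
    "toggle_collapse",
    "edit_tree",
]


class PhyloError(ValueError):
    pass


class PhyloNode:
    """A rooted tree node. Identity-hashed so layouts can key on nodes."""

    __slots__ = ("name", "branch_length", "annotation", "children", "collapsed")

    def __init__(
        self,
        name: str | None = None,
        branch_length: float | None = None,
        annotation: str = "",
        children: list["PhyloNode"] | None = None,
    ):
        if branch_length is not None and branch_length < 0:
            raise PhyloError(f"negative branch length {branch_length}")
        self.name = name
        self.branch_length = branch_length
        self.annotation = annotation
        self.children = children or []
        self.collapsed = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Pre-order iteration over the subtree (iterative)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["PhyloNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def n_nodes(self) -> int:
        return sum(1 for _ in self.walk())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloNode({self.name!r}, bl={self.branch_length}, {len(self.children)} children)"


# ---------------------------------------------------------------------------
# newick

_UNQUOTED_DISALLOWED = set(" ()[]':;,")


def _tokenize_newick(text: str):
    """Yield newick tokens; handles 'quoted labels' ('' escapes a quote)
    and skips [bracketed comments]."""
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c == "[":  # comment: skip to matching ]
            j = text.find("]", i + 1)
            if j == -1:
                raise PhyloError("unterminated [comment] in newick")
            i = j + 1
        elif c in "(),;":
            yield c, None
            i += 1
        elif c == ":":
            j = i + 1
            while j < n and (text[j].isdigit() or text[j] in ".+-eE"):
                j += 1
            try:
                value = float(text[i + 1 : j])
            except ValueError:
                raise PhyloError(
                    f"malformed branch length at offset {i}: {text[i:j]!r}"
                ) from None
            yield ":", value
            i = j
        elif c == "'":
            parts = []
            i += 1
            while True:
                j = text.find("'", i)
                if j == -1:
                    raise PhyloError("unterminated quoted label in newick")
                parts.append(text[i:j])
                if j + 1 < n and text[j + 1] == "'":  # doubled quote
                    parts.append("'")
                    i = j + 2
                else:
                    i = j + 1
                    break
            yield "label", "".join(parts)
        else:
            j = i
            while j < n and text[j] not in _UNQUOTED_DISALLOWED and not text[j].isspace():
                j += 1
            yield "label", text[i:j]
            i = j


def parse_newick(text: str) -> PhyloNode:
    """Parse one newick tree (iterative; no recursion limit)."""
    root = PhyloNode()
    node = root
    stack: list[PhyloNode] = []
    saw_semicolon = False
    for kind, value in _tokenize_newick(text):
        if saw_semicolon:
            raise PhyloError("trailing content after ';'")
        if kind == "(":
            child = PhyloNode()
            node.children.append(child)
            stack.append(node)
            node = child
        elif kind == ",":
            if not stack:
                raise PhyloError("',' outside parentheses")
            parent = stack[-1]
            child = PhyloNode()
            parent.children.append(child)
            node = child
        elif kind == ")":
            if not stack:
                raise PhyloError("unbalanced parentheses: too many ')'")
            node = stack.pop()
        elif kind == "label":
            node.name = value
        elif kind == ":":
            if value < 0:
                raise PhyloError(f"negative branch length {value}")
            node.branch_length = value
        elif kind == ";":
            if stack:
                raise PhyloError("unbalanced parentheses: unclosed '('")
            saw_semicolon = True
    if not saw_semicolon:
        raise PhyloError("newick tree is missing its terminating ';'")
    # "(A);" wraps a single subtree in a redundant root; keep as parsed.
    return root


def _format_label(name: str) -> str:
    if name == "" or any(c in _UNQUOTED_DISALLOWED or c.isspace() for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_length(value: float) -> str:
    return repr(value) if value != int(value) else str(int(value))


def write_newick(root: PhyloNode) -> str:
    """Serialize a tree; ``parse_newick(write_newick(t))`` is isomorphic to t."""
    out: list[str] = []
    # iterative post-order emission via an explicit work stack
    stack: list[tuple[PhyloNode, str]] = [(root, "node")]
    while stack:
        item, what = stack.pop()
        if what == "text":
            out.append(item)
            continue
        node = item
        tail = ""
        if node.name is not None:
            tail += _format_label(node.name)
        if node.branch_length is not None:
            tail += ":" + _format_length(node.branch_length)
        if node.is_leaf:
            out.append(tail or _format_label(""))
        else:
            stack.append((")" + tail, "text"))
            for i in range(len(node.children) - 1, -1, -1):
                stack.append((node.children[i], "node"))
                if i > 0:
                    stack.append((",", "text"))
            out.append("(")
    return "".join(out) + ";"


# ---------------------------------------------------------------------------
# phyloxml / nexus

_PHYLOXML_KNOWN = {"clade", "name", "branch_length", "phylogeny", "phyloxml"}


def parse_phyloxml(text: str) -> PhyloNode:
    """Parse the clade/name/branch_length subset of PhyloXML."""
    try:
        xml_root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise PhyloError(f"malformed PhyloXML: {exc}") from exc

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    def find_clade(element) -> ET.Element | None:
        for child in element:
            if local(child.tag) == "clade":
                return child
        return None

    phylogeny = None
    for elem in xml_root.iter():
        if local(elem.tag) == "phylogeny":
            phylogeny = elem
            break
    top = find_clade(phylogeny if phylogeny is not None else xml_root)
    if top is None:
        raise PhyloError("PhyloXML document has no <clade>")

    skipped: set[str] = set()

    def build_one(elem: ET.Element) -> PhyloNode:
        node = PhyloNode()
        if "branch_length" in elem.attrib:
            node.branch_length = float(elem.attrib["branch_length"])
        return node

    root = build_one(top)
    stack = [(top, root)]
    while stack:
        elem, node = stack.pop()
        for child in elem:
            tag = local(child.tag)
            if tag == "clade":
                child_node = build_one(child)
                node.children.append(child_node)
                stack.append((child, child_node))
            elif tag == "name":
                node.name = (child.text or "").strip() or None
            elif tag == "branch_length":
                node.branch_length = float((child.text or "").strip())
            elif tag not in _PHYLOXML_KNOWN:
                skipped.add(tag)
    if skipped:
        warnings.warn(
            f"PhyloXML elements not supported and skipped: {sorted(skipped)}",
            stacklevel=2,
        )
    return root


_NEXUS_COMMENT_RE = re.compile(r"\[[^\]]*\]")
_NEXUS_TREES_RE = re.compile(
    r"begin\s+trees\s*;(.*?)end\s*;", re.IGNORECASE | re.DOTALL
)
_NEXUS_TREE_CMD_RE = re.compile(
    r"\btree\s+\S+\s*=\s*(.*?);", re.IGNORECASE | re.DOTALL
)
_NEXUS_TRANSLATE_RE = re.compile(
    r"\btranslate\s+(.*?);", re.IGNORECASE | re.DOTALL
)


def parse_nexus(text: str) -> PhyloNode:
    """Parse the first tree of a Nexus TREES block (translate table honored).

    Other Nexus blocks (taxa, characters, ...) are ignored with a warning.
    """
    block = _NEXUS_TREES_RE.search(text)
    if not block:
        raise PhyloError("Nexus input has no TREES block")
    other = len(re.findall(r"begin\s+(\w+)", text, re.IGNORECASE)) - 1
    if other > 0:
        warnings.warn(
            f"ignoring {other} non-TREES Nexus block(s)", stacklevel=2
        )
    body = block.group(1)
    translate: dict[str, str] = {}
    tmatch = _NEXUS_TRANSLATE_RE.search(body)
    if tmatch:
        for entry in tmatch.group(1).split(","):
            parts = entry.split()
            if len(parts) >= 2:
                translate[parts[0]] = parts[1].strip("'")
    tree_match = _NEXUS_TREE_CMD_RE.search(body)
    if not tree_match:
        raise PhyloError("TREES block has no tree command")
    newick = _NEXUS_COMMENT_RE.sub("", tree_match.group(1)).strip() + ";"
    root = parse_newick(newick)
    if translate:
        for node in root.walk():
            if node.name in translate:
                node.name = translate[node.name]
    return root


def parse_tree(source: str, format: str = "newick") -> PhyloNode:
    """Parse a tree from a path or from literal text, in the given format."""
    text = source
    if "\n" not in source and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    if format == "newick":
        return parse_newick(text)
    if format == "phyloxml":
        return parse_phyloxml(text)
    if format == "nexus":
        return parse_nexus(text)
    raise PhyloError(f"unsupported tree format {format!r}")


# ---------------------------------------------------------------------------
# layout


class TreeLayout:
    """node -> (x, y): x is cumulative distance from the root, y the row."""

    def __init__(self):
        self.coords: dict[PhyloNode, tuple[float, float]] = {}
        self.n_rows = 0

    def x(self, node: PhyloNode) -> float:
        return self.coords[node][0]

    def y(self, node: PhyloNode) -> float:
        return self.coords[node][1]


def layout_tree(root: PhyloNode, collapse_respected: bool = True) -> TreeLayout:
    """Rectangular dendrogram coordinates (see module docstring).

    A collapsed node is treated as a leaf when ``collapse_respected``.
    """
    layout = TreeLayout()

    def visible_children(node: PhyloNode) -> list[PhyloNode]:
        if collapse_respected and node.collapsed:
            return []
        return node.children

    # x: pre-order accumulation; root uses its own length (or 0 if absent)
    root_x = root.branch_length if root.branch_length is not None else 0.0
    xs: dict[PhyloNode, float] = {root: root_x}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in reversed(visible_children(node)):
            step = child.branch_length if child.branch_length is not None else 1.0
            xs[child] = xs[node] + step
            stack.append(child)

    # y: leaves get consecutive rows in traversal order; internals the mean
    ys: dict[PhyloNode, float] = {}
    next_row = 0
    post: list[PhyloNode] = []
    stack2: list[tuple[PhyloNode, bool]] = [(root, False)]
    while stack2:
        node, expanded = stack2.pop()
        kids = visible_children(node)
        if expanded or not kids:
            post.append(node)
        else:
            stack2.append((node, True))
            for child in reversed(kids):
                stack2.append((child, False))
    for node in post:
        kids = visible_children(node)
        if not kids:
            ys[node] = float(next_row)
            next_row += 1
        else:
            ys[node] = sum(ys[c] for c in kids) / len(kids)
    layout.n_rows = next_row
    layout.coords = {node: (xs[node], ys[node]) for node in post}
    return layout


# ---------------------------------------------------------------------------
# search


def search_tree(
    root: PhyloNode,
    name: str | None = None,
    annotation: str | None = None,
    distance: float | None = None,
    direction: str = "ge",
    distance_mode: str = "root",
) -> set[PhyloNode]:
    """Find nodes by name/annotation substring or by distance.

    Substring matches are case-insensitive. Distance search compares either
    the cumulative distance from the root (``distance_mode="root"``) or the
    node's own edge length (``"edge"``) against the threshold, with
    ``direction`` "ge" or "le". Results ignore collapse state.
    """
    criteria = [c for c in (name, annotation, distance) if c is not None]
    if not criteria:
        raise PhyloError("empty search: give a name, annotation, or distance")
    if name is not None and name == "":
        raise PhyloError("empty name query is ambiguous")
    if annotation is not None and annotation == "":
        raise PhyloError("empty annotation query is ambiguous")
    if direction not in ("ge", "le"):
        raise PhyloError(f"direction must be 'ge' or 'le', got {direction!r}")

    dist_of: dict[PhyloNode, float] = {}
    if distance is not None:
        full = layout_tree(root, collapse_respected=False)
        dist_of = {node: xy[0] for node, xy in full.coords.items()}

    hits: set[PhyloNode] = set()
    for node in root.walk():
        if name is not None:
            if node.name is None or name.lower() not in node.name.lower():
                continue
        if annotation is not None:
            if annotation.lower() not in (node.annotation or "").lower():
                continue
        if distance is not None:
            if distance_mode == "edge":
                d = node.branch_length if node.branch_length is not None else 1.0
                if node is root:
                    d = root.branch_length if root.branch_length is not None else 0.0
            else:
                d = dist_of[node]
            if direction == "ge" and d < distance:
                continue
            if direction == "le" and d > distance:
                continue
        hits.add(node)
    return hits


# ---------------------------------------------------------------------------
# editing


def set_annotation(node: PhyloNode, text: str) -> PhyloNode:
    node.annotation = text
    return node


def set_branch_length(node: PhyloNode, value: float) -> PhyloNode:
    if value < 0:
        raise PhyloError(f"negative branch length {value}")
    node.branch_length = float(value)
    return node


def toggle_collapse(node: PhyloNode) -> PhyloNode:
    node.collapsed = not node.collapsed
    return node


def edit_tree(root: PhyloNode, op: str, node: PhyloNode, value=None) -> PhyloNode:
    """Dispatch an edit; only the targeted node's field changes."""
    if not any(n is node for n in root.walk()):
        raise PhyloError("node is not in this tree")
    if op == "set_annotation":
        set_annotation(node, str(value))
    elif op == "set_branch_length":
        set_branch_length(node, float(value))
    elif op == "toggle_collapse":
        toggle_collapse(node)
    else:
        raise PhyloError(f"unknown edit op {op!r}")
    return root
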