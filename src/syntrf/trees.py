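"""Bracketed parse trees and incremental-parser node counts.

A node count is the number of syntactic nodes an incremental parser is
assumed to build upon hearing a given word; it depends on the parsing
strategy.  Three standard strategies are implemented:

* top-down (maximally predictive): a node is built at its *leftmost*
  terminal descendant — upon "the" in "the train arrived" the parser
  posits the determiner, the NP and the clause node, a count of three;
* bottom-up (non-predictive): a node is built at its *rightmost* terminal
  descendant, i.e. once all its evidence has been heard;
* left-corner (mildly predictive): a node is projected as soon as its
  first child is complete.

Every strategy assigns each non-terminal node (pre-terminals included) to
exactly one terminal, so per-sentence counts always sum to the number of
non-terminal nodes in the tree.  Traces — phonologically empty terminals
marking moved elements — carry no acoustic signal; their counts are folded
onto the next overt word (or the preceding one for sentence-final traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "Tree",
    "ParseError",
    "read_trees",
    "write_tree",
    "count_topdown",
    "count_bottomup",
    "count_leftcorner",
    "fold_traces",
    "node_count_table",
]

DEFAULT_TRACE_PREFIX = "*"


class ParseError(ValueError):
    """Raised on malformed bracketed-tree input."""


@dataclass
class Tree:
    """Ordered labelled tree.  A leaf's ``label`` is its token string."""

    label: str
    children: list["Tree"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_preterminal(self) -> bool:
        return len(self.children) == 1 and self.children[0].is_leaf

    def leaves(self) -> list["Tree"]:
        if self.is_leaf:
            return [self]
        out: list[Tree] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def terminals(self) -> list[str]:
        return [lf.label for lf in self.leaves()]

    def internal_nodes(self) -> list["Tree"]:
        """All non-terminal nodes (pre-terminals included), preorder."""
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out

    def n_internal(self) -> int:
        return len(self.internal_nodes())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return self.label == other.label and self.children == other.children


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            yield ch, i
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            yield text[i:j], i
            i = j


def read_trees(text: str) -> list[Tree]:
    """Parse zero or more balanced bracketed trees from ``text``.

    Labels and tokens are whitespace-delimited.  Raises :class:`ParseError`
    (naming the character offset) on unbalanced brackets or an empty
    non-terminal ``()``.
    """
    trees: list[Tree] = []
    stack: list[Tree] = []
    expecting_label = False
    for tok, off in _tokenize(text):
        if tok == "(":
            node = Tree(label="")
            if stack:
                stack[-1].children.append(node)
            stack.append(node)
            expecting_label = True
        elif tok == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at offset {off}")
            node = stack.pop()
            if expecting_label or not node.children:
                raise ParseError(f"empty non-terminal at offset {off}")
            if not stack:
                trees.append(node)
        else:
            if not stack:
                raise ParseError(
                    f"token {tok!r} outside any tree at offset {off}"
                )
            if expecting_label:
                stack[-1].label = tok
                expecting_label = False
            else:
                stack[-1].children.append(Tree(label=tok))
    if stack:
        raise ParseError(f"unbalanced '(' — {len(stack)} unclosed at end of input")
    return trees


def write_tree(tree: Tree) -> str:
    """Serialize a tree so that :func:`read_trees` re-parses it identically."""
    if tree.is_leaf:
        return tree.label
    inner = " ".join(write_tree(c) for c in tree.children)
    return f"({tree.label} {inner})"


def _check(tree: Tree) -> None:
    if tree.is_leaf:
        raise ValueError("a bare leaf is not a valid parse tree")


def _leftmost_leaf_index(tree: Tree) -> dict[int, int]:
    """Map id(node) -> index of its leftmost terminal, for internal nodes."""
    index: dict[int, int] = {}
    counter = [0]

    def walk(node: Tree) -> int:
        if node.is_leaf:
            i = counter[0]
            counter[0] += 1
            return i
        first = walk(node.children[0])
        for c in node.children[1:]:
            walk(c)
        index[id(node)] = first
        return first

    walk(tree)
    return index


def _rightmost_leaf_index(tree: Tree) -> dict[int, int]:
    index: dict[int, int] = {}
    counter = [0]

    def walk(node: Tree) -> int:
        if node.is_leaf:
            i = counter[0]
            counter[0] += 1
            return i
        last = -1
        for c in node.children:
            last = walk(c)
        index[id(node)] = last
        return last

    walk(tree)
    return index


def count_topdown(tree: Tree) -> list[int]:
    """Per-terminal top-down counts: node built at its leftmost terminal."""
    _check(tree)
    counts = [0] * len(tree.leaves())
    for node, i in _leftmost_leaf_index(tree).items():
        counts[i] += 1
    return counts


def count_bottomup(tree: Tree) -> list[int]:
    """Per-terminal bottom-up counts: node built at its rightmost terminal."""
    _check(tree)
    counts = [0] * len(tree.leaves())
    for node, i in _rightmost_leaf_index(tree).items():
        counts[i] += 1
    return counts


def count_leftcorner(tree: Tree) -> list[int]:
    """Per-terminal left-corner counts.

    A pre-terminal is built at its own terminal; any other non-terminal is
    built once its first child's subtree is complete, i.e. at the rightmost
    terminal of the first child.
    """
    _check(tree)
    counts = [0] * len(tree.leaves())
    right = _rightmost_leaf_index(tree)
    leaf_pos = {id(lf): i for i, lf in enumerate(tree.leaves())}

    def walk(node: Tree) -> None:
        if node.is_leaf:
            return
        first = node.children[0]
        if first.is_leaf:
            counts[leaf_pos[id(first)]] += 1
        else:
            counts[right[id(first)]] += 1
        for c in node.children:
            walk(c)

    walk(tree)
    return counts


def trace_flags(tree: Tree, trace_prefix: str = DEFAULT_TRACE_PREFIX) -> list[bool]:
    """Per-terminal flags marking trace terminals (by token prefix)."""
    return [lf.label.startswith(trace_prefix) for lf in tree.leaves()]


def fold_traces(
    counts: Iterable[int],
    tree: Tree,
    trace_prefix: str = DEFAULT_TRACE_PREFIX,
) -> list[int]:
    """Fold trace counts onto overt words; returns counts over overt words.

    Each trace's count is added to the next overt word in the sentence;
    a sentence-final trace folds backward onto the preceding overt word.
    Per-sentence totals are preserved exactly.
    """
    counts = list(counts)
    flags = trace_flags(tree, trace_prefix)
    if len(counts) != len(flags):
        raise ValueError("counts not aligned with the tree's terminals")
    if all(flags):
        raise ValueError("sentence consists only of traces")
    out: list[int] = []
    pending = 0
    for c, is_trace in zip(counts, flags):
        if is_trace:
            pending += c
        else:
            out.append(c + pending)
            pending = 0
    if pending:  # sentence-final trace(s) fold backward
        out[-1] += pending
    return out


def node_count_table(
    trees: Iterable[Tree], trace_prefix: str = DEFAULT_TRACE_PREFIX
) -> pd.DataFrame:
    """Per-word node counts for a list of sentences, traces folded.

    Columns: sentence_id, word_index, token, topdown, bottomup, leftcorner.
    """
    rows = []
    for sid, tree in enumerate(trees):
        flags = trace_flags(tree, trace_prefix)
        tokens = [t for t, f in zip(tree.terminals(), flags) if not f]
        td = fold_traces(count_topdown(tree), tree, trace_prefix)
        bu = fold_traces(count_bottomup(tree), tree, trace_prefix)
        lc = fold_traces(count_leftcorner(tree), tree, trace_prefix)
        for wi, (tok, a, b, c) in enumerate(zip(tokens, td, bu, lc)):
            rows.append(
                dict(sentence_id=sid, word_index=wi, token=tok,
                     topdown=a, bottomup=b, leftcorner=c)
            )
    return pd.DataFrame(rows)
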