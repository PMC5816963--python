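"""Taxonomy tree of the identified core taxa.

The tree is a trie over rank paths of the core taxa's lineage strings — a
taxonomy tree, not an inferred phylogeny: shared rank prefixes become shared
internal nodes, and each distinct lineage is one leaf.  The container is a
scikit-bio ``TreeNode``; leaves carry their q-value, group-of-origin tag and
full canonical lineage as attributes.  Exports are Newick (with the full
lineage preserved in a bracket comment after each leaf label) and an indented
plain-text rendering in which numeric q-value annotation stands in for the
color-coded significance of graphical tools.
"""

from __future__ import annotations

from pathlib import Path

from skbio import TreeNode

from .corestats import CoreResult
from .tableops import canonicalize_lineage

__all__ = ["build_tree", "export_newick", "render_ascii"]

ROOT_NAME = "root"


def _path_tokens(canonical: str) -> list[str]:
    """Rank tokens of a lineage up to (and including) the last named rank."""
    lin = canonicalize_lineage(canonical)
    last_named = 0
    for i, (_, name) in enumerate(lin.ranks):
        if name:
            last_named = i
    tokens = []
    for prefix, name in lin.ranks[: last_named + 1]:
        tokens.append(f"{prefix}__{name}" if prefix else name)
    return tokens


def build_tree(results: list[CoreResult]) -> TreeNode:
    """Build the rank-nested trie over the lineages of ``results``.

    Shared prefixes are merged; trailing unnamed ranks are dropped so paths
    end at the deepest named rank.  Leaf count equals the number of distinct
    input lineages.  Insertion order does not affect the result: children are
    kept sorted by label.
    """
    root = TreeNode(name=ROOT_NAME)
    # sort for order-invariance of the built topology
    for res in sorted(results, key=lambda r: r.taxonomy.canonical):
        node = root
        for token in _path_tokens(res.taxonomy.canonical):
            child = next((c for c in node.children if c.name == token), None)
            if child is None:
                child = TreeNode(name=token)
                node.append(child)
            node = child
        node.q_value = res.q_value
        node.group_tag = getattr(res, "group_tag", "in")
        node.lineage = res.taxonomy.canonical
    return root


def _quote(label: str) -> str:
    if any(ch in label for ch in "()[]{}:;,' \t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _sanitize_comment(text: str) -> str:
    return text.replace("[", "(").replace("]", ")")


def _to_newick(node: TreeNode) -> str:
    label = _quote(node.name or "")
    if node.is_tip():
        comment = getattr(node, "lineage", None)
        return label + (f"[{_sanitize_comment(comment)}]" if comment else "")
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}){label}"


def export_newick(tree: TreeNode, path) -> None:
    """Serialize the taxonomy tree as Newick.

    Internal node labels are rank names; each leaf label is the terminal rank
    token followed by the sanitized full lineage in a bracket comment, which
    standard Newick readers skip.  Labels containing Newick metacharacters
    are quoted.
    """
    Path(path).write_text(_to_newick(tree) + ";\n")


def render_ascii(tree: TreeNode, annotate: bool = True) -> str:
    """Indented text rendering of the tree.

    With ``annotate``, each leaf is suffixed with its q-value (3 significant
    digits) and group tag.
    """
    lines: list[str] = []

    def walk(node: TreeNode, depth: int) -> None:
        label = node.name or ""
        if annotate and node.is_tip() and hasattr(node, "q_value"):
            label += f"  [q={node.q_value:.3g}, group={node.group_tag}]"
        lines.append("  " * depth + label)
        for child in node.children:
            walk(child, depth + 1)

    walk(tree, 0)
    return "\n".join(lines) + "\n"
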