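"""Dollo parsimony tracing of binary characters on a rooted tree.

Under Dollo parsimony a derived character state (here: a signed gene
adjacency) may be gained at most once, and is afterwards only lost; the
reconstruction places the single gain on the edge above the most recent
common ancestor of the taxa carrying the state and the minimum set of
losses below it.  Leaves where the character is *inapplicable* (one of the
pair's genes was itself lost) are treated as wildcards and assigned
whichever state avoids a loss.  Characters are then classified as
invariant, autapomorphic, synapomorphic (gain or single clade-level loss)
or homoplasic (two or more independent losses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd

from .gene_pairs import ABSENT, INAPPLICABLE, PRESENT, PairMatrix


@dataclass
class TreeNode:
    """A node of a rooted tree; the edge above a node is keyed by the node."""

    id: str
    name: Optional[str] = None
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class RootedTree:
    root: TreeNode
    leaf_by_name: dict[str, TreeNode]

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def nodes_preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def edges(self) -> list[str]:
        """Edge identifiers (child-node keyed), excluding the root."""
        return [n.id for n in self.nodes_preorder() if n.parent is not None]

    def mrca(self, leaf_names: Iterable[str]) -> TreeNode:
        names = list(leaf_names)
        paths = []
        for nm in names:
            node = self.leaf_by_name[nm]
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            candidate = paths[0][depth]
            if all(p[depth] is candidate for p in paths):
                mrca = candidate
            else:
                break
        return mrca


def _convert(dtree: dendropy.Tree) -> RootedTree:
    """Convert a dendropy tree; node ids are sorted clade leaf-name signatures."""
    root = dtree.seed_node

    def build(dnode, parent: Optional[TreeNode]) -> TreeNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            node = TreeNode(id=name, name=name, parent=parent)
            return node
        node = TreeNode(id="", name=dnode.label, parent=parent)
        for dch in dnode.child_nodes():
            node.children.append(build(dch, node))
        node.id = "|".join(sorted(
            lf.name for lf in node.leaves()
        ))
        return node

    tree = RootedTree(root=build(root, None), leaf_by_name={})
    names = []
    for lf in tree.root.leaves():
        names.append(lf.name)
        tree.leaf_by_name[lf.name] = lf
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf names in tree: {sorted(dupes)}")
    return tree


def read_newick(
    path_or_string: str | Path,
    outgroup: Optional[Sequence[str]] = None,
) -> RootedTree:
    """Read a rooted Newick tree; optionally (re)root with an outgroup.

    Accepts a file path or a literal Newick string.  With ``outgroup``
    given, the tree is rerooted so the outgroup clade's edge is basal.
    """
    text = None
    p = Path(str(path_or_string))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_string)
        if "(" not in text:
            raise ValueError(f"{path_or_string!r}: not a readable file or Newick string")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        if "Duplicate taxon" in str(exc) or "duplicate" in str(exc).lower():
            raise ValueError(f"duplicate leaf names in tree: {exc}") from exc
        raise ValueError(f"could not parse Newick input: {exc}") from exc
    dtree.is_rooted = True
    if outgroup:
        taxa = [t for t in dtree.taxon_namespace if t.label in set(outgroup)]
        missing = set(outgroup) - {t.label for t in taxa}
        if missing:
            raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
        mrca = dtree.mrca(taxa=taxa)
        if mrca is not dtree.seed_node:
            dtree.reroot_at_edge(mrca.edge, update_bipartitions=False)
        dtree.suppress_unifurcations()
    return _convert(dtree)


def check_taxa(tree: RootedTree, taxa: Iterable[str]) -> None:
    """Verify leaf names and matrix taxa coincide; list offenders otherwise."""
    leaves, wanted = set(tree.leaf_by_name), set(taxa)
    extra, missing = sorted(wanted - leaves), sorted(leaves - wanted)
    if extra or missing:
        raise ValueError(
            f"tree/matrix taxon mismatch: matrix-only={extra}, tree-only={missing}"
        )


# ---------------------------------------------------------------------------
# Dollo reconstruction


@dataclass
class DolloResult:
    character: str
    gain_edge: str  # edge id (child-node keyed) or 'root'
    loss_edges: list[str]
    n_losses: int
    classification: str
    ambiguous: bool

    def as_row(self) -> dict:
        return {
            "character": self.character,
            "gain_edge": self.gain_edge,
            "loss_edges": ";".join(self.loss_edges),
            "n_losses": self.n_losses,
            "classification": self.classification,
            "ambiguous": self.ambiguous,
        }


class NoPresentLeafError(ValueError):
    """The character is present in no leaf; Dollo tracing is undefined."""


def dollo_trace(
    tree: RootedTree,
    states: dict[str, str],
    character: str = "",
) -> DolloResult:
    """Single-gain, minimum-loss reconstruction of one character.

    ``states`` maps each leaf name to present/absent/inapplicable.  The
    gain sits on the edge above the MRCA of all present leaves ('root'
    when that ancestor is the root); losses are the topmost edges inside
    the gain clade whose subtree holds no present leaf, counted only when
    the subtree holds at least one definitely-absent leaf (purely
    inapplicable subtrees cost nothing).
    """
    check_taxa(tree, states)
    present = [nm for nm, s in states.items() if s == PRESENT]
    if not present:
        raise NoPresentLeafError(f"character {character!r} has no present leaf")
    gain_node = tree.mrca(present)
    gain_edge = "root" if gain_node.parent is None else gain_node.id

    loss_edges: list[str] = []

    def subtree_tally(node: TreeNode) -> tuple[int, int]:
        n_pres = n_abs = 0
        for lf in node.leaves():
            s = states[lf.name]
            if s == PRESENT:
                n_pres += 1
            elif s == ABSENT:
                n_abs += 1
        return n_pres, n_abs

    def walk(node: TreeNode) -> None:
        n_pres, n_abs = subtree_tally(node)
        if n_pres == 0:
            if n_abs > 0:
                loss_edges.append(node.id)
            return  # inapplicable-only subtrees are free under the wildcard rule
        for ch in node.children:
            walk(ch)

    for ch in gain_node.children:
        walk(ch)

    result = DolloResult(
        character=character,
        gain_edge=gain_edge,
        loss_edges=sorted(loss_edges),
        n_losses=len(loss_edges),
        classification="",
        ambiguous=False,
    )
    result.classification, result.ambiguous = classify_character(result, tree, states)
    return result


def classify_character(
    result: DolloResult, tree: RootedTree, states: dict[str, str]
) -> tuple[str, bool]:
    """Classify a traced character; flags ambiguity from inapplicable leaves.

    invariant: present at every (applicable) leaf, no losses.
    autapomorphic: gained on a pendant edge, or a single pendant-edge loss.
    synapomorphic_gain: gained on an internal edge, no losses.
    synapomorphic_loss: exactly one loss on an internal (>= 2-leaf) edge.
    homoplasic_loss: two or more independent losses.

    A character with any inapplicable leaf is flagged ambiguous: a taxon
    that lost one of the pair's genes could have carried the adjacency, so
    the character cannot be unambiguously placed on the tree.
    """
    gain_node = (
        tree.root
        if result.gain_edge == "root"
        else _node_by_id(tree, result.gain_edge)
    )
    applicable = [nm for nm, s in states.items() if s != INAPPLICABLE]
    all_present = all(states[nm] == PRESENT for nm in applicable)
    ambiguous = any(s == INAPPLICABLE for s in states.values())

    if result.n_losses == 0 and all_present:
        cls = "invariant"
    elif gain_node.is_leaf:
        cls = "autapomorphic"
    elif result.n_losses == 0:
        cls = "synapomorphic_gain"
    elif result.n_losses == 1:
        loss_node = _node_by_id(tree, result.loss_edges[0])
        cls = "synapomorphic_loss" if not loss_node.is_leaf else "autapomorphic"
    else:
        cls = "homoplasic_loss"
    return cls, ambiguous


def _node_by_id(tree: RootedTree, node_id: str) -> TreeNode:
    for node in tree.nodes_preorder():
        if node.id == node_id:
            return node
    raise KeyError(node_id)


def reconstructed_leaf_states(
    tree: RootedTree, result: DolloResult
) -> dict[str, str]:
    """Leaf states implied by (gain edge, loss edges) — for invariant checks."""
    gain_node = (
        tree.root
        if result.gain_edge == "root"
        else _node_by_id(tree, result.gain_edge)
    )
    losses = set(result.loss_edges)
    implied: dict[str, str] = {nm: ABSENT for nm in tree.leaf_by_name}

    def walk(node: TreeNode, state: str) -> None:
        if node.id in losses:
            state = ABSENT
        if node.is_leaf:
            implied[node.name] = state
            return
        for ch in node.children:
            walk(ch, state)

    walk(gain_node, PRESENT)
    return implied


def trace_matrix(
    tree: RootedTree, matrix: PairMatrix, skip_no_present: bool = True
) -> list[DolloResult]:
    """Dollo-trace every character of a pair matrix."""
    results = []
    for label in matrix.states.columns:
        states = {t: matrix.states.at[t, label] for t in matrix.taxa}
        try:
            results.append(dollo_trace(tree, states, character=label))
        except NoPresentLeafError:
            if not skip_no_present:
                raise
    return results


def per_branch_summary(
    results: Sequence[DolloResult],
    tree: RootedTree,
    exclude_ambiguous: bool = False,
) -> pd.DataFrame:
    """Characters gained and lost on each edge of the tree.

    ``exclude_ambiguous`` restricts the summary to characters whose call
    involves no gene loss (no inapplicable cell in the gain clade).
    """
    gains: dict[str, list[str]] = {}
    losses: dict[str, list[str]] = {}
    for res in results:
        if exclude_ambiguous and res.ambiguous:
            continue
        if res.classification == "invariant":
            continue
        if res.gain_edge != "root":
            gains.setdefault(res.gain_edge, []).append(res.character)
        for e in res.loss_edges:
            losses.setdefault(e, []).append(res.character)
    rows = []
    for edge in tree.edges():
        g, l = gains.get(edge, []), losses.get(edge, [])
        if g or l:
            rows.append(
                {
                    "edge": edge,
                    "gained": ";".join(sorted(g)),
                    "lost": ";".join(sorted(l)),
                    "n_gained": len(g),
                    "n_lost": len(l),
                }
            )
    return pd.DataFrame(rows, columns=["edge", "gained", "lost", "n_gained", "n_lost"])


def annotated_newick(tree: RootedTree, results: Sequence[DolloResult]) -> str:
    """Newick string with per-edge gain/loss counts as internal labels."""
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    for res in results:
        if res.gain_edge != "root":
            gains[res.gain_edge] = gains.get(res.gain_edge, 0) + 1
        for e in res.loss_edges:
            losses[e] = losses.get(e, 0) + 1

    def label(node: TreeNode) -> str:
        g, l = gains.get(node.id, 0), losses.get(node.id, 0)
        return f"+{g}-{l}" if (g or l) else ""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            tag = label(node)
            return node.name + (f"[&{tag}]" if tag else "")
        inner = ",".join(render(ch) for ch in node.children)
        tag = label(node)
        return f"({inner})" + (f"[&{tag}]" if tag else "")

    return render(tree.root) + ";"
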