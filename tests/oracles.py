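"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the Dollo oracle
enumerates gain placements and loss subsets, the repeat oracle compares
raw k-mer sets, and random trees are built by sequential joining.
"""

from __future__ import annotations

import itertools
import random

from plastidarch.dollo import RootedTree
from plastidarch.gene_pairs import ABSENT, INAPPLICABLE, PRESENT


def random_newick(leaves: list[str], rng: random.Random) -> str:
    """Random binary topology over the given leaves, as a Newick string."""
    nodes = list(leaves)
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def dollo_min_losses_oracle(tree: RootedTree, states: dict[str, str]) -> int:
    """Minimum losses over all single-gain placements and loss-edge subsets.

    Exhaustive: tries every node as the gain point and every combination
    of loss edges of growing size until the implied leaf states match the
    observations (inapplicable leaves match anything).
    """
    nodes = tree.nodes_preorder()
    loss_candidates = [n for n in nodes if n.parent is not None]
    present = {nm for nm, s in states.items() if s == PRESENT}

    paths = {}
    for lf in tree.root.leaves():
        path = []
        x = lf
        while x is not None:
            path.append(x)
            x = x.parent
        paths[lf.name] = path

    best = None
    for gain in nodes:
        below = {lf.name for lf in gain.leaves()}
        if not present <= below:
            continue
        upper = len(loss_candidates) if best is None else best
        for k in range(0, upper):
            found = False
            for combo in itertools.combinations(loss_candidates, k):
                ids = {id(x) for x in combo}
                ok = True
                for lf in tree.root.leaves():
                    s = states[lf.name]
                    if s == INAPPLICABLE:
                        continue
                    path = paths[lf.name]
                    if gain in path:
                        upto = path[: path.index(gain) + 1]
                        implied = (
                            ABSENT if any(id(x) in ids for x in upto) else PRESENT
                        )
                    else:
                        implied = ABSENT
                    if implied != s:
                        ok = False
                        break
                if ok:
                    found = True
                    break
            if found:
                best = k if best is None else min(best, k)
                break
    return best


def has_inverted_repeat_kmers(seq: str, min_len: int, circular: bool = True) -> bool:
    """True iff some ``min_len``-mer of the (circular) sequence also occurs
    reverse-complemented — a necessary condition for an IR of that length."""
    comp = str.maketrans("ACGT", "TGCA")
    d = seq + seq[: min_len - 1] if circular else seq
    kmers = {d[i : i + min_len] for i in range(len(d) - min_len + 1)}
    rc = seq.translate(comp)[::-1]
    rd = rc + rc[: min_len - 1] if circular else rc
    return any(rd[i : i + min_len] in kmers for i in range(len(rd) - min_len + 1))
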