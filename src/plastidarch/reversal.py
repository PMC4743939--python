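"""Minimum signed reversal distance (Hannenhalli–Pevzner theory).

Computes the exact minimum number of segment reversals transforming one
signed gene order into another via the breakpoint graph:

    d = (n + 1) - c + h + f

for a framed linear signed permutation, where ``c`` is the number of
alternating cycles, ``h`` the number of hurdles (unoriented components
whose elements are consecutive on the circle of unoriented positions) and
``f`` the fortress indicator (an odd number of hurdles, all of them
superhurdles).  Circular gene orders are handled by the standard anchor
reduction: rotate/reflect so one chosen gene reads +1 first, then solve
the linear problem on the remaining elements.

A breadth-first-search oracle over reversal moves provides exact distances
for small n, used to validate the closed-form computation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional

from .genome_model import SignedGeneOrder


@dataclass(frozen=True)
class SignedPermutation:
    """Signed integers 1..n in some order, on a line or a circle."""

    elements: tuple[int, ...]
    topology: str = "linear"  # 'linear' | 'circular'

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        n = len(self.elements)
        if sorted(abs(x) for x in self.elements) != list(range(1, n + 1)):
            raise ValueError("elements must be signed 1..n, each exactly once")

    @property
    def n(self) -> int:
        return len(self.elements)

    def is_identity(self) -> bool:
        if self.topology == "linear":
            return self.elements == tuple(range(1, self.n + 1))
        return canonical_circular(self.elements) == tuple(range(1, self.n + 1))


@dataclass(frozen=True)
class BreakpointGraphStats:
    """Breakpoint-graph decomposition and the resulting distance."""

    n: int
    c: int  # cycles
    h: int  # hurdles
    f: int  # fortress indicator
    d: int  # reversal distance

    def as_dict(self) -> dict:
        return {"n": self.n, "c": self.c, "h": self.h, "f": self.f, "d": self.d}


# ---------------------------------------------------------------------------
# building permutations from gene orders


def to_permutation(a: SignedGeneOrder, b: SignedGeneOrder) -> SignedPermutation:
    """Relabel genes so that ``b`` reads as the identity; return ``a``.

    Both orders must cover the same unsigned gene set (reduce first).  The
    topology is circular iff both inputs are circular.
    """
    if a.name_set() != b.name_set():
        raise ValueError("gene sets differ; apply reduce_to_shared first")
    rank = {g.name: (i + 1, g.sign) for i, g in enumerate(b.genes)}
    elements = tuple(rank[g.name][0] * (g.sign * rank[g.name][1]) for g in a.genes)
    topology = "circular" if (a.circular and b.circular) else "linear"
    return SignedPermutation(elements, topology)


def apply_reversal(elements: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    """Reverse (and negate) the segment at positions i..j inclusive."""
    return (
        elements[:i]
        + tuple(-x for x in reversed(elements[i : j + 1]))
        + elements[j + 1 :]
    )


def canonical_circular(elements: tuple[int, ...]) -> tuple[int, ...]:
    """Rotate (and reflect if needed) so the permutation starts with +1.

    A circular signed genome is unchanged by rotation and by reflection
    (reverse order, flip all signs); this picks the representative with +1
    in front.
    """
    els = elements
    k = next(i for i, x in enumerate(els) if abs(x) == 1)
    if els[k] < 0:
        els = tuple(-x for x in reversed(els))
        k = next(i for i, x in enumerate(els) if abs(x) == 1)
    return els[k:] + els[:k]


# ---------------------------------------------------------------------------
# Hannenhalli–Pevzner distance


def reversal_distance(p: SignedPermutation) -> BreakpointGraphStats:
    """Exact minimum reversal distance with full breakpoint-graph statistics."""
    if p.topology == "circular":
        reduced = _reduce_circular(p.elements)
        stats = _linear_stats(reduced)
        return BreakpointGraphStats(n=p.n, c=stats.c, h=stats.h, f=stats.f, d=stats.d)
    return _linear_stats(p.elements)


def _reduce_circular(elements: tuple[int, ...]) -> tuple[int, ...]:
    """Anchor gene 1 as +1 at the front and relabel the rest 1..n-1."""
    canon = canonical_circular(elements)
    return tuple((x - 1) if x > 0 else (x + 1) for x in canon[1:])


def _linear_stats(perm: tuple[int, ...]) -> BreakpointGraphStats:
    n = len(perm)
    if n == 0:
        return BreakpointGraphStats(0, 1, 0, 0, 0)
    # doubled-vertex representation framed by 0 and 2n+1
    u = [0]
    for x in perm:
        u.extend((2 * x - 1, 2 * x) if x > 0 else (-2 * x, -2 * x - 1))
    u.append(2 * n + 1)
    m = len(u)  # 2n + 2
    pos = [0] * m
    for idx, v in enumerate(u):
        pos[v] = idx

    # cycles: black edges pair indices (2i, 2i+1); gray edges pair values (v, v^1)
    seen = [False] * m
    cycles: list[list[int]] = []  # each cycle as a list of gray-edge min-values
    for start_idx in range(m):
        if seen[start_idx]:
            continue
        cycle_grays: list[int] = []
        idx = start_idx
        while not seen[idx]:
            seen[idx] = True
            idx_b = idx ^ 1  # black partner (same framed pair)
            seen[idx_b] = True
            v = u[idx_b]
            w = v ^ 1  # gray partner value
            cycle_grays.append(min(v, w))
            idx = pos[w]
        cycles.append(cycle_grays)
    c = len(cycles)

    # gray edge (v, v+1) is oriented iff its endpoints sit at same-parity indices
    def oriented(gmin: int) -> bool:
        return (pos[gmin] % 2) == (pos[gmin ^ 1] % 2)

    def span(gmin: int) -> tuple[int, int]:
        a, b = pos[gmin], pos[gmin ^ 1]
        return (a, b) if a < b else (b, a)

    nontrivial = [cy for cy in cycles if len(cy) > 1]
    if not nontrivial:
        return BreakpointGraphStats(n, c, 0, 0, (n + 1) - c)

    # interleaving graph over nontrivial cycles -> components (union-find)
    parent = list(range(len(nontrivial)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    spans = [[span(g) for g in cy] for cy in nontrivial]
    for i in range(len(nontrivial)):
        for j in range(i + 1, len(nontrivial)):
            if find(i) == find(j):
                continue
            if any(
                (a1 < a2 < b1 < b2) or (a2 < a1 < b2 < b1)
                for a1, b1 in spans[i]
                for a2, b2 in spans[j]
            ):
                union(i, j)

    comp_cycles: dict[int, list[int]] = {}
    for i in range(len(nontrivial)):
        comp_cycles.setdefault(find(i), []).append(i)

    unoriented_comps: list[set[int]] = []  # position sets of unoriented components
    for members in comp_cycles.values():
        if any(oriented(g) for i in members for g in nontrivial[i]):
            continue
        positions: set[int] = set()
        for i in members:
            for g in nontrivial[i]:
                positions.add(pos[g])
                positions.add(pos[g ^ 1])
        unoriented_comps.append(positions)

    if not unoriented_comps:
        return BreakpointGraphStats(n, c, 0, 0, (n + 1) - c)

    h, f = _hurdles_and_fortress(unoriented_comps)
    return BreakpointGraphStats(n, c, h, f, (n + 1) - c + h + f)


def _hurdles_and_fortress(unoriented_comps: list[set[int]]) -> tuple[int, int]:
    """Count hurdles and decide the fortress on the circle of unoriented
    positions.

    A hurdle is an unoriented component whose positions are consecutive in
    the circular sequence of all unoriented-component positions (joining the
    two frame ends makes the 'greatest hurdle' case uniform).  A superhurdle
    is a hurdle whose removal turns some non-hurdle into a hurdle; a fortress
    arises when the hurdles are odd in number and all of them are super.
    """
    owner: dict[int, int] = {}
    for ci, positions in enumerate(unoriented_comps):
        for p in positions:
            owner[p] = ci
    ring = [owner[p] for p in sorted(owner)]

    def contiguous(comp: int, seq: list[int]) -> bool:
        k = len(seq)
        idxs = [i for i, x in enumerate(seq) if x == comp]
        if len(idxs) <= 1:
            return True
        gaps = [(idxs[(i + 1) % len(idxs)] - idxs[i]) % k for i in range(len(idxs))]
        # contiguous on the circle iff all circular gaps but one equal 1
        return sum(1 for g in gaps if g != 1) <= 1

    hurdles = [ci for ci in range(len(unoriented_comps)) if contiguous(ci, ring)]
    h = len(hurdles)
    if h % 2 == 0 or h < 3:
        return h, 0
    non_hurdles = [ci for ci in range(len(unoriented_comps)) if ci not in hurdles]
    for hu in hurdles:
        reduced = [x for x in ring if x != hu]
        if not any(contiguous(nh, reduced) for nh in non_hurdles):
            return h, 0  # this hurdle is not super
    return h, 1


# ---------------------------------------------------------------------------
# brute-force oracle


def bfs_distance_oracle(p: SignedPermutation, cap: Optional[int] = None) -> int:
    """Exact reversal distance by breadth-first search over reversal moves.

    Guarded to n <= 8 (the state space is n! * 2^n).  Circular states are
    canonicalized over rotations and reflection so the search runs on
    genome equivalence classes.  ``cap`` aborts the search beyond that
    depth (raises RuntimeError).
    """
    n = p.n
    if n > 8:
        raise ValueError("BFS oracle is limited to n <= 8")
    if n == 0:
        return 0
    target = tuple(range(1, n + 1))

    if p.topology == "linear":
        canon = lambda els: els  # noqa: E731
        start = p.elements
    else:
        canon = canonical_circular
        start = canon(p.elements)
    if canon(start) == target:
        return 0
    frontier = deque([(start, 0)])
    visited = {canon(start)}
    while frontier:
        state, depth = frontier.popleft()
        if cap is not None and depth >= cap:
            raise RuntimeError(f"BFS oracle exceeded cap={cap}")
        for i in range(n):
            for j in range(i, n):
                nxt = apply_reversal(state, i, j)
                key = canon(nxt)
                if key == target:
                    return depth + 1
                if key not in visited:
                    visited.add(key)
                    frontier.append((nxt, depth + 1))
    raise AssertionError("reversal moves connect all signed permutations")


def all_distances_bfs(n: int, topology: str = "linear") -> dict[tuple[int, ...], int]:
    """Distances from the identity to every signed permutation of size n.

    One BFS over the whole state space; distances are symmetric, so the
    result oracle-checks any permutation of that size.  Intended for n <= 6
    (linear) in tests.
    """
    if n > 7:
        raise ValueError("full BFS beyond n=7 is too large")
    identity = tuple(range(1, n + 1))
    canon = (lambda e: e) if topology == "linear" else canonical_circular
    start = canon(identity)
    dist: dict[tuple[int, ...], int] = {start: 0}
    frontier = deque([start])
    while frontier:
        state = frontier.popleft()
        d = dist[state]
        for i in range(n):
            for j in range(i, n):
                key = canon(apply_reversal(state, i, j))
                if key not in dist:
                    dist[key] = d + 1
                    frontier.append(key)
    return dist
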