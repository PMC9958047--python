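"""(6,6) body-bar pebble game and rigid-cluster decomposition.

Each body holds six pebbles (its six degrees of freedom).  A bar between two
bodies is independent iff seven pebbles can be gathered on its endpoints;
accepting it orients the bar and consumes one pebble.  Two bodies are
mutually rigid iff, after all bars are inserted, seven pebbles can *not* be
gathered on the pair — i.e. a further generic bar between them would be
redundant.  The decomposition reported here is the partition induced by the
transitive closure of pairwise mutual rigidity (matching FIRST-style rigid
cluster labelling on body-bar networks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ConstraintNetwork

PEBBLES_PER_BODY = 6
_NEED = PEBBLES_PER_BODY + 1


@dataclass(frozen=True)
class RigidDecomposition:
    labels: np.ndarray          # cluster id per body (0-based, arbitrary)
    cluster_sizes: tuple[int, ...]   # descending
    largest_fraction: float

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def size_counts(self) -> dict[int, int]:
        """Map cluster size s -> number of clusters of that size (n_s)."""
        out: dict[int, int] = {}
        for s in self.cluster_sizes:
            out[s] = out.get(s, 0) + 1
        return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


class PebbleGame:
    """Mutable game state over ``n`` bodies."""

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [PEBBLES_PER_BODY] * n
        # directed multigraph of accepted bars: adj[u][v] = count
        self.adj: list[dict[int, int]] = [dict() for _ in range(n)]

    # -- pebble motion ------------------------------------------------------

    def _free_pebble(self, root: int, exclude: tuple[int, int]) -> bool:
        """DFS from ``root`` along directed bars for a body with a spare
        pebble outside ``exclude``; on success reverse the path and move one
        pebble to ``root``."""
        seen = {root}
        stack = [(root, iter(self.adj[root]))]
        parent: dict[int, int] = {}
        while stack:
            u, it = stack[-1]
            found = None
            for v in it:
                if v in seen or self.adj[u].get(v, 0) == 0:
                    continue
                seen.add(v)
                parent[v] = u
                if v not in exclude and self.pebbles[v] > 0:
                    found = v
                    break
                stack.append((v, iter(self.adj[v])))
                break
            else:
                stack.pop()
                continue
            if found is not None:
                # walk back reversing one bar per hop
                self.pebbles[found] -= 1
                w = found
                while w != root:
                    p = parent[w]
                    self.adj[p][w] -= 1
                    if self.adj[p][w] == 0:
                        del self.adj[p][w]
                    self.adj[w][p] = self.adj[w].get(p, 0) + 1
                    w = p
                self.pebbles[root] += 1
                return True
        return False

    def _collect(self, u: int, v: int, need: int = _NEED) -> bool:
        """Try to gather ``need`` pebbles on the pair (u, v)."""
        while self.pebbles[u] + self.pebbles[v] < need:
            if not (self._free_pebble(u, (u, v))
                    or self._free_pebble(v, (u, v))):
                return False
        return True

    # -- public API ---------------------------------------------------------

    def insert_bar(self, u: int, v: int) -> bool:
        """Insert one bar; returns True when independent."""
        if u == v:
            raise ValueError("self-bars not allowed")
        if not self._collect(u, v):
            return False
        self.adj[u][v] = self.adj[u].get(v, 0) + 1
        self.pebbles[u] -= 1
        return True

    def rigid_pair(self, u: int, v: int) -> bool:
        """True iff a further generic bar between u and v would be redundant."""
        return not self._collect(u, v)


def play_game(network: ConstraintNetwork,
              e_cut: float | None = None) -> PebbleGame:
    """Insert every present bar (canonical order, expanded to multiplicity)."""
    game = PebbleGame(network.n_bodies)
    for bar in network.canonical_bars(e_cut):
        for _ in range(bar.multiplicity):
            game.insert_bar(bar.i, bar.j)
    return game


def _components(n: int, bars) -> list[list[int]]:
    uf = _UnionFind(n)
    for b in bars:
        uf.union(b.i, b.j)
    comp: dict[int, list[int]] = {}
    for x in range(n):
        comp.setdefault(uf.find(x), []).append(x)
    return list(comp.values())


def decompose(game: PebbleGame, network: ConstraintNetwork,
              e_cut: float | None = None) -> RigidDecomposition:
    """Rigid-cluster partition from an already-played game.

    Pairwise rigidity is tested within each connected component of the
    present-bar graph (bodies in different components can never be mutually
    rigid); already-merged pairs are skipped.
    """
    uf = _UnionFind(game.n)
    for comp in _components(game.n, network.bars_present(e_cut)):
        for a in range(len(comp)):
            for b in range(a + 1, len(comp)):
                u, v = comp[a], comp[b]
                if uf.find(u) == uf.find(v):
                    continue
                if game.rigid_pair(u, v):
                    uf.union(u, v)
    roots = [uf.find(x) for x in range(game.n)]
    ids = {r: i for i, r in enumerate(dict.fromkeys(roots))}
    labels = np.array([ids[r] for r in roots])
    sizes = tuple(sorted(np.bincount(labels).tolist(), reverse=True))
    return RigidDecomposition(labels=labels, cluster_sizes=sizes,
                              largest_fraction=sizes[0] / game.n)


def pebble_game(network: ConstraintNetwork,
                e_cut: float | None = None) -> RigidDecomposition:
    """Full pipeline: play the (6,6) game on the present bars and return the
    rigid-cluster decomposition."""
    return decompose(play_game(network, e_cut), network, e_cut)
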