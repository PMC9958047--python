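"""Independent oracles used by the test suite.

The rigidity oracle places every bar generically in 3-space and works with
the numeric rank of the body-bar rigidity matrix: each body contributes six
velocity coordinates (linear + angular), and a bar attached at points a, b
on bodies u, v yields the row

    [d, a x d]  on u,   [-d, -(b x d)]  on v,   d = a - b.

Two bodies are mutually rigid iff a further generic test bar between them
falls inside the row space (the rank does not increase).  The partition is
the transitive closure of pairwise rigidity, exactly as in the pebble-game
decomposition, so the two routes are comparable cluster by cluster.
"""

from __future__ import annotations

import numpy as np


def bar_rows(n_bodies: int, bars, rng: np.random.Generator) -> np.ndarray:
    rows = []
    for b in bars:
        for _ in range(b.multiplicity):
            rows.append(_generic_row(n_bodies, b.i, b.j, rng))
    if not rows:
        return np.zeros((0, 6 * n_bodies))
    return np.array(rows)


def _generic_row(n: int, u: int, v: int, rng) -> np.ndarray:
    a = rng.normal(size=3)
    c = rng.normal(size=3)
    d = a - c
    row = np.zeros(6 * n)
    row[6 * u:6 * u + 3] = d
    row[6 * u + 3:6 * u + 6] = np.cross(a, d)
    row[6 * v:6 * v + 3] = -d
    row[6 * v + 3:6 * v + 6] = -np.cross(c, d)
    return row


def rank_oracle_partition(n_bodies: int, bars,
                          rng: np.random.Generator) -> np.ndarray:
    """Cluster label per body from the rigidity-matrix rank test."""
    M = bar_rows(n_bodies, bars, rng)
    if M.shape[0]:
        _, s, vt = np.linalg.svd(M, full_matrices=False)
        tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        basis = vt[s > max(tol, 1e-9)]
    else:
        basis = np.zeros((0, 6 * n_bodies))

    parent = list(range(n_bodies))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(n_bodies):
        for v in range(u + 1, n_bodies):
            if find(u) == find(v):
                continue
            row = _generic_row(n_bodies, u, v, rng)
            if basis.size:
                resid = row - (row @ basis.T) @ basis
            else:
                resid = row
            if np.linalg.norm(resid) < 1e-6 * np.linalg.norm(row):
                ru, rv = find(u), find(v)
                parent[max(ru, rv)] = min(ru, rv)

    roots = [find(x) for x in range(n_bodies)]
    ids: dict[int, int] = {}
    return np.array([ids.setdefault(r, len(ids)) for r in roots])


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when the two labelings induce identical partitions."""
    if len(a) != len(b):
        return False
    fwd: dict[int, int] = {}
    bwd: dict[int, int] = {}
    for x, y in zip(a.tolist(), b.tolist()):
        if fwd.setdefault(x, y) != y or bwd.setdefault(y, x) != x:
            return False
    return True
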