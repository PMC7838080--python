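"""Independent brute-force oracles the implementation is checked against.

Deliberately written in a different style from the package (top-down
memoized recursion / plain loops / boolean matrix powers) so that shared
bugs are unlikely.
"""

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def global_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal global affine-gap score by memoized recursion over the
    three affine states (match, gap-in-b, gap-in-a); a gap of length g
    costs gap_open + g * gap_extend, end gaps included."""
    go = gap_open + gap_extend  # first gap residue
    ge = gap_extend

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        if state == "M":
            if i == 0 or j == 0:
                return NEG
            prev = max(best(i - 1, j - 1, s) for s in "MXY")
            if prev == NEG:
                return NEG
            return prev + _B62[a[i - 1], b[j - 1]]
        if state == "X":  # consumed a[i-1] against a gap
            if i == 0:
                return NEG
            return max(
                max(best(i - 1, j, s) for s in "MY") - go,
                best(i - 1, j, "X") - ge,
            )
        # state == "Y": consumed b[j-1] against a gap
        if j == 0:
            return NEG
        return max(
            max(best(i, j - 1, s) for s in "MX") - go,
            best(i, j - 1, "Y") - ge,
        )

    return int(max(best(len(a), len(b), s) for s in "MXY"))


def local_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Smith–Waterman affine-gap optimum by plain nested loops."""
    go, ge = gap_open + gap_extend, gap_extend
    la, lb = len(a), len(b)
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(M[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(M[i - 1][j] - go, F[i - 1][j] - ge)
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0, s + max(M[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            )
            best = max(best, M[i][j], E[i][j], F[i][j])
    return int(max(best, 0.0))


def motif_windows_oracle(seq: str, max_dfgwg_mismatch: int):
    """All (motif, 1-based start) pairs by exhaustive window enumeration."""
    hits = set()
    for i in range(len(seq) - 4):
        w = seq[i : i + 5]
        if w.startswith("H") and w.endswith("D"):
            hits.add(("HXXXD", i + 1))
        if sum(x != y for x, y in zip(w, "DFGWG")) <= max_dfgwg_mismatch:
            hits.add(("DFGWG", i + 1))
    return hits


def components_by_matrix_power(n_nodes: int, edges) -> list[frozenset]:
    """Connected components via boolean transitive closure."""
    reach = np.eye(n_nodes, dtype=bool)
    for u, v in edges:
        reach[u, v] = reach[v, u] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    comps = set()
    for i in range(n_nodes):
        comps.add(frozenset(np.flatnonzero(reach[i]).tolist()))
    return sorted(comps, key=lambda c: min(c))


def greedy_redundancy_oracle(records, threshold, identity_fn):
    """Replay the greedy collapse rule from an explicit all-pairs
    identity table."""
    ident = {}
    for i, a in enumerate(records):
        for j, b in enumerate(records):
            if i < j:
                ident[(a.id, b.id)] = identity_fn(a, b)

    def get(x, y):
        return ident.get((x, y), ident.get((y, x), 1.0))

    groups: dict[str, list[str]] = {}
    for rec in records:
        for rep in groups:
            if get(rep, rec.id) >= threshold:
                groups[rep].append(rec.id)
                break
        else:
            groups[rec.id] = [rec.id]
    return groups


def kabsch_rmsd_by_optimizer(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimal RMSD by direct numerical optimization over a rotation-
    vector parametrization (reflection-free by construction)."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return ((Qc @ R.T - Pc) ** 2).sum()

    best = np.inf
    for guess in ([0, 0, 0], [np.pi, 0, 0], [0, np.pi, 0], [0, 0, np.pi],
                  [np.pi / 2, np.pi / 2, 0], [-np.pi / 2, 0, np.pi / 2]):
        res = minimize(cost, np.array(guess, float), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best / len(P)))


def random_additive_matrix(n_taxa: int, rng: np.random.Generator):
    """A distance matrix that is exactly additive on a random binary
    tree; returns (ids, matrix, networkx tree graph)."""
    import networkx as nx

    g = nx.Graph()
    ids = [f"t{i}" for i in range(n_taxa)]
    groups = [[i] for i in ids]
    g.add_nodes_from(ids)
    counter = 0
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        new = f"int{counter}"
        counter += 1
        g.add_edge(groups[i][0], new, weight=float(rng.uniform(0.1, 1.0)))
        g.add_edge(groups[j][0], new, weight=float(rng.uniform(0.1, 1.0)))
        merged = [new]
        groups = [grp for k, grp in enumerate(groups) if k not in (i, j)] + [merged]
    d = np.zeros((n_taxa, n_taxa))
    import networkx as nx

    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            d[x, y] = d[y, x] = lengths[ids[x]][ids[y]]
    return ids, d
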