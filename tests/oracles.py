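"""Independent brute-force reference implementations used only by tests.

Everything here is written against the plain parent-edge dictionaries of a
DAG, never against the package's graph class internals, so the two code
paths share no logic beyond the mathematical definitions.
"""

from __future__ import annotations

import itertools
import math


def bfs_ancestors(parents: dict[str, list[tuple[str, str]]], t: str) -> set[str]:
    """Transitive closure over parent edges by explicit BFS, including t."""
    seen = {t}
    frontier = [t]
    while frontier:
        nxt = []
        for x in frontier:
            for p, _rel in parents[x]:
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return seen


def all_upward_paths(parents, t) -> list[list[str]]:
    """Every path from t up to a parentless term, by exhaustive DFS."""
    if not parents[t]:
        return [[t]]
    paths = []
    for p, _rel in parents[t]:
        for tail in all_upward_paths(parents, p):
            paths.append([t] + tail)
    return paths


def longest_depth(parents, t) -> int:
    """Longest root-to-term path length via exhaustive path enumeration."""
    return max(len(path) - 1 for path in all_upward_paths(parents, t))


def longest_path_between(parents, ancestor, t) -> int:
    """Longest path length from ancestor down to t (enumerative)."""
    best = -1
    for path in all_upward_paths(parents, t):
        if ancestor in path:
            best = max(best, path.index(ancestor))
    if best < 0:
        raise ValueError(f"{ancestor} not above {t}")
    return best


def ic_table(parents, annotations: dict[str, list[str]]) -> dict[str, float]:
    """Annotation-frequency IC recomputed from scratch with BFS closures."""
    freq: dict[str, int] = {}
    for _protein, terms in annotations.items():
        for t in terms:
            for a in bfs_ancestors(parents, t):
                freq[a] = freq.get(a, 0) + 1
    roots = [t for t in parents if not parents[t]]
    assert len(roots) == 1
    root = roots[0]
    return {t: -math.log(f / freq[root]) for t, f in freq.items()}


def resnik(parents, ic: dict[str, float], t1, t2) -> float:
    common = bfs_ancestors(parents, t1) & bfs_ancestors(parents, t2)
    return max(ic[a] for a in common)


def lin(parents, ic, t1, t2) -> float:
    return 2.0 * resnik(parents, ic, t1, t2) / (ic[t1] + ic[t2])


def pekar(parents, t1, t2) -> float:
    roots = [t for t in parents if not parents[t]]
    root = roots[0]
    best = 0.0
    for c in bfs_ancestors(parents, t1) & bfs_ancestors(parents, t2):
        d_root = longest_path_between(parents, root, c)
        d1 = longest_path_between(parents, c, t1)
        d2 = longest_path_between(parents, c, t2)
        if d_root + d1 + d2 > 0:
            best = max(best, d_root / (d_root + d1 + d2))
    return best


def wang_svalues(parents, children, t, w) -> dict[str, float]:
    """S-values by memoised recursion straight from the definition."""
    s = {t: 1.0}

    def visit(node):
        if node in s:
            return s[node]
        val = 0.0
        for child, rel in children.get(node, []):
            if child in bfs_ancestors(parents, t):
                val = max(val, w[rel] * visit(child))
        s[node] = val
        return val

    for a in bfs_ancestors(parents, t):
        visit(a)
    return s


def wang(parents, t1, t2, w_is_a=0.8, w_part_of=0.6) -> float:
    w = {"is_a": w_is_a, "part_of": w_part_of}
    children: dict[str, list[tuple[str, str]]] = {}
    for c, plist in parents.items():
        for p, rel in plist:
            children.setdefault(p, []).append((c, rel))
    s1 = wang_svalues(parents, children, t1, w)
    s2 = wang_svalues(parents, children, t2, w)
    common = set(s1) & set(s2)
    return sum(s1[a] + s2[a] for a in common) / (sum(s1.values()) + sum(s2.values()))


def aggregate_bruteforce(simfn, T1, T2, mode) -> float:
    vals = [[simfn(a, b) for b in T2] for a in T1]
    flat = [v for row in vals for v in row]
    if mode == "avg":
        return sum(flat) / len(flat)
    if mode == "max":
        return max(flat)
    if mode == "bma":
        row = sum(max(r) for r in vals) / len(T1)
        col = sum(max(vals[i][j] for i in range(len(T1))) for j in range(len(T2))) / len(T2)
        return 0.5 * (row + col)
    raise ValueError(mode)


def mann_whitney_auc(labels, scores) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie), counted exhaustively."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        if p > n:
            wins += 1
        elif p == n:
            ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
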