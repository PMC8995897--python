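"""GO-structure semantic-similarity baselines.

Term-level measures:

* Resnik — information content of the most informative common ancestor
  (MICA): ``max_{a in anc(t1) ∩ anc(t2)} IC(a)``.
* Lin — ``2·IC(MICA) / (IC(t1) + IC(t2))``, in [0, 1].
* Pekar–Staab — edge-based: ``δ(root, c) / (δ(root, c) + δ(c, t1) +
  δ(c, t2))`` maximised over common ancestors ``c``, where δ is the
  longest-path length, in [0, 1].
* Wang — semantic-contribution method: S-values decay along parent edges
  by a relation-specific factor (0.8 for is_a, 0.6 for part_of) and the
  similarity is the shared S-mass over the total S-mass of both terms.

Protein-level aggregation over the two annotation term sets T1, T2:
AVG (mean over all pairs), Max (maximum over all pairs) and BMA
(best-match average: each term matched to its best counterpart in the
other set, symmetrised). ``bma_literal`` additionally exposes the
non-best-match variant ``½(Σ/|T1| + Σ/|T2|)`` over all pairs, which
collapses to a reweighted AVG; the canonical best-match form is the
default meaning of "bma".
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from .annotation import WeightedAnnotationSet
from .corpus import PairExample
from .ontology import GoGraph, IcTable

WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def _check_namespace(g: GoGraph, t1: str, t2: str) -> None:
    if g.namespace_of(t1) != g.namespace_of(t2):
        raise ValueError(
            f"terms {t1} ({g.namespace_of(t1)}) and {t2} ({g.namespace_of(t2)}) "
            "are in different namespaces; similarity is undefined"
        )


def sim_resnik(g: GoGraph, ic: IcTable, t1: str, t2: str) -> float:
    """IC of the most informative common ancestor (0 when only the root is shared)."""
    _check_namespace(g, t1, t2)
    common = g.common_ancestors(t1, t2)
    return max(ic[a] for a in common)


def sim_lin(g: GoGraph, ic: IcTable, t1: str, t2: str) -> float:
    """Lin similarity 2·IC(MICA)/(IC(t1)+IC(t2)); undefined for two zero-IC terms."""
    _check_namespace(g, t1, t2)
    denom = ic[t1] + ic[t2]
    if denom == 0.0:
        raise ValueError(f"Lin similarity undefined: IC({t1}) + IC({t2}) = 0")
    return 2.0 * sim_resnik(g, ic, t1, t2) / denom


def sim_pekar(g: GoGraph, t1: str, t2: str) -> float:
    """Pekar–Staab edge-based similarity over longest paths."""
    _check_namespace(g, t1, t2)
    root = g.root_of(t1)
    best = 0.0
    for c in g.common_ancestors(t1, t2):
        d_root = g.longest_path_length(root, c)
        d1 = g.longest_path_length(c, t1)
        d2 = g.longest_path_length(c, t2)
        denom = d_root + d1 + d2
        if denom == 0:
            continue  # degenerate root-vs-root comparison contributes nothing
        best = max(best, d_root / denom)
    return best


def _wang_svalues(g: GoGraph, t: str, weights: dict[str, float]) -> dict[str, float]:
    """Semantic contributions S_t(a) for every ancestor a of t."""
    anc = g.ancestors(t)
    s = {t: 1.0}
    # walk roots-first order reversed => children before parents
    order = [x for x in reversed(g.topological_order()) if x in anc]
    for a in order:
        if a == t:
            continue
        best = 0.0
        for child, rel in g.children(a):
            if child in s:
                best = max(best, weights[rel] * s[child])
        s[a] = best
    return s


def sim_wang(
    g: GoGraph,
    t1: str,
    t2: str,
    w_is_a: float = 0.8,
    w_part_of: float = 0.6,
) -> float:
    """Wang's hybrid similarity from relation-weighted semantic contributions."""
    _check_namespace(g, t1, t2)
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    s1 = _wang_svalues(g, t1, weights)
    s2 = _wang_svalues(g, t2, weights)
    common = set(s1) & set(s2)
    num = sum(s1[a] + s2[a] for a in common)
    den = sum(s1.values()) + sum(s2.values())
    return num / den


SimFn = Callable[[str, str], float]


def aggregate(
    simfn: SimFn, T1: Iterable[str], T2: Iterable[str], mode: str = "bma"
) -> float:
    """Combine term-level similarities over two annotation sets.

    Modes: ``avg`` (mean over the |T1|·|T2| cross pairs), ``max``
    (maximum over pairs), ``bma`` (best-match average) and
    ``bma_literal`` (all-pairs sum normalised by each set size,
    symmetrised — the non-best-match variant).

    Term pairs for which ``simfn`` raises ValueError (e.g. cross-namespace
    pairs) are skipped, with the averages renormalised over the retained
    pairs; if no pair is comparable a ValueError propagates.
    """
    T1, T2 = sorted(set(T1)), sorted(set(T2))
    if not T1 or not T2:
        raise ValueError("both term sets must be non-empty")
    sim = np.full((len(T1), len(T2)), np.nan)
    for i, a in enumerate(T1):
        for j, b in enumerate(T2):
            try:
                sim[i, j] = simfn(a, b)
            except ValueError:
                pass
    if np.all(np.isnan(sim)):
        raise ValueError("no comparable term pair between the two sets")
    if mode == "avg":
        return float(np.nanmean(sim))
    if mode == "max":
        return float(np.nanmax(sim))
    if mode == "bma":
        row_best = np.nanmax(sim, axis=1)  # warns-free: full-nan rows excluded below
        col_best = np.nanmax(sim, axis=0)
        row_best = row_best[~np.isnan(row_best)]
        col_best = col_best[~np.isnan(col_best)]
        return float(0.5 * (row_best.mean() + col_best.mean()))
    if mode == "bma_literal":
        total = np.nansum(sim)
        n1 = np.sum(~np.all(np.isnan(sim), axis=1))
        n2 = np.sum(~np.all(np.isnan(sim), axis=0))
        return float(0.5 * (total / n1 + total / n2))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def make_term_simfn(
    measure: str, g: GoGraph, ic: IcTable | None = None
) -> SimFn:
    """Bind a named term-level measure to a graph (and IC table where needed)."""
    if measure == "resnik":
        if ic is None:
            raise ValueError("resnik requires an IC table")
        return lambda a, b: sim_resnik(g, ic, a, b)
    if measure == "lin":
        if ic is None:
            raise ValueError("lin requires an IC table")
        return lambda a, b: sim_lin(g, ic, a, b)
    if measure == "pekar":
        return lambda a, b: sim_pekar(g, a, b)
    if measure == "wang":
        return lambda a, b: sim_wang(g, a, b)
    raise ValueError(f"unknown measure {measure!r}")


def score_pairs(
    pairs: Sequence[PairExample],
    pgaa: WeightedAnnotationSet,
    g: GoGraph,
    ic: IcTable | None,
    measure: str = "lin",
    mode: str = "bma",
) -> list[float]:
    """Per-pair aggregate similarity scores (annotation weights ignored).

    The baselines consume the distinct term sets only; reliability weights
    play no role in the structural measures.
    """
    simfn = make_term_simfn(measure, g, ic)
    scores = []
    for p in pairs:
        for prot in (p.protein_i, p.protein_j):
            if prot not in pgaa:
                raise ValueError(f"protein {prot} has no annotations")
        scores.append(
            aggregate(simfn, pgaa.terms_of(p.protein_i), pgaa.terms_of(p.protein_j), mode)
        )
    return scores
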