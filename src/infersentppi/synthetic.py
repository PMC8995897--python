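"""Self-consistent synthetic fixtures: ontology, annotations, PPI pairs.

The generator emits a desk-scale stand-in for the GO/GOA/PPI-database
inputs: a random rooted DAG over one namespace with mixed is_a/part_of
edges, a GAF 2.2 annotation file with mixed evidence codes and duplicated
records, and a balanced, labeled protein-pair list with a planted
co-annotation signal.

The interaction signal is subtree co-annotation: every protein has a home
subtree (rooted at one of the root's children) from which its "signal"
terms are drawn; interacting pairs share a home subtree with probability
``signal_strength`` while negatives always span two subtrees. Every method
under study — embedding-based and structure-based alike — can in principle
detect shared-subtree annotation, so the fixture discriminates
implementations rather than biology.

Reliability structure: signal annotations receive ``Poisson(dup_rate)``
duplicate records under distinct references (so their post-filter weight
exceeds 1), while each protein additionally carries ``n_noise_terms``
uniform-random terms emitted once (weight 1). Duplication count therefore
correlates with annotation correctness, which is what the weighted
sentence mode is designed to exploit.

Every stage writes a generation ledger with the exact emitted counts
(per evidence code, NOT lines, expected post-filter weights, home
subtrees) so tests can use the generator's own bookkeeping as an oracle.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from .corpus import PairExample, write_pairs_tsv
from .ontology import GoGraph, GoTerm

NAMESPACE = "biological_process"
RELIABLE_CODES = ("EXP", "IDA")


@dataclass
class SynthConfig:
    """Generator settings; the defaults define the reference study conditions."""

    n_terms: int = 50
    max_depth: int = 6
    branching: float = 0.3  # probability of a second parent per term
    n_proteins: int = 120
    terms_per_protein: tuple[int, int] = (3, 8)
    n_noise_terms: int = 2
    n_pos_pairs: int = 100
    signal_strength: float = 1.0
    frac_iea: float = 0.3
    frac_nd: float = 0.1
    dup_rate: float = 1.0
    not_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 5:
            raise ValueError("need at least 5 terms")
        self.terms_per_protein = tuple(self.terms_per_protein)


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def _protein_id(i: int) -> str:
    return f"P{i:06d}"


def _rng(cfg: SynthConfig, stage: int) -> np.random.Generator:
    # independent stream per stage so stages are individually reproducible
    return np.random.default_rng([cfg.seed % (2**31), stage])


# -- ontology ----------------------------------------------------------


def generate_ontology(cfg: SynthConfig) -> tuple[str, GoGraph]:
    """Random rooted DAG emitted as OBO text plus the parsed-equivalent graph.

    Term 1 is the namespace root. The next ``A`` terms (A >= 2, roughly one
    per dozen terms) are its direct children and anchor disjoint top-level
    branches; every later term is assigned to one branch and attaches only
    to shallower terms of that branch, so the anchor subtrees never merge —
    the property the cross-subtree negative pairs rely on. Each term gets
    one uniform parent and, with probability ``branching``, a second one
    from the same branch; edges are is_a with probability 0.7, part_of
    otherwise.
    """
    rng = _rng(cfg, 1)
    n_anchors = max(2, cfg.n_terms // 12)
    depth = {1: 0}
    parents: dict[int, list[tuple[int, str]]] = {1: []}
    branch: dict[int, int] = {}
    members: dict[int, list[int]] = {}
    for i in range(2, cfg.n_terms + 1):
        if i <= 1 + n_anchors:
            chosen = [1]
            branch[i] = i
            members[i] = [i]
        else:
            b = 2 + int(rng.integers(n_anchors))
            branch[i] = b
            eligible = [j for j in members[b] if depth[j] < cfg.max_depth]
            if not eligible:
                eligible = [b]
            chosen = [int(rng.choice(eligible))]
            if rng.random() < cfg.branching:
                extra = [j for j in eligible if j != chosen[0]]
                if extra:
                    chosen.append(int(rng.choice(extra)))
            members[b].append(i)
        plist = []
        for p in sorted(set(chosen)):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            plist.append((p, rel))
        parents[i] = plist
        depth[i] = 1 + max(depth[p] for p, _ in plist)

    terms = {
        _term_id(i): GoTerm(
            term_id=_term_id(i),
            name=f"synthetic process {i}",
            namespace=NAMESPACE,
            parents=sorted((_term_id(p), rel) for p, rel in parents[i]),
        )
        for i in range(1, cfg.n_terms + 1)
    }
    g = GoGraph(terms)

    lines = ["format-version: 1.2", f"ontology: synthetic-go-seed{cfg.seed}", ""]
    for tid in sorted(terms):
        t = terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.term_id}")
        lines.append(f"name: {t.name}")
        lines.append(f"namespace: {t.namespace}")
        for pid, rel in t.parents:
            if rel == "is_a":
                lines.append(f"is_a: {pid} ! {terms[pid].name}")
            else:
                lines.append(f"relationship: part_of {pid} ! {terms[pid].name}")
        lines.append("")
    return "\n".join(lines), g


# -- annotations -------------------------------------------------------


def generate_annotations(cfg: SynthConfig, g: GoGraph) -> tuple[str, dict]:
    """Emit a GAF 2.2 file plus the generation ledger.

    Returns ``(gaf_text, ledger)``; the ledger records per-code emission
    counts, NOT-line count, the expected post-filter weight of every
    (protein, term) axiom, each protein's home subtree anchor, and which
    terms were noise.
    """
    rng = _rng(cfg, 2)
    root = g.roots[NAMESPACE]
    anchors = sorted(c for c, _ in g.children(root))
    subtrees = {a: sorted(g.descendants(a)) for a in anchors}

    per_code: dict[str, int] = {}
    expected_weights: dict[str, dict[str, int]] = {}
    protein_anchor: dict[str, str] = {}
    noise_terms: dict[str, list[str]] = {}
    rows: list[list[str]] = []
    n_not = 0
    ref_counter = 0

    def emit(protein: str, term: str, code: str, qualifier: str = "") -> None:
        nonlocal ref_counter
        ref_counter += 1
        rows.append(
            [
                "SYNT",
                protein,
                protein,
                qualifier,
                term,
                f"PMID:{ref_counter:07d}",
                code,
                "",
                "P",
                "",
                "",
                "protein",
                "taxon:0000",
                "20240101",
                "SYNT",
                "",
                "",
            ]
        )
        per_code[code] = per_code.get(code, 0) + 1

    lo, hi = cfg.terms_per_protein
    all_terms = sorted(g.terms)
    for pi in range(1, cfg.n_proteins + 1):
        protein = _protein_id(pi)
        anchor = anchors[int(rng.integers(len(anchors)))]
        protein_anchor[protein] = anchor
        pool = subtrees[anchor]
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(pool))
        signal = [pool[i] for i in sorted(rng.choice(len(pool), size=k, replace=False))]
        weights: dict[str, int] = {}
        for term in signal:
            u = rng.random()
            if u < cfg.frac_iea:
                emit(protein, term, "IEA")
            elif u < cfg.frac_iea + cfg.frac_nd:
                emit(protein, term, "ND")
            else:
                code = RELIABLE_CODES[int(rng.integers(2))]
                emit(protein, term, code)
                extra = int(rng.poisson(cfg.dup_rate))
                for _ in range(extra):
                    emit(protein, term, RELIABLE_CODES[int(rng.integers(2))])
                weights[term] = 1 + extra
        # uniform-random noise terms, reliable but never duplicated
        remaining = [t for t in all_terms if t not in set(signal)]
        n_noise = min(cfg.n_noise_terms, len(remaining))
        picked = [
            remaining[i]
            for i in sorted(rng.choice(len(remaining), size=n_noise, replace=False))
        ]
        noise_terms[protein] = picked
        for term in picked:
            emit(protein, term, RELIABLE_CODES[int(rng.integers(2))])
            weights[term] = 1
        if weights:
            expected_weights[protein] = weights
        if rng.random() < cfg.not_rate:
            term = all_terms[int(rng.integers(len(all_terms)))]
            emit(protein, term, "EXP", qualifier="NOT")
            n_not += 1

    header = ["!gaf-version: 2.2", "!generated-by: infersentppi.synthetic"]
    gaf_text = "\n".join(header + ["\t".join(r) for r in rows]) + "\n"
    ledger = {
        "per_code": per_code,
        "n_not": n_not,
        "n_records": len(rows),
        "expected_weights": expected_weights,
        "protein_anchor": protein_anchor,
        "noise_terms": noise_terms,
        "anchors": anchors,
    }
    return gaf_text, ledger


# -- pairs -------------------------------------------------------------


def generate_pairs(cfg: SynthConfig, g: GoGraph, ledger: dict) -> list[PairExample]:
    """Balanced labeled pairs with subtree co-annotation as the positive signal.

    Positives: with probability ``signal_strength`` both proteins come from
    the same home subtree, otherwise they are a uniform random pair.
    Negatives always span two different subtrees. Only proteins with at
    least one reliable annotation participate; no unordered pair appears
    twice.
    """
    rng = _rng(cfg, 3)
    anchor = ledger["protein_anchor"]
    usable = sorted(ledger["expected_weights"])
    groups: dict[str, list[str]] = {}
    for p in usable:
        groups.setdefault(anchor[p], []).append(p)
    multi = [a for a, ps in groups.items() if len(ps) >= 2]
    if not multi or len(usable) < 4:
        raise ValueError("not enough annotated proteins to plant pairs")

    seen: set[tuple[str, str]] = set()
    positives: list[PairExample] = []
    attempts = 0
    while len(positives) < cfg.n_pos_pairs and attempts < 100 * cfg.n_pos_pairs:
        attempts += 1
        if rng.random() < cfg.signal_strength:
            grp = groups[multi[int(rng.integers(len(multi)))]]
            i, j = rng.choice(len(grp), size=2, replace=False)
            a, b = grp[int(i)], grp[int(j)]
        else:
            i, j = rng.choice(len(usable), size=2, replace=False)
            a, b = usable[int(i)], usable[int(j)]
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        positives.append(PairExample(a, b, 1))

    negatives: list[PairExample] = []
    attempts = 0
    while len(negatives) < len(positives) and attempts < 1000 * cfg.n_pos_pairs:
        attempts += 1
        i, j = rng.choice(len(usable), size=2, replace=False)
        a, b = usable[int(i)], usable[int(j)]
        if anchor[a] == anchor[b]:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        negatives.append(PairExample(a, b, 0))
    if len(negatives) < len(positives):
        raise ValueError("could not sample enough cross-subtree negatives")
    return positives + negatives


# -- one-call fixture --------------------------------------------------


def generate_all(cfg: SynthConfig, outdir: str) -> dict:
    """Write obo/gaf/pairs/idmap/ledger under ``outdir``; return the paths.

    The pairs file uses external identifiers (``X######``) resolved to
    accessions (``P######``) by the emitted two-column id map, exercising
    the screening step's identifier mapping.
    """
    os.makedirs(outdir, exist_ok=True)
    obo_text, g = generate_ontology(cfg)
    gaf_text, ledger = generate_annotations(cfg, g)
    pairs = generate_pairs(cfg, g, ledger)

    paths = {
        "obo": os.path.join(outdir, "ontology.obo"),
        "gaf": os.path.join(outdir, "annotations.gaf"),
        "pairs": os.path.join(outdir, "pairs.tsv"),
        "id_map": os.path.join(outdir, "idmap.tsv"),
        "ledger": os.path.join(outdir, "ledger.json"),
    }
    with open(paths["obo"], "w") as fh:
        fh.write(obo_text)
    with open(paths["gaf"], "w") as fh:
        fh.write(gaf_text)
    external = [
        PairExample(p.protein_i.replace("P", "X", 1), p.protein_j.replace("P", "X", 1), p.label)
        for p in pairs
    ]
    write_pairs_tsv(external, paths["pairs"])
    with open(paths["id_map"], "w") as fh:
        for i in range(1, cfg.n_proteins + 1):
            fh.write(f"X{i:06d}\tP{i:06d}\n")
    with open(paths["ledger"], "w") as fh:
        cfg_d = asdict(cfg)
        cfg_d["terms_per_protein"] = list(cfg_d["terms_per_protein"])
        json.dump({"config": cfg_d, **ledger}, fh, indent=1, sort_keys=True)
    return paths
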