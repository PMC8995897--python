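"""Pair screening, protein sentences and the labeled pair corpus.

A protein is represented as a "sentence" whose words are its annotated GO
terms; in weighted mode each term token is repeated as many times as its
annotation reliability weight (capped), which is how the sentence encoder
sees the weight without any architectural change. The pair corpus (PC)
holds (protein_i, protein_j, label) examples, balanced and split 90/10 for
training and held-out evaluation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .annotation import WeightedAnnotationSet
from .term_embedding import TermVectorTable

POSITIVE = 1
NEGATIVE = 0


@dataclass(frozen=True)
class PairExample:
    """A labeled protein pair; label 1 = interacting, 0 = non-interacting."""

    protein_i: str
    protein_j: str
    label: int

    def __post_init__(self):
        if self.protein_i == self.protein_j:
            raise ValueError(f"self-pair {self.protein_i}")

    def key(self) -> tuple[str, str]:
        """Unordered pair identity."""
        return (min(self.protein_i, self.protein_j), max(self.protein_i, self.protein_j))


@dataclass
class ProteinSentence:
    """A protein as an ordered list of GO-term tokens plus their vectors."""

    protein_id: str
    term_ids: list[str]
    matrix: np.ndarray  # shape (len(term_ids), dim)


@dataclass
class SplitSpec:
    """Train/test split configuration: stratified, seeded shuffle."""

    train_fraction: float = 0.9
    seed: int = 0


def read_pairs_tsv(path: str) -> list[PairExample]:
    """Read a pair list TSV: protein_a, protein_b, optional 0/1 label.

    Pairs without a label column get label 1 (positive-only datasets)."""
    pairs: list[PairExample] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            label = int(row[2]) if len(row) > 2 and row[2] != "" else POSITIVE
            pairs.append(PairExample(row[0], row[1], label))
    return pairs


def write_pairs_tsv(pairs: Sequence[PairExample], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for p in pairs:
            w.writerow([p.protein_i, p.protein_j, p.label])


def read_id_map(path: str) -> dict[str, str]:
    """Two-column TSV: source_id -> accession."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if row and not row[0].startswith("#"):
                mapping[row[0]] = row[1]
    return mapping


def screen_pairs(
    pairs: Sequence[PairExample],
    pgaa: WeightedAnnotationSet,
    id_map: Mapping[str, str] | None = None,
) -> list[PairExample]:
    """Keep pairs whose endpoints both map to an annotated accession.

    ``id_map`` translates database-specific identifiers to the accessions
    used in the annotation set (identity when None). Surviving pairs carry
    the mapped accessions; input order is preserved.
    """
    out: list[PairExample] = []
    for p in pairs:
        if id_map is None:
            a, b = p.protein_i, p.protein_j
        else:
            a = id_map.get(p.protein_i)
            b = id_map.get(p.protein_j)
            if a is None or b is None:
                continue
        if a in pgaa and b in pgaa:
            out.append(PairExample(a, b, p.label))
    return out


def balance_sample(
    pairs: Sequence[PairExample],
    seed: int = 0,
    pgaa: WeightedAnnotationSet | None = None,
) -> list[PairExample]:
    """Equalize class counts by down-sampling, or generate negatives.

    With both classes present, the majority class is down-sampled without
    replacement to the minority count. With positives only, the same number
    of negatives is generated by seeded random pairing of annotated
    proteins (``pgaa`` required), avoiding every known positive pair;
    a degree-agnostic null.
    """
    rng = np.random.default_rng(seed)
    pos = [p for p in pairs if p.label == POSITIVE]
    neg = [p for p in pairs if p.label == NEGATIVE]
    if not pos:
        raise ValueError("no positive pairs to balance against")
    if not neg:
        if pgaa is None:
            raise ValueError(
                "no negatives present and no annotation set given to sample from"
            )
        proteins = sorted(pgaa.axioms)
        if len(proteins) < 2:
            raise ValueError("need at least two annotated proteins")
        forbidden = {p.key() for p in pos}
        seen: set[tuple[str, str]] = set()
        while len(neg) < len(pos):
            a, b = rng.choice(len(proteins), size=2, replace=False)
            pair = PairExample(proteins[a], proteins[b], NEGATIVE)
            if pair.key() in forbidden or pair.key() in seen:
                continue
            seen.add(pair.key())
            neg.append(pair)
        return pos + neg
    n = min(len(pos), len(neg))
    if len(pos) > n:
        pos = [pos[i] for i in sorted(rng.choice(len(pos), size=n, replace=False))]
    if len(neg) > n:
        neg = [neg[i] for i in sorted(rng.choice(len(neg), size=n, replace=False))]
    return pos + neg


def build_sentence(
    protein: str,
    pgaa: WeightedAnnotationSet,
    vectors: TermVectorTable,
    weighted: bool = True,
    weight_cap: int = 10,
) -> ProteinSentence:
    """Expand a protein's axioms into a term-token sentence with vectors.

    In weighted mode each term appears ``min(weight, weight_cap)`` times —
    the cap bounds encoder input length on heavily re-annotated proteins.
    Tokens are sorted by term id: GO-term "words" carry no meaningful
    order, and a canonical order makes runs reproducible.
    """
    if protein not in pgaa:
        raise ValueError(f"protein {protein} has no annotation axioms")
    term_ids: list[str] = []
    for term, weight in pgaa.axioms[protein]:  # already sorted by term
        reps = min(weight, weight_cap) if weighted else 1
        term_ids.extend([term] * reps)
    matrix = np.vstack([vectors.get(t) for t in term_ids])
    return ProteinSentence(protein_id=protein, term_ids=term_ids, matrix=matrix)


def split_corpus(
    pairs: Sequence[PairExample], spec: SplitSpec | None = None
) -> tuple[list[PairExample], list[PairExample]]:
    """Stratified, seeded train/test split (default 90/10)."""
    spec = spec or SplitSpec()
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to split")
    labels = [p.label for p in pairs]
    n_classes = len(set(labels))
    n_test = len(pairs) - int(round(spec.train_fraction * len(pairs)))
    # stratification needs room for every class in both splits
    feasible = n_classes > 1 and min(n_test, len(pairs) - n_test) >= n_classes
    stratify = labels if feasible else None
    train, test = train_test_split(
        list(pairs),
        train_size=spec.train_fraction,
        random_state=spec.seed,
        shuffle=True,
        stratify=stratify,
    )
    return train, test
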