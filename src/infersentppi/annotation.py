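"""GAF reading, evidence-code filtering and weighted annotation axioms.

Annotations whose evidence code is ``IEA`` (inferred from electronic
annotation, not manually reviewed) or ``ND`` (no biological data available)
are considered unreliable and removed. The remaining records are grouped
into protein-GO annotation axioms; the number of times an axiom recurs in
the GAF — typically distinct literature references asserting the same
association — is kept as an integer reliability weight (PGAA_Weight). The
unweighted variant (PGAA_noWeight) sets every weight to 1.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable

UNRELIABLE_CODES = frozenset({"IEA", "ND"})

GAF_N_COLUMNS = 17

_GO_RE = re.compile(r"GO:\d{7}$")


class GafParseError(ValueError):
    """Raised for structurally invalid GAF lines."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One GAF data line: a protein annotated to a GO term with evidence."""

    protein_id: str
    term_id: str
    evidence_code: str
    aspect: str
    reference: str


@dataclass
class WeightedAnnotationSet:
    """Protein-GO annotation axioms with reliability weights (the PGAA).

    ``axioms`` maps each protein to its list of ``(term_id, weight)`` pairs,
    sorted by term. ``weighted=False`` marks the PGAA_noWeight variant, in
    which every weight is 1.
    """

    axioms: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    weighted: bool = True

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.axioms

    def __len__(self) -> int:
        return len(self.axioms)

    def terms_of(self, protein_id: str) -> list[str]:
        """Distinct annotated terms of a protein (weights dropped)."""
        return [t for t, _ in self.axioms[protein_id]]

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for protein in sorted(self.axioms):
                for term, weight in self.axioms[protein]:
                    w.writerow([protein, term, weight])

    @classmethod
    def from_tsv(cls, path: str, weighted: bool = True) -> "WeightedAnnotationSet":
        axioms: dict[str, list[tuple[str, int]]] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row:
                    continue
                protein, term, weight = row[0], row[1], int(row[2])
                axioms.setdefault(protein, []).append((term, weight))
        for terms in axioms.values():
            terms.sort()
        return cls(axioms=axioms, weighted=weighted)


def parse_gaf(path: str) -> list[AnnotationRecord]:
    """Read a GAF 2.1/2.2 file into annotation records.

    Comment lines (``!``) are skipped; lines whose qualifier column contains
    ``NOT`` assert absence of association and are dropped. Raises
    :class:`GafParseError` naming the line on a wrong column count.
    """
    records: list[AnnotationRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("!"):
                continue
            if len(row) != GAF_N_COLUMNS:
                raise GafParseError(
                    f"{path}:{lineno}: expected {GAF_N_COLUMNS} tab-separated "
                    f"columns, found {len(row)}"
                )
            qualifier = row[3]
            if "NOT" in qualifier.split("|"):
                continue
            records.append(
                AnnotationRecord(
                    protein_id=row[1],
                    term_id=row[4],
                    reference=row[5],
                    evidence_code=row[6].upper(),
                    aspect=row[8],
                )
            )
    return records


def filter_by_evidence(
    records: Iterable[AnnotationRecord],
) -> list[AnnotationRecord]:
    """Drop records whose evidence code is IEA or ND; order preserved."""
    return [r for r in records if r.evidence_code not in UNRELIABLE_CODES]


def build_pgaa(
    records: Iterable[AnnotationRecord], weighted: bool = True
) -> WeightedAnnotationSet:
    """Group evidence-filtered records into a weighted annotation set.

    Two records are the same axiom iff their (protein, term) pair matches;
    aspect and reference do not participate, so the same association
    asserted by different papers accumulates weight. With ``weighted=False``
    every retained axiom gets weight 1.
    """
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        per = counts.setdefault(r.protein_id, {})
        per[r.term_id] = per.get(r.term_id, 0) + 1
    axioms = {
        protein: sorted(
            (term, n if weighted else 1) for term, n in per.items()
        )
        for protein, per in counts.items()
    }
    return WeightedAnnotationSet(axioms=axioms, weighted=weighted)
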