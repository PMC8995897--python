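"""One-call end-to-end workflow on synthetic (or on-disk) inputs.

Glues the stages together with the package defaults: generate (or load)
ontology/annotations/pairs, evidence-filter into a PGAA, train term
vectors on random-walk sentences, screen/balance/split the pair corpus,
fit InferSent_PN and score the held-out split. Mainly a convenience for
scripted experiments; the CLI exposes the same stages individually.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import numpy as np

from . import annotation as A
from . import corpus as C
from . import model as M
from . import ontology as O
from . import synthetic as S
from . import term_embedding as T
from .evaluation import MetricsReport


@dataclass
class PipelineRun:
    """Everything an end-to-end run produced."""

    graph: O.GoGraph
    pgaa: A.WeightedAnnotationSet
    vectors: T.TermVectorTable
    train_pairs: list[C.PairExample]
    test_pairs: list[C.PairExample]
    results: M.InferSentPNResults
    test_report: MetricsReport


def run_end_to_end(
    cfg: S.SynthConfig,
    mode: str = "weighted",
    model_config: M.ModelConfig | None = None,
    embed_dim: int = 64,
    embed_epochs: int = 20,
    weight_cap: int = 10,
    train_fraction: float = 0.9,
    shuffle_labels: bool = False,
    augment_symmetric: bool = True,
) -> PipelineRun:
    """Run the full InferSentPPI pipeline on a fresh synthetic fixture.

    ``mode`` selects PGAA_Weight ("weighted") vs PGAA_noWeight
    ("noweight") end to end. ``shuffle_labels`` permutes the pair labels
    before splitting (a negative control: the planted signal is destroyed
    while marginals are kept). ``augment_symmetric`` additionally presents
    every training pair in swapped order, encoding that interaction is a
    symmetric relation. All randomness derives from ``cfg.seed``.
    """
    weighted = mode == "weighted"
    outdir = tempfile.mkdtemp(prefix="infersentppi-")
    paths = S.generate_all(cfg, outdir)

    graph = O.parse_obo(paths["obo"])
    records = A.filter_by_evidence(A.parse_gaf(paths["gaf"]))
    pgaa = A.build_pgaa(records, weighted=weighted)

    raw = C.read_pairs_tsv(paths["pairs"])
    id_map = C.read_id_map(paths["id_map"])
    screened = C.screen_pairs(raw, pgaa, id_map)
    balanced = C.balance_sample(screened, seed=cfg.seed, pgaa=pgaa)
    if shuffle_labels:
        rng = np.random.default_rng([cfg.seed % (2**31), 9])
        labels = [p.label for p in balanced]
        rng.shuffle(labels)
        balanced = [
            C.PairExample(p.protein_i, p.protein_j, lab)
            for p, lab in zip(balanced, labels)
        ]
    train_pairs, test_pairs = C.split_corpus(
        balanced, C.SplitSpec(train_fraction, cfg.seed)
    )

    walks = T.graph_to_walk_corpus(graph, seed=cfg.seed)
    vectors = T.train_term_vectors(
        walks, dim=embed_dim, epochs=embed_epochs, seed=cfg.seed
    )

    if model_config is None:
        model_config = M.ModelConfig(embed_dim=embed_dim, seed=cfg.seed)
    spec = M.InferSentPN.from_corpus(
        train_pairs, pgaa, vectors, weighted=weighted,
        weight_cap=weight_cap, config=model_config,
    )
    if augment_symmetric:
        spec = M.InferSentPN(
            spec.examples + [(sj, si, lab) for si, sj, lab in spec.examples],
            model_config,
        )
    results = spec.fit()

    test_examples = M.InferSentPN.from_corpus(
        test_pairs, pgaa, vectors, weighted=weighted,
        weight_cap=weight_cap, config=model_config,
    ).examples
    report = results.evaluate(test_examples)
    return PipelineRun(
        graph=graph,
        pgaa=pgaa,
        vectors=vectors,
        train_pairs=train_pairs,
        test_pairs=test_pairs,
        results=results,
        test_report=report,
    )
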