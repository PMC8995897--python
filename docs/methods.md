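# Methods

## Problem setting and model

The package predicts protein–protein interaction from GO annotation
alone. Its working hypothesis is the standard one behind GO-based
interaction prediction: interacting proteins tend to participate in the
same processes and locations, so their annotation term sets are close in
the ontology. Two families of methods operationalise this closeness:

1. **Structural semantic similarity** (the baselines): a term-pair
   similarity derived from the GO DAG — Resnik, Lin, Pekar–Staab, Wang —
   aggregated over the two proteins' term sets (AVG, Max, BMA) and
   thresholded.
2. **Learned sentence-pair classification** (the main model): each
   protein is a sentence of GO-term embedding tokens; a CNN encoder maps
   it to a fixed-length vector; a classifier on the InferSent composition
   [u; v; |u−v|; u⊙v] is trained on labeled pairs.

The learned route can exploit information the fixed formulas cannot —
in particular the per-annotation reliability weights described next.

## Annotation processing

GAF records with evidence codes `IEA` or `ND` are removed; these are,
respectively, unreviewed electronic inferences and explicit "no data"
placeholders, and both carry no experimental support. Records asserting
the same (protein, term) association are then collapsed; the multiplicity
of the group is the axiom's **weight**. Two records count as the same
axiom iff protein and term match — aspect and reference deliberately do
not participate, so independent publications accumulate weight, which is
the intended meaning of the weight as a reliability index. NOT-qualified
records are dropped (they assert absence of association).

In weighted mode a term with weight w contributes min(w, cap) identical
tokens to the protein sentence (cap defaults to 10 to bound sentence
length); in unweighted mode each term contributes one token.

## Term embeddings

Skip-gram with negative sampling (5 negatives, unigram^0.75 noise,
linearly decaying learning rate 0.025 → 1e-4, min count 1) is trained on
sentences generated from the ontology graph. Two corpus constructions are
provided:

* **Per-edge axioms** — one three-token sentence `child relation parent`
  per edge. This is the minimal construction, but on desk-scale
  ontologies it leaves sibling terms without shared contexts and the
  resulting vectors separate ontology branches poorly.
* **Random walks** (default for the pipeline) — from every term, 10
  walks of 8 tokens over the undirected is_a/part_of graph. Walks place
  whole neighbourhoods in shared windows and produce clearly
  branch-clustered vectors, which is the property the pair model needs.

Defaults: dimension 64, window 5, 20 epochs, seeded; the trainer is
single-threaded numpy, so vectors are bitwise reproducible. Vectors are
exported unnormalised: norms grow with token frequency and carry
centrality information that the encoder can use (normalising them was
observed to cost held-out accuracy on synthetic data). Terms that are
annotated but absent from the ontology's edge set get a zero vector and
a warning, keeping prediction total.

## The pair model

Encoder: stacked 1-D convolutions over the token axis (default two
layers of 32 channels), ReLU, max-over-time pooling after every layer,
pooled features concatenated — a hierarchical-ConvNet pooling scheme
giving a 64-dimensional sentence embedding independent of sentence
length.

**Kernel size 2 and the weighting mechanism.** GO-term "words" have no
meaningful order, so sentences are built in canonical sorted order. A
kernel of 1 would make the encoder exactly permutation-invariant, but it
would also make it blind to token repetition: a max-pool over per-token
features is unchanged when a token is duplicated, so annotation weights
could never influence the encoding. With kernel 2 a term repeated by its
weight produces a distinctive repeated-token window (x, x) that singleton
terms cannot produce; channels can learn to respond to such windows,
which makes multiply-evidenced terms selectively visible. This is the
mechanism by which weighted mode outperforms unweighted mode when
duplication correlates with annotation correctness. Kernel 1 remains
available in the configuration.

Classifier: [u; v; |u−v|; u⊙v] → hidden layer (64, ReLU, dropout 0.1) →
2-way softmax; cross-entropy loss, Adam (lr 1e-3), batch size 2, 30
epochs, seeded init and shuffling. A pair is labeled positive iff
P(positive) strictly exceeds P(negative); an exact tie is negative.
Training examples are augmented with the swapped order of every pair,
encoding the symmetry of the interaction relation; prediction-time
symmetrisation (averaging both orders) exists but is off by default.
Examples are processed one at a time with gradients averaged over the
mini-batch, which is numerically equivalent to zero-padding a batch and
masking the pooling. Optional word dropout (`token_dropout`) is available
as additional regularisation but off by default.

All training is plain numpy with hand-written backpropagation: fixed
seed + fixed corpus ⇒ identical parameters and predictions.

## Baselines

* Resnik: IC of the most informative common ancestor, with
  annotation-frequency IC `-ln(freq(t)/freq(root))` in natural log;
  freq counts distinct (protein, term) pairs propagated to ancestors.
  The original comparison's exact IC formula was published only in
  unavailable supplementary material; the standard Resnik IC is used
  instead. Terms never annotated have undefined IC and similarity calls
  touching them raise — silent zeros would mask corpus/ontology
  mismatches.
* Lin: 2·IC(MICA)/(IC(t1)+IC(t2)); undefined when both ICs are zero.
* Pekar–Staab: δ(root,c)/(δ(root,c)+δ(c,t1)+δ(c,t2)) maximised over
  common ancestors c, δ the longest-path length (depth is longest-path
  throughout); the degenerate root-with-itself comparison scores 0.
* Wang: semantic contributions decaying by 0.8 (is_a) / 0.6 (part_of)
  along parent edges; similarity is shared S-mass over total S-mass.

Aggregation: AVG (mean over the cross product), Max, and BMA in its
canonical best-match form — each term matched with its best counterpart,
symmetrised. The literal printed variant of the formula, which omits the
inner best-match and collapses to a reweighted AVG, is kept behind the
`bma_literal` mode for comparability. Cross-namespace term pairs are
skipped with renormalisation over the retained pairs. Baselines consume
distinct term sets only; weights play no role in them. For threshold
metrics, baseline scores are cut at the training-set-optimal accuracy
threshold; the learned model uses 0.5.

## Evaluation

Accuracy, precision, recall and F1 from the confusion table with guarded
zero denominators (0 with a warning); ROC with tied scores grouped and
trapezoidal area; PR area as average precision (step-wise achievable
precision, not trapezoids — the two differ and the step-wise form is
reported). Splits are stratified 90/10, seeded, falling back to an
unstratified split only when a class cannot be represented in both parts
(e.g. two examples).

## Synthetic fixtures

The generator emulates the shape of the real inputs, not their biology:

* **Ontology**: a rooted single-namespace DAG (default 50 terms, max
  depth 6). The root's children anchor disjoint branches; every other
  term attaches uniformly within one branch, with a 0.3 chance of a
  second parent, edges is_a/part_of at 7:3. Keeping branches disjoint is
  what makes "same subtree" a well-defined planted signal.
* **Annotations**: each of 120 proteins draws 3–8 "signal" terms from
  its home branch and 2 uniform-random "noise" terms. Signal annotations
  get an evidence code that is reliable (EXP/IDA) with probability 0.6,
  IEA with 0.3, ND with 0.1; reliable signal records receive
  Poisson(1.0) duplicate records under distinct references, while noise
  records are always reliable singletons. Duplication therefore
  correlates with annotation correctness — the regime in which
  reliability weighting should help.
* **Pairs**: 100 positives drawn within a home branch (with probability
  `signal_strength`, default 1.0), 100 negatives always across branches,
  no duplicates, balanced. Pair files use external identifiers resolved
  through an emitted id-map, exercising the screening stage.
* A generation ledger (JSON) records exact per-code counts and expected
  post-filter weights, so tests can use the generator's own bookkeeping
  as an oracle.

What passing on these fixtures shows: the pipeline recovers a planted
co-annotation signal, ranks it above chance-level controls, and benefits
from reliability weights when duplication is informative. What it does
not show: performance on real interactomes — real GO has three
namespaces, heavy-tailed annotation depth, literature bias correlated
between interacting proteins, and negatives that are not random
cross-process pairs.

## Problem sizes and numerical choices

Replicated experiments use the 50-term/120-protein/200-pair fixture with
5 seeds (signal recovery and shuffled control), 7 seeds (weighted vs
unweighted trend) and 3 seeds (baseline comparison); oracle equivalence
sweeps use DAGs of at most 12 terms where exhaustive enumeration is
exact. These sizes were chosen so a full replication completes in
minutes on one CPU while keeping median statistics stable.

Ties in the strict decision rule go to negative. The evidence filter and
axiom grouping are order-preserving and idempotent. IC uses natural log
(base only rescales Resnik; Lin and the aggregators are ratio-based).
Degenerate inputs raise rather than default: empty annotation sets, empty
term sets, single-class training corpora and unannotated proteins are all
errors.

## Known limitations

* The skip-gram and CNN implementations are deliberately minimal
  (single-threaded, no sub-sampling, no GPU); they target desk-scale
  corpora, not the multi-million-pair datasets of full interactomes.
* Negative pairs, when generated, are degree-agnostic random non-edges;
  no homology-aware or degree-matched sampling.
* The weighting mechanism requires kernel ≥ 2; with kernel 1 weighted
  and unweighted modes coincide by construction.
* Cross-namespace similarity is undefined by design; protein pairs whose
  term sets share no namespace raise.
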