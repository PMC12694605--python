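# Methods

`adjurank` ranks candidate vaccine adjuvants for a query disease over a
heterogeneous knowledge graph.  This note records the model, its training
procedure, the synthetic benchmark, and the numerical and design choices a
maintainer would want spelled out.

## Model

**Graph.** Four node types — Disease, Vaccine, Adjuvant, Platform — connected
by typed edges (`vaccine-targets-disease`, `vaccine-uses-adjuvant`,
`vaccine-on-platform`).  Propagation treats the graph as a single undirected
graph with one shared row-stochastic, self-looped adjacency
Â = D⁻¹(A + I); edge types are retained as metadata only.  Relational
(typed) message passing is deliberately out of scope.  Node order is
lexicographic by (node_type, node_id) so every matrix is bit-reproducible
from the input files.

**Features.** Each node's name + free-text metadata is encoded to an initial
vector x_v.  The default encoder is signed feature hashing of lowercase word
unigrams into D_in = 256 dimensions, L2-normalized per row, keyed with
BLAKE2b so it is deterministic across processes.  Unigrams (not higher
n-grams) are used on purpose: biomedical entity texts share vocabulary
heavily, and unigram bags keep that shared signal dominant over per-entity
n-gram signatures, which materially improves zero-shot generalization (an
entity-unique signature is an open invitation to memorize).  A pretrained
biomedical sentence encoder can be plugged in behind the same interface; it
requires an external model download and fails loudly when unavailable.

**Propagation.** Embeddings z_v = f_θ(x_v) from an affine encoder
(W_f ∈ R^{D_in×D}, b_f, D = 64 by default) are smoothed with approximate
personalized PageRank:

    H⁽⁰⁾ = Z,   H⁽ᵏ⁾ = (1 − α) Â H⁽ᵏ⁻¹⁾ + α Z,   k = 1…K

with teleport α = 0.1 and K = 10 (the conventional APPNP settings; the
fixed point is α(I − (1−α)Â)⁻¹Z and K = 10 is close to converged at
α = 0.1).  Because encoder and propagation are both linear, the
implementation propagates the *raw* features once (X̃ = M X, where M is the
K-step APPNP operator; Â is row-stochastic so the bias passes through) and
applies the encoder afterwards — identical output, closed-form gradients.
A node with no edges keeps its own feature row through propagation, which
is exactly how unseen diseases are represented (below).

**Scoring.** For disease d and adjuvant a with propagated embeddings
h_d, h_a and multi-hot mechanism-cue vector φ(a) ∈ {0,1}^P over a pathway
vocabulary (TLR9, TLR4, TLR7, TLR3, STING, NLRP3, MINCLE, ALUM by default):

    s(d, a) = h_dᵀ W h_a + γ · σ((W_m h_d)ᵀ φ(a))

W is a full unconstrained D×D interaction; W_m projects the disease into a
mechanism-demand space; the sigmoid is applied to the *scalar* alignment so
the prior is always in (0, 1) — an adjuvant with no known cues contributes
the neutral 0.5.  γ ≥ 0 weights the prior and is a tuned hyperparameter
(grid {0, 0.5, 1, 2} on validation NDCG@10), not a trained weight.
Rankings sort by score descending with deterministic id-ascending
tie-breaks.

**Unseen (inductive) diseases.** An unseen disease contributes no edges, so
its propagated row equals its encoded text row; scoring it inside the full
graph is mathematically identical to appending it in isolation.  The
synthetic generator therefore keeps inductive disease nodes in the graph
but never emits their label edges.

## Training

The listwise objective per disease mixes two surrogates over the candidate
list (exact positives ∪ sampled negatives):

* **ApproxNDCG**: smooth ranks r_i = 1 + Σ_{j≠i} σ((s_j − s_i)/τ), discount
  1/log₂(r_i + 1), a smooth top-k gate σ((k + ½ − r_i)/τ), normalized by
  the exact IDCG@k; loss = 1 − smooth-NDCG@k.  As τ → 0 this is exactly
  1 − NDCG@k, which the tests verify.
* **ListNet** (top-1): cross-entropy between softmax(gains) and
  softmax(scores).

Batch loss = Σ_d [w·ApproxNDCG + (1−w)·ListNet] + λ‖θ‖², with w = 0.5,
λ = 1e−4 over (W_f, W, W_m) (bias excluded, standard weight-decay
convention; γ is not trained).  The surrogate temperature defaults to
τ = 0.1: bilinear scores live on a cosine-like scale where neighboring
candidates differ by ~0.1, and a temperature at that scale is what makes
the smooth ranks actually resolve them — at τ = 1 the surrogate is nearly
inert and the hybrid degenerates to ListNet in practice.  One caveat worth
recording: with an adaptive optimizer the λ-gradient is rescaled per
coordinate and has little practical shrinkage effect; λ is kept for the
objective's definition, and capacity control comes mainly from the
augmentation below.

All gradients are closed-form (the scorer is bilinear in its parameters)
and optimization is mini-batch Adam (lr 1e−2, batches of 8 queries,
200 epochs); negatives are resampled every epoch (20 per query, uniform
without replacement from the non-positives).  Randomness flows from one
root seed split into named substreams (validation split, per-γ init,
negative sampling, cold-start coin), so identical config + seed reproduces
checkpoints bitwise.

**Cold-start augmentation.** With probability 0.5 a training query is
scored from the disease's *raw* feature row instead of the propagated one —
i.e. as if that disease were unseen, the exact representation used at
inductive inference.  Without this, the bilinear term memorizes through the
graph (a transductive disease's propagated row literally contains its
positive adjuvants' features two hops away) and the text→mechanism pathway
stays untrained; with it, one model serves both splits.

**Model selection.** A deterministic 25% of the training diseases is held
out of the training queries and scored cold; the γ grid is selected on
their NDCG@10.  This targets zero-shot generalization, which is the
headline use case; transductive performance is insensitive to γ here.

**Ablations.** `--ablate no-ndcg-surrogate` trains with w = 0 (ListNet-only
"base loss"); `--ablate binary-gains` collapses training gains 2→1, 1→0
(evaluation stays graded).  Ablations reuse the full model's selected γ so
the contrast isolates the loss/gain structure.

## Evaluation

Graded gains per disease: 2 for an exact known disease-adjuvant pair, 1 for
an adjuvant sharing a functional class with any positive of that disease,
0 otherwise; diseases with no positives are excluded (IDCG would be 0).
Metrics: DCG@k = Σ g_i/log₂(i+1), NDCG@k (IDCG over the full candidate
list truncated at k), Recall@k (gain > 0 retrieved / gain > 0 total), and
Precision@k (gain > 0 in the top k by default; an exact-only switch counts
gain 2 alone).  Everything is macro-averaged over diseases with 95%
disease-level percentile-bootstrap CIs (B = 1000).  Ranker comparisons use
a two-sided paired sign-flip randomization test — exhaustive over 2ⁿ
patterns for n ≤ 12 (exact, unsmoothed), Monte Carlo with 10 000 draws and
add-one smoothing otherwise.  Case-study output includes cumulative
DCG/IDCG curves, a 10-bin reliability diagram over sigmoid-mapped scores
with ECE (empty bins skipped), and rank-swap tables
(Δ = rank_ablated − rank_full) against a second checkpoint.

## Synthetic benchmark

The generator emulates a curated vaccine-adjuvant knowledge base at desk
scale; its defaults are the study conditions used by the tests and the
acceptance script.

* 89 diseases (48 transductive / 41 inductive), 120 adjuvants, 6 platforms,
  8 pathways, 8 functional classes, ~3 positives per disease.
* Adjuvants: a latent primary pathway (30% gain a secondary), observed cue
  rows hidden for 10% ("unknown mechanism"), class = primary pathway's
  class with 10% label noise.
* Diseases belong to one of six pathogen families (intracellular/
  extracellular bacterium, RNA/DNA virus, helminth, fungus).  Each family
  has a demand profile concentrated on two pathways; a disease's demand is
  0.8·family + 0.2·individual variation.  This mirrors the immunological
  regularity that, e.g., intracellular pathogens demand Th1-driving TLR
  agonists.
* Positives: P(d, a positive) = σ(β·z + b) with z the standardized
  demand·cue alignment, β = 4 by default (β = 0 is the null benchmark) and
  b bisected so the expected positives per disease hit the target; every
  disease is guaranteed ≥ 1 positive (drawn proportionally to its pair
  probabilities, so the null stays null).
* Graph: every positive pair of a *transductive* disease is connected
  through a dedicated vaccine node (plus a random platform edge) and ten
  extra vaccines carry disease/platform edges only; inductive diseases get
  no edges at all — their positives exist only as held-out labels.
* Text: disease text names its family; adjuvant text carries its observed
  cue tokens, class token and — with probability 0.7 — the family it best
  aligns with; all texts get 4 random filler tokens.  The family mention is
  the partial lexical bridge that keeps the text-similarity baseline
  clearly above random yet clearly below a model that learns the full
  family→pathway map.  (The alternative of writing a disease's demand
  pathways directly into its text makes the text baseline
  information-complete and unbeatable by construction, which matches no
  real corpus.)

What the generator does **not** emulate: realistic literature text,
adjuvant dose/route/safety structure, non-uniform candidate availability
per disease, ontology hierarchy among adjuvants, or cross-source identifier
drift.  Passing tests on this benchmark show the pipeline recovers planted
mechanism-aligned structure under sparse supervision — not that it attains
any particular performance on curated real-world data.

## Degenerate inputs and numerical notes

* Empty text encodes to the zero vector (norm left at 0); the
  text-similarity baseline ranks zero-norm candidates last,
  deterministically.
* An all-zero cue row contributes the neutral prior 0.5 everywhere.
* ApproxNDCG rejects queries whose gains are all zero (filtered upstream);
  ListNet accepts them (uniform target).
* The isolated-node pass-through of APPNP is exact in floating point when
  α is a power of two and holds to ~1e−15 otherwise.
* Bootstrap CIs on a single disease collapse to the point estimate rather
  than erroring (reports stay well-defined on tiny fixtures).
* Checkpoints are JSON with full-precision floats (`repr` round-trip), so
  byte-identical reruns are a testable contract.

## Problem sizes used by the test suite and acceptance script

Training runs in the tests and acceptance script use the default fixture
(89 diseases, 120 adjuvants, ≈340 nodes): a full γ-grid fit is ~15 s on one
CPU and each ablation fit ~4 s, which keeps the complete suite and the
acceptance script each well under a few minutes.  These sizes were chosen
to match the evaluated query counts of the emulated study design (48/41)
while staying desk-scale.
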