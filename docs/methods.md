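# Methods

## Model and topology

The core model is a profile HMM over the standard topology: silent
begin/end states, match states `M_1..M_L` with position-specific
emission distributions over the 20 amino acids, insert states
`I_1..I_{L-1}` and left/right flanking inserts sharing one emission
distribution, and a silent delete chain `D_1..D_L`. Flank states emit on
their self-loops (k flank residues cost `loop^k · exit`), `M_L` and
`D_L` enter the end state with probability 1, and there are no
insert→delete or early-exit transitions. The model is *proper*: every
state's outgoing probabilities sum to one, so the likelihood sums to one
over all finite sequences (verified numerically on a two-letter toy).
Domain repeats and fragment-specific topology extensions are out of
scope; the model length is fixed per run (default: the median input
length).

Non-standard residues (B, Z, J, U, O, `*`, `.`) are normalized to `X`,
which emits with the state-independent constant probability 1/20 in
every emitting state: unknown residues therefore influence neither the
alignment nor any gradient.

All parameters are stored unconstrained (logits; one softmax per state
at use time, with a probability floor of 1e-16 before logs). This makes
plain first-order ascent well-posed without projections.

## Embedding emissions

Match state `M_i` additionally emits the compressed embedding
`x_j ∈ R^r` of the residue it aligns, under a diagonal Gaussian
`N(μ_i, σ_i)` tempered by τ: the joint emission log-probability is
`log P(S_j|q) + τ·log N(x_j; μ_i, σ_i)`. τ defaults to 1.0 and is held
fixed (a learned τ would make runs harder to compare and reproduce;
τ = 0 recovers the amino-acid-only model bit for bit). Variances are
`softplus(raw) + 1e-6`, keeping them positive under gradient updates.
Full covariances and per-state Gaussian mixtures are deliberately not
supported (cost grows quadratically/linearly in r per state for little
benefit at r = 16).

Insert and flank states use a single *frozen* background Gaussian
obtained by moment-matching the prior mixture (mixture mean, total
variance). With `frozen_insertions` (default on), the shared insert
amino-acid distribution also stays at its uniform background; only
match states learn emission models.

A C-component diagonal Gaussian mixture (default C = 32) serves as the
prior over the match means μ_i and as their initialization (each μ_i is
drawn from the mixture; σ_i starts at the sampled component's variance).
When reference alignments are available the prior is fitted by EM
(diagonal Gaussian mixture, k-means++ initialization, ≤200 iterations,
1e-6 relative tolerance, variance floor 1e-6) to embeddings of residues
in densely populated columns — columns with at most 50% gaps. In the
plain `align` pipeline, which sees only unaligned sequences, it is
fitted to the compressed embeddings of all input residues instead; this
keeps the initialization in the region embeddings actually occupy,
which is the prior's purpose. At C = 32, r = 16 the prior has
32·16 + 32·16 + 32 = 1056 parameters under this parameterization
(means + variances + weights).

## Scoring model

Residue pairs are scored by a symmetric bilinear form through a
logistic sigmoid, `A = sigmoid(φ(S) R (φ(T) R)ᵀ)`, i.e. `W = R Rᵀ` with
`R ∈ R^{d×r}` and r ≪ d (default r = 16; at d = 1024 that is 16 384
trainable parameters). The same `R` is the compression used at
alignment time, `ζ(φ(S)) = φ(S) R`, so scoring compressed embeddings is
*identical* to scoring raw ones — an algebraic identity asserted
exactly in the tests. Pretraining treats every entry of `A` as an
independent binary classification of "do residues i and j align",
supervised by pairwise alignments induced from reference MSAs (two
residues are aligned iff they share a gap-free column). Because
positives are O(L) of O(L²) entries, positives are reweighted by the
per-pair negative/positive ratio; the optimizer is Adam (lr 1e-3, one
sequence-pair matrix per step), only `R` trains, and the random
initialization is Gaussian with scale 1/√d.

## Training

The objective is the mean per-sequence forward log-likelihood plus the
amino-acid prior and the embedding prior, each scaled by 1/n. The
default amino-acid prior is a single symmetric Dirichlet with α = 1.1 —
a mild pull toward the simplex interior that keeps prior gradients
finite; at weight 1/n it is practically negligible, and any Dirichlet
mixture can be supplied instead.

Gradients are exact: the forward recursion is a composition of
log-sum-exp and addition, and a reverse sweep of the same recursion
yields the adjoint of every emission cell (the posterior state
occupancies) and the expected usage count of every transition — the
classical forward–backward identities — from which the chain rule
through the softmax/softplus parameterizations is closed-form. The
analytic gradient is verified against central finite differences to
1e-4 relative in the test suite. The same adjoints double as the
posterior match-probability table exposed as the probabilistic MSA
output.

Optimization is Adam over shuffled mini-batches (default batch 256),
lr 0.05 for HMM parameters and 0.005 for Gaussian means/scales, at most
200 epochs with early stopping after 10 epochs without objective
improvement. Four replicas with different seeds are trained by default
and the highest-objective replica is selected (ties go to the smallest
seed). Everything is deterministic given the seed — two runs produce
byte-identical model files. Sequences longer than 10× the median are
rejected with an explicit error rather than truncated.

One forward/backward pass costs O(n·T·L) per batch — linear in the
number of sequences, as the timing test confirms (doubling n at fixed
length stays under ~2.5× wall time).

## Decoding and evaluation

Each sequence is aligned to the trained profile by Viterbi (with the
embedding term when enabled). Ties prefer Match over Delete over
Insert, for determinism. Residues from `M_i` form match column i;
insertions are placed lowercase, left-justified in blocks between match
columns and are not aligned to each other (the standard profile
convention). De-gapping any output row reproduces its input sequence —
asserted on every decode.

SP, TC and column scores compare alignments by residue *coordinates*
(row identifier, ungapped index), never characters. Conventions pinned
here, since reference implementations differ at the margins: two
residues are aligned iff they share a non-gap column; columns with
fewer than two residues contribute no pairs to SP or to the
column-score weights but still count as columns for TC; all-gap columns
are ignored. Each score is validated against an independent brute-force
enumeration on random small alignments.

## Synthetic data

The generators supply every fixture without network access, emulating a
reference-set benchmark family:

* `make_family` draws match emissions from a symmetric Dirichlet with
  concentration 1/conservation (one-hot as conservation → ∞) and uses a
  single indel-rate knob for insert/delete open and extend
  probabilities; sequences are sampled from the generative process with
  their true paths, so the true MSA is known. The first 10 sequences
  form the reference subset. Defaults (8 match states, 300 sequences,
  conservation 10, indel rate 0.03) give mid-range conservation
  families whose emissions are recoverable but not trivially so.
* `make_ambiguous_family_with_embedding_signal` builds a tandem-repeat
  profile: two halves with *identical* per-column amino-acid
  distributions, and sequences that carry both motif copies (40%) or a
  single copy. On residues alone a single-copy sequence fits either
  half equally well; each true column carries a distinct orthonormal
  planted embedding direction (norm 4 against unit noise — separable by
  a linear probe at ≥95% but not noise-free), so only the embedding
  channel can resolve the half. This isolates exactly the situation
  where contextual embeddings should help alignment.
* `make_planted_scoring_pairs` plants a pool of 16 orthonormal latent
  directions (signal 3, noise 0.5) shared by aligned residues of a
  pair. The signal-to-noise here is set so that the *optimal* bilinear
  scorer is clearly separated from chance — the quadratic-form noise of
  a rank-r scorer grows like √r, which bounds achievable AUROC for any
  choice of W.

What these generators do **not** emulate: real embedding geometry
(anisotropy, shared directions between columns, length effects),
realistic indel length distributions, fragmentary sequences, and
alignment ambiguity that is *not* resolvable from embeddings. Passing
tests therefore demonstrate correctness of the machinery and the
qualitative value of an informative embedding channel, not benchmark
accuracy on real protein families — that requires a real protein
language model plugged into the embedder registry.

## Problem sizes used in the checks

The bundled end-to-end checks run at desk scale by design: oracle
comparisons use models with ≤3 match states and sequences of length ≤4
(where full path enumeration is exact), parameter recovery uses 300
sequences from an 8-state profile, the embeddings-help comparison uses
5 family seeds × 200 sequences with 3 replicas each, and the timing
ratio compares 1000 vs 2000 sequences. These sizes make the whole suite
reproducible in minutes on one CPU while exercising every code path at
the same operating points the defaults target.

## Known limitations

* Unsupervised gradient ascent on an HMM likelihood has local optima;
  replicas mitigate but do not eliminate them (column-shifted solutions
  are the typical failure, visible as good SP but reduced TC).
* Accurate profiles need depth — below a few hundred sequences the
  method is not competitive, and the CLI warns accordingly.
* Insertions are unaligned within their blocks by construction.
* No model surgery: the number of match states is fixed per run.
* The shipped embedder is synthetic; conclusions about real-family
  accuracy require a real pLM adapter.
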