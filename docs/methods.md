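# Methods

## Problem setting

`augmem` fine-tunes a SMILES language model ("Agent") against a frozen copy
of itself ("Prior") so that sampled molecules maximize a black-box scoring
function ("oracle") under a budget on oracle calls. The package implements
the Augmented Memory update — which reuses every oracle score for several
gradient steps by re-writing molecules as alternative SMILES — alongside the
classic REINVENT-style baseline, Augmented Hill Climbing (AHC), and Best
Agent Reminder (BAR), plus the scaffold diversity filter and Selective
Memory Purge.

## Model

The policy is an autoregressive LSTM over a SMILES token vocabulary:
embedding → LSTM stack → linear projection to next-token logits. Sequence
generation starts from an implicit start token and ends at the end token or
`max_length`. The negative log-likelihood (NLL) of a sequence is the sum of
per-step cross-entropies through the end token.

The network, backpropagation through time, and the Adam optimizer are
implemented directly in NumPy (float32 weights, float64 softmax/likelihood
arithmetic). Checkpoints are single `.npz` archives (format tag
`augmem-policy-v1`) holding the weight arrays plus a JSON metadata entry
with the architecture and the embedded vocabulary, so a saved policy is
self-contained. A finite-difference check of the full gradient path is part of
the development history; the test suite asserts the observable consequence
(a single update step reduces the training loss).

## Losses and update algorithms

For a sequence A with reward S(A) ∈ [0, 1]:

    log P_aug(A) = log P_prior(A) + σ · S(A)
    L(θ)         = mean over batch of (log P_aug(A) − log P_agent(A))²

All four algorithms minimize this squared difference; they differ in which
sequences enter the batch:

* **reinvent** — the sampled batch plus a uniformly replayed subset
  (default 10) of the replay buffer.
* **ahc** — only the top-k fraction (default 0.5) of the batch by reward,
  plus the replay subset. Ties at the cutoff keep batch order.
* **bar** — a convex combination (α, default 0.5) of the loss on the current
  Agent's batch and on a batch sampled from the best Agent seen so far. Both
  batches are oracle-scored, so a BAR epoch may charge up to 2× the batch
  size; the best Agent is refreshed whenever the current batch's mean reward
  exceeds the best mean seen.
* **augmented_memory** — the batch is scored once (the only oracle charge of
  the epoch); then N times (default 2), every SMILES in the batch *and in
  the entire replay buffer* is re-written by randomizing the atom order, the
  Prior and Agent likelihoods are recomputed on the re-written strings, and
  one gradient step is taken against the stored rewards. The Prior
  likelihood is deliberately recomputed per representation — different
  writings have different likelihoods, which is what makes each round carry
  fresh gradient information.

Invalid and zero-reward samples stay in the gradient batch (their augmented
target is just the prior likelihood); only the buffer excludes them.

## Oracle accounting

One oracle call is charged per distinct canonical SMILES ever scored.
Duplicates — including augmented re-writings of an already-scored molecule —
are free. This is the budgeted-benchmark convention and the accounting that
makes augmentation rounds oracle-free. The ledger also keeps the ordered
(call index, SMILES, reward) history that the AUC Top-10 metric consumes.
A run's epoch loop starts a new epoch only while
`call_count + batch_size ≤ budget`, so the ledger can never exceed the
budget; because a converged policy stops paying for new molecules, runs are
additionally capped by `max_epochs` (default 4 · budget / batch).

## Memory components

* **Replay buffer** — capacity 100, unique by canonical SMILES, sorted by
  reward descending with stable insertion-order tie-breaks; zero-reward
  molecules are never inserted.
* **Diversity filter (DF)** — each Bemis–Murcko scaffold has a bucket of
  size 25; a molecule whose bucket is already full receives reward 0, and
  every valid molecule then increments its bucket. Counting is
  order-dependent within a batch (the 26th same-scaffold molecule is the
  first zeroed). Acyclic molecules use their own canonical SMILES as the
  bucket key so they are not collectively penalized through one shared empty
  scaffold.
* **Selective Memory Purge** — with the DF active, every epoch removes from
  the buffer all entries whose scaffold is penalized. The purge runs after
  the batch is merged, so it also evicts entries whose bucket filled during
  that very batch: each augmentation round then replays only scaffolds that
  still earn reward.

## Scoring

Components map a canonical SMILES through a raw function and a monotone
transform onto [0, 1]; the reward is their weighted geometric mean, so any
zero component (e.g. a hard molecular-weight cap) zeroes the reward.
Built-ins: Tanimoto similarity to a reference (Morgan radius 2, 2048 bits,
optionally capped as `min(1, sim/threshold)` per the rediscovery-benchmark
convention), QED, and a molecular-weight step (1 if MW < 500 Da). External
oracles (docking, xTB ionization potential, synthetic-accessibility score)
are interface-only adapters: a user-supplied raw function wrapped in a
reverse sigmoid (minimized quantities; midpoint/steepness configurable) or
the reversed linear [1, 10] map for SA. Tests use deterministic stubs.

## Fixture chemical space and the desk-scale study

Real applications use priors pretrained on millions of molecules; the
package instead ships a combinatorial micro-space: two drug-like ring
templates, each with two attachment points, decorated with 30 substituent
fragments (1800 unique products, ~200 distinct Bemis–Murcko scaffolds). The
prior corpus is a seeded 500-molecule sample; the rediscovery target (a
furan/ethyl decoration of the benzamide–piperidine template) is excluded
from it, so the Prior can spell the target but has never seen it.

The desk-scale prior is a 1-layer LSTM (embedding 64, hidden 256) trained
for 250 epochs at lr 5e-3 (annealed to 5e-4 for the final fifth) on
*randomized* SMILES: each molecule is re-written with shuffled atom order
every epoch. Randomized-SMILES training matters here — a canonical-only
prior at this scale assigns ~80 nats more NLL to non-canonical writings,
which poisons the augmented-likelihood targets that Augmented Memory
regresses onto; the augmented prior scores all writings within a fraction of
a nat of each other. It samples ≥95% valid SMILES.

The fixture similarity task scores Tanimoto similarity to the held-out
target capped at 0.6. The cap mirrors the rediscovery-benchmark transform
and keeps the top of the reward landscape populated: in an 1800-molecule
space only two molecules exceed raw similarity 0.8, so an uncapped mean
batch reward of 0.8 would be unreachable by construction, whereas ~100
molecules reach capped reward 0.8. RL runs use the algorithm defaults
(σ = 128, batch 64, lr 1e-4, N = 2, buffer 100, replay subset 10) with
`max_length` 64 and an oracle budget of 3000 calls.

What the fixture study does *not* emulate: the scale and heterogeneity of a
drug-like corpus (ChEMBL-sized vocabularies, stereochemistry, charged
species), expensive noisy oracles, and the sparse-reward regime of
classifier-based tasks. Passing the desk-scale comparisons shows the
mechanisms behave as designed (oracle-free reuse, purge-rescued diversity,
relative sample-efficiency ordering), not that the absolute call counts
transfer to production-scale runs.

## Metrics

* **AUC Top-10** — after every oracle call, the running mean of the 10 best
  rewards seen so far; step-function integration over the call budget
  (evaluated per call, not per batch), carried forward at the final value if
  the run ends early, normalized by the budget. Step integration (rather
  than trapezoid) matches budgeted-call semantics and is exactly
  reproducible.
* **IntDiv1** — 1 minus the mean pairwise Tanimoto similarity over all
  ordered pairs of the generated set, self-pairs included (power-mean p = 1
  definition), so n copies of one molecule score 0 and a disjoint pair
  scores 0.5.
* **filter_pass** — triage counting against per-component threshold rules
  (e.g. MW < 500, QED > 0.4, docking < −9.4).
* Algorithm comparisons across seeds use Welch's t-test at the 95%
  confidence level (`evalx.compare_runs`).

## Numerical and design choices

* Weighted geometric mean as the MPO aggregator (REINVENT convention).
* Sampling is exact multinomial ancestral sampling; a single integer seed
  fans out through `numpy.random.SeedSequence` to sampling, augmentation
  shuffles, and buffer subsampling, making runs bit-reproducible.
* SMILES randomization uses a uniformly shuffled atom renumbering followed
  by the toolkit's depth-first writer; a randomized string that fails to
  re-parse (guarded, not observed) falls back to the canonical form, and one
  that uses a token outside the vocabulary falls back to the input string.
* The vocabulary always contains ring-closure digits, parentheses, and bond
  symbols in addition to corpus tokens, so re-writings of encodable
  molecules stay encodable; rare canonical forms with out-of-vocabulary
  bracket atoms (e.g. hypervalent-sulfur writings sampled by a young agent)
  fall back to the sampled string in gradient batches and are skipped when
  replayed from the buffer.
* Degenerate inputs: unparseable SMILES score 0 and are never charged to
  the ledger; an all-invalid batch leaves the buffer unchanged; bucket size
  0 zeroes every molecule; `tanimoto` of two empty fingerprints is 0.

## Known limitations

* The NumPy LSTM is single-threaded and desk-scale; production-scale priors
  (3×512 networks on millions of molecules) are architecturally supported
  but not computationally practical here.
* BAR follows the published formulation in which both batches are
  oracle-scored; its per-epoch oracle cost is therefore up to twice that of
  the other algorithms.
* External-oracle adapters are interfaces with documented transforms; no
  docking or quantum-chemistry code is executed.
* The diversity filter counts only valid molecules; whether invalid samples
  should consume bucket capacity is left as a non-issue since they carry no
  scaffold.
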