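# Methods

## Problem setting

`molgrow` implements scaffold-constrained de novo molecule design: the
user supplies a *scaffold* — one or more molecular fragments, joined with
`'.'`, that may be disconnected — and a generative model grows and links
those fragments into complete molecules. The intended use case is
fragment-based lead finding against a protein target (the package's
synthetic benchmark emulates adenosine-receptor ligand series), where
known warheads or privileged cores must be preserved while the rest of
the molecule is invented.

The pipeline has four stages:

1. **Pair construction.** Every training molecule is cut at BRICS
   retrosynthetic bonds; the leaf fragments (at most the four largest by
   heavy-atom count, attachment points hydrogen-capped) define up to
   2^n − 1 scaffold→molecule training pairs, one per non-empty fragment
   subset. Data are split 8:1:1 by *scaffold identity* (the sorted
   canonical fragment multiset), so no scaffold leaks across splits.
2. **Supervised training** of an encoder–decoder generator on those
   pairs (negative log likelihood, Adam, early stopping on validation
   loss).
3. **Scoring environment**: a random-forest regressor over 2048-bit
   ECFP6 + 19 physicochemical descriptors predicts activity (pX); QED
   measures drug-likeness; a synthetic-accessibility heuristic is
   reported but never optimized.
4. **Reinforcement learning**: REINFORCE with Pareto-rank-shaped rewards
   steers the generator toward predicted-active (and optionally
   drug-like) chemistry.

## Molecular representations

### SMILES sequences

SMILES are tokenized with atom-level rules (two-letter halogens and
bracket atoms are single tokens), wrapped in GO/END control tokens and
padded to a fixed length (default 100 tokens; longer training pairs are
dropped with a log count). The vocabulary is the union of a frozen
default token list and the tokens observed in the corpus.

### The five-row graph matrix

Each molecule (kekulized, so per-atom valence sums are well defined) is
written as an integer matrix with rows (atom type, bond type, connected
atom index, current atom index, fragment index). Columns fall into three
sections: the *fragment section* (the input scaffold, fragment index
≥ 1), the *growing section* (new atoms attached to existing ones, plus
ring closures), and — after an end-token column — the *linking section*,
single bonds joining the grown components, closed by a second end token.
A new atom's column carries its element token and the bond to its parent
(bond 0 for the first atom of a fragment); a closure/link column carries
atom type 0 (`'*'`) and references two existing atoms.

The atom vocabulary covers the 12-element organic subset with ±1 charge
states (39 tokens including `'*'`, GO, END). The word index
`W = T_atom × 4 + T_bond` (four bond types: none/single/double/triple)
and the position index `P = I_atom × L_max + I_connected` feed one
embedding table and one sinusoidal positional-encoding table
respectively. Matrix width defaults to `l_max = 80` columns.

Encoding traverses each fragment breadth-first from its lowest
canonical-rank atom, then grows the remaining atoms outward from the
fragments by multi-source BFS (every growing atom attaches inside the
group of the fragment that reached it first); single bonds between
different groups are deferred to the linking section. Decoding replays
the columns into an RDKit molecule and sanitizes it, which re-perceives
aromaticity. Round-trip identity on canonical SMILES is enforced by test
over an entire fixture library times all fragment subsets.

### Valence masking

During generation a `GraphState` tracks, per placed atom, the remaining
valence (maximum bond-order total minus bonds placed) and the connected
component. At every step it exposes exactly the continuations that keep
every atom within its maximum valence and respect the section grammar
(growing: new atoms or closures, END always available; linking: single
bonds across components only, END available once the components are
joined or no feasible link remains). Each token's maximum valence is
determined *empirically* against RDKit's sanitizer at vocabulary
construction (an atom plus k single-bonded carbons), so the mask agrees
exactly with the validity check used at decode time; halogens are
additionally capped at their standard organic valences (X 1, X⁺ 2, X⁻ 0)
because RDKit's sanitization cleanup rewrites hypervalent halogen–oxide
motifs, which can invalidate a neighbouring atom after the per-atom
check has passed. This is what makes
100% of sampled graph matrices decode: a 10,000-sample random-policy
fuzz with zero decode failures is part of the test suite. If the linking
phase runs out of valence before connecting everything, the largest
component is returned; this is rare after training.

## Generator architectures

All four models are implemented on a small in-package reverse-mode
autodiff engine over NumPy float32 arrays (`molgrow.nn`): tensors with a
tape, the layer set the models need (linear, embedding, layer norm,
multi-head attention, pre-norm transformer blocks, LSTM, GRU cell) and
Adam with global-norm gradient clipping (clip 5.0).

* **Graph transformer** — transformer encoder over the fragment-section
  columns, transformer decoder (causal self-attention + cross-attention
  to the encoder) over the growing/linking columns. The decoder hidden
  state is unrolled through a GRU cell into four chained decisions per
  column — atom type, bond type, connected index, current index — each
  conditioned on the previous choice's embedding; the loss is the sum of
  the four negative log likelihoods.
* **Sequence transformer** — standard encoder–decoder over SMILES tokens
  with sinusoidal positional encodings.
* **LSTM-BASE** — 3-layer LSTM encoder and decoder (embedding 128,
  hidden 512 by default); the encoder's final hidden/cell states
  initialize the decoder.
* **LSTM+ATTN** — as LSTM-BASE, plus per-step dot-product attention of
  the previous top-layer decoder state over encoder outputs; the context
  vector is concatenated with the token embedding as decoder input.

Transformer defaults follow the usual configuration (8 heads,
d_k = d_v = d_model/h, feed-forward width 4×d_model); depth defaults to
3 encoder + 3 decoder layers and is configurable — the desk-scale tests
use 2 layers at d_model 64. Pre-norm residual blocks were chosen over
post-norm for optimization stability at small width without a warmup
schedule. Training defaults: learning rate 1e-4, batch 256, 20 epochs
for pretraining (up to 1000 with patience 100 for fine-tuning); the
returned parameters are the best-validation-epoch snapshot. Teacher
forcing is used throughout supervised training; sampling is pure
multinomial (temperature 1.0). Sequence models mask only the control
tokens at sampling time — no grammar enforcement, so invalid SMILES are
possible and are measured, not hidden.

## Scoring environment

Descriptors: 2048-bit Morgan radius-3 fingerprints (ECFP6) followed by
19 physicochemical descriptors (MW, logP, HBA, HBD, rotatable bonds,
amide bonds, bridgeheads, heteroatoms, spiro atoms, heavy atoms,
fraction Csp3, aliphatic/saturated/total/aromatic rings, heterocycles,
valence electrons, TPSA, Wildman–Crippen MR), length 2067. The affinity
model is a scikit-learn random forest (500 trees by default, fixed
seed); `fit` requires ≥ 25 finite-activity records and rejects constant
targets. A molecule is *desired* when predicted pX ≥ 6.5 (≈ 316 nM);
an additional QED cutoff can be enabled but is off by default, so QED
influences the Pareto ranking without changing the desired flag.

The synthetic-accessibility score is a lightweight in-package heuristic
in [1, 10] combining size, fused/bridged/spiro/macrocyclic ring
complexity and stereocentre count. It is intended for relative
comparison within generated sets and is reported only.

## Pareto ranking and reinforcement learning

Score vectors (all larger-is-better) are sorted into Pareto frontiers
with a vectorized pairwise-dominance algorithm, verified against an
O(N²·n) brute force. Within a frontier, molecules are ordered by mean
Tanimoto distance to the other members, most crowded first, with
canonical-SMILES tie-breaks for determinism. The global 1-based rank k
places invalid molecules first, then valid undesired (worst frontier
first), then desired; rewards are

    R* = k / (2 N_und)                    undesired,
    R* = 1/2 + (k − N_und) / (2 N_des)    desired,

so undesired rewards fall in (0, 0.5] and desired in (0.5, 1]. Crowded
molecules get lower rewards, which pushes the policy toward diverse
solutions.

RL uses REINFORCE on complete episodes: the objective weights each
episode's summed step log-likelihood by its terminal reward (for the
graph model, all four decision log-probabilities per column). An
exploration net G_φ with frozen parameters answers a fraction ε ∈ [0, 1]
of each scaffold batch; all generated molecules are scored and ranked
together, and only the exploitation net G_θ is updated. The update uses
the unmasked teacher-forced log-likelihood of the sampled episodes —
the sampled actions are valid by construction, and this keeps one
forward pass per update rather than replaying per-step masks. Scaffold
batches are drawn with replacement from the training scaffold pool
(batch 64 by default).

## Population metrics

For a generated set: validity (parsable fraction), accuracy (fraction
containing all input-scaffold fragments as substructures — matching is
tried on both the aromatic-perceived and kekulized molecule), desirability
(desired-flag fraction), uniqueness (distinct canonical structures /
total) and novelty (unique structures absent from the reference corpus;
novelty ≤ uniqueness by construction). Diversity is the Solow–Polasky
measure I(A) = (1/m) eᵀ F⁻¹ e with kernel f(d) = e^(−θd), θ = 0.5, over
pairwise ECFP6 Tanimoto distances, computed by linear solve (verified
against explicit inversion to 1e-8). Exact duplicates make F singular
and are collapsed first; m counts distinct structures, so one molecule
has diversity exactly 1 and adding a duplicate never increases it.

## The synthetic benchmark library

Because the original training corpora are large public databases, the
package ships a generator of synthetic libraries instead of data: a
panel of eight heteroaromatic cores common among adenosine-receptor
ligands (furan, thiophene, benzene, pyrimidine, aminotriazine,
aminotriazole, xanthine-like, azapurine-like) is decorated at one or two
sites with fourteen small substituents, giving a 1336-molecule
enumerable space. Each molecule receives a deterministic pseudo-activity:
a base value in [4, 9] pChEMBL units from a stable hash of its Murcko
ring system, plus seeded Gaussian noise (σ = 0.3) — a learnable,
reproducible structure–activity signal. A 300-molecule library with a
200-tree forest recovers this signal at cross-validated R² ≈ 0.8.

What the fixture does *not* emulate: real assay noise structure,
activity cliffs, large/flexible molecules, stereochemistry, tautomerism,
and the scale of public corpora. Passing tests therefore demonstrate
that the machinery is correct and that learning dynamics behave as
designed, not that the models reach publication-scale accuracy/novelty
figures on real data — those depend on corpus-scale pretraining, which
is out of scope here.

## Numerical and design choices

* Desk-scale problem sizes used by the test suite: 300-molecule
  training library (≈ 960 scaffold pairs), graph transformer d_model 64 /
  2 layers / 30 epochs, 1000-sample validity checks, RL with batch 32
  for 30 epochs over 5 seeds. Chosen as the smallest sizes at which the
  learning-dynamics claims are stable.
* Fragment ranking ties (equal heavy-atom counts) break on canonical
  SMILES order; 8:1:1 splits on small sets give validation and test
  ⌈N/10⌉ scaffolds each, remainder to train.
* Duplicate scaffold→molecule pairs from symmetric molecules are kept
  (and visible in logs), not deduplicated.
* Charge handling in standardization keeps un-neutralizable centres
  (e.g. quaternary N) charged, with a log flag; "small fragment
  removal" is implemented as keep-largest-organic-component, and any
  non-organic element in the largest component rejects the molecule.
* Stereochemistry is preserved as given; tautomers are not canonicalized.
* Invalid molecules during RL are treated as undesired and ranked below
  every valid undesired molecule (a configurable choice in the ranking
  call).
* The graph decoder's GRU cell is shared across the three
  decision-to-decision transitions; the fragment-index row is used only
  for matrix construction and bookkeeping, never as a network input.
* Sampling determinism: every stochastic component takes an explicit
  integer seed through `numpy.random.default_rng`.

## Known limitations

* The in-package autodiff engine is single-threaded NumPy; it is sized
  for desk-scale experiments, not for corpus-scale pretraining.
* Valence masking guarantees parsability, not chemical reasonableness:
  an untrained model can emit exotic-but-sanitizable species (charged
  chalcogen chains, odd ring systems). Training data quality, QED and
  the SA report are the guards against this.
* Linking uses single bonds only, so scaffolds whose fragments must be
  joined by double bonds cannot be linked directly (they can still be
  reached by growing).
* Scaffold-containment accuracy inherits the aromaticity/kekulization
  ambiguity of substructure matching; matching on both molecule forms
  reduces but does not eliminate mismatches when growing aromatizes
  scaffold bonds.
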