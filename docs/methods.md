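# Methods

## The problem and the model

Molecular data resolve the relationships of extant species far more
reliably than morphology, but fossils carry no sequences. The workflow this
package implements takes a discrete morphological character matrix that
mixes extant and fossil taxa, together with a sample of molecular trees
over the extant taxa (e.g. a Bayesian posterior sample), and infers
phylogenies by maximum parsimony under a *conservative molecular backbone*:
clades of the molecular tree whose posterior probability reaches a
threshold (0.70 by convention) are enforced; weaker clades are collapsed,
leaving morphology free to resolve them; fossil taxa are entirely
unconstrained and attach wherever the character data place them.

### Parsimony scoring

Characters are unordered by default (Fitch costs); characters flagged
ordered use linear (|i−j|) costs. Two scorers coexist deliberately:

- a **general Sankoff dynamic program**, vectorized across characters of
  equal state count, which handles polytomies, ordered characters,
  polymorphic cells (treated as uncertainty: any member state may be
  assigned) and missing/inapplicable cells (full state set) — used for all
  reporting and as a correctness net;
- a **bit-packed Fitch pass** over deduplicated site patterns, restricted
  to binary trees and unordered characters — the search hot path. State
  sets are machine-word bitmasks; a tree evaluation is one postorder sweep
  of AND/OR operations over pattern arrays.

The test suite asserts the two agree (together with a naive set-based
Fitch written independently in the tests) on hundreds of random instances.

Inapplicable entries (`-`) are stored distinctly from missing (`?`) but
scored as missing by default, the conventional treatment for reductively
coded matrices; `inapplicable_as_state=True` scores the gap as an extra
state instead.

### Homoplasy indices

For character i, mᵢ is the minimum conceivable number of steps on any tree
(number of required states minus one, where a state is required when it is
some taxon's unique observed state) and gᵢ the star-tree maximum
(observed taxa minus the modal state count, ambiguous cells resolved
greedily to their most frequent member state — a documented approximation;
exact optima under heavy polymorphism would need a small combinatorial
search). With sᵢ the steps realized on the evaluated tree,

    CI = Σmᵢ / Σsᵢ        RI = (Σgᵢ − Σsᵢ) / (Σgᵢ − Σmᵢ).

All characters enter the sums by default (the ensemble convention of
common parsimony programs); `include_uninformative=False` restricts to
characters with mᵢ < gᵢ. Because per-character sᵢ can differ between
equally long trees, ensemble values are reported per tree with their
range; the headline value uses the first tree.

### Backbone constraints

The backbone is built from a support-annotated rooted tree — usually the
maximum clade credibility (MCC) topology of a tree sample, selected by
maximizing the sum of log clade frequencies (ties to the lowest sample
index; a burn-in fraction, default 0.10 in the pipeline, can be discarded
first). Supports given in percent are divided by 100. Internal nodes with
pp below the threshold are collapsed (strictly below; the count is
reported), and the result is restricted to the constrained taxa.

Constraint semantics are **rooted-clade** based, matching how constraint
trees behave in parsimony programs: backbone clade C over constrained set
K requires the candidate to display C — some node whose leaf set,
restricted to K, is exactly C. Candidates in the search are rooted at the
first matrix taxon (the outgroup-first convention); a clade containing
that taxon is matched through its complement, which is the unrooted
reading of the same edge. Unconstrained taxa are invisible to the check,
so fossils may nest anywhere, including inside enforced clades. During
stepwise addition the backbone is restricted to the taxa already placed,
pruning violations early; final trees are re-checked in full. Raising the
pp threshold only ever collapses more nodes and therefore never shrinks
the set of admissible trees (property-tested by exhaustive enumeration).

### Heuristic search

Per replicate: a random-sequence addition tree (each taxon inserted at the
length-minimizing constraint-satisfying edge, ties broken uniformly at
random), then TBR hill-climbing — every bisection of every edge, every
reconnection pair — in randomized order, accepting the first strictly
shorter constraint-satisfying neighbor and restarting; equally best trees
fill a hold-k buffer. Replicate buffers are pooled, trimmed to the global
best length, optionally collapsed and deduplicated by bipartition set.
Trees are re-scored in full at every evaluation through the packed Fitch
pass rather than incrementally; at the problem sizes this package targets
a full vectorized re-score is a few tens of microseconds, and one code
path is far easier to verify. All randomness flows from a single seeded
generator, so a (config, seed) pair reproduces its MPT set exactly.

The default collapse rule (`min_length_zero`) contracts internal branches
whose minimum optimized length is zero — detected per branch as non-empty
intersection of the Fitch final (MPR) state sets at its two ends for every
character — before deduplication, approximating the common collapsing
convention of parsimony programs; `none` keeps binary trees. Branches that
realize an enforced backbone clade are exempt from collapsing so that
every reported MPT still displays the constraint. The MPT *count* (unlike
the length) depends on the collapse convention; both modes are exposed.

### Character mapping

MPR state sets come from a two-direction Sankoff pass (cost below + cost
above each node), which is exact for polytomies, multistate and missing
data; the sets are validated against brute-force enumeration of all
internal assignments in the tests. ACCTRAN and DELTRAN are operationalized
as root-to-tip walks through the cost-optimal choice sets: DELTRAN keeps
the parent's state whenever optimal (changes delayed, favoring
parallelisms), ACCTRAN prefers a change whenever optimal (changes pulled
rootward, favoring reversals); both provably realize sᵢ steps. A change is
reported on a consensus branch when every MPT shows it there under at
least one optimization, is *unambiguous* when both optimizations agree in
every MPT, and is flagged homoplastic when the character's ci < 1 — the
black/white point convention of published character maps. Bootstrap
resamples characters with replacement; jackknife deletes each character
with probability 0.36 (the e⁻¹ convention) unless overridden; support is
the fraction of replicate strict consensus trees containing a bipartition.

### Mkv likelihood

The Mk model is the k-state symmetric Markov process with stationary
frequencies 1/k; on a branch of length v (expected substitutions per
character) P(same) = 1/k + (k−1)/k·e^(−kv/(k−1)). Each character uses
k = its observed state count (minimum 2) unless a global k is set — an
approximation to how mixed binary/multistate matrices are commonly
handled; the per-character choice interacts with the ascertainment
correction and is deliberately overridable. The Mkv correction conditions
on variability by dividing every site likelihood by (1 − k·L(constant)),
with all terms averaged over discrete-gamma rate categories
(equal-probability categories, category means, mean normalized to 1).
Missing and inapplicable cells enter the pruning pass as all-ones partial
likelihoods. The reduced ML search — neighbor joining on p-distances
(state-set overlap counts as a match; deterministic lowest-index
tie-breaks; negative branch lengths floored at 1e−8), then rounds of
random TBR proposals with bounded coordinate-wise branch-length
optimization (golden-section on [1e−8, 20], xatol 1e−4), accepting strict
improvements — is a correctness-scale tool, not a production ML engine:
its contract is that the likelihood it reports is exact for the tree it
returns, verified against closed forms, brute-force sums over internal
states and pattern-probability normalization.

## The synthetic-data generator

`simulate_dataset` emulates the statistical structure the analysis
assumes: a Yule tree; Mk characters with optional gamma rate multipliers;
rejection sampling until every character is variable (the Mkv
ascertainment regime); missing data injected at a base rate with a
multiplier (default 4×, or an explicit rate) for fossil-flagged taxa; and
a "posterior" sample made by hitting each internal edge of the true tree
with an NNI at a fixed probability.

Branch lengths are rescaled so the root-to-tip height is 0.15 expected
substitutions per character, with every branch floored at 0.03. Raw Yule
branch lengths at rate 1 would saturate binary characters (about one
change per character per branch) and contain near-zero internal branches
carrying no expected signal — under either condition no method can recover
the generating tree, so recovery tests would measure the simulation, not
the software. The chosen regime corresponds to roughly one expected change
per character across the whole tree, which is where curated morphological
characters live, while the floor guarantees each internal edge expects a
handful of changes across a few-hundred-character matrix. What passing
recovery tests therefore show is that the machinery is correct and the
backbone mechanism helps *when the data carry signal*; they say nothing
about saturated or signal-free real data, and the generator makes no
claim to realistic fossil sampling through time (pure birth, no death),
correlated character evolution, or reductive-coding dependency structure.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full suite completes in well under a minute: exhaustive-vs-heuristic
equivalence on 5–7 taxa (50 seeds; 4 addition replicates — 2 suffice
unconstrained but constrained landscapes occasionally trap a single
climb), recovery at 12 taxa × 300 characters (20 seeds, 3 replicates),
fossil placement at 12 taxa with 4 half-missing fossils (20 seeds,
paired), and a 26-taxon × 224-character synthetic analogue of a full
constrained study in the acceptance script. The search defaults
(1000 replicates, hold 10) mirror the full-scale protocol the package
targets; callers pass smaller budgets explicitly everywhere in the tests.

## Known limitations

- Polymorphic cells are treated as uncertainty, not true polymorphism
  (no minimum-cost-over-member-states scoring); matrices relying on
  polymorphism-aware step counting will score lower here.
- mᵢ/gᵢ under polymorphism use the stated greedy resolution, so CI/RI can
  deviate slightly from programs that resolve ambiguity exactly.
- The collapse rule approximates, but is not bit-identical to, any one
  program's convention; MPT counts are convention-sensitive.
- Inapplicable states are not given Brazeau-style hierarchical semantics;
  only missing-equivalent or extra-state treatments are offered.
- The ML search is not meant to reproduce a full 10,000-rearrangement
  PAUP-scale analysis; no ML point estimates are treated as targets.
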