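# Methods

This note documents the models, rewards, training objective and synthetic
data underlying `simplerl`, together with the numerical choices and the
limits of what desk-scale tests can show.

## Problem setting

Paragraph-level medical text simplification: given a complex source
paragraph S (e.g. a technical abstract), produce a generated paragraph G
that preserves the meaning of a reference simple paragraph T (e.g. a
plain-language summary) while reading at a lower grade level and using
more frequent words. The package treats the task as conditional sequence
generation trained with reinforcement learning: the policy p_θ(y_t | y_<t, x)
emits one token at a time, and scalar rewards computed on the decoded text
supply the training signal that ordinary likelihood training cannot.

## Text measurement layer

All statistics flow through one canonical tokenizer: text is lowercased,
sentences end at `. ! ?` followed by whitespace or end-of-text (with a
small packaged abbreviation guard — "e.g.", "et al.", titles, "fig." and
similar), and words are maximal alphanumeric-plus-apostrophe runs.
Syllables are counted by the standard vowel-group heuristic over
`aeiouy`, dropping a trailing silent "e" unless it is the word's only
vowel group, flooring at one, with a small exception table for common
irregulars ("people", "business", ...). The heuristic is exact on the
synthetic vocabulary (built to have unambiguous vowel-group structure) and
approximate on natural English — corpus readability numbers computed with
other tokenizers will differ by a few tenths of a grade.

Readability formulas:

* FKGL = a·(words/sentence) + b·(syllables/word) − c. Two named
  coefficient presets are provided. `"standard"` = (0.39, 11.8, 15.59),
  the Flesch-Kincaid grade level as usually published, and the package
  default for corpus reports. `"paper"` = (0.38, 1.8, 15.59), a variant
  triple that appears in print in parts of the simplification literature;
  it is provided for strict fidelity and for reproducing worked examples.
  The two differ materially (the syllable coefficient 1.8 vs 11.8), so the
  preset is always part of a report's configuration echo.
* ARI = 4.71·(characters/word) + 0.5·(words/sentence) − 21.43, with
  characters counted over word tokens only.

Generation metrics:

* ROUGE-n uses multiset (clipped-count) n-gram overlap with no stemming or
  stopword removal, reporting precision, recall and F1. This is the
  simplest reproducible variant; published ROUGE implementations differ in
  preprocessing, so absolute values are comparable only within the
  package.
* SARI scores the three edit operations of a simplification — n-grams
  added, kept and deleted relative to the source — against the references,
  for n = 1..4 with equal weight. Additions and keeps are scored by F1,
  deletions by precision only; operation sets use unique-n-gram (set)
  semantics over the union of references. When the predicted and the
  reference operation set are both empty the component scores 1 (the
  candidate did the right thing by doing nothing); when exactly one is
  empty it scores 0. These conventions are pinned because published SARI
  implementations disagree on exactly these cases; a documented
  consequence is that a candidate identical to the sole reference always
  scores exactly 1.

## Rewards

Each generated text G is scored against the pair's reference T and source
S with three bounded components:

* **Relevance** R_cosine ∈ [0, 1]: cosine similarity between sentence
  embeddings of T and G, negatives clipped to 0. The embedding model is a
  contract (any text → fixed-dimension vector); the packaged default is a
  deterministic hashed bag-of-words embedder (BLAKE2-hashed token slots
  with signs, default dimension 256). It captures lexical overlap, not
  meaning: synonym substitutions that a trained sentence embedding would
  reward are invisible to it. Domain sentence embeddings (e.g. models
  trained on biomedical text) attach through the same contract.
* **Readability gain** R_Flesch ∈ [−1, 1]: the relative difference
  (r(T) − r(G)) / max(|r(T)|, 1e-6), clipped to [−1, 1], where r(·) is the
  FKGL under the configured preset. Positive exactly when the generation
  reads at a lower grade than the reference. The epsilon floor keeps the
  ratio defined for near-zero reference grades; clipping bounds the
  training signal.
* **Lexical simplicity** R_lexical ∈ [0, 1]: let ΔZ(S, G) be the mean Zipf
  frequency of the word types G inserted (types in G not in S) minus the
  mean Zipf of the types it deleted. The reward is the linear ramp
  clip(ΔZ / 0.4, 0, 1). The saturation point 0.4 is the corpus-typical
  shift between complex paragraphs and their plain-language rewrites and
  is configurable. Word sets use unique lowercased types with stopwords
  retained; an empty inserted or deleted set contributes mean 0, so a
  verbatim copy earns 0 — copying is never rewarded. Unknown words default
  to Zipf 0 ("below measurable frequency"), configurable via the lexicon's
  `oov_zipf`.

The total reward is the weighted sum α·R_cosine + β·R_Flesch + d·R_lexical
with defaults α = β = d = 1/3. A degenerate generation (no word tokens)
scores 0 on every component rather than raising, which keeps training
total on arbitrary policies.

## Training objective

Two losses are mixed:

* MLE: Lml = −Σ_t log p_θ(y_t | y_<t, x) over the reference tokens
  (a sum, as conventional; a per-token-mean reporting mode exists for
  comparability across lengths).
* Policy gradient with baseline:
  Lpg = −(1/n) Σ_t log p_θ(y_t^s | ...) · (r(y^s) − b), where y^s is a
  multinomial sample (temperature 1, no truncation) and the baseline b is
  the reward r(y*) of the model's own greedy decode — self-critical
  sequence training. Sequences that beat their own greedy decode are
  promoted, the rest suppressed, and no learned value function is needed.
  The advantage is treated as a constant (no gradient flows through the
  reward), and per-sample advantages are used rather than batch means.

The total loss is L = γ·Lpg + (1 − γ)·Lml, and training runs a two-phase
schedule: `mle_epochs` of pure likelihood training (γ = 0) to give the
policy a sensible starting distribution, then `rl_epochs` of the mixed
loss. Greedy argmax ties break to the lowest token id; rollouts that hit
`max_decode_length` without emitting the end token are scored as-is.

## Toy policy

The packaged `ToyConditionalGenerator` is a log-linear policy: per-step
features are the L2-normalized bag-of-tokens of the source, a one-hot of
the previous token (or a begin marker), the L2-normalized bag of the
tokens generated so far, and a bias; a fixed seeded random matrix projects
them to `embedding_dim` dimensions; the only trainable parameter is a
vocab × embedding_dim weight matrix feeding a softmax. Gradients of all
losses are closed-form (softmax-minus-one-hot times features), which is
what makes the finite-difference gradient tests exact to 1e-5 and a full
training run take seconds on one CPU. The prefix-bag feature deserves a
note: without it the policy conditions only on the previous token, and
greedy decoding readily collapses into short repetition loops; with it the
policy can learn to penalize tokens it has already emitted.

Defaults (chosen for stable optimization at this scale, all exposed in
`TrainingConfig`): plain SGD with learning rate 0.1, γ = 0.95, 10 MLE +
30 RL epochs, batch size 16, decode cap 30 tokens, embedding_dim 32.
Larger learning rates destabilize the MLE phase; smaller γ dilutes the
reward signal. External frameworks (a transformer fine-tuned under this
objective, for instance) attach through the `ConditionalGenerator`
contract and bring their own optimizer.

## Synthetic corpus

The generator emulates only the statistical axes the rewards read — it
makes no attempt at medical terminology, discourse structure or
factuality. Each pair draws three disjoint word-type sets from a packaged
~500-word synthetic vocabulary: shared types (common pool, Zipf 5–7, 1–2
syllables) appearing on both sides; complex-only types (3–5 syllables,
Zipf 2.6–4.4) appearing only in the source; and simple-only types (1–2
syllables, Zipf 3.6–5.2) appearing only in the reference. Because set
differences then equal these pools exactly, ΔZ(S, reference) is controlled
directly: complex-only types are selected sequentially with
Gaussian weights around the running mean required to land the pair's ΔZ on
the target (default 0.4). Surface forms are synthesized from
consonant-vowel syllable units (final "e" avoided) so the package's own
syllable counter is exact on them.

Sentence lengths are truncated normals (floor 3): complex side mean 25
words (sd 5), simple side mean 8 (sd 2). Filler slots repeat shared types,
except a `complex_rare_fill` = 0.15 fraction on the complex side that
repeats rare polysyllabic types; with these defaults the complex side
lands near FKGL 15 (standard preset) — comparable to real technical
abstracts — and the simple side near grade 2–3, far simpler than real
plain-language summaries, which keeps the readability gap unambiguous for
testing. The dataset-statistic check operationalizes "ΔZ ≈ 0.4" as the
band [0.3, 0.5]; generated corpora put roughly 90% of pairs in that band,
versus 87% reported for the real paired corpus.

Generation is a pure function of the vocabulary and corpus specs
(including their seeds). What passing tests show: the rewards, metrics and
trainer behave correctly on text with controlled readability and frequency
structure. What they do not show: performance on real medical prose, where
tokenization noise, morphology, named entities and semantic paraphrase all
matter.

## Problem sizes and reproducibility

Desk-scale defaults used by the test suite and the acceptance script: 200
synthetic pairs, five training seeds, 40 epochs per run (two-phase and
MLE-only comparison). A full five-seed comparison completes in a few
minutes on one CPU. Every stochastic component (corpus generation, policy
initialization, epoch shuffling, rollout sampling) derives from explicit
integer seeds, and identical seeds reproduce training traces bit-for-bit.

## Known limitations

* The hashed bag-of-words relevance reward cannot see synonymy; with it,
  "relevance" reduces to vocabulary overlap with the reference.
* The toy policy has no syntax beyond previous-token and repetition
  features; it demonstrates the objective, not fluent generation.
* The syllable heuristic and tokenizer make natural-language readability
  values approximate (a few tenths of a grade against other
  implementations).
* Greedy-decode reward curves are noisy across epochs at this scale;
  conclusions about reward ascent are therefore framed as medians across
  seeds, not per-run guarantees.
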