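# simplerl

A reinforcement-learning toolkit for **paragraph-level medical text
simplification**. Technical abstracts of clinical research are public but
largely unreadable for non-experts; systems that rewrite them into plain
language are usually sequence-to-sequence models, and likelihood training
alone neither targets readability nor rewards simpler word choices. This
package implements the ingredients of a reward-driven approach — for NLP
researchers and practitioners who want to study or extend it without a GPU:

* **Metrics** (`simplerl.text_metrics`): a canonical tokenizer and syllable
  counter, FKGL and ARI readability grades, ROUGE-n F1, and SARI (the
  add/keep/delete n-gram metric specific to simplification).
* **Rewards** (`simplerl.rewards`): for a source paragraph S, reference
  simplification T and generated text G —
  * relevance `R_cosine = max(0, cos(E_T, E_G))` via a pluggable sentence
    embedding (packaged default: deterministic hashed bag-of-words);
  * readability gain `R_Flesch = clip((r(T) − r(G)) / max(|r(T)|, ε), −1, 1)`
    with r(·) the FKGL grade;
  * lexical simplicity `R_lexical = clip(ΔZ(S, G)/0.4, 0, 1)` where
    ΔZ = mean Zipf frequency of inserted minus deleted word types;
  * the weighted total `R = α·R_cosine + β·R_Flesch + d·R_lexical`.
* **Training** (`simplerl.scst`): the maximum-likelihood loss
  `Lml = −Σ_t log p_θ(y_t | y_<t, x)`, the REINFORCE loss with baseline
  `Lpg = −(1/n) Σ_t log p_θ(y_t^s) · (r(y^s) − r(y*))` where the baseline is
  the reward of the model's own greedy decode (self-critical sequence
  training), the mixture `L = γ·Lpg + (1 − γ)·Lml`, and a two-phase
  MLE-then-RL trainer. A packaged log-linear toy policy with closed-form
  gradients makes everything runnable and finite-difference-checkable on one
  CPU; real models attach via the `ConditionalGenerator` contract.
* **Synthetic corpora** (`simplerl.synthetic_corpus`): paired paragraphs
  with a controllable readability gap and a controllable Zipf shift between
  deleted and inserted words, so the whole pipeline is testable offline.
* **I/O and CLI** (`simplerl.corpus_io`, `simplerl.cli`): JSONL / parallel
  text corpora, evaluation reports, and the `simplerl` command.

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Score one simplification:

```python
from simplerl import FrequencyLexicon, RewardScorer

lexicon = FrequencyLexicon(
    {"the": 7.0, "study": 5.3, "showed": 5.1, "drug": 4.9, "helped": 5.0,
     "patients": 4.8, "people": 5.9, "got": 5.8, "better": 5.6,
     "demonstrated": 4.1, "amelioration": 1.9, "pharmacotherapy": 2.3,
     "considerable": 4.2, "in": 7.2, "of": 7.5, "symptoms": 4.6},
)
scorer = RewardScorer(lexicon=lexicon)
source = "The pharmacotherapy demonstrated considerable amelioration of symptoms in patients."
reference = "The study showed the drug helped patients."
generated = "The drug helped. People got better."
b = scorer.score(source, reference, generated)
print(f"r_cosine={b.r_cosine:.3f} r_flesch={b.r_flesch:.3f} "
      f"r_lexical={b.r_lexical:.3f} total={b.total:.3f}")
```

prints

```
r_cosine=0.544 r_flesch=0.423 r_lexical=1.000 total=0.656
```

The generation shares about half its vocabulary with the reference
(`r_cosine` 0.544), reads 2.4 grades below it (FKGL 3.28 vs 5.68, a 42%
relative reduction → `r_flesch` 0.423), and swapped rare words
("pharmacotherapy", Zipf 2.3) for common ones ("people", 5.9), saturating
the lexical ramp.

From the shell, generate a synthetic corpus and train the toy policy:

```sh
$ simplerl gen-corpus --n 50 --seed 7 --out corpus.jsonl
wrote 50 pairs to corpus.jsonl (lexicon: corpus.lexicon.tsv)
mean FKGL complex 15.65 / simple 3.22; mean dZ 0.413

$ simplerl train-toy --corpus corpus.jsonl --lexicon corpus.lexicon.tsv \
    --checkpoint policy.ckpt --trace trace.csv
```

The complex side of the generated corpus reads like a technical abstract
(grade ~15), the simple side far below it, and the mean Zipf shift lands on
the 0.4 target. `train-toy` writes a per-epoch CSV trace (losses and mean
reward components) and a text checkpoint; every command also writes a
`*.config.json` sidecar with all resolved settings so runs can be
reproduced exactly. `simplerl evaluate --input corpus.jsonl
--readability-only` and `simplerl rewards --input ...` produce corpus
reports and per-pair reward tables.

To evaluate a real corpus (for instance the public paired corpus of
complex/plain-language paragraphs derived from the Cochrane Database of
Systematic Reviews), convert it to JSONL records with fields `id`,
`source`, `reference`, `generated` — or parallel `source.txt` /
`reference.txt` / `generated.txt` files — and run the same commands. The
optional external test in `tests/test_acceptance.py` activates when that
corpus is placed under `data/cochrane/` as `train.jsonl` and `eval.jsonl`.

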