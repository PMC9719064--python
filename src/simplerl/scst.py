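"""Self-critical sequence training (SCST) for conditional text generators.

The training objective combines two losses.  The maximum-likelihood loss

    Lml = - sum_t log p_theta(y_t | y_<t, x)

teacher-forces the reference simplification.  The policy-gradient loss with
a baseline (REINFORCE)

    Lpg = - (1/n) sum_t log p_theta(y_t^s | ...) * (r(y^s) - b)

promotes sampled sequences whose reward exceeds the baseline; SCST
instantiates the baseline b with the reward of the model's own greedy
decode, b = r(y*), so no learned critic is needed.  The total loss is the
convex mixture

    L = gamma * Lpg + (1 - gamma) * Lml,

and training follows a two-phase schedule: MLE-only epochs first, then
mixed-loss epochs.

Any parametric generator can plug in through the
:class:`ConditionalGenerator` contract (per-step log-probabilities over the
vocabulary, flat parameter access, gradients of summed token
log-probabilities).  The packaged :class:`ToyConditionalGenerator` is a
small log-linear policy over source bag-of-token features with closed-form
gradients, which makes every gradient in the trainer checkable against
finite differences and keeps end-to-end training runnable on one CPU in
seconds.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .rewards import RewardScorer, RewardWeights

__all__ = [
    "SequencePair",
    "Rollout",
    "RolloutPair",
    "TrainingConfig",
    "EpochRecord",
    "TrainingTrace",
    "ConditionalGenerator",
    "ToyConditionalGenerator",
    "make_toy_policy",
    "vocab_from_texts",
    "encode_corpus",
    "mle_loss",
    "pg_loss",
    "scst_loss",
    "total_loss",
    "greedy_decode",
    "sample_decode",
    "train_step",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

EOS_TOKEN = "</s>"


@dataclass(frozen=True)
class SequencePair:
    """One (source, target) token-id pair; the unit of supervised training."""

    source_tokens: tuple[int, ...]
    target_tokens: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.source_tokens or not self.target_tokens:
            raise ValueError("source and target token sequences must be non-empty")


@dataclass
class Rollout:
    """A decoded sequence with its per-token log-probabilities and reward."""

    tokens: tuple[int, ...]
    per_token_logprob: np.ndarray
    mode: str  # "greedy" | "sampled"
    reward: float | None = None
    seed: int | None = None
    reward_weights: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.per_token_logprob):
            raise ValueError("tokens and per_token_logprob lengths differ")


@dataclass
class RolloutPair:
    """Sampled rollout plus the greedy (baseline) rollout for one source."""

    sampled: Rollout
    greedy: Rollout

    @property
    def advantage(self) -> float:
        if self.sampled.reward is None or self.greedy.reward is None:
            raise ValueError("both rollouts must be scored before use")
        return self.sampled.reward - self.greedy.reward


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the two-phase MLE -> RL schedule.

    ``gamma`` mixes the policy-gradient and MLE losses during the RL phase
    (gamma = 0 degenerates to pure MLE); ``mle_epochs``/``rl_epochs`` are
    the phase lengths; everything stochastic derives from ``seed``.
    """

    gamma: float = 0.95
    reward_weights: RewardWeights = field(default_factory=RewardWeights)
    learning_rate: float = 0.1
    mle_epochs: int = 10
    rl_epochs: int = 30
    batch_size: int = 16
    max_decode_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.mle_epochs < 0 or self.rl_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 1 or self.max_decode_length < 1:
            raise ValueError("batch_size and max_decode_length must be >= 1")

    @property
    def epochs(self) -> int:
        return self.mle_epochs + self.rl_epochs


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    phase: str  # "mle" | "rl"
    lml: float
    lpg: float
    r_cosine: float
    r_flesch: float
    r_lexical: float
    reward_total: float
    sampled_reward: float

    FIELDS = (
        "epoch",
        "phase",
        "lml",
        "lpg",
        "r_cosine",
        "r_flesch",
        "r_lexical",
        "reward_total",
        "sampled_reward",
    )


@dataclass
class TrainingTrace:
    records: list[EpochRecord] = field(default_factory=list)

    def append(self, record: EpochRecord) -> None:
        self.records.append(record)

    @property
    def initial_reward(self) -> float:
        return self.records[0].reward_total

    @property
    def final_reward(self) -> float:
        return self.records[-1].reward_total

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(EpochRecord.FIELDS)
            for rec in self.records:
                writer.writerow([getattr(rec, name) for name in EpochRecord.FIELDS])


@runtime_checkable
class ConditionalGenerator(Protocol):
    """Contract a trainable policy must satisfy.

    ``token_logprobs`` must return a normalized log-distribution
    (logsumexp = 0) over the vocabulary at every step and be deterministic
    given (parameters, inputs).
    """

    vocab: tuple[str, ...]
    eos_id: int

    def token_logprobs(
        self, source: Sequence[int], prefix: Sequence[int]
    ) -> np.ndarray: ...

    def sequence_logprobs(
        self, source: Sequence[int], tokens: Sequence[int]
    ) -> np.ndarray: ...

    def sequence_logprob_grad(
        self, source: Sequence[int], tokens: Sequence[int]
    ) -> tuple[np.ndarray, np.ndarray]: ...

    def get_params(self) -> np.ndarray: ...

    def set_params(self, params: np.ndarray) -> None: ...

    def detokenize(self, tokens: Sequence[int]) -> str: ...


class ToyConditionalGenerator:
    """Log-linear conditional policy with closed-form gradients.

    At each step the policy computes features from (a) the L2-normalized
    bag-of-tokens of the source, (b) a one-hot of the previous token (or a
    begin marker), (c) the L2-normalized bag of the tokens generated so far
    (letting it learn to avoid repetition), and (d) a bias; projects them
    through a fixed seeded random matrix to ``embedding_dim`` dimensions;
    and applies a trainable vocab x embedding_dim weight matrix followed by
    a softmax.  The model is deliberately weak at syntax, but it is
    differentiable in closed form, fast, and expressive enough to shift its
    output distribution toward high-reward word choices, which is all the
    trainer's contracts require.
    """

    def __init__(
        self,
        vocab: Sequence[str],
        embedding_dim: int = 32,
        seed: int = 0,
        eos_token: str = EOS_TOKEN,
    ) -> None:
        vocab = tuple(vocab)
        if len(vocab) < 2:
            raise ValueError("vocabulary must contain at least 2 tokens")
        if len(set(vocab)) != len(vocab):
            raise ValueError("vocabulary tokens must be unique")
        if eos_token not in vocab:
            raise ValueError(f"end token {eos_token!r} missing from vocabulary")
        self.vocab = vocab
        self.eos_token = eos_token
        self.eos_id = vocab.index(eos_token)
        self.embedding_dim = int(embedding_dim)
        self.seed = int(seed)
        v = len(vocab)
        n_features = 3 * v + 2  # source bag | prev one-hot | BOS | prefix bag | bias
        rng = np.random.default_rng(seed)
        self._projection = rng.normal(0.0, 1.0, (embedding_dim, n_features))
        self.weights = rng.normal(0.0, 0.05 / math.sqrt(embedding_dim), (v, embedding_dim))
        self._index = {tok: i for i, tok in enumerate(vocab)}
        self._memo_source: tuple[int, ...] | None = None
        self._memo_base: np.ndarray | None = None

    # -- parameter access -------------------------------------------------
    def get_params(self) -> np.ndarray:
        return self.weights.ravel().copy()

    def set_params(self, params: np.ndarray) -> None:
        self.weights = np.asarray(params, dtype=float).reshape(self.weights.shape).copy()

    # -- token/text plumbing ----------------------------------------------
    def encode(self, tokens: Sequence[str]) -> tuple[int, ...]:
        try:
            return tuple(self._index[t] for t in tokens)
        except KeyError as exc:
            raise ValueError(f"token {exc.args[0]!r} outside vocabulary") from None

    def detokenize(self, tokens: Sequence[int]) -> str:
        return " ".join(
            self.vocab[t] for t in tokens if t != self.eos_id
        )

    def _check_ids(self, ids: Sequence[int]) -> None:
        v = len(self.vocab)
        for t in ids:
            if not 0 <= t < v:
                raise ValueError(f"token id {t} outside vocabulary of size {v}")

    # -- forward -----------------------------------------------------------
    def _source_base(self, source: tuple[int, ...]) -> np.ndarray:
        if source == self._memo_source and self._memo_base is not None:
            return self._memo_base
        v = len(self.vocab)
        bag = np.zeros(v)
        for t in source:
            bag[t] += 1.0
        norm = np.linalg.norm(bag)
        if norm > 0:
            bag /= norm
        base = self._projection[:, :v] @ bag + self._projection[:, -1]
        self._memo_source = source
        self._memo_base = base
        return base

    def _prev_column(self, prev: int | None) -> np.ndarray:
        v = len(self.vocab)
        col = 2 * v if prev is None else v + prev
        return self._projection[:, col]

    def _prefix_feature(self, prefix: Sequence[int]) -> np.ndarray:
        """Projected L2-normalized bag of the already-generated tokens."""
        if not prefix:
            return np.zeros(self.embedding_dim)
        v = len(self.vocab)
        counts = np.bincount(prefix, minlength=v).astype(float)
        p_pref = self._projection[:, 2 * v + 1 : 3 * v + 1]
        return p_pref @ (counts / np.linalg.norm(counts))

    def _step_features(
        self, source: Sequence[int], tokens: Sequence[int]
    ) -> np.ndarray:
        """Feature matrix H (embedding_dim x T) for teacher-forced steps."""
        source = tuple(source)
        self._check_ids(source)
        self._check_ids(tokens)
        base = self._source_base(source)
        v = len(self.vocab)
        p_pref = self._projection[:, 2 * v + 1 : 3 * v + 1]
        n = len(tokens)
        prefix_part = np.zeros((self.embedding_dim, n))
        acc = np.zeros(self.embedding_dim)
        counts = np.zeros(v)
        sq_norm = 0.0
        for t in range(1, n):
            tok = tokens[t - 1]
            sq_norm += 2.0 * counts[tok] + 1.0
            counts[tok] += 1.0
            acc = acc + p_pref[:, tok]
            prefix_part[:, t] = acc / math.sqrt(sq_norm)
        cols = [2 * v] + [v + t for t in tokens[:-1]]
        return base[:, None] + self._projection[:, cols] + prefix_part

    @staticmethod
    def _log_softmax(logits: np.ndarray) -> np.ndarray:
        shifted = logits - logits.max(axis=0, keepdims=True)
        return shifted - np.log(np.exp(shifted).sum(axis=0, keepdims=True))

    def token_logprobs(
        self, source: Sequence[int], prefix: Sequence[int]
    ) -> np.ndarray:
        source = tuple(source)
        self._check_ids(source)
        self._check_ids(prefix)
        prev = prefix[-1] if prefix else None
        h = (
            self._source_base(source)
            + self._prev_column(prev)
            + self._prefix_feature(prefix)
        )
        return self._log_softmax(self.weights @ h)

    def sequence_logprobs(
        self, source: Sequence[int], tokens: Sequence[int]
    ) -> np.ndarray:
        """Per-token log p(y_t | y_<t, x) for a given token sequence."""
        if not tokens:
            return np.zeros(0)
        h = self._step_features(source, tokens)
        logp = self._log_softmax(self.weights @ h)
        return logp[list(tokens), range(len(tokens))]

    def sequence_logprob_grad(
        self, source: Sequence[int], tokens: Sequence[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-token log-probs and the flat gradient of their sum w.r.t. weights."""
        if not tokens:
            return np.zeros(0), np.zeros(self.weights.size)
        h = self._step_features(source, tokens)
        logp_all = self._log_softmax(self.weights @ h)
        probs = np.exp(logp_all)
        y = np.zeros_like(probs)
        y[list(tokens), range(len(tokens))] = 1.0
        grad = (y - probs) @ h.T
        logp = logp_all[list(tokens), range(len(tokens))]
        return logp, grad.ravel()


def make_toy_policy(
    vocab: Sequence[str],
    embedding_dim: int = 32,
    seed: int = 0,
    eos_token: str = EOS_TOKEN,
) -> ToyConditionalGenerator:
    """Construct the packaged toy policy over ``vocab`` (must include the end token)."""
    return ToyConditionalGenerator(vocab, embedding_dim=embedding_dim, seed=seed, eos_token=eos_token)


def vocab_from_texts(texts: Sequence[str], eos_token: str = EOS_TOKEN) -> tuple[str, ...]:
    """Sorted token vocabulary (words plus sentence punctuation) of a corpus."""
    import re

    token_re = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*|[.!?]")
    types: set[str] = set()
    for text in texts:
        types.update(token_re.findall(text.lower()))
    return tuple(sorted(types)) + (eos_token,)


def encode_corpus(
    pairs: Sequence,
    model: ToyConditionalGenerator,
    max_source_len: int = 80,
    max_target_len: int = 40,
) -> list[SequencePair]:
    """Tokenize paragraph pairs into :class:`SequencePair`s for the toy policy.

    Sources are truncated to ``max_source_len`` tokens, targets to
    ``max_target_len``; the end token is appended to every target so the
    policy can learn to stop.
    """
    import re

    token_re = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*|[.!?]")
    encoded = []
    for pair in pairs:
        src = model.encode(token_re.findall(pair.source.lower())[:max_source_len])
        tgt = model.encode(token_re.findall(pair.reference.lower())[: max_target_len - 1])
        encoded.append(SequencePair(src, tgt + (model.eos_id,)))
    return encoded


# -- losses ----------------------------------------------------------------


def mle_loss(
    model: ConditionalGenerator, pair: SequencePair, per_token: bool = False
) -> float:
    """Negative log-likelihood of the target sequence; >= 0.

    The loss is a sum over target positions; ``per_token=True`` reports the
    mean instead, which is comparable across sequence lengths.
    """
    logp = model.sequence_logprobs(pair.source_tokens, pair.target_tokens)
    total = float(-logp.sum())
    return total / len(pair.target_tokens) if per_token else total


def pg_loss(sampled: Rollout, baseline_reward: float) -> float:
    """REINFORCE loss with baseline: -(mean log p) * (reward - baseline).

    Minimizing it raises the probability of rollouts that beat the baseline
    and lowers the probability of rollouts that fall short.
    """
    if len(sampled.per_token_logprob) == 0:
        raise ValueError("rollout has no tokens")
    if sampled.reward is None:
        raise ValueError("rollout must be scored before computing pg_loss")
    mean_logp = float(np.mean(sampled.per_token_logprob))
    return -mean_logp * (sampled.reward - baseline_reward)


def scst_loss(pair: RolloutPair) -> float:
    """Self-critical loss: pg_loss with the greedy rollout's reward as baseline."""
    if (
        pair.sampled.reward_weights is not None
        and pair.greedy.reward_weights is not None
        and pair.sampled.reward_weights != pair.greedy.reward_weights
    ):
        raise ValueError("rollouts were scored with different reward weights")
    if pair.greedy.reward is None:
        raise ValueError("greedy rollout must be scored before computing scst_loss")
    return pg_loss(pair.sampled, baseline_reward=pair.greedy.reward)


def total_loss(lpg: float, lml: float, gamma: float) -> float:
    """Mixed objective gamma*Lpg + (1-gamma)*Lml."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return gamma * lpg + (1.0 - gamma) * lml


# -- decoding --------------------------------------------------------------


def greedy_decode(
    model: ConditionalGenerator, source: Sequence[int], max_len: int
) -> Rollout:
    """Argmax decoding until the end token or ``max_len``; ties -> lowest id."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tokens: list[int] = []
    logprobs: list[float] = []
    for _ in range(max_len):
        lp = model.token_logprobs(source, tokens)
        tok = int(np.argmax(lp))  # argmax returns the lowest index on ties
        tokens.append(tok)
        logprobs.append(float(lp[tok]))
        if tok == model.eos_id:
            break
    return Rollout(tuple(tokens), np.array(logprobs), mode="greedy")


def sample_decode(
    model: ConditionalGenerator, source: Sequence[int], max_len: int, seed: int
) -> Rollout:
    """Multinomial sampling at temperature 1; reproducible from ``seed``."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    rng = np.random.default_rng(seed)
    tokens: list[int] = []
    logprobs: list[float] = []
    for _ in range(max_len):
        lp = model.token_logprobs(source, tokens)
        probs = np.exp(lp)
        probs /= probs.sum()
        tok = int(rng.choice(len(probs), p=probs))
        tokens.append(tok)
        logprobs.append(float(lp[tok]))
        if tok == model.eos_id:
            break
    return Rollout(tuple(tokens), np.array(logprobs), mode="sampled", seed=seed)


def _rollout_seed(base_seed: int, epoch: int, index: int) -> int:
    return (base_seed * 2654435761 + epoch * 1000003 + index * 7919) % (2**31)


def _score_rollout(
    rollout: Rollout,
    model: ConditionalGenerator,
    pair: SequencePair,
    scorer: RewardScorer,
) -> Rollout:
    source_text = model.detokenize(pair.source_tokens)
    target_text = model.detokenize(pair.target_tokens)
    generated = model.detokenize(rollout.tokens)
    breakdown = scorer.score(source_text, target_text, generated)
    rollout.reward = breakdown.total
    rollout.reward_weights = scorer.weights.as_tuple()
    return rollout


@dataclass
class StepTrace:
    lml: float
    lpg: float
    sampled_reward: float
    greedy_reward: float


def train_step(
    model: ConditionalGenerator,
    batch: Sequence[SequencePair],
    scorer: RewardScorer,
    config: TrainingConfig,
    *,
    gamma: float | None = None,
    epoch: int = 0,
    batch_offset: int = 0,
) -> StepTrace:
    """One mixed-loss gradient step on a batch; returns the batch trace.

    Computes the MLE gradient, and when gamma > 0 also rolls out a greedy
    and a sampled sequence per pair, scores both with the reward function
    (target = the pair's reference, source = the pair's complex text),
    forms the SCST loss, mixes the two gradients with gamma, and applies
    one plain-SGD update.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    g = config.gamma if gamma is None else gamma
    if not 0.0 <= g <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")

    grad = np.zeros_like(model.get_params())
    lml_sum = 0.0
    lpg_sum = 0.0
    sampled_rewards: list[float] = []
    greedy_rewards: list[float] = []
    for i, pair in enumerate(batch):
        logp, grad_ml = model.sequence_logprob_grad(
            pair.source_tokens, pair.target_tokens
        )
        lml = float(-logp.sum())
        lml_sum += lml
        pair_grad = -(1.0 - g) * grad_ml

        lpg = 0.0
        if g > 0.0:
            greedy = greedy_decode(model, pair.source_tokens, config.max_decode_length)
            seed = _rollout_seed(config.seed, epoch, batch_offset + i)
            sampled = sample_decode(
                model, pair.source_tokens, config.max_decode_length, seed
            )
            _score_rollout(greedy, model, pair, scorer)
            _score_rollout(sampled, model, pair, scorer)
            rollout_pair = RolloutPair(sampled=sampled, greedy=greedy)
            lpg = scst_loss(rollout_pair)
            sampled_rewards.append(sampled.reward)
            greedy_rewards.append(greedy.reward)
            advantage = rollout_pair.advantage
            if advantage != 0.0:
                _, grad_sampled = model.sequence_logprob_grad(
                    pair.source_tokens, sampled.tokens
                )
                pair_grad += -g * (advantage / len(sampled.tokens)) * grad_sampled
        lpg_sum += lpg

        loss = total_loss(lpg, lml, g)
        if not math.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}, pair {batch_offset + i}: "
                f"lml={lml}, lpg={lpg}, gamma={g}"
            )
        grad += pair_grad

    grad /= len(batch)
    if config.learning_rate > 0:
        model.set_params(model.get_params() - config.learning_rate * grad)

    n = len(batch)
    return StepTrace(
        lml=lml_sum / n,
        lpg=lpg_sum / n,
        sampled_reward=float(np.mean(sampled_rewards)) if sampled_rewards else math.nan,
        greedy_reward=float(np.mean(greedy_rewards)) if greedy_rewards else math.nan,
    )


def evaluate_policy(
    model: ConditionalGenerator,
    corpus: Sequence[SequencePair],
    scorer: RewardScorer,
    max_len: int,
) -> tuple[float, float, float, float]:
    """Mean greedy-decode reward components (cosine, flesch, lexical, total)."""
    comps = np.zeros(4)
    for pair in corpus:
        rollout = greedy_decode(model, pair.source_tokens, max_len)
        breakdown = scorer.score(
            model.detokenize(pair.source_tokens),
            model.detokenize(pair.target_tokens),
            model.detokenize(rollout.tokens),
        )
        comps += (
            breakdown.r_cosine,
            breakdown.r_flesch,
            breakdown.r_lexical,
            breakdown.total,
        )
    comps /= len(corpus)
    return tuple(comps)  # type: ignore[return-value]


def train(
    model: ConditionalGenerator,
    corpus: Sequence[SequencePair],
    scorer: RewardScorer,
    config: TrainingConfig,
) -> TrainingTrace:
    """Two-phase schedule: ``mle_epochs`` of pure MLE, then mixed-loss RL epochs.

    Fully reproducible from ``config.seed``: the epoch shuffles and every
    sampled rollout derive their randomness from it.  The returned trace
    holds one record per epoch with the mean losses and the mean greedy
    reward components over the corpus.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    trace = TrainingTrace()
    rng = np.random.default_rng(config.seed)
    for epoch in range(config.epochs):
        in_rl_phase = epoch >= config.mle_epochs
        gamma = config.gamma if in_rl_phase else 0.0
        order = rng.permutation(len(corpus))
        lml_sum = lpg_sum = 0.0
        sampled_sum = 0.0
        sampled_n = 0
        n_batches = 0
        for start in range(0, len(corpus), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [corpus[i] for i in idx]
            step = train_step(
                model,
                batch,
                scorer,
                config,
                gamma=gamma,
                epoch=epoch,
                batch_offset=start,
            )
            lml_sum += step.lml
            lpg_sum += step.lpg
            if not math.isnan(step.sampled_reward):
                sampled_sum += step.sampled_reward * len(batch)
                sampled_n += len(batch)
            n_batches += 1
        r_cos, r_fk, r_lex, r_total = evaluate_policy(
            model, corpus, scorer, config.max_decode_length
        )
        trace.append(
            EpochRecord(
                epoch=epoch,
                phase="rl" if in_rl_phase else "mle",
                lml=lml_sum / n_batches,
                lpg=lpg_sum / n_batches,
                r_cosine=r_cos,
                r_flesch=r_fk,
                r_lexical=r_lex,
                reward_total=r_total,
                sampled_reward=sampled_sum / sampled_n if sampled_n else math.nan,
            )
        )
    return trace


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(model: ToyConditionalGenerator, path: str | Path) -> None:
    """Write the toy policy as a text file: one JSON header line, then parameters."""
    header = {
        "format": "simplerl-toy-policy",
        "version": 1,
        "vocab": list(model.vocab),
        "eos_token": model.eos_token,
        "embedding_dim": model.embedding_dim,
        "seed": model.seed,
    }
    lines = [json.dumps(header)]
    lines.extend(f"{value:.17g}" for value in model.get_params())
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_checkpoint(path: str | Path) -> ToyConditionalGenerator:
    """Rebuild a toy policy from :func:`save_checkpoint` output."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    header = json.loads(text[0])
    if header.get("format") != "simplerl-toy-policy":
        raise ValueError(f"{path} is not a simplerl toy-policy checkpoint")
    model = ToyConditionalGenerator(
        header["vocab"],
        embedding_dim=header["embedding_dim"],
        seed=header["seed"],
        eos_token=header["eos_token"],
    )
    params = np.array([float(line) for line in text[1:] if line.strip()])
    model.set_params(params)
    return model
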