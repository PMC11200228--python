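"""Policy-gradient fine-tuning of the Agent against the frozen Prior.

Four per-epoch update algorithms share one loss. For a sequence A with
reward S(A) in [0,1], the augmented log-likelihood is

    log P_aug(A) = log P_prior(A) + sigma * S(A)

and the update regresses the Agent onto it by minimizing the batch mean of

    (log P_aug(A) - log P_agent(A))^2

("difference between agent and prior", DAP, squared loss). The Prior term
anchors the Agent to syntactically valid, chemically reasonable SMILES while
sigma scales how aggressively reward bends the policy.

Algorithms:

* ``reinvent_epoch`` — the classic baseline: one gradient step per epoch on
  the sampled batch plus a small replayed subset of the buffer.
* ``ahc_epoch`` — augmented hill climbing: same, but only the top-k fraction
  of the batch (by reward) contributes to the gradient.
* ``bar_epoch`` — best-agent reminder: a convex combination of the loss on
  the current Agent's batch and on a batch sampled from the best Agent seen.
* ``augmented_memory_epoch`` — scores the batch once, then performs N
  gradient steps, each on freshly randomized SMILES of the batch and of the
  *entire* replay buffer paired with their stored rewards. Oracle cost per
  epoch is identical to the baseline regardless of N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import chemio
from .memory import (
    DiversityFilter,
    ReplayBuffer,
    ScoredMolecule,
    buffer_sample,
    df_apply,
    selective_memory_purge,
)
from .objective import ObjectiveFunction, OracleLedger, score_batch
from .seqmodel import Adam, PolicyNetwork, UnknownTokenError, sample_batch, sequence_nll

ALGORITHMS = ("reinvent", "ahc", "bar", "augmented_memory")


@dataclass
class RLConfig:
    """Hyperparameters of the RL fine-tuning loop.

    Defaults follow the REINVENT convention where the method leaves them
    open: sigma 128, batch 64, lr 1e-4, two augmentation rounds, replay
    subset 10, buffer capacity 100.
    """

    sigma: float = 128.0
    batch_size: int = 64
    learning_rate: float = 1e-4
    augmentation_rounds: int = 2
    algorithm: str = "augmented_memory"
    ahc_topk_fraction: float = 0.5
    bar_alpha: float = 0.5
    replay_sample_size: int = 10
    buffer_capacity: int = 100
    max_length: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0.0 < self.ahc_topk_fraction <= 1.0):
            raise ValueError("ahc_topk_fraction must be in (0, 1]")
        if not (0.0 <= self.bar_alpha <= 1.0):
            raise ValueError("bar_alpha must be in [0, 1]")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.batch_size < 1 or self.augmentation_rounds < 1:
            raise ValueError("batch_size and augmentation_rounds must be >= 1")


@dataclass
class EpochStats:
    epoch: int
    oracle_calls: int
    mean_reward: float
    max_reward: float
    valid_fraction: float
    buffer_size: int
    buffer_mean_reward: float
    loss: float


@dataclass
class TrainingState:
    """Everything one fine-tuning run owns. The Prior is never updated."""

    config: RLConfig
    prior: PolicyNetwork
    agent: PolicyNetwork
    optimizer: Adam
    ledger: OracleLedger
    buffer: ReplayBuffer
    df: DiversityFilter | None = None
    selective_purge: bool = False
    best_agent: PolicyNetwork | None = None
    best_mean_reward: float = -math.inf
    epoch: int = 0
    last_stats: EpochStats | None = None
    rng_sample: np.random.Generator = field(default=None)  # type: ignore[assignment]
    rng_augment: np.random.Generator = field(default=None)  # type: ignore[assignment]
    rng_replay: np.random.Generator = field(default=None)  # type: ignore[assignment]

    @classmethod
    def create(
        cls,
        prior: PolicyNetwork,
        config: RLConfig,
        df: DiversityFilter | None = None,
        selective_purge: bool = False,
        ledger: OracleLedger | None = None,
    ) -> "TrainingState":
        agent = prior.copy()
        # one seed fans out deterministically to every randomness source
        streams = np.random.SeedSequence(config.seed).spawn(3)
        state = cls(
            config=config,
            prior=prior,
            agent=agent,
            optimizer=Adam(agent.params, lr=config.learning_rate),
            ledger=ledger if ledger is not None else OracleLedger(),
            buffer=ReplayBuffer(capacity=config.buffer_capacity),
            df=df,
            selective_purge=selective_purge,
            rng_sample=np.random.default_rng(streams[0]),
            rng_augment=np.random.default_rng(streams[1]),
            rng_replay=np.random.default_rng(streams[2]),
        )
        if config.algorithm == "bar":
            state.best_agent = agent.copy()
        return state

    @property
    def vocab(self):
        return self.prior.vocab


# ---------------------------------------------------------------------------
# Losses


def augmented_log_likelihood(prior_loglik, reward, sigma: float):
    """log P_aug = log P_prior + sigma * S(A); elementwise on arrays."""
    return np.asarray(prior_loglik) + sigma * np.asarray(reward)


def dap_loss(agent_loglik, augmented_loglik) -> float:
    """Batch mean of the squared difference between augmented and agent log-likelihoods."""
    agent_loglik = np.asarray(agent_loglik, dtype=float)
    augmented_loglik = np.asarray(augmented_loglik, dtype=float)
    if agent_loglik.shape != augmented_loglik.shape:
        raise ValueError("agent and augmented log-likelihood lists differ in length")
    return float(np.mean((augmented_loglik - agent_loglik) ** 2))


def _dap_grads(
    agent: PolicyNetwork,
    prior: PolicyNetwork,
    smiles: Sequence[str],
    rewards: Sequence[float],
    sigma: float,
):
    """Loss and parameter gradients of one DAP step on the given strings.

    Likelihoods are computed on the strings exactly as passed — for augmented
    representations both the Prior and Agent terms are re-evaluated on the
    augmented string, which is what makes each augmentation round carry new
    gradient information rather than repeating a constant target.
    """
    vocab = agent.vocab
    seqs = [vocab.encode(s) for s in smiles]
    prior_nll, _ = prior.sequence_nll_batch(seqs)
    agent_nll, extras = agent.sequence_nll_batch(seqs, keep_cache=True)
    agent_ll = -agent_nll
    aug_ll = augmented_log_likelihood(-prior_nll, rewards, sigma)
    diff = aug_ll - agent_ll
    loss = float(np.mean(diff**2))
    B = len(seqs)
    # dloss/d(agent_ll_i) = -2 diff_i / B ; d(agent_ll)/d(logits) = onehot - softmax
    dll = -2.0 * diff / B
    probs = np.exp(extras["logp"])
    dlogits = probs * (-dll)[:, None, None]
    np.put_along_axis(
        dlogits,
        extras["targets"][:, :, None],
        np.take_along_axis(dlogits, extras["targets"][:, :, None], axis=2) + dll[:, None, None],
        axis=2,
    )
    dlogits *= extras["mask"][:, :, None]
    grads = agent.backward(dlogits.astype(agent.dtype), extras["cache"])
    return loss, grads


def dap_step(state: TrainingState, smiles: Sequence[str], rewards: Sequence[float]) -> float:
    """One optimizer step of the DAP loss on (smiles, rewards)."""
    loss, grads = _dap_grads(state.agent, state.prior, smiles, rewards, state.config.sigma)
    state.optimizer.step(state.agent.params, grads)
    return loss


# ---------------------------------------------------------------------------
# Shared epoch plumbing


def _sample_and_score(
    state: TrainingState, objective: ObjectiveFunction, model: PolicyNetwork | None = None
):
    model = model if model is not None else state.agent
    seqs = sample_batch(
        model, state.config.batch_size, max_length=state.config.max_length, rng=state.rng_sample
    )
    smiles = [state.vocab.decode(s.token_ids) for s in seqs]
    scored = score_batch(objective, smiles, state.ledger)
    return smiles, scored


def _encodable(vocab, smiles: str) -> bool:
    try:
        vocab.encode(smiles)
        return True
    except UnknownTokenError:
        return False


def _training_strings(raw: Sequence[str], scored: Sequence[ScoredMolecule], vocab):
    """Canonical SMILES for valid samples, the raw sampled string otherwise.

    Zero-reward and invalid molecules stay in the gradient batch (their
    augmented target is just the prior likelihood); only the buffer excludes
    them. A canonical form that uses a token outside the vocabulary (e.g. a
    bracket atom the corpus never produced) falls back to the raw string,
    which by construction encodes.
    """
    strings, rewards = [], []
    for r, m in zip(raw, scored):
        s = m.canonical_smiles if m.valid and _encodable(vocab, m.canonical_smiles) else r
        strings.append(s)
        rewards.append(m.reward)
    return strings, rewards


def _safe_randomize(smiles: str, vocab, rng: np.random.Generator) -> str:
    """Randomized SMILES that is guaranteed to re-encode under ``vocab``.

    Falls back to the input string when the randomized writing uses a token
    outside the vocabulary (rare; e.g. an unusual ring-closure digit).
    """
    out = chemio.randomize_smiles(smiles, rng)
    try:
        vocab.encode(out)
        return out
    except UnknownTokenError:
        return smiles


def _finish_epoch(state: TrainingState, scored: Sequence[ScoredMolecule], loss: float) -> TrainingState:
    rewards = [m.reward for m in scored]
    buf_rewards = [m.reward for m in state.buffer]
    state.epoch += 1
    state.last_stats = EpochStats(
        epoch=state.epoch,
        oracle_calls=state.ledger.call_count,
        mean_reward=float(np.mean(rewards)) if rewards else 0.0,
        max_reward=float(np.max(rewards)) if rewards else 0.0,
        valid_fraction=float(np.mean([m.valid for m in scored])) if scored else 0.0,
        buffer_size=len(state.buffer),
        buffer_mean_reward=float(np.mean(buf_rewards)) if buf_rewards else 0.0,
        loss=loss,
    )
    return state


# ---------------------------------------------------------------------------
# Epoch algorithms


def reinvent_epoch(state: TrainingState, objective: ObjectiveFunction) -> TrainingState:
    """Baseline: one DAP step on the sampled batch plus a replayed buffer subset."""
    raw, scored = _sample_and_score(state, objective)
    if state.df is not None:
        scored = df_apply(state.df, scored)
    state.buffer.update(scored)
    replay = buffer_sample(state.buffer, state.config.replay_sample_size, state.rng_replay)
    replay = [m for m in replay if _encodable(state.vocab, m.canonical_smiles)]
    strings, rewards = _training_strings(raw, scored, state.vocab)
    strings += [m.canonical_smiles for m in replay]
    rewards += [m.reward for m in replay]
    loss = dap_step(state, strings, rewards)
    return _finish_epoch(state, scored, loss)


def ahc_epoch(state: TrainingState, objective: ObjectiveFunction) -> TrainingState:
    """Augmented hill climbing: gradient uses only the top-k fraction of the batch."""
    raw, scored = _sample_and_score(state, objective)
    if state.df is not None:
        scored = df_apply(state.df, scored)
    state.buffer.update(scored)
    strings, rewards = _training_strings(raw, scored, state.vocab)
    k = math.ceil(state.config.batch_size * state.config.ahc_topk_fraction)
    order = np.argsort(-np.asarray(rewards), kind="stable")[:k]  # ties: batch order
    strings = [strings[i] for i in order]
    rewards = [rewards[i] for i in order]
    replay = buffer_sample(state.buffer, state.config.replay_sample_size, state.rng_replay)
    replay = [m for m in replay if _encodable(state.vocab, m.canonical_smiles)]
    strings += [m.canonical_smiles for m in replay]
    rewards += [m.reward for m in replay]
    loss = dap_step(state, strings, rewards)
    return _finish_epoch(state, scored, loss)


def bar_epoch(state: TrainingState, objective: ObjectiveFunction) -> TrainingState:
    """Best-agent reminder: (1-alpha) * current-batch loss + alpha * best-agent-batch loss.

    The best-agent batch is oracle-scored like any other (so a BAR epoch can
    charge up to twice the batch size). The best agent is refreshed whenever
    the current batch's mean reward beats the best mean seen so far.
    """
    if state.best_agent is None:
        state.best_agent = state.agent.copy()
    alpha = state.config.bar_alpha
    cfg = state.config
    raw, scored = _sample_and_score(state, objective)
    if state.df is not None:
        scored = df_apply(state.df, scored)
    state.buffer.update(scored)
    strings, rewards = _training_strings(raw, scored, state.vocab)
    if cfg.replay_sample_size > 0:
        replay = buffer_sample(state.buffer, cfg.replay_sample_size, state.rng_replay)
        replay = [m for m in replay if _encodable(state.vocab, m.canonical_smiles)]
        strings += [m.canonical_smiles for m in replay]
        rewards += [m.reward for m in replay]

    total_loss = 0.0
    grads_sum = None
    if alpha < 1.0:
        loss_cur, grads_cur = _dap_grads(state.agent, state.prior, strings, rewards, cfg.sigma)
        total_loss += (1 - alpha) * loss_cur
        grads_sum = {k: (1 - alpha) * v for k, v in grads_cur.items()}
    if alpha > 0.0:
        raw_b, scored_b = _sample_and_score(state, objective, model=state.best_agent)
        strings_b, rewards_b = _training_strings(raw_b, scored_b, state.vocab)
        loss_best, grads_best = _dap_grads(state.agent, state.prior, strings_b, rewards_b, cfg.sigma)
        total_loss += alpha * loss_best
        if grads_sum is None:
            grads_sum = {k: alpha * v for k, v in grads_best.items()}
        else:
            for k in grads_sum:
                grads_sum[k] += alpha * grads_best[k]
    state.optimizer.step(state.agent.params, grads_sum)

    mean_cur = float(np.mean([m.reward for m in scored])) if scored else 0.0
    if mean_cur > state.best_mean_reward:
        state.best_mean_reward = mean_cur
        state.best_agent = state.agent.copy()
    return _finish_epoch(state, scored, total_loss)


def augmented_memory_epoch(state: TrainingState, objective: ObjectiveFunction) -> TrainingState:
    """Score once, then N augmented updates over the batch plus the whole buffer.

    (1) sample a batch; (2) score it — the only oracle charge of the epoch;
    (3) apply the diversity filter, purge the buffer of penalized scaffolds
    (when selective purge is on), merge the batch into the buffer; (4) N
    times: randomize every SMILES in the batch and in the entire buffer,
    recompute Prior and Agent likelihoods on the augmented strings, pair them
    with the stored rewards, and take one gradient step. N gradient steps,
    zero additional oracle calls.
    """
    cfg = state.config
    raw, scored = _sample_and_score(state, objective)
    if state.df is not None:
        scored = df_apply(state.df, scored)
    state.buffer.update(scored)
    if state.df is not None and state.selective_purge:
        # purging after insertion also evicts entries whose bucket filled
        # during this very batch, so every augmentation round below replays
        # only scaffolds that still earn reward
        selective_memory_purge(state.buffer, state.df)
    base_strings, base_rewards = _training_strings(raw, scored, state.vocab)
    valid_mask = [m.valid for m in scored]
    loss = 0.0
    for _ in range(cfg.augmentation_rounds):
        strings = [
            _safe_randomize(s, state.vocab, state.rng_augment) if ok else s
            for s, ok in zip(base_strings, valid_mask)
        ]
        rewards = list(base_rewards)
        for entry in state.buffer:
            if not _encodable(state.vocab, entry.canonical_smiles):
                continue
            strings.append(_safe_randomize(entry.canonical_smiles, state.vocab, state.rng_augment))
            rewards.append(entry.reward)
        loss = dap_step(state, strings, rewards)
    return _finish_epoch(state, scored, loss)


_EPOCH_FNS = {
    "reinvent": reinvent_epoch,
    "ahc": ahc_epoch,
    "bar": bar_epoch,
    "augmented_memory": augmented_memory_epoch,
}


def run_epoch(state: TrainingState, objective: ObjectiveFunction) -> TrainingState:
    """Dispatch one epoch of the configured algorithm."""
    return _EPOCH_FNS[state.config.algorithm](state, objective)


def nll_trace(agent_snapshots: Sequence[PolicyNetwork], target: str) -> list[float]:
    """NLL of the canonical target molecule under each Agent snapshot.

    Tracks how strongly successive policies concentrate on (or move away
    from) one molecule across a generative run.
    """
    canonical = chemio.canonicalize(target)
    if not canonical.valid:
        raise ValueError(f"unparseable target SMILES: {target!r}")
    return [sequence_nll(m, canonical.canonical_smiles) for m in agent_snapshots]
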