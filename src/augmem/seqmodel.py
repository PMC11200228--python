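"""SMILES vocabulary, tokenizer, and the autoregressive LSTM policy network.

The policy pi_theta is a token-level language model over SMILES: an embedding
layer, one or more LSTM layers, and a linear projection to vocabulary logits.
Both the frozen Prior and the trainable Agent are instances of
:class:`PolicyNetwork`. The network is implemented directly in NumPy
(forward, sampling, and full backpropagation through time), which keeps the
package dependency-light and makes every gradient step exactly reproducible
under a seed.

Sequence conventions: generation begins after an implicit start token and
terminates with the end token or at ``max_length``. The negative
log-likelihood (NLL) of a sequence is the sum over steps, through the end
token, of -log P(a_t | s_t; theta) — the Markov factorization of the
sequence likelihood used by the RL losses.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PAD, START, END = "<pad>", "^", "$"

# Multi-character lexical units that must stay single tokens: bracket atoms,
# two-letter halogens, and %NN ring-closure labels.
_TOKEN_RE = re.compile(r"(\[[^\]]*\]|%\d{2}|Cl|Br|.)")

# Structural SMILES characters always present in the vocabulary, so that a
# randomized rewriting of an encodable molecule (which may interleave ring
# closures differently or introduce explicit bonds) remains encodable.
_BASE_TOKENS = list("123456789()=-#/\\")


class UnknownTokenError(KeyError):
    """A lexical unit of a SMILES string is not in the vocabulary."""


def split_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into lexical units (no vocabulary check)."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:  # pragma: no cover - regex is total
        raise ValueError(f"cannot tokenize {smiles!r}")
    return tokens


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> index map with pad/start/end specials at 0/1/2."""

    tokens: tuple[str, ...]
    index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    @classmethod
    def from_corpus(cls, corpus: Iterable[str]) -> "Vocabulary":
        seen: set[str] = set(_BASE_TOKENS)
        for smi in corpus:
            seen.update(split_smiles(smi))
        ordered = [PAD, START, END] + sorted(seen)
        return cls(tokens=tuple(ordered))

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def pad(self) -> int:
        return self.index[PAD]

    @property
    def start(self) -> int:
        return self.index[START]

    @property
    def end(self) -> int:
        return self.index[END]

    def encode(self, smiles: str) -> np.ndarray:
        """Token indices of ``smiles`` (no start/end). Raises on unknown units."""
        ids = []
        for tok in split_smiles(smiles):
            if tok not in self.index:
                raise UnknownTokenError(f"token {tok!r} (in {smiles!r}) not in vocabulary")
            ids.append(self.index[tok])
        return np.asarray(ids, dtype=np.int64)

    def decode(self, ids: Sequence[int]) -> str:
        out = []
        for i in ids:
            tok = self.tokens[int(i)]
            if tok == END:
                break
            if tok in (PAD, START):
                continue
            out.append(tok)
        return "".join(out)

    def to_dict(self) -> dict:
        return {"tokens": list(self.tokens)}

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(tokens=tuple(d["tokens"]))


@dataclass
class TokenSequence:
    """A tokenized SMILES with its NLL under the policy that produced it."""

    token_ids: np.ndarray  # sequence tokens, including terminal END if emitted
    nll: float | None = None
    per_token_nll: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.token_ids)


def tokenize(smiles: str, vocab: Vocabulary) -> TokenSequence:
    """Encode a SMILES string against ``vocab``; round-trips exactly."""
    return TokenSequence(token_ids=vocab.encode(smiles))


# ---------------------------------------------------------------------------
# Network


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


class PolicyNetwork:
    """Autoregressive LSTM language model over a token vocabulary.

    Parameters
    ----------
    vocab:
        Vocabulary bound to the model (embedded in checkpoints). May be None
        for low-level use, in which case ``vocab_size`` must be given and
        start/end indices are passed explicitly to :meth:`sample`.
    embedding_dim, hidden_size, num_layers:
        Architecture. Defaults follow the REINVENT convention (embedding 128,
        3 LSTM layers of 512 units); desk-scale runs use much smaller values.
    """

    def __init__(
        self,
        vocab: Vocabulary | None = None,
        vocab_size: int | None = None,
        embedding_dim: int = 128,
        hidden_size: int = 512,
        num_layers: int = 3,
        seed: int = 0,
        dtype=np.float32,
    ):
        if vocab is None and vocab_size is None:
            raise ValueError("either vocab or vocab_size is required")
        self.vocab = vocab
        self.vocab_size = len(vocab) if vocab is not None else int(vocab_size)
        self.embedding_dim = embedding_dim
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        V, E, H = self.vocab_size, embedding_dim, hidden_size
        self.params["emb"] = (rng.standard_normal((V, E)) * 0.1).astype(self.dtype)
        for layer in range(num_layers):
            d_in = E if layer == 0 else H
            scale = 1.0 / np.sqrt(d_in + H)
            self.params[f"Wx{layer}"] = (rng.standard_normal((d_in, 4 * H)) * scale).astype(self.dtype)
            self.params[f"Wh{layer}"] = (rng.standard_normal((H, 4 * H)) * scale).astype(self.dtype)
            b = np.zeros(4 * H, dtype=self.dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b{layer}"] = b
        self.params["Wo"] = (rng.standard_normal((H, V)) * (1.0 / np.sqrt(H))).astype(self.dtype)
        self.params["bo"] = np.zeros(V, dtype=self.dtype)

    # -- utilities ---------------------------------------------------------

    def copy(self) -> "PolicyNetwork":
        clone = object.__new__(PolicyNetwork)
        clone.__dict__.update(
            vocab=self.vocab,
            vocab_size=self.vocab_size,
            embedding_dim=self.embedding_dim,
            hidden_size=self.hidden_size,
            num_layers=self.num_layers,
            dtype=self.dtype,
        )
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def param_fingerprint(self) -> bytes:
        """Byte digest of all parameters (used to assert the Prior is frozen)."""
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.digest()

    # -- forward / backward ------------------------------------------------

    def _step(self, layer: int, x, h_prev, c_prev):
        H = self.hidden_size
        z = x @ self.params[f"Wx{layer}"] + h_prev @ self.params[f"Wh{layer}"] + self.params[f"b{layer}"]
        z[:, : 2 * H] = _sigmoid(z[:, : 2 * H])
        z[:, 2 * H : 3 * H] = np.tanh(z[:, 2 * H : 3 * H])
        z[:, 3 * H :] = _sigmoid(z[:, 3 * H :])
        i, f = z[:, :H], z[:, H : 2 * H]
        g, o = z[:, 2 * H : 3 * H], z[:, 3 * H :]
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        return h, c

    def forward(self, inputs: np.ndarray, keep_cache: bool = True):
        """Run the model over a (B, T) int array of input token indices.

        Returns ``(logits, cache)`` where logits has shape (B, T, V). With
        ``keep_cache=False`` the cache is None (cheaper, inference only).
        """
        B, T = inputs.shape
        H, L = self.hidden_size, self.num_layers
        x = self.params["emb"][inputs]  # (B, T, E)
        layer_in = x
        hs = [np.zeros((B, H), dtype=self.dtype) for _ in range(L)]
        cs = [np.zeros((B, H), dtype=self.dtype) for _ in range(L)]
        cache_layers = []
        for layer in range(L):
            # precompute the input contribution for all timesteps at once
            zx = layer_in.reshape(B * T, -1) @ self.params[f"Wx{layer}"]
            zx = zx.reshape(B, T, 4 * H)
            h_seq = np.empty((B, T, H), dtype=self.dtype)
            # time-major caches: contiguous (B, .) rows per step in backward
            act_seq = np.empty((T, B, 4 * H), dtype=self.dtype) if keep_cache else None
            tc_seq = np.empty((T, B, H), dtype=self.dtype) if keep_cache else None
            cprev_seq = np.empty((T, B, H), dtype=self.dtype) if keep_cache else None
            h, c = hs[layer], cs[layer]
            Wh = self.params[f"Wh{layer}"]
            b = self.params[f"b{layer}"]
            for t in range(T):
                z = zx[:, t] + h @ Wh + b
                z[:, : 2 * H] = _sigmoid(z[:, : 2 * H])  # input & forget gates
                z[:, 2 * H : 3 * H] = np.tanh(z[:, 2 * H : 3 * H])  # candidate
                z[:, 3 * H :] = _sigmoid(z[:, 3 * H :])  # output gate
                i, f = z[:, :H], z[:, H : 2 * H]
                g, o = z[:, 2 * H : 3 * H], z[:, 3 * H :]
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                if keep_cache:
                    act_seq[t] = z
                    tc_seq[t] = tc
                    cprev_seq[t] = c
                h, c = h_new, c_new
                h_seq[:, t] = h
            if keep_cache:
                cache_layers.append(
                    {"in": layer_in, "h": h_seq, "act": act_seq, "tc": tc_seq, "c_prev": cprev_seq}
                )
            layer_in = h_seq
        logits = layer_in.reshape(B * T, H) @ self.params["Wo"] + self.params["bo"]
        logits = logits.reshape(B, T, self.vocab_size)
        cache = {"inputs": inputs, "layers": cache_layers, "top": layer_in} if keep_cache else None
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Backpropagation through time given d(loss)/d(logits).

        ``dlogits`` must already be masked (zero at padded positions).
        Returns a gradient dict matching :attr:`params`.
        """
        inputs = cache["inputs"]
        B, T = inputs.shape
        H, L, V = self.hidden_size, self.num_layers, self.vocab_size
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        top = cache["top"]  # (B, T, H)
        grads["Wo"] = top.reshape(B * T, H).T @ dlogits.reshape(B * T, V)
        grads["bo"] = dlogits.sum(axis=(0, 1))
        d_layer_out = (dlogits.reshape(B * T, V) @ self.params["Wo"].T).reshape(B, T, H)

        for layer in range(L - 1, -1, -1):
            lc = cache["layers"][layer]
            layer_in, h_seq = lc["in"], lc["h"]
            act_seq, tc_seq, cprev_seq = lc["act"], lc["tc"], lc["c_prev"]
            Wh = self.params[f"Wh{layer}"]
            dz_seq = np.empty((B, T, 4 * H), dtype=self.dtype)
            dz = np.empty((B, 4 * H), dtype=self.dtype)  # contiguous scratch
            dh_rec = np.zeros((B, H), dtype=self.dtype)
            dc_rec = np.zeros((B, H), dtype=self.dtype)
            for t in range(T - 1, -1, -1):
                act = act_seq[t]
                i, f = act[:, :H], act[:, H : 2 * H]
                g, o = act[:, 2 * H : 3 * H], act[:, 3 * H :]
                tc = tc_seq[t]
                dh = d_layer_out[:, t] + dh_rec
                do = dh * tc
                dc = dc_rec + dh * o * (1.0 - tc * tc)
                np.multiply(dc * g, i * (1 - i), out=dz[:, :H])
                np.multiply(dc * cprev_seq[t], f * (1 - f), out=dz[:, H : 2 * H])
                np.multiply(dc * i, 1 - g * g, out=dz[:, 2 * H : 3 * H])
                np.multiply(do, o * (1 - o), out=dz[:, 3 * H :])
                dz_seq[:, t] = dz
                dc_rec = dc * f
                if t > 0:
                    grads[f"Wh{layer}"] += h_seq[:, t - 1].T @ dz
                dh_rec = dz @ Wh.T
            flat_dz = dz_seq.reshape(B * T, 4 * H)
            grads[f"Wx{layer}"] = layer_in.reshape(B * T, -1).T @ flat_dz
            grads[f"b{layer}"] = flat_dz.sum(axis=0)
            d_layer_out = (flat_dz @ self.params[f"Wx{layer}"].T).reshape(B, T, -1)

        # d_layer_out is now the gradient wrt the embedding rows
        np.add.at(grads["emb"], inputs.reshape(-1), d_layer_out.reshape(B * T, -1))
        return grads

    # -- sampling and likelihoods -------------------------------------------

    def sample(
        self,
        batch_size: int,
        max_length: int = 256,
        rng: np.random.Generator | None = None,
        start_idx: int | None = None,
        end_idx: int | None = None,
    ) -> list[TokenSequence]:
        """Multinomial ancestral sampling of ``batch_size`` sequences.

        Each sequence terminates with the end token or at ``max_length``;
        the exact per-step NLL of the sampled tokens is accumulated on the
        fly. Deterministic given ``rng`` state.
        """
        if rng is None:
            rng = np.random.default_rng()
        if start_idx is None:
            start_idx = self.vocab.start if self.vocab is not None else 0
        if end_idx is None and self.vocab is not None:
            end_idx = self.vocab.end
        B, H, L = batch_size, self.hidden_size, self.num_layers
        hs = [np.zeros((B, H), dtype=self.dtype) for _ in range(L)]
        cs = [np.zeros((B, H), dtype=self.dtype) for _ in range(L)]
        x = np.full(B, start_idx, dtype=np.int64)
        alive = np.ones(B, dtype=bool)
        token_steps: list[np.ndarray] = []
        nll_steps: list[np.ndarray] = []
        lengths = np.zeros(B, dtype=np.int64)
        rows = np.arange(B)
        for _ in range(max_length):
            inp = self.params["emb"][x]
            for layer in range(L):
                hs[layer], cs[layer] = self._step(layer, inp, hs[layer], cs[layer])
                inp = hs[layer]
            logits = inp @ self.params["Wo"] + self.params["bo"]
            logp = _log_softmax(logits.astype(np.float64))
            probs = np.exp(logp)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(B)
            nxt = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
            token_steps.append(nxt)
            nll_steps.append(np.where(alive, -logp[rows, nxt], 0.0))
            lengths += alive
            if end_idx is not None:
                alive &= nxt != end_idx
            if not alive.any():
                break
            x = nxt
        token_mat = np.stack(token_steps, axis=1)  # (B, T)
        nll_mat = np.stack(nll_steps, axis=1)
        return [
            TokenSequence(
                token_ids=token_mat[bi, : lengths[bi]].astype(np.int64),
                nll=float(nll_mat[bi, : lengths[bi]].sum()),
                per_token_nll=nll_mat[bi, : lengths[bi]].copy(),
            )
            for bi in range(B)
        ]

    def _encode_training_batch(self, sequences: Sequence[np.ndarray], start_idx: int, end_idx: int, pad_idx: int):
        """Build (inputs, targets, mask) arrays from raw token-id sequences.

        Sequences must not already contain the end token; it is appended as
        the final prediction target.
        """
        B = len(sequences)
        T = max((len(s) for s in sequences), default=0) + 1
        inputs = np.full((B, T), pad_idx, dtype=np.int64)
        targets = np.full((B, T), pad_idx, dtype=np.int64)
        mask = np.zeros((B, T), dtype=self.dtype)
        for bi, seq in enumerate(sequences):
            n = len(seq)
            inputs[bi, 0] = start_idx
            inputs[bi, 1 : n + 1] = seq
            targets[bi, :n] = seq
            targets[bi, n] = end_idx
            mask[bi, : n + 1] = 1.0
        return inputs, targets, mask

    def sequence_nll_batch(self, sequences: Sequence[np.ndarray], keep_cache: bool = False):
        """Exact NLL of each token sequence (end token appended), batched.

        Returns ``(nll, extras)`` where extras carries the pieces a gradient
        step needs (logits, cache, targets, mask).
        """
        if self.vocab is None:
            raise ValueError("sequence_nll_batch requires a vocabulary-bound model")
        v = self.vocab
        seqs = [s[:-1] if len(s) and s[-1] == v.end else s for s in sequences]
        inputs, targets, mask = self._encode_training_batch(seqs, v.start, v.end, v.pad)
        logits, cache = self.forward(inputs, keep_cache=keep_cache)
        logp = _log_softmax(logits.astype(np.float64))
        tok_logp = np.take_along_axis(logp, targets[:, :, None], axis=2)[:, :, 0]
        nll = -(tok_logp * mask).sum(axis=1)
        extras = {"logits": logits, "cache": cache, "targets": targets, "mask": mask, "logp": logp}
        return nll, extras


def sequence_nll(model: PolicyNetwork, seq: TokenSequence | str) -> float:
    """NLL of one sequence (or SMILES string) under ``model``."""
    if isinstance(seq, str):
        seq = tokenize(seq, model.vocab)
    nll, _ = model.sequence_nll_batch([seq.token_ids])
    return float(nll[0])


def sample_batch(
    model: PolicyNetwork,
    batch_size: int,
    max_length: int = 256,
    rng: np.random.Generator | None = None,
) -> list[TokenSequence]:
    """Sample a batch of token sequences from a vocabulary-bound model."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    return model.sample(batch_size, max_length=max_length, rng=rng)


# ---------------------------------------------------------------------------
# Optimization


class Adam:
    """Plain Adam. State is kept per parameter key."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype, copy=False)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def mean_corpus_nll(model: PolicyNetwork, corpus: Sequence[str], batch_size: int = 128) -> float:
    total, n = 0.0, 0
    for i in range(0, len(corpus), batch_size):
        seqs = [model.vocab.encode(s) for s in corpus[i : i + batch_size]]
        nll, _ = model.sequence_nll_batch(seqs)
        total += float(nll.sum())
        n += len(seqs)
    return total / max(n, 1)


def train_prior(
    corpus: Sequence[str],
    epochs: int = 10,
    lr: float = 1e-3,
    rng: np.random.Generator | int | None = None,
    batch_size: int = 64,
    embedding_dim: int = 128,
    hidden_size: int = 512,
    num_layers: int = 3,
    vocab: Vocabulary | None = None,
    augment: bool = False,
    final_lr: float | None = None,
) -> PolicyNetwork:
    """Maximum-likelihood training of a Prior on a SMILES corpus.

    The loss is the batch-mean sequence NLL; the vocabulary is built from the
    corpus (plus structural base tokens) unless one is supplied. Deterministic
    given the seed/generator.

    With ``augment=True`` every molecule is re-written as a fresh randomized
    SMILES each epoch, so the model learns the molecule rather than one
    canonical spelling. A prior trained this way assigns comparable
    likelihood to all representations of a molecule — the property that
    augmentation-based fine-tuning relies on.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if vocab is None:
        vocab = Vocabulary.from_corpus(corpus)
    model_seed = int(rng.integers(2**31 - 1))
    model = PolicyNetwork(
        vocab=vocab,
        embedding_dim=embedding_dim,
        hidden_size=hidden_size,
        num_layers=num_layers,
        seed=model_seed,
    )
    encoded = [vocab.encode(s) for s in corpus]
    opt = Adam(model.params, lr=lr)
    for epoch in range(epochs):
        if final_lr is not None and epoch == int(epochs * 0.8):
            opt.lr = final_lr  # anneal for the final stretch
        if augment:
            from . import chemio  # local import: chemio does not depend on seqmodel

            encoded = []
            for s in corpus:
                written = chemio.randomize_smiles(s, rng)
                try:
                    encoded.append(vocab.encode(written))
                except UnknownTokenError:
                    encoded.append(vocab.encode(s))
        order = rng.permutation(len(encoded))
        for i in range(0, len(order), batch_size):
            batch = [encoded[j] for j in order[i : i + batch_size]]
            nll, extras = model.sequence_nll_batch(batch, keep_cache=True)
            logp = extras["logp"]
            probs = np.exp(logp)
            onehot_sub = np.take_along_axis(probs, extras["targets"][:, :, None], axis=2)
            dlogits = probs.copy()
            np.put_along_axis(
                dlogits, extras["targets"][:, :, None], onehot_sub - 1.0, axis=2
            )
            dlogits *= extras["mask"][:, :, None] / len(batch)
            grads = model.backward(dlogits.astype(model.dtype), extras["cache"])
            opt.step(model.params, grads)
    return model


# ---------------------------------------------------------------------------
# Checkpoints: single .npz with weights plus a JSON metadata entry carrying
# the architecture and the embedded vocabulary (format "augmem-policy-v1").

_CKPT_FORMAT = "augmem-policy-v1"


def save_policy(model: PolicyNetwork, path: str | Path) -> None:
    meta = {
        "format": _CKPT_FORMAT,
        "vocab": model.vocab.to_dict() if model.vocab is not None else None,
        "vocab_size": model.vocab_size,
        "embedding_dim": model.embedding_dim,
        "hidden_size": model.hidden_size,
        "num_layers": model.num_layers,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_policy(path: str | Path) -> PolicyNetwork:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format") != _CKPT_FORMAT:
            raise ValueError(f"{path}: not an {_CKPT_FORMAT} checkpoint")
        vocab = Vocabulary.from_dict(meta["vocab"]) if meta["vocab"] else None
        model = PolicyNetwork(
            vocab=vocab,
            vocab_size=meta["vocab_size"],
            embedding_dim=meta["embedding_dim"],
            hidden_size=meta["hidden_size"],
            num_layers=meta["num_layers"],
        )
        for k in model.params:
            model.params[k] = data[k]
    return model
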