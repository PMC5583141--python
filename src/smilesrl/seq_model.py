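"""Autoregressive GRU sequence model over SMILES tokens.

The model is the policy pi(a_t | s_t): at each step it consumes the previous
token (one-hot) and emits a distribution over the vocabulary. A *prior* is
obtained by maximum-likelihood training on a corpus; an *agent* is a copy of
a prior whose weights are later moved by policy gradients (see
:mod:`smilesrl.rl_agent`).

The network, backpropagation through time, and the Adam/SGD optimizers are
implemented directly on NumPy arrays. The single backward primitive computes
the gradient of a per-sequence-weighted sum of negative log-likelihoods,
which is the common shape of both the MLE cost and every policy-gradient
cost used downstream.

GRU step (gate order z, r, n; update-gate bias initialised positive so the
cell starts out carrying state, the GRU analogue of an LSTM forget bias):

    z = sigmoid(x Wx_z + h Wh_z + b_z)
    r = sigmoid(x Wx_r + h Wh_r + b_r)
    n = tanh(x Wx_n + r * (h Wh_n) + b_n)
    h' = z * h + (1 - z) * n
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .chem import EOS, GO, Vocabulary

DTYPE = np.float32


@dataclass
class TrainConfig:
    """Hyperparameters for maximum-likelihood (prior) training.

    Defaults follow the standard full-scale recipe: Adam (beta1=0.9, beta2=0.999,
    eps=1e-8), initial learning rate 1e-3 multiplied by (1 - 0.02) every
    100 steps, gradients value-clipped to [-3, 3], batches of 128 drawn
    with replacement.
    """

    batch_size: int = 128
    n_steps: int = 1000
    learning_rate: float = 1e-3
    lr_decay: float = 0.02
    lr_decay_every: int = 100
    grad_clip: tuple[float, float] = (-3.0, 3.0)
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        lo, hi = self.grad_clip
        if not lo < hi:
            raise ValueError("grad_clip lower bound must be below upper bound")


@dataclass
class Episode:
    """One sampled sequence: token indices (terminating at EOS unless
    truncated at max_length), the SMILES text, per-step log-probabilities
    and their sum."""

    indices: np.ndarray
    smiles: str
    step_log_probs: np.ndarray
    log_prob: float
    truncated: bool = False


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _log_softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def pad_batch(sequences: list[np.ndarray], go_index: int, eos_index: int):
    """Stack variable-length index sequences into (inputs, targets, mask).

    ``targets[b]`` is the sequence itself, EOS-padded; ``inputs[b]`` is GO
    followed by the sequence shifted right; ``mask`` is 1 on real steps and
    0 on padding, so padded steps contribute nothing to any likelihood.
    """
    B = len(sequences)
    T = max(len(s) for s in sequences)
    targets = np.full((B, T), eos_index, dtype=np.int64)
    mask = np.zeros((B, T), dtype=DTYPE)
    for b, s in enumerate(sequences):
        targets[b, : len(s)] = s
        mask[b, : len(s)] = 1.0
    inputs = np.empty_like(targets)
    inputs[:, 0] = go_index
    inputs[:, 1:] = targets[:, :-1]
    return inputs, targets, mask


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)


class _SGD:
    def __init__(self, params):
        pass

    def step(self, params, grads, lr):
        for k in params:
            params[k] -= (lr * grads[k]).astype(DTYPE)


class SmilesGRU:
    """GRU language model over a token vocabulary.

    Parameters
    ----------
    vocabulary : Vocabulary
        Token set the model emits; output layer width equals its size.
    n_layers, hidden_size : int
        Stacked GRU depth and width. Desk-scale default is 2 x 128; the
        full-scale recipe is 3 x 1024.
    update_gate_bias : float
        Initial bias of the update gate z (positive = carry state).
    max_length : int
        Hard cap on sampled episode length, in tokens.
    random_state : int
        Seed for weight initialisation and for sampling when no explicit
        generator is passed.
    """

    def __init__(self, vocabulary: Vocabulary, n_layers: int = 2,
                 hidden_size: int = 128, update_gate_bias: float = 5.0,
                 max_length: int = 140, random_state: int = 0):
        self.vocabulary = vocabulary
        self.n_layers = n_layers
        self.hidden_size = hidden_size
        self.update_gate_bias = update_gate_bias
        self.max_length = max_length
        self.random_state = random_state
        self.params_: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(random_state))
        self._rng = np.random.default_rng(random_state)

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self, deep=True):
        return {
            "vocabulary": self.vocabulary,
            "n_layers": self.n_layers,
            "hidden_size": self.hidden_size,
            "update_gate_bias": self.update_gate_bias,
            "max_length": self.max_length,
            "random_state": self.random_state,
        }

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- parameters --------------------------------------------------------
    def _init_params(self, rng):
        V, H, L = len(self.vocabulary), self.hidden_size, self.n_layers
        p = {}
        for l in range(L):
            in_dim = V if l == 0 else H
            k = 1.0 / np.sqrt(H)
            p[f"Wx{l}"] = rng.uniform(-k, k, (in_dim, 3 * H)).astype(DTYPE)
            p[f"Wh{l}"] = rng.uniform(-k, k, (H, 3 * H)).astype(DTYPE)
            b = np.zeros(3 * H, dtype=DTYPE)
            b[:H] = self.update_gate_bias
            p[f"b{l}"] = b
        k = 1.0 / np.sqrt(H)
        p["Wo"] = rng.uniform(-k, k, (H, V)).astype(DTYPE)
        p["bo"] = np.zeros(V, dtype=DTYPE)
        self.params_ = p

    def copy(self) -> "SmilesGRU":
        """Deep copy sharing no arrays (e.g. to spawn an agent from a prior)."""
        m = SmilesGRU(self.vocabulary, self.n_layers, self.hidden_size,
                      self.update_gate_bias, self.max_length, self.random_state)
        m.params_ = {k: v.copy() for k, v in self.params_.items()}
        return m

    # -- forward/backward --------------------------------------------------
    def _step(self, x_idx, h_list, cache=None):
        """One time step for a batch. x_idx: (B,) token indices.
        Returns log-probs (B, V) and updates h_list in place."""
        H = self.hidden_size
        p = self.params_
        inp_onehot_idx = x_idx
        x = None
        for l in range(self.n_layers):
            if l == 0:
                hx = p["Wx0"][inp_onehot_idx] + p["b0"]
            else:
                hx = x @ p[f"Wx{l}"] + p[f"b{l}"]
            hh = h_list[l] @ p[f"Wh{l}"]
            z = _sigmoid(hx[:, :H] + hh[:, :H])
            r = _sigmoid(hx[:, H:2 * H] + hh[:, H:2 * H])
            hhn = hh[:, 2 * H:]
            n = np.tanh(hx[:, 2 * H:] + r * hhn)
            h_new = z * h_list[l] + (1 - z) * n
            if cache is not None:
                cache.append((l, x_idx if l == 0 else x, h_list[l], z, r, n, hhn))
            h_list[l] = h_new
            x = h_new
        logits = x @ p["Wo"] + p["bo"]
        return _log_softmax(logits)

    @property
    def _dtype(self):
        return self.params_["Wo"].dtype

    def _forward(self, inputs, collect_cache=False):
        """Run the full batch. inputs: (B, T) indices. Returns per-step
        log-prob tensors (T, B, V), final hidden states, and caches.
        Computation runs in the dtype of the parameters."""
        B, T = inputs.shape
        H = self.hidden_size
        h_list = [np.zeros((B, H), dtype=self._dtype) for _ in range(self.n_layers)]
        log_probs = np.empty((T, B, len(self.vocabulary)), dtype=self._dtype)
        caches = [] if collect_cache else None
        hidden_trace = [] if collect_cache else None
        for t in range(T):
            step_cache = [] if collect_cache else None
            log_probs[t] = self._step(inputs[:, t], h_list, step_cache)
            if collect_cache:
                caches.append(step_cache)
                hidden_trace.append([h.copy() for h in h_list])
        return log_probs, h_list, caches, hidden_trace

    def nll(self, sequences: list[np.ndarray]) -> np.ndarray:
        """Per-sequence negative log-likelihood, in nats.

        Each sequence is an index array ending at EOS (as produced by
        ``Vocabulary.encode_smiles``); steps after a sequence's own end
        contribute zero.
        """
        for s in sequences:
            if len(s) > self.max_length:
                raise ValueError(
                    f"sequence of length {len(s)} exceeds max_length {self.max_length}")
        v = self.vocabulary
        inputs, targets, mask = pad_batch(sequences, v.go_index, v.eos_index)
        log_probs, _, _, _ = self._forward(inputs)
        B, T = inputs.shape
        tok_ll = log_probs[np.arange(T)[:, None], np.arange(B)[None, :],
                           targets.T]              # (T, B)
        return -(tok_ll.astype(np.float64) * mask.T).sum(axis=0)

    def nll_smiles(self, smiles: str) -> float:
        return float(self.nll([self.vocabulary.encode_smiles(smiles)])[0])

    def log_likelihood(self, smiles: str) -> float:
        """log P(sequence), EOS included, in nats."""
        return -self.nll_smiles(smiles)

    def weighted_nll_grad(self, sequences: list[np.ndarray],
                          weights: np.ndarray):
        """Gradient of  L = sum_b w_b * NLL(seq_b)  w.r.t. all parameters.

        Every training cost in the package (MLE and the four policy-gradient
        costs) reduces to this form for an appropriate choice of per-sequence
        weights. ``weights`` may be a vector or a callable mapping the
        per-sequence NLL vector to a weight vector (for costs whose weights
        depend on the batch's own likelihoods). Returns (per-sequence NLL
        vector, gradient dict).
        """
        v = self.vocabulary
        H = self.hidden_size
        p = self.params_
        inputs, targets, mask = pad_batch(sequences, v.go_index, v.eos_index)
        B, T = inputs.shape
        log_probs, _, caches, hidden_trace = self._forward(inputs, collect_cache=True)
        probs = np.exp(log_probs)
        tok_ll = log_probs[np.arange(T)[:, None], np.arange(B)[None, :], targets.T]
        nll = -(tok_ll.astype(np.float64) * mask.T).sum(axis=0)

        w = np.asarray(weights(nll) if callable(weights) else weights, dtype=DTYPE)
        grads = {k: np.zeros_like(val) for k, val in p.items()}
        dh_next = [np.zeros((B, H), dtype=DTYPE) for _ in range(self.n_layers)]
        for t in range(T - 1, -1, -1):
            # d L / d logits at step t
            dlogits = probs[t].copy()
            dlogits[np.arange(B), targets[:, t]] -= 1.0
            dlogits *= (w * mask[:, t])[:, None]
            grads["Wo"] += hidden_trace[t][-1].T @ dlogits
            grads["bo"] += dlogits.sum(axis=0)
            dx = dlogits @ p["Wo"].T
            for l in range(self.n_layers - 1, -1, -1):
                (_, x_in, h_prev, z, r, n, hhn) = caches[t][l]
                dh = dx + dh_next[l]
                dz = dh * (h_prev - n)
                dn = dh * (1 - z)
                dh_prev = dh * z
                da_n = dn * (1 - n * n)
                dr = da_n * hhn
                da_z = dz * z * (1 - z)
                da_r = dr * r * (1 - r)
                da_x = np.concatenate([da_z, da_r, da_n], axis=1)
                da_h = np.concatenate([da_z, da_r, da_n * r], axis=1)
                if l == 0:
                    np.add.at(grads["Wx0"], x_in, da_x)
                else:
                    grads[f"Wx{l}"] += x_in.T @ da_x
                    # propagate into the hidden state of the layer below
                    dx = da_x @ p[f"Wx{l}"].T
                grads[f"Wh{l}"] += h_prev.T @ da_h
                grads[f"b{l}"] += da_x.sum(axis=0)
                dh_prev += da_h @ p[f"Wh{l}"].T
                dh_next[l] = dh_prev
        return nll, grads

    # -- training ----------------------------------------------------------
    def fit(self, corpus: list[str], config: TrainConfig | None = None,
            progress: bool = False):
        """Maximum-likelihood training on a SMILES corpus (the prior recipe).

        Batches are drawn with replacement. Records ``loss_trace_`` (mean
        per-sequence NLL per step). Returns self.
        """
        if not corpus:
            raise ValueError("corpus must be non-empty")
        cfg = config or TrainConfig()
        v = self.vocabulary
        encoded = [v.encode_smiles(s) for s in corpus]
        rng = np.random.default_rng(cfg.seed)
        opt = _Adam(self.params_) if cfg.optimizer == "adam" else _SGD(self.params_)
        lr = cfg.learning_rate
        lo, hi = cfg.grad_clip
        trace = []
        iterator = range(cfg.n_steps)
        if progress:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="mle")
        for step in iterator:
            if step > 0 and step % cfg.lr_decay_every == 0:
                lr *= 1.0 - cfg.lr_decay
            idx = rng.integers(0, len(encoded), size=cfg.batch_size)
            batch = [encoded[i] for i in idx]
            weights = np.full(cfg.batch_size, 1.0 / cfg.batch_size, dtype=DTYPE)
            nll, grads = self.weighted_nll_grad(batch, weights)
            for k in grads:
                np.clip(grads[k], lo, hi, out=grads[k])
            opt.step(self.params_, grads, lr)
            trace.append(float(nll.mean()))
        self.loss_trace_ = np.array(trace)
        return self

    # -- sampling ----------------------------------------------------------
    def sample(self, n: int, max_length: int | None = None,
               rng: np.random.Generator | None = None) -> list[Episode]:
        """Draw n episodes: start at GO, sample each next token from the
        model's distribution (temperature 1), stop at EOS or max_length."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = rng if rng is not None else self._rng
        T_max = max_length or self.max_length
        H = self.hidden_size
        v = self.vocabulary
        B = n
        h_list = [np.zeros((B, H), dtype=self._dtype) for _ in range(self.n_layers)]
        x = np.full(B, v.go_index, dtype=np.int64)
        finished = np.zeros(B, dtype=bool)
        seqs: list[list[int]] = [[] for _ in range(B)]
        lps: list[list[float]] = [[] for _ in range(B)]
        for _ in range(T_max):
            log_probs = self._step(x, h_list)
            probs = np.exp(log_probs.astype(np.float64))
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(B)
            choice = (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)
            for b in range(B):
                if not finished[b]:
                    seqs[b].append(int(choice[b]))
                    lps[b].append(float(log_probs[b, choice[b]]))
            finished |= choice == v.eos_index
            if finished.all():
                break
            x = choice
        episodes = []
        for b in range(B):
            idx = np.array(seqs[b], dtype=np.int64)
            truncated = len(idx) == 0 or idx[-1] != v.eos_index
            episodes.append(Episode(
                indices=idx,
                smiles=v.decode_to_smiles(idx),
                step_log_probs=np.array(lps[b]),
                log_prob=float(np.sum(lps[b])),
                truncated=bool(truncated),
            ))
        return episodes

    def stepwise_distributions(self, smiles: str) -> np.ndarray:
        """(T+1) x |X| matrix: row t is the model's next-token distribution
        after observing GO plus the first t tokens of ``smiles``; the final
        row is the distribution at the EOS decision. Rows sum to 1."""
        v = self.vocabulary
        seq = v.encode_smiles(smiles, add_eos=True)
        inputs, _, _ = pad_batch([seq], v.go_index, v.eos_index)
        log_probs, _, _, _ = self._forward(inputs)
        return np.exp(log_probs[:, 0, :].astype(np.float64))

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights + architecture + vocabulary."""
        meta = json.dumps({
            "n_layers": self.n_layers,
            "hidden_size": self.hidden_size,
            "update_gate_bias": self.update_gate_bias,
            "max_length": self.max_length,
            "random_state": self.random_state,
            "vocabulary": self.vocabulary.tokens,
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params_)

    @classmethod
    def load(cls, path) -> "SmilesGRU":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        vocab = Vocabulary(meta["vocabulary"])
        if vocab.tokens != meta["vocabulary"]:
            vocab.tokens = list(meta["vocabulary"])
            vocab.index_of = {t: i for i, t in enumerate(vocab.tokens)}
            vocab.go_index = vocab.index_of[GO]
            vocab.eos_index = vocab.index_of[EOS]
        m = cls(vocab, meta["n_layers"], meta["hidden_size"],
                meta["update_gate_bias"], meta["max_length"], meta["random_state"])
        m.params_ = params
        return m


def train_mle(model: SmilesGRU, corpus: list[str],
              config: TrainConfig | None = None, progress: bool = False):
    """Functional wrapper over :meth:`SmilesGRU.fit`; returns (model, trace)."""
    model.fit(corpus, config, progress=progress)
    return model, model.loss_trace_
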