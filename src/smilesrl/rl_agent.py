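"""Policy-gradient fine-tuning of a SMILES prior toward a scoring function.

The central method keeps the agent anchored to the prior through an
*augmented episodic likelihood*: for a generated sequence A with score
S(A) in [-1, 1],

    log P_U(A) = log P_prior(A) + sigma * S(A)

and the agent minimises the squared disagreement between its own sequence
log-likelihood and this target,

    J = [log P_U(A) - log P_agent(A)]^2 .

Three baseline policy-gradient costs are provided for comparison: the same
disagreement accumulated from per-action log-probabilities ("action basis"),
plain REINFORCE with final reward S(A), and REINFORCE with final reward
S(A) + log P_prior(A). All four reduce to a per-sequence-weighted
log-likelihood gradient, which the sequence model computes in one pass.

The squared-disagreement cost is itself a REINFORCE method in disguise:
the full gradient of r(theta) * log P_agent(theta), with final-step reward
r = [log P_U - log P_agent]^2 / log P_agent, equals the gradient of J
exactly (see :func:`reinforce_equivalence_reward`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import is_valid
from .seq_model import SmilesGRU, _SGD

METHODS = ("agent_episodic", "action_basis", "reinforce", "reinforce_prior")

#: Reference per-method defaults (sigma, learning rate) for the
#: sulphur-avoidance comparison.
METHOD_DEFAULTS = {
    "agent_episodic": {"sigma": 2.0, "learning_rate": 5e-4},
    "action_basis": {"sigma": 8.0, "learning_rate": 5e-4},
    "reinforce": {"sigma": 0.0, "learning_rate": 1e-4},
    "reinforce_prior": {"sigma": 2.0, "learning_rate": 1e-4},
}


def _check_score(s: float) -> float:
    if not -1.0 <= s <= 1.0:
        raise ValueError(f"score {s} outside [-1, 1]")
    return float(s)


def augmented_loglik(prior_ll: float, score: float, sigma: float) -> float:
    """log P_U = log P_prior + sigma * S(A)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return float(prior_ll) + sigma * _check_score(score)


def episodic_cost(agent_ll: float, prior_ll: float, score: float,
                  sigma: float) -> float:
    """J = [log P_U - log P_agent]^2; zero iff the agent matches the target."""
    d = augmented_loglik(prior_ll, score, sigma) - float(agent_ll)
    return d * d


def action_basis_cost(agent_step_log_probs, prior_step_log_probs,
                      score: float, sigma: float) -> float:
    """[sum_t (log pi_prior - log pi_agent) + sigma * S(A)]^2.

    Numerically identical to :func:`episodic_cost` on full sequences, since
    the per-step log-probabilities sum to the sequence log-likelihoods; it is
    kept as the stepwise formulation used in the baseline comparison (with
    its own sigma default).
    """
    a = np.asarray(agent_step_log_probs, dtype=np.float64)
    p = np.asarray(prior_step_log_probs, dtype=np.float64)
    if a.shape != p.shape:
        raise ValueError(f"stepwise trace length mismatch: {a.shape} vs {p.shape}")
    d = float((p - a).sum()) + sigma * _check_score(score)
    return d * d


def reinforce_cost(agent_step_log_probs, score: float) -> float:
    """S(A) * sum_t log pi_agent(a_t | s_t).

    A gain: gradient *ascent* on this quantity increases the likelihood of
    positively scored sequences (the trainer ascends it).
    """
    return _check_score(score) * float(np.sum(agent_step_log_probs))


def reinforce_prior_cost(agent_step_log_probs, prior_ll: float,
                         score: float, sigma: float) -> float:
    """[log P_prior + sigma * S(A)] * sum_t log pi_agent(a_t | s_t); a gain,
    as in :func:`reinforce_cost`, with the prior likelihood folded into the
    final-step reward."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    reward = float(prior_ll) + sigma * _check_score(score)
    return reward * float(np.sum(agent_step_log_probs))


def reinforce_equivalence_reward(agent_ll: float, prior_ll: float,
                                 score: float, sigma: float) -> float:
    """r = [log P_U - log P_agent]^2 / log P_agent.

    The full parameter gradient of r(theta) * log P_agent(theta) equals the
    gradient of the episodic cost; used as a gradient-equivalence oracle,
    never for training. Always <= 0 for a proper (sub-unit) probability.
    """
    agent_ll = float(agent_ll)
    if agent_ll == 0.0:
        raise ValueError("agent log-likelihood of 0 is degenerate here")
    if agent_ll > 0:
        raise ValueError("agent log-likelihood must be negative")
    d = augmented_loglik(prior_ll, score, sigma) - agent_ll
    return d * d / agent_ll


def _batch_weights(method: str, agent_ll: np.ndarray, prior_ll: np.ndarray,
                   scores: np.ndarray, sigma: float) -> np.ndarray:
    """Per-sequence weights w such that grad of sum_b w_b * NLL_agent(b)
    equals the gradient of the batch-mean cost (episodic / action basis) or
    the *descent* direction on the negated gain (REINFORCE variants)."""
    B = len(scores)
    if method in ("agent_episodic", "action_basis"):
        delta = prior_ll + sigma * scores - agent_ll   # log P_U - log P_A
        return 2.0 * delta / B
    if method == "reinforce":
        return scores / B
    if method == "reinforce_prior":
        return (prior_ll + sigma * scores) / B
    raise ValueError(f"unknown RL method {method!r}; choose from {METHODS}")


@dataclass
class AgentConfig:
    """Hyperparameters for agent fine-tuning. ``sigma``/``learning_rate``
    of None pick the per-method reference default."""

    method: str = "agent_episodic"
    sigma: float | None = None
    learning_rate: float | None = None
    n_steps: int = 500
    batch_size: int = 128
    grad_clip: tuple[float, float] = (-3.0, 3.0)
    max_length: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown RL method {self.method!r}; choose from {METHODS}")
        if self.sigma is None:
            self.sigma = METHOD_DEFAULTS[self.method]["sigma"]
        if self.learning_rate is None:
            self.learning_rate = METHOD_DEFAULTS[self.method]["learning_rate"]


class ReinforcementFineTuner:
    """Fine-tunes a copy of a prior on-policy against a scorer.

    Each step: sample a batch of episodes from the agent, score every
    completed SMILES (valid or not), form the chosen cost, and update the
    agent with value-clipped plain-SGD gradients. The prior is only ever
    read, never written.

    Fitted attributes: ``agent_`` (the tuned model) and ``trace_``
    (a DataFrame with one row per step).
    """

    def __init__(self, scorer, config: AgentConfig | None = None, **kwargs):
        self.scorer = scorer
        self.config = config or AgentConfig(**kwargs)

    def get_params(self, deep=True):
        return {"scorer": self.scorer, "config": self.config}

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, prior: SmilesGRU, progress: bool = False):
        cfg = self.config
        agent = prior.copy()
        rng = np.random.default_rng(cfg.seed)
        opt = _SGD(agent.params_)
        lo, hi = cfg.grad_clip
        max_len = cfg.max_length or prior.max_length
        rows = []
        iterator = range(cfg.n_steps)
        if progress:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc=cfg.method)
        for step in iterator:
            episodes = agent.sample(cfg.batch_size, max_length=max_len, rng=rng)
            scores = np.array([_check_score(self.scorer(ep.smiles))
                               for ep in episodes])
            seqs = [ep.indices for ep in episodes]
            prior_ll = -prior.nll(seqs)

            def weights(nll_vec):
                return _batch_weights(cfg.method, -nll_vec, prior_ll,
                                      scores, cfg.sigma)

            agent_nll, grads = agent.weighted_nll_grad(seqs, weights)
            if any(not np.isfinite(g).all() for g in grads.values()):
                raise RuntimeError(
                    f"non-finite gradient at step {step} "
                    f"(mean score {scores.mean():.3f}); aborting")
            for k in grads:
                np.clip(grads[k], lo, hi, out=grads[k])
            opt.step(agent.params_, grads, cfg.learning_rate)

            agent_ll = -agent_nll
            aug_ll = prior_ll + cfg.sigma * scores
            smiles = [ep.smiles for ep in episodes]
            rows.append({
                "step": step,
                "mean_score": float(scores.mean()),
                "frac_valid": float(np.mean([is_valid(s) for s in smiles])),
                "mean_agent_ll": float(agent_ll.mean()),
                "mean_prior_ll": float(prior_ll.mean()),
                "mean_aug_ll": float(aug_ll.mean()),
                "frac_unique": len(set(smiles)) / len(smiles),
            })
        self.agent_ = agent
        self.trace_ = pd.DataFrame(rows)
        return self


def train_agent(prior: SmilesGRU, scorer, config: AgentConfig | None = None,
                progress: bool = False, **kwargs):
    """Functional wrapper over :class:`ReinforcementFineTuner`.
    Returns (agent, trace DataFrame)."""
    tuner = ReinforcementFineTuner(scorer, config, **kwargs).fit(
        prior, progress=progress)
    return tuner.agent_, tuner.trace_
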