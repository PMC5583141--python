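import itertools

import numpy as np
import pytest

import smilesrl as sr
from smilesrl.chem import Vocabulary
from smilesrl.rl_agent import (METHOD_DEFAULTS, AgentConfig, _batch_weights,
                               action_basis_cost, augmented_loglik,
                               episodic_cost, reinforce_cost,
                               reinforce_equivalence_reward,
                               reinforce_prior_cost, train_agent)
from smilesrl.scoring import Scorer
from smilesrl.seq_model import SmilesGRU, TrainConfig


class TestCostFunctions:
    def test_augmented_loglik_values(self):
        assert augmented_loglik(-10.0, 0.0, 7.0) == -10.0
        # a low-likelihood query with a perfect similarity score at sigma 15
        assert np.isclose(augmented_loglik(-19.2, 1.0, 15.0), -4.2)
        # its close analogue: S = -1 + 2*0.87 at k=1 gives the same target
        assert np.isclose(augmented_loglik(-15.2, -1 + 2 * 0.87, 15.0), -4.1,
                          atol=0.05)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            augmented_loglik(-5.0, 1.5, 2.0)
        with pytest.raises(ValueError):
            episodic_cost(-5.0, -5.0, -1.2, 2.0)

    def test_episodic_cost_fixed_point_and_value(self):
        assert episodic_cost(-5.0 + 2.0, -5.0, 1.0, 2.0) == 0.0
        assert episodic_cost(-5.0, -5.0, 1.0, 2.0) == 4.0

    def test_action_basis_equals_episodic_on_full_sums(self):
        rng = np.random.default_rng(0)
        a = rng.normal(-1.5, 0.5, size=8)
        p = rng.normal(-1.5, 0.5, size=8)
        assert np.isclose(
            action_basis_cost(a, p, 0.5, 8.0),
            episodic_cost(a.sum(), p.sum(), 0.5, 8.0))

    def test_action_basis_identical_traces(self):
        lp = np.full(5, -0.3)
        assert action_basis_cost(lp, lp, 0.0, 8.0) == 0.0
        assert action_basis_cost(lp, lp, 1.0, 8.0) == 64.0
        with pytest.raises(ValueError, match="mismatch"):
            action_basis_cost(lp, lp[:-1], 0.0, 8.0)

    def test_reinforce_zero_score_zero_cost(self):
        assert reinforce_cost([-1.0, -2.0], 0.0) == 0.0

    def test_reinforce_gradient_sign_on_one_param_model(self):
        # maximizing S * log pi must increase the likelihood of a
        # positively scored outcome: d/dtheta [S * log sigmoid(theta)] > 0
        theta = 0.0
        eps = 1e-6

        def gain(th, s):
            return reinforce_cost([np.log(1 / (1 + np.exp(-th)))], s)

        grad_pos = (gain(theta + eps, 1.0) - gain(theta - eps, 1.0)) / (2 * eps)
        grad_neg = (gain(theta + eps, -1.0) - gain(theta - eps, -1.0)) / (2 * eps)
        assert grad_pos > 0 > grad_neg

    def test_reinforce_prior_cost_value(self):
        lp = np.array([-1.0, -1.0])
        assert np.isclose(reinforce_prior_cost(lp, -10.0, 1.0, 2.0),
                          (-10.0 + 2.0) * -2.0)

    def test_equivalence_reward_properties(self):
        assert abs(reinforce_equivalence_reward(-4.2, -19.2, 1.0, 15.0)) < 1e-12
        assert reinforce_equivalence_reward(-8.0, -19.2, 1.0, 15.0) <= 0.0
        with pytest.raises(ValueError):
            reinforce_equivalence_reward(0.0, -5.0, 0.0, 1.0)

    def test_episodic_gradient_equals_reinforce_surrogate_gradient(self):
        # finite differences on a 3-parameter softmax policy: the gradient of
        # the squared-disagreement cost equals the full gradient of
        # r(theta) * log P(theta) with r the equivalence reward
        theta = np.array([0.3, -0.7, 1.1])
        episode = [0, 2, 1, 0]
        prior_ll, score, sigma = -6.0, 0.6, 4.0

        def log_p(th):
            z = np.exp(th - th.max())
            z /= z.sum()
            return float(np.sum(np.log(z[episode])))

        def grad_fd(f):
            g = np.zeros_like(theta)
            for i in range(len(theta)):
                d = np.zeros_like(theta)
                d[i] = 1e-6
                g[i] = (f(theta + d) - f(theta - d)) / 2e-6
            return g

        g_cost = grad_fd(lambda th: episodic_cost(log_p(th), prior_ll,
                                                  score, sigma))
        g_surr = grad_fd(lambda th: reinforce_equivalence_reward(
            log_p(th), prior_ll, score, sigma) * log_p(th))
        assert np.linalg.norm(g_cost - g_surr) / np.linalg.norm(g_cost) < 1e-4


class TestBatchWeights:
    def test_episodic_weights_recover_mean_cost_gradient(self):
        agent_ll = np.array([-4.0, -9.0])
        prior_ll = np.array([-5.0, -7.0])
        scores = np.array([1.0, -1.0])
        w = _batch_weights("agent_episodic", agent_ll, prior_ll, scores, 2.0)
        # d/d(nll) of mean((aug - agent_ll)^2) with agent_ll = -nll
        delta = prior_ll + 2.0 * scores - agent_ll
        assert np.allclose(w, 2 * delta / 2)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            _batch_weights("bogus", np.zeros(1), np.zeros(1), np.zeros(1), 1.0)
        with pytest.raises(ValueError):
            AgentConfig(method="bogus")

    def test_method_defaults_applied(self):
        cfg = AgentConfig(method="action_basis")
        assert cfg.sigma == METHOD_DEFAULTS["action_basis"]["sigma"]
        assert cfg.learning_rate == 5e-4


class _StartsWith(Scorer):
    def __init__(self, prefix):
        self.prefix = prefix

    def __call__(self, s):
        return 1.0 if s.startswith(self.prefix) else -1.0


class _BadScorer(Scorer):
    def __call__(self, s):
        return 2.0


@pytest.fixture(scope="module")
def enum_prior():
    """Prior over an enumerable two-letter language (plus EOS)."""
    vocab = Vocabulary(["C", "O"])
    corpus = ["CC", "CO", "OC", "OO", "C", "O", "CCO", "OCC", "COC"] * 5
    m = SmilesGRU(vocab, n_layers=1, hidden_size=32, update_gate_bias=1.0,
                  max_length=6, random_state=2)
    m.fit(corpus, TrainConfig(n_steps=300, batch_size=32, seed=0))
    return m


def _enumerate(vocab, max_tokens=5):
    seqs = []
    for L in range(0, max_tokens + 1):
        for comb in itertools.product([0, 1], repeat=L):
            seqs.append(np.array(list(comb) + [vocab.eos_index]))
    return seqs


class TestTrainAgent:
    def test_zero_sigma_leaves_agent_at_prior(self, enum_prior):
        # with sigma = 0 the augmented target IS the prior likelihood, the
        # cost is zero at initialisation, and the gradient vanishes: the
        # agent must remain exactly the prior
        agent, trace = train_agent(
            enum_prior, _StartsWith("C"),
            AgentConfig(method="agent_episodic", sigma=0.0,
                        learning_rate=5e-3, n_steps=50, batch_size=32, seed=0))
        for k in enum_prior.params_:
            assert np.array_equal(agent.params_[k], enum_prior.params_[k])

    def test_prior_never_updated(self, enum_prior):
        before = {k: v.copy() for k, v in enum_prior.params_.items()}
        train_agent(enum_prior, _StartsWith("C"),
                    AgentConfig(n_steps=20, batch_size=16, seed=0,
                                learning_rate=5e-3))
        for k in before:
            assert np.array_equal(before[k], enum_prior.params_[k])

    def test_out_of_range_scorer_rejected(self, enum_prior):
        with pytest.raises(ValueError, match="outside"):
            train_agent(enum_prior, _BadScorer(),
                        AgentConfig(n_steps=2, batch_size=8, seed=0))

    def test_agent_converges_to_normalized_augmented_target(self, enum_prior):
        # global-minimum property on the enumerable language: the tuned
        # agent's sequence distribution approaches
        # P(A) proportional to P_prior(A) * exp(sigma * S(A))
        sigma = 2.0
        agent, _ = train_agent(
            enum_prior, _StartsWith("C"),
            AgentConfig(method="agent_episodic", sigma=sigma,
                        learning_rate=5e-3, n_steps=2000, batch_size=64,
                        seed=3))
        vocab = enum_prior.vocabulary
        seqs = _enumerate(vocab)
        smiles = [vocab.decode_to_smiles(s) for s in seqs]
        scores = np.array([1.0 if s.startswith("C") else -1.0 for s in smiles])
        p_prior = np.exp(-enum_prior.nll(seqs))
        p_agent = np.exp(-agent.nll(seqs))
        target = p_prior * np.exp(sigma * scores)
        target /= target.sum()
        tv = 0.5 * np.abs(p_agent / p_agent.sum() - target).sum()
        assert tv < 0.1, f"total variation {tv:.3f}"

    def test_trace_columns_and_ranges(self, enum_prior):
        _, trace = train_agent(enum_prior, _StartsWith("C"),
                               AgentConfig(n_steps=10, batch_size=16, seed=0,
                                           learning_rate=5e-3))
        for col in ("step", "mean_score", "frac_valid", "mean_agent_ll",
                    "mean_prior_ll", "mean_aug_ll", "frac_unique"):
            assert col in trace.columns
        assert len(trace) == 10
        assert trace["mean_score"].between(-1, 1).all()

    def test_reinforce_prior_drifts_toward_high_reward_mode(self, enum_prior):
        # the reward log P_prior + sigma * S is maximized by the single best
        # sequence; the trained policy should concentrate relative to prior
        agent, _ = train_agent(
            enum_prior, _StartsWith("C"),
            AgentConfig(method="reinforce_prior", sigma=2.0,
                        learning_rate=5e-3, n_steps=1500, batch_size=64,
                        seed=3))
        vocab = enum_prior.vocabulary
        seqs = _enumerate(vocab)
        p_prior = np.exp(-enum_prior.nll(seqs))
        p_agent = np.exp(-agent.nll(seqs))
        assert p_agent.max() > p_prior.max()
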