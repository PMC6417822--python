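"""The triage MDP: episodes, states, rewards, and the training loops."""

import numpy as np
import pytest

from genetriage.agent import AgentConfig, DQNAgent
from genetriage.classifier import BiLSTMClassifier, ClassifierConfig
from genetriage.environment import (
    Action,
    ArticleScorer,
    EnvConfig,
    aggregate_prediction,
    build_state,
    evaluate_triage,
    legal_actions,
    make_episode,
    reward,
    run_episode,
    step,
    train_triage,
)
from genetriage.preprocess import build_vocabulary
from genetriage.synthetic import first_article_world_config, generate_world
from genetriage.types import Article, ConceptToken, QueryCase

ENV = EnvConfig(d_emb=4)


def tiny_world():
    world = first_article_world_config(seed=2, n_queries=12, vocab_size=40,
                                       article_length_range=(4, 8))
    return generate_world(world)


@pytest.fixture(scope="module")
def scorer():
    articles, _ = tiny_world()
    vocab = build_vocabulary(articles, size=60)
    cfg = ClassifierConfig(embed_dim=8, hidden_dim=6, vocab_size=len(vocab), max_len=15)
    return ArticleScorer(BiLSTMClassifier(cfg, seed=0), vocab)


@pytest.fixture()
def world():
    articles, queries = tiny_world()
    return {a.article_id: a for a in articles}, queries


class TestMakeEpisode:
    def test_pool_in_retrieval_order(self, world):
        index, queries = world
        q = queries[0]
        ep = make_episode(q, index)
        assert [a.article_id for a in ep.pool] == q.candidate_ids
        assert ep.cursor == 0 and not ep.done

    def test_candidates_failing_mention_filter_excluded(self, world):
        index = {"X1": Article("X1", title="unrelated", abstract="nothing here", year=2000)}
        ep = make_episode(QueryCase("APOE", "alzheimer", True, ["X1"]), index)
        assert ep.pool == [] and ep.done

    def test_empty_pool_abstains(self, world):
        ep = make_episode(QueryCase("APOE", "alzheimer", True, []), {})
        assert ep.done
        assert aggregate_prediction(ep) == (False, 0.0)

    def test_unknown_candidate_rejected(self):
        with pytest.raises(KeyError):
            make_episode(QueryCase("G", "t", True, ["missing"]), {})


class TestAggregate:
    def make_episode_with(self, ps):
        arts = [Article(f"A{i}", title="G t", abstract="G t", year=2000) for i in range(len(ps))]
        ep = make_episode(QueryCase("G", "t", True, [a.article_id for a in arts]),
                          {a.article_id: a for a in arts})
        for a, p in zip(arts, ps):
            ep.read_info[a.article_id] = (p, np.zeros(4))
            ep.selected_ids.append(a.article_id)
        return ep

    def test_single_read_selection(self):
        ep = self.make_episode_with([0.9])
        assert aggregate_prediction(ep) == (True, pytest.approx(0.9))

    def test_confidence_weighted_vote(self):
        # independent oracle: weights are the probabilities themselves
        ps = [0.9, 0.2]
        expected = sum(p * p for p in ps) / sum(ps)
        ep = self.make_episode_with(ps)
        verdict, conf = aggregate_prediction(ep)
        assert conf == pytest.approx(expected)
        assert verdict is (expected > 0.5)

    def test_unread_selection_is_uninformative(self):
        ep = self.make_episode_with([0.9])
        ep.read_info.clear()  # selected but never read -> contributes 0.5
        verdict, conf = aggregate_prediction(ep)
        assert conf == pytest.approx(0.5) and verdict is False


class TestReward:
    @pytest.mark.parametrize(
        "prev,cur,expected",
        [(0.5, 0.7, 0.199), (0.4, 0.4, -0.001), (1.0, 0.0, -1.001)],
    )
    def test_arithmetic(self, prev, cur, expected):
        assert reward(prev, cur, -0.001) == pytest.approx(expected)


class TestStep:
    def test_stop_first_action(self, world, scorer):
        index, queries = world
        q = next(q for q in queries if q.gold_associated is False)
        ep = make_episode(q, index)
        _, r, done = step(ep, Action.STOP, scorer, ENV)
        # abstaining predicts no-association: correct for a negative query
        assert done and r == pytest.approx(1.0 - 0.001)
        assert ep.articles_read == 0

    def test_conservation_and_cursor_flow(self, world, scorer):
        index, queries = world
        ep = make_episode(queries[1], index)
        n = len(ep.pool)
        while not ep.done:
            assert len(ep.selected_ids) + len(ep.rejected_ids) + (n - ep.cursor) == n
            step(ep, Action.READ, scorer, ENV)
            if ep.done:
                break
            step(ep, Action.SELECT if ep.cursor % 2 == 0 else Action.REJECT, scorer, ENV)
        assert len(ep.selected_ids) + len(ep.rejected_ids) == n
        assert ep.articles_read == n

    def test_double_read_rejected(self, world, scorer):
        index, queries = world
        ep = make_episode(queries[0], index)
        step(ep, Action.READ, scorer, ENV)
        with pytest.raises(RuntimeError, match="already read"):
            step(ep, Action.READ, scorer, ENV)

    def test_stepping_finished_episode_rejected(self, world, scorer):
        index, queries = world
        ep = make_episode(queries[0], index)
        step(ep, Action.STOP, scorer, ENV)
        with pytest.raises(RuntimeError):
            step(ep, Action.SELECT, scorer, ENV)

    def test_reject_to_exhaustion(self, world, scorer):
        index, queries = world
        ep = make_episode(queries[2], index)
        for _ in range(len(ep.pool)):
            _, _, done = step(ep, Action.REJECT, scorer, ENV)
        assert done and ep.done

    def test_total_reward_telescopes(self, world, scorer, rng):
        """Sum of rewards == final correctness − 0.001·steps, path-independent."""
        index, queries = world
        for q in queries[:6]:
            ep = make_episode(q, index)
            while not ep.done:
                choices = [Action.SELECT, Action.REJECT, Action.STOP]
                if not ep.current_read:
                    choices.append(Action.READ)
                step(ep, choices[rng.integers(0, len(choices))], scorer, ENV)
            final_acc = 1.0 if aggregate_prediction(ep)[0] == q.gold_associated else 0.0
            assert ep.total_reward == pytest.approx(final_acc - 0.001 * ep.step_count)


class TestBuildState:
    def test_initial_state_features(self, world, scorer):
        index, queries = world
        ep = make_episode(queries[0], index)
        s = build_state(ep, scorer, ENV)
        assert s.shape == (ENV.state_dim,)
        assert np.all(s == 0.0)  # nothing read, nothing decided

    def test_consumed_fraction_after_selection(self, world, scorer):
        index, queries = world
        q = next(q for q in queries if len(q.candidate_ids) == 4)
        ep = make_episode(q, index)
        step(ep, Action.SELECT, scorer, ENV)
        s = build_state(ep, scorer, ENV)
        offset = 2 + ENV.d_emb + 1  # p, has_read, embedding, margin
        assert s[offset] == pytest.approx(0.25)  # consumed
        assert s[offset + 1] == pytest.approx(0.25)  # selected count

    def test_state_is_idempotent(self, world, scorer):
        index, queries = world
        ep = make_episode(queries[3], index)
        step(ep, Action.READ, scorer, ENV)
        assert np.array_equal(build_state(ep, scorer, ENV), build_state(ep, scorer, ENV))

    def test_read_sets_indicator_and_probability(self, world, scorer):
        index, queries = world
        ep = make_episode(queries[0], index)
        step(ep, Action.READ, scorer, ENV)
        s = build_state(ep, scorer, ENV)
        assert s[1] == 1.0  # has-read flag
        assert 0.0 <= s[0] <= 1.0


class TestRunEpisode:
    def test_legal_actions_forbid_second_read(self, world, scorer):
        index, queries = world
        ep = make_episode(queries[0], index)
        assert 2 in legal_actions(ep)
        step(ep, Action.READ, scorer, ENV)
        assert 2 not in legal_actions(ep)

    def test_deterministic_under_seeds(self, world, scorer):
        index, queries = world
        results = []
        for _ in range(2):
            agent = DQNAgent(ENV.state_dim, AgentConfig(batch_size=4), seed=1)
            ep = make_episode(queries[4], index)
            res, trs = run_episode(agent, ep, scorer, 0.3, np.random.default_rng(9), ENV)
            results.append((res.predicted_association, res.articles_read, res.total_reward,
                            len(trs)))
        assert results[0] == results[1]

    def test_empty_pool_result(self, scorer):
        agent = DQNAgent(ENV.state_dim, AgentConfig(batch_size=4), seed=0)
        ep = make_episode(QueryCase("G", "t", True, []), {})
        res, trs = run_episode(agent, ep, scorer, 0.0, np.random.default_rng(0), ENV)
        assert res.articles_read == 0 and res.predicted_association is False
        assert trs == []

    def test_transitions_cover_all_steps(self, world, scorer):
        index, queries = world
        agent = DQNAgent(ENV.state_dim, AgentConfig(batch_size=4), seed=2)
        ep = make_episode(queries[5], index)
        res, trs = run_episode(agent, ep, scorer, 0.5, np.random.default_rng(3), ENV)
        assert len(trs) == res.steps  # one atomic action per transition
        assert trs[-1].done


class TestTrainEvaluate:
    def test_zero_epochs_leaves_agent_unchanged(self, world, scorer):
        index, queries = world
        agent = DQNAgent(ENV.state_dim, AgentConfig(batch_size=4), seed=0)
        before = {k: v.copy() for k, v in agent.network.params.items()}
        train_triage(agent, scorer, queries, index, epochs=0, seed=0, env_config=ENV)
        for k in before:
            assert np.array_equal(agent.network.params[k], before[k])

    def test_empty_query_list_rejected(self, world, scorer):
        index, _ = world
        agent = DQNAgent(ENV.state_dim, AgentConfig(batch_size=4), seed=0)
        with pytest.raises(ValueError):
            train_triage(agent, scorer, [], index, epochs=1, seed=0, env_config=ENV)

    def test_transition_count_conserved(self, world, scorer):
        index, queries = world
        agent = DQNAgent(ENV.state_dim,
                         AgentConfig(batch_size=8, replay_capacity=1000,
                                     epsilon_anneal_steps=100, target_sync_every=50),
                         seed=0)
        _, curves = train_triage(agent, scorer, queries, index, epochs=2, seed=0, env_config=ENV)
        assert agent.step_count == sum(c.transitions for c in curves)

    def test_evaluation_metrics_shape_and_bounds(self, world, scorer):
        index, queries = world
        agent = DQNAgent(ENV.state_dim, AgentConfig(batch_size=4), seed=0)
        m = evaluate_triage(agent, scorer, queries, index, ENV)
        assert set(m) >= {"precision", "recall", "f1", "mean_articles_read", "mean_pool_size"}
        assert m["mean_articles_read"] <= m["mean_pool_size"]
        m2 = evaluate_triage(agent, scorer, queries, index, ENV)
        assert m == m2  # greedy evaluation is deterministic
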