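"""Canonical desk-scale experiment protocols.

These functions wire the full system together — world generation,
vocabulary, classifier training, agent training, greedy evaluation — at
sizes chosen so a complete experiment runs in minutes on one CPU while
preserving the structure of the full-scale configuration (reduced widths:
32-dim embeddings / 64-dim hidden; 100–150-concept worlds matching the
full corpus's records-per-concept ratio; replay and anneal windows scaled
with total training length).

Agent training uses a phased schedule: a high-learning-rate exploration
phase followed by progressively lower learning rates and exploration
floors. The late phases matter because the stop/read orderings that
control reading cost differ by fractions of the per-step penalty (1e-3),
which the Q-network only resolves once learning-rate noise drops below
that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent import AgentConfig, DQNAgent
from .classifier import BiLSTMClassifier, ClassifierConfig, precision_recall_f1, train_classifier
from .corpus_io import split_records
from .environment import ArticleScorer, EnvConfig, evaluate_triage, train_triage
from .preprocess import build_vocabulary, encode
from .synthetic import (
    WorldConfig,
    article_labels,
    default_world_config,
    first_article_world_config,
    generate_world,
)

__all__ = [
    "DeskScale",
    "train_triage_system",
    "read_all_metrics",
    "behavior_recovery",
    "triage_vs_read_all",
]


@dataclass(frozen=True)
class DeskScale:
    """Reduced-size training protocol used by the bundled experiments."""

    embed_dim: int = 32
    hidden_dim: int = 64
    max_len: int = 40
    vocab_cap: int = 100
    classifier_lr: float = 0.01
    classifier_epochs: int = 12
    classifier_batch: int = 32
    d_emb: int = 4
    replay_capacity: int = 4_000
    epsilon_anneal_steps: int = 4_000
    agent_batch: int = 128
    # (learning rate, epochs, epsilon floor, target-sync interval)
    agent_phases: tuple[tuple[float, int, float, int], ...] = (
        (0.01, 12, 0.10, 100),
        (0.002, 30, 0.03, 100),
        (0.0005, 50, 0.01, 50),
        (0.0001, 25, 0.01, 50),
    )


def train_triage_system(
    world: WorldConfig,
    seed: int,
    scale: DeskScale = DeskScale(),
    train_fraction: float = 0.5,
):
    """Generate a world and train classifier + agent on its training split.

    Returns (scorer, agent, train queries, eval queries, corpus index,
    environment config).
    """
    articles, queries = generate_world(world)
    train_q, eval_q = split_records(queries, train_fraction, seed=seed)
    vocab = build_vocabulary(articles, size=scale.vocab_cap)
    cls_cfg = ClassifierConfig(
        embed_dim=scale.embed_dim,
        hidden_dim=scale.hidden_dim,
        vocab_size=len(vocab),
        max_len=scale.max_len,
        learning_rate=scale.classifier_lr,
        epochs=scale.classifier_epochs,
        batch_size=scale.classifier_batch,
    )
    pairs = [
        (encode(a.concepts, vocab, scale.max_len), y)
        for a, y in article_labels(articles, train_q)
    ]
    model, _ = train_classifier(pairs, cls_cfg, seed=seed)
    scorer = ArticleScorer(model, vocab)

    env = EnvConfig(d_emb=scale.d_emb)
    agent_cfg = AgentConfig(
        learning_rate=scale.agent_phases[0][0],
        replay_capacity=scale.replay_capacity,
        epsilon_anneal_steps=scale.epsilon_anneal_steps,
        epsilon_end=scale.agent_phases[0][2],
        target_sync_every=scale.agent_phases[0][3],
        batch_size=scale.agent_batch,
    )
    agent = DQNAgent(env.state_dim, agent_cfg, seed=seed)
    for lr, epochs, eps_end, sync in scale.agent_phases:
        agent.config.learning_rate = lr
        agent.config.epsilon_end = eps_end
        agent.config.target_sync_every = sync
        agent, _ = train_triage(
            agent, scorer, train_q, articles,
            epochs=epochs, steps_per_epoch=10_000, seed=seed + 1, env_config=env,
        )
    index = {a.article_id: a for a in articles}
    return scorer, agent, train_q, eval_q, index, env


def read_all_metrics(queries, index, scorer: ArticleScorer) -> dict[str, float]:
    """Read-everything baseline: classify and aggregate every candidate."""
    preds, golds, pools = [], [], []
    for q in queries:
        ps = np.array([scorer.score(index[aid])[0] for aid in q.candidate_ids])
        mean = float((ps**2).sum() / ps.sum()) if len(ps) and ps.sum() > 0 else 0.0
        preds.append(mean > 0.5)
        golds.append(q.gold_associated)
        pools.append(len(ps))
    precision, recall, f1 = precision_recall_f1(preds, golds)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mean_articles_read": float(np.mean(pools)) if pools else 0.0,
    }


def behavior_recovery(seed: int, n_queries: int = 400) -> dict[str, float]:
    """First-article-suffices preset: does the agent read once and stop?

    Trains the full system on half the queries and evaluates the greedy
    policy on the held-out half, reporting the fraction of held-out
    episodes with exactly one read alongside the standard metrics.
    """
    world = first_article_world_config(seed=seed, n_queries=n_queries)
    scorer, agent, _, eval_q, index, env = train_triage_system(world, seed)
    eval_q = eval_q[:200]
    from .environment import make_episode, run_episode

    rng = np.random.default_rng(0)
    reads = []
    for q in eval_q:
        result, _ = run_episode(agent, make_episode(q, index), scorer, 0.0, rng, env)
        reads.append(result.articles_read)
    metrics = evaluate_triage(agent, scorer, eval_q, index, env)
    metrics["frac_one_read"] = float(np.mean(np.array(reads) == 1))
    return metrics


_VS_READALL_SCALE = DeskScale(
    vocab_cap=150,
    classifier_epochs=10,
    agent_phases=(
        (0.01, 10, 0.10, 100),
        (0.002, 14, 0.05, 100),
        (0.0005, 18, 0.02, 50),
        (0.0001, 8, 0.02, 50),
    ),
)


def triage_vs_read_all(seed: int, n_queries: int = 200) -> dict[str, float]:
    """Default noisy world: greedy triage agent vs the read-all baseline.

    30% of each pool is unreliable (label-independent signal); the agent
    should match or beat exhaustive reading while reading far fewer
    articles.
    """
    world = default_world_config(seed=seed, n_queries=n_queries)
    scorer, agent, _, eval_q, index, env = train_triage_system(
        world, seed, scale=_VS_READALL_SCALE
    )
    agent_m = evaluate_triage(agent, scorer, eval_q, index, env)
    base_m = read_all_metrics(eval_q, index, scorer)
    return {
        "agent_f1": agent_m["f1"],
        "baseline_f1": base_m["f1"],
        "agent_precision": agent_m["precision"],
        "agent_recall": agent_m["recall"],
        "mean_articles_read": agent_m["mean_articles_read"],
        "mean_pool_size": agent_m["mean_pool_size"],
    }
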