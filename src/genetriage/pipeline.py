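"""File-based orchestration of the full triage pipeline.

Each stage reads and writes plain files inside a run directory, so every
command is re-runnable and the whole pipeline is a pure function of
(inputs, config, seeds):

    simulate         -> corpus.jsonl, queries.tsv, queries_{train,eval}.tsv
    prepare          -> vocab.tsv
    train-classifier -> classifier.npz, classifier_metrics.json
    train-agent      -> agent.npz, agent_curves.json
    evaluate         -> metrics.json
    extract          -> kb.tsv (and kb.json)

The classifier trains on articles belonging to the training queries; the
agent trains on the training queries and is evaluated on the held-out
evaluation queries with a greedy policy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from . import corpus_io
from .agent import AgentConfig, DQNAgent
from .classifier import BiLSTMClassifier, ClassifierConfig, train_classifier
from .environment import (
    ArticleScorer,
    EnvConfig,
    aggregate_prediction,
    evaluate_triage,
    make_episode,
    run_episode,
    train_triage,
)
from .kb_store import AssociationRecord, KnowledgeBase, export_kb
from .preprocess import Vocabulary, build_vocabulary, encode
from .synthetic import WorldConfig, article_labels, generate_world, world_summary

__all__ = ["RunConfig", "simulate", "prepare", "train_classifier_stage",
           "train_agent_stage", "evaluate_stage", "extract_stage"]


@dataclass
class RunConfig:
    """Declarative configuration for a full run; every stochastic component
    receives an explicit seed derived from ``seed``."""

    world: WorldConfig = field(default_factory=WorldConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    agent: AgentConfig = field(default_factory=AgentConfig)
    env: EnvConfig = field(default_factory=EnvConfig)
    seed: int = 0
    train_fraction: float = 0.8
    agent_epochs: int = 10
    steps_per_epoch: int = 10_000
    kb_timestamp: str = "1970-01-01T00:00:00"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        for section, sub_cls in (
            ("world", WorldConfig),
            ("classifier", ClassifierConfig),
            ("agent", AgentConfig),
            ("env", EnvConfig),
        ):
            if section in raw:
                sub = dict(raw[section])
                for key in ("pool_size_range", "article_length_range"):
                    if key in sub and isinstance(sub[key], list):
                        sub[key] = tuple(sub[key])
                kwargs[section] = sub_cls(**sub)
        for f in fields(cls):
            if f.name in raw and f.name not in ("world", "classifier", "agent", "env"):
                kwargs[f.name] = raw[f.name]
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, world=replace(self.world, seed=seed))


def _write_json(path: Path, payload) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate(config: RunConfig, outdir: str | Path) -> dict:
    """Generate a synthetic world and write its corpus and query files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    articles, queries = generate_world(config.world)
    corpus_io.write_corpus(articles, outdir / "corpus.jsonl")
    corpus_io.write_queries(queries, outdir / "queries.tsv")
    if queries:
        train_q, eval_q = corpus_io.split_records(queries, config.train_fraction, config.seed)
    else:
        train_q, eval_q = [], []
    corpus_io.write_queries(train_q, outdir / "queries_train.tsv")
    corpus_io.write_queries(eval_q, outdir / "queries_eval.tsv")
    summary = world_summary((articles, queries))
    _write_json(outdir / "world_summary.json", summary)
    return summary


def prepare(config: RunConfig, outdir: str | Path) -> Vocabulary:
    """Build the concept vocabulary from the corpus and serialise it."""
    outdir = Path(outdir)
    articles = corpus_io.read_corpus(outdir / "corpus.jsonl")
    vocab = build_vocabulary(articles, size=config.classifier.vocab_size - 4)
    vocab.save(outdir / "vocab.tsv")
    return vocab


def _load_world(outdir: Path):
    articles = corpus_io.read_corpus(outdir / "corpus.jsonl")
    vocab = Vocabulary.load(outdir / "vocab.tsv")
    return articles, vocab


def _encoded_pairs(pairs, vocab, max_len):
    return [(encode(a.concepts, vocab, max_len), lbl) for a, lbl in pairs]


def train_classifier_stage(config: RunConfig, outdir: str | Path) -> list[float]:
    """Train the recurrent extractor on training-query articles."""
    outdir = Path(outdir)
    articles, vocab = _load_world(outdir)
    train_q = corpus_io.read_queries(outdir / "queries_train.tsv")
    cls_cfg = replace(config.classifier, vocab_size=len(vocab))
    pairs = _encoded_pairs(article_labels(articles, train_q), vocab, cls_cfg.max_len)
    model, losses = train_classifier(pairs, cls_cfg, seed=config.seed)
    model.save(outdir / "classifier.npz")
    probs, _ = model.forward_batch([e for e, _ in pairs])
    acc = float(np.mean((probs[:, 1] > 0.5) == np.array([y for _, y in pairs])))
    _write_json(
        outdir / "classifier_metrics.json",
        {"epoch_losses": [round(x, 6) for x in losses], "train_accuracy": round(acc, 4),
         "n_train": len(pairs)},
    )
    return losses


def _scorer(config: RunConfig, outdir: Path) -> tuple[ArticleScorer, list, list]:
    articles, vocab = _load_world(outdir)
    model = BiLSTMClassifier.load(outdir / "classifier.npz")
    return ArticleScorer(model, vocab), articles, vocab


def train_agent_stage(config: RunConfig, outdir: str | Path) -> list[dict]:
    """Train the DQN triage agent on the training queries."""
    outdir = Path(outdir)
    scorer, articles, _ = _scorer(config, outdir)
    train_q = corpus_io.read_queries(outdir / "queries_train.tsv")
    agent = DQNAgent(config.env.state_dim, config.agent, seed=config.seed)
    agent, curves = train_triage(
        agent,
        scorer,
        train_q,
        articles,
        epochs=config.agent_epochs,
        steps_per_epoch=config.steps_per_epoch,
        seed=config.seed + 1,
        env_config=config.env,
    )
    agent.save(outdir / "agent.npz")
    payload = [
        {"epoch": c.epoch, "transitions": c.transitions, "mean_reward": round(c.mean_reward, 6),
         "mean_loss": round(c.mean_loss, 8), "epsilon": round(c.epsilon, 4)}
        for c in curves
    ]
    _write_json(outdir / "agent_curves.json", payload)
    return payload


def evaluate_stage(config: RunConfig, outdir: str | Path) -> dict:
    """Greedy-policy evaluation on the held-out queries."""
    outdir = Path(outdir)
    scorer, articles, _ = _scorer(config, outdir)
    eval_q = corpus_io.read_queries(outdir / "queries_eval.tsv")
    agent = DQNAgent.load(outdir / "agent.npz")
    metrics = evaluate_triage(agent, scorer, eval_q, articles, env_config=config.env)
    metrics = {k: round(v, 6) for k, v in metrics.items()}
    _write_json(outdir / "metrics.json", metrics)
    return metrics


def extract_stage(config: RunConfig, outdir: str | Path, queries_file: str | None = None) -> KnowledgeBase:
    """Run greedy episodes over a query list and export the KB."""
    outdir = Path(outdir)
    scorer, articles, _ = _scorer(config, outdir)
    queries = corpus_io.read_queries(outdir / (queries_file or "queries_eval.tsv"))
    agent = DQNAgent.load(outdir / "agent.npz")
    index = {a.article_id: a for a in articles}
    rng = np.random.default_rng(0)
    kb = KnowledgeBase()
    for q in queries:
        episode = make_episode(q, index)
        result, _ = run_episode(agent, episode, scorer, 0.0, rng, config.env)
        predicted, confidence = aggregate_prediction(episode)
        kb.add(
            AssociationRecord(
                gene=q.gene,
                trait=q.trait,
                associated=predicted,
                confidence=confidence if predicted else confidence,
                supporting_ids=result.selected_ids,
                n_articles_read=result.articles_read,
                timestamp=config.kb_timestamp,
            )
        )
    export_kb(kb, outdir / "kb.tsv", "tsv")
    export_kb(kb, outdir / "kb.json", "json")
    return kb
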