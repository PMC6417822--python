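"""Seeded synthetic worlds for end-to-end testing without any download.

A world is a corpus of concept-annotated articles plus a list of
gene–trait queries with gold association labels. Each query owns a pool
of candidate articles mixing *reliable* articles — whose concept sequence
carries a query-specific signal concept correlated with the gold label —
and *less favorable* articles whose signal occurrence is label-
independent noise. Retrieval order can be biased so reliable articles
tend to appear at early ranks, emulating a search engine that surfaces
curated evidence first.

The planted signal is a single concept token, which keeps the
Bayes-optimal triage behaviour analytically known: in the
"first-article-suffices" preset (deterministic signal, strong rank bias)
the optimal policy is to read the first article, decide from its verdict,
and stop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import Article, ConceptToken, QueryCase

__all__ = [
    "WorldConfig",
    "generate_world",
    "world_summary",
    "article_labels",
    "default_world_config",
    "separable_world_config",
    "first_article_world_config",
]

_SIGNAL_CATEGORY = 91


@dataclass(frozen=True)
class WorldConfig:
    """Generator settings; probabilities are per-article.

    ``p_signal_given_reliable_assoc`` is the probability that a reliable
    article's signal occurrence reflects the gold label (signal present for
    associated queries, absent for non-associated); with the complementary
    probability the occurrence is flipped. Unreliable articles carry the
    signal with label-independent probability ``p_signal_given_unreliable``.
    ``rank_bias`` ≥ 0 pushes reliable articles toward early retrieval
    ranks (0 = unbiased, large = reliable-first).
    """

    n_queries: int = 100
    pool_size_range: tuple[int, int] = (3, 8)
    reliable_fraction: float = 0.7
    p_signal_given_reliable_assoc: float = 0.95
    p_signal_given_unreliable: float = 0.5
    vocab_size: int = 150
    article_length_range: tuple[int, int] = (10, 30)
    rank_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reliable_fraction", "p_signal_given_reliable_assoc", "p_signal_given_unreliable"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.reliable_fraction <= 1.0):
            raise ValueError("reliable_fraction must be in (0, 1]")
        for name in ("pool_size_range", "article_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name}=({lo}, {hi}) is not a valid interval")
        if self.rank_bias < 0:
            raise ValueError("rank_bias must be >= 0")
        if self.n_queries < 0 or self.vocab_size < 1:
            raise ValueError("n_queries must be >= 0 and vocab_size >= 1")


def default_world_config(seed: int = 0, **overrides) -> WorldConfig:
    """The default study conditions: 70% reliable pools, 0.95 signal fidelity."""
    return replace(WorldConfig(seed=seed), **overrides)


def separable_world_config(seed: int = 0, **overrides) -> WorldConfig:
    """Fully reliable, deterministic signal: signal concept ⇔ gold label."""
    cfg = WorldConfig(
        reliable_fraction=1.0,
        p_signal_given_reliable_assoc=1.0,
        pool_size_range=(3, 5),
        vocab_size=100,
        seed=seed,
    )
    return replace(cfg, **overrides)


def first_article_world_config(seed: int = 0, **overrides) -> WorldConfig:
    """Reliable-first retrieval with deterministic signal.

    The first-ranked article is almost surely reliable and its verdict
    determines the label, so the Bayes-optimal policy reads exactly one
    article, decides, and stops.
    """
    cfg = WorldConfig(
        reliable_fraction=0.95,
        p_signal_given_reliable_assoc=1.0,
        rank_bias=1e9,
        pool_size_range=(3, 6),
        seed=seed,
    )
    return replace(cfg, **overrides)


def _background_weights(vocab_size: int) -> np.ndarray:
    w = 1.0 / np.arange(1, vocab_size + 1)
    return w / w.sum()


def generate_world(config: WorldConfig) -> tuple[list[Article], list[QueryCase]]:
    """Generate (corpus, queries), fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    weights = _background_weights(config.vocab_size)
    # each background concept keeps one fixed semantic category (as in a real
    # metathesaurus); categories avoid the signal slot so the category channel
    # identifies signal concepts across queries
    bg_categories = rng.integers(0, 132, size=config.vocab_size)
    bg_categories = np.where(bg_categories >= _SIGNAL_CATEGORY, bg_categories + 1, bg_categories)
    articles: list[Article] = []
    queries: list[QueryCase] = []
    counter = 0
    for qi in range(config.n_queries):
        gene = f"GENE{qi}"
        trait = f"trait{qi}"
        gold = bool(rng.random() < 0.5)
        signal_concept = f"SIG{qi:04d}"
        pool_size = int(rng.integers(config.pool_size_range[0], config.pool_size_range[1] + 1))

        pool: list[Article] = []
        reliable_flags: list[bool] = []
        for _ in range(pool_size):
            reliable = bool(rng.random() < config.reliable_fraction)
            if reliable:
                faithful = rng.random() < config.p_signal_given_reliable_assoc
                has_signal = gold if faithful else not gold
            else:
                has_signal = rng.random() < config.p_signal_given_unreliable
            length = int(
                rng.integers(config.article_length_range[0], config.article_length_range[1] + 1)
            )
            background = rng.choice(config.vocab_size, size=length, p=weights)
            # Concept sequences carry the informative content only; the
            # queried gene/trait mentions live in the title/abstract text
            # (they are constant within a pool, so as concept tokens they
            # would only leak query identity into the classifier).
            concepts = [
                ConceptToken(
                    f"C{int(k):05d}",
                    category_index=int(bg_categories[int(k)]),
                    confidence=float(np.round(rng.uniform(0.5, 1.0), 3)),
                )
                for k in background
            ]
            if has_signal:
                # repeated mention, as in real abstracts: ~1 occurrence per
                # 10 background concepts keeps signal salience constant
                # across article lengths
                n_mentions = max(1, round(length / 10))
                for _ in range(n_mentions):
                    pos = int(rng.integers(0, len(concepts) + 1))
                    concepts.insert(
                        pos,
                        ConceptToken(
                            signal_concept, category_index=_SIGNAL_CATEGORY, confidence=0.9
                        ),
                    )
            article = Article(
                article_id=f"S{counter:06d}",
                title=f"Study of {gene} and {trait}",
                abstract=f"We investigated {gene} variants in {trait} cohorts.",
                year=int(rng.integers(1995, 2014)),
                concepts=concepts,
                reliable_label=reliable,
            )
            counter += 1
            pool.append(article)
            reliable_flags.append(reliable)

        keys = config.rank_bias * np.array(reliable_flags, dtype=float) + rng.gumbel(
            size=pool_size
        )
        order = np.argsort(-keys, kind="stable")
        ranked = [pool[i] for i in order]
        articles.extend(ranked)
        queries.append(
            QueryCase(
                gene=gene,
                trait=trait,
                gold_associated=gold,
                candidate_ids=[a.article_id for a in ranked],
            )
        )
    return articles, queries


def article_labels(
    articles: list[Article], queries: list[QueryCase]
) -> list[tuple[Article, bool]]:
    """Per-article classifier training pairs: (article, its query's gold label)."""
    index = {a.article_id: a for a in articles}
    pairs = []
    for q in queries:
        if q.gold_associated is None:
            continue
        pairs.extend((index[aid], q.gold_associated) for aid in q.candidate_ids)
    return pairs


def world_summary(world: tuple[list[Article], list[QueryCase]]) -> dict[str, float]:
    """Realised counts and fractions for a generated world."""
    articles, queries = world
    labeled = [q for q in queries if q.gold_associated is not None]
    pool_sizes = [len(q.candidate_ids) for q in queries]
    reliable = [a.reliable_label for a in articles if a.reliable_label is not None]
    return {
        "n_queries": len(queries),
        "n_articles": len(articles),
        "positive_label_fraction": (
            float(np.mean([q.gold_associated for q in labeled])) if labeled else 0.0
        ),
        "mean_pool_size": float(np.mean(pool_sizes)) if pool_sizes else 0.0,
        "reliable_fraction_realized": float(np.mean(reliable)) if reliable else 0.0,
    }
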