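"""The triage MDP: one episode per gene–trait query.

The agent walks a retrieval-ordered pool of candidate articles. At each
step it may *read* the current article (run the relation classifier on it;
at most once per article), *select* it as supporting evidence, *reject*
it, or *stop*. The per-query association prediction is a
confidence-weighted vote over the selected articles; classifier outputs
are available to the state and to the vote only for articles that have
been read — an unread selected article contributes an uninformative 0.5 —
so reading is how the agent buys information.

The reward per step is the change in per-query correctness of the running
aggregate prediction (1 if it matches the gold label, else 0) plus a
constant step penalty, so episode returns telescope to final correctness
minus 0.001 per step taken.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .agent import A_READ, A_REJECT, A_SELECT, A_STOP, DQNAgent, Transition
from .corpus_io import mentions_both
from .preprocess import Vocabulary, encode
from .types import Article, QueryCase

logger = logging.getLogger(__name__)

__all__ = [
    "Action",
    "EnvConfig",
    "Episode",
    "EpisodeResult",
    "ArticleScorer",
    "make_episode",
    "build_state",
    "reward",
    "aggregate_prediction",
    "step",
    "run_episode",
    "train_triage",
    "evaluate_triage",
]


class Action(enum.IntEnum):
    SELECT = 0
    REJECT = 1
    READ = 2
    STOP = 3


@dataclass
class EnvConfig:
    """Environment knobs.

    ``d_emb`` is the dimension the pooled article embedding is projected to
    inside the state vector (fixed seeded Gaussian projection, so the state
    is a deterministic function of the classifier). ``step_penalty``
    mirrors the agent's per-step cost. The step cap (``2·|pool| + 2``
    scaled by ``step_cap_factor``) bounds episode length: one read plus one
    decision per article, plus slack for an explicit stop.
    """

    d_emb: int = 16
    step_penalty: float = -0.001
    step_cap_factor: float = 1.0
    projection_seed: int = 777

    @property
    def state_dim(self) -> int:
        return self.d_emb + 8


_PROJECTION_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _projection(in_dim: int, out_dim: int, seed: int) -> np.ndarray:
    key = (in_dim, out_dim, seed)
    if key not in _PROJECTION_CACHE:
        rng = np.random.default_rng(seed)
        _PROJECTION_CACHE[key] = rng.normal(0.0, 1.0 / np.sqrt(in_dim), (in_dim, out_dim))
    return _PROJECTION_CACHE[key]


class ArticleScorer:
    """Classifier facade: encodes articles once and memoises outputs.

    The underlying model is deterministic, so per-article probability and
    embedding are cached by article_id for the lifetime of the scorer.
    """

    def __init__(self, model, vocab: Vocabulary, max_len: int | None = None):
        self.model = model
        self.vocab = vocab
        self.max_len = max_len or model.config.max_len
        self._cache: dict[str, tuple[float, np.ndarray]] = {}

    @property
    def embedding_dim(self) -> int:
        return self.model.embedding_dim

    def score(self, article: Article) -> tuple[float, np.ndarray]:
        if article.article_id not in self._cache:
            enc = encode(article.concepts, self.vocab, self.max_len)
            out = self.model.forward(enc)
            self._cache[article.article_id] = (out.p_association, out.embedding)
        return self._cache[article.article_id]


@dataclass
class Episode:
    """Mutable state of one query's triage walk."""

    query: QueryCase
    pool: list[Article]
    cursor: int = 0
    selected_ids: list[str] = field(default_factory=list)
    rejected_ids: list[str] = field(default_factory=list)
    read_info: dict[str, tuple[float, np.ndarray]] = field(default_factory=dict)
    step_count: int = 0
    articles_read: int = 0
    prev_accuracy: float = 0.0
    total_reward: float = 0.0
    selection_confidence: float = 0.0
    done: bool = False

    @property
    def current(self) -> Article | None:
        if self.done or self.cursor >= len(self.pool):
            return None
        return self.pool[self.cursor]

    @property
    def current_read(self) -> bool:
        cur = self.current
        return cur is not None and cur.article_id in self.read_info


@dataclass
class EpisodeResult:
    predicted_association: bool
    confidence: float
    articles_read: int
    selected_ids: list[str]
    total_reward: float
    steps: int
    pool_size: int


def make_episode(
    query: QueryCase, corpus: Mapping[str, Article] | Iterable[Article]
) -> Episode:
    """Build an episode from a query's candidate list.

    Candidates are resolved in retrieval order and must explicitly mention
    both the gene and the trait; an empty pool yields an episode that is
    already done (the prediction then abstains to negative).
    """
    index = corpus if isinstance(corpus, Mapping) else {a.article_id: a for a in corpus}
    pool = []
    for aid in query.candidate_ids:
        if aid not in index:
            raise KeyError(f"candidate article {aid!r} not found in corpus")
        article = index[aid]
        if mentions_both(article, query):
            pool.append(article)
    episode = Episode(query=query, pool=pool)
    if not pool:
        episode.done = True
    return episode


def aggregate_prediction(
    episode: Episode, classifier: ArticleScorer | None = None
) -> tuple[bool, float]:
    """Confidence-weighted vote over the selected articles.

    Each selected article contributes its classifier probability if it was
    read, else an uninformative 0.5; weights equal the probabilities, so
    the vote is Σp²/Σp. Predicts association iff the weighted mean exceeds
    0.5; with nothing selected the system abstains to (False, 0.0).
    ``classifier`` is accepted for interface symmetry but unused: only read
    articles carry informative probabilities by design.
    """
    if not episode.selected_ids:
        return False, 0.0
    ps = np.array(
        [episode.read_info.get(aid, (0.5, None))[0] for aid in episode.selected_ids]
    )
    total = float(ps.sum())
    mean = float((ps**2).sum() / total) if total > 0 else 0.0
    return mean > 0.5, mean


def _accuracy(episode: Episode) -> float:
    gold = episode.query.gold_associated
    if gold is None:
        return 0.0
    predicted, _ = aggregate_prediction(episode)
    return 1.0 if predicted == gold else 0.0


def reward(prev_accuracy: float, current_accuracy: float, step_penalty: float) -> float:
    """Accuracy delta plus the constant per-step penalty."""
    return (current_accuracy - prev_accuracy) + step_penalty


def build_state(
    episode: Episode, classifier: ArticleScorer, config: EnvConfig | None = None
) -> np.ndarray:
    """Assemble the continuous state vector.

    Layout: [p_association of current article if read else 0;
    has-read indicator for the current article (distinguishes "unread"
    from "read with a negative verdict");
    projected current-article embedding (d_emb, zeros if unread);
    selection-confidence margin from the previous decision;
    fraction of pool consumed; selected and rejected counts (normalised by
    pool size); running aggregate confidence; agreement flag between the
    current article's verdict and the aggregate].
    """
    config = config or EnvConfig()
    n = max(len(episode.pool), 1)
    p_cur = 0.0
    has_read = 0.0
    emb_proj = np.zeros(config.d_emb)
    agreement = 0.0
    _, agg_conf = aggregate_prediction(episode)
    cur = episode.current
    if cur is not None and cur.article_id in episode.read_info:
        has_read = 1.0
        p_cur, emb = episode.read_info[cur.article_id]
        proj = _projection(len(emb), config.d_emb, config.projection_seed)
        emb_proj = np.tanh(emb @ proj)
        agg_pred, _ = aggregate_prediction(episode)
        agreement = 1.0 if (p_cur > 0.5) == agg_pred else 0.0
    state = np.concatenate(
        [
            [p_cur, has_read],
            emb_proj,
            [
                episode.selection_confidence,
                episode.cursor / n,
                len(episode.selected_ids) / n,
                len(episode.rejected_ids) / n,
                agg_conf,
                agreement,
            ],
        ]
    )
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite entries in state vector")
    return state


def step(
    episode: Episode,
    action: Action,
    classifier: ArticleScorer,
    config: EnvConfig | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Apply one atomic action; returns (next state, reward, done).

    Reading runs the classifier on the current article (once per article);
    select/reject record the decision and advance the cursor; stop — or
    pool exhaustion, or the episode step cap — terminates the episode.
    The reward is the change in aggregate-prediction correctness plus the
    step penalty.
    """
    config = config or EnvConfig()
    if episode.done:
        raise RuntimeError("cannot step a finished episode")
    if action == Action.READ:
        cur = episode.current
        if cur is None:
            raise RuntimeError("no current article to read")
        if cur.article_id in episode.read_info:
            raise RuntimeError(f"article {cur.article_id} already read")
        episode.read_info[cur.article_id] = classifier.score(cur)
        episode.articles_read += 1
    elif action == Action.SELECT:
        cur = episode.current
        if cur is None:
            raise RuntimeError("no current article to select")
        episode.selected_ids.append(cur.article_id)
        episode.cursor += 1
    elif action == Action.REJECT:
        cur = episode.current
        if cur is None:
            raise RuntimeError("no current article to reject")
        episode.rejected_ids.append(cur.article_id)
        episode.cursor += 1
    elif action == Action.STOP:
        episode.done = True
    else:  # pragma: no cover
        raise ValueError(f"unknown action {action}")

    episode.step_count += 1
    if episode.cursor >= len(episode.pool):
        episode.done = True
    if episode.step_count >= config.step_cap_factor * (2 * len(episode.pool) + 2):
        episode.done = True

    acc = _accuracy(episode)
    r = reward(episode.prev_accuracy, acc, config.step_penalty)
    episode.prev_accuracy = acc
    episode.total_reward += r
    return build_state(episode, classifier, config), r, episode.done


_A_TO_ACTION = {
    A_SELECT: Action.SELECT,
    A_REJECT: Action.REJECT,
    A_READ: Action.READ,
    A_STOP: Action.STOP,
}


def legal_actions(episode: Episode) -> list[int]:
    """Agent actions legal at the current cursor position.

    Select/reject are always available while an article is in view, read
    at most once per article; stop is always legal.
    """
    legal = [A_SELECT, A_REJECT]
    if not episode.current_read:
        legal.append(A_READ)
    legal.append(A_STOP)
    return legal


def run_episode(
    agent: DQNAgent,
    episode: Episode,
    classifier: ArticleScorer,
    epsilon: float,
    rng: np.random.Generator,
    config: EnvConfig | None = None,
) -> tuple[EpisodeResult, list[Transition]]:
    """Roll one episode under the agent's ε-greedy policy.

    One atomic action per agent step, as in the episode loop: the agent is
    asked for an action, the environment applies it, and the resulting
    transition (with the next state's legal-action set, for the masked
    Bellman bootstrap) is recorded for replay.
    """
    config = config or EnvConfig()
    transitions: list[Transition] = []
    while not episode.done:
        s = build_state(episode, classifier, config)
        a, margin = agent.act(s, legal_actions(episode), epsilon, rng)
        episode.selection_confidence = margin
        s_next, r, done = step(episode, _A_TO_ACTION[a], classifier, config)
        next_legal = () if done else tuple(legal_actions(episode))
        transitions.append(Transition(s, a, r, s_next, done, next_legal=next_legal))
    predicted, confidence = aggregate_prediction(episode)
    result = EpisodeResult(
        predicted_association=predicted,
        confidence=confidence,
        articles_read=episode.articles_read,
        selected_ids=list(episode.selected_ids),
        total_reward=episode.total_reward,
        steps=episode.step_count,
        pool_size=len(episode.pool),
    )
    return result, transitions


@dataclass
class TrainLogEntry:
    epoch: int
    transitions: int
    mean_reward: float
    mean_loss: float
    epsilon: float


def train_triage(
    agent: DQNAgent,
    classifier: ArticleScorer,
    queries: Sequence[QueryCase],
    corpus: Mapping[str, Article] | Iterable[Article],
    *,
    epochs: int = 10,
    steps_per_epoch: int = 10_000,
    seed: int = 0,
    env_config: EnvConfig | None = None,
) -> tuple[DQNAgent, list[TrainLogEntry]]:
    """Train the triage agent over the query list.

    Each epoch shuffles the queries (seeded), rolls episodes under the
    annealing ε schedule, pushes every transition to replay, takes one
    gradient step per transition, and syncs the target network on the
    configured schedule, up to ``steps_per_epoch`` transitions per epoch.
    """
    if not queries:
        raise ValueError("query list is empty")
    env_config = env_config or EnvConfig()
    index = corpus if isinstance(corpus, Mapping) else {a.article_id: a for a in corpus}
    rng = np.random.default_rng(seed)
    curves: list[TrainLogEntry] = []
    for epoch in range(epochs):
        order = rng.permutation(len(queries))
        epoch_rewards: list[float] = []
        epoch_losses: list[float] = []
        epoch_steps = 0
        for qi in order:
            if epoch_steps >= steps_per_epoch:
                break
            episode = make_episode(queries[qi], index)
            if episode.done:
                continue
            eps = agent.epsilon()
            result, transitions = run_episode(agent, episode, classifier, eps, rng, env_config)
            for tr in transitions:
                loss = agent.observe(tr, rng)
                if loss is not None:
                    epoch_losses.append(loss)
                epoch_steps += 1
            epoch_rewards.append(result.total_reward)
        entry = TrainLogEntry(
            epoch=epoch,
            transitions=epoch_steps,
            mean_reward=float(np.mean(epoch_rewards)) if epoch_rewards else 0.0,
            mean_loss=float(np.mean(epoch_losses)) if epoch_losses else 0.0,
            epsilon=agent.epsilon(),
        )
        curves.append(entry)
        logger.info(
            "epoch %d: %d transitions, mean reward %.4f, mean loss %.5f, eps %.3f",
            entry.epoch, entry.transitions, entry.mean_reward, entry.mean_loss, entry.epsilon,
        )
    return agent, curves


def evaluate_triage(
    agent: DQNAgent,
    classifier: ArticleScorer,
    queries: Sequence[QueryCase],
    corpus: Mapping[str, Article] | Iterable[Article],
    env_config: EnvConfig | None = None,
) -> dict[str, float]:
    """Evaluate the greedy policy (ε = 0) over a query list.

    Returns precision/recall/F1 of the per-query association predictions
    plus mean articles read per query and mean pool size.
    """
    from .classifier import precision_recall_f1

    env_config = env_config or EnvConfig()
    index = corpus if isinstance(corpus, Mapping) else {a.article_id: a for a in corpus}
    rng = np.random.default_rng(0)  # unused at epsilon=0; kept for interface symmetry
    preds: list[bool] = []
    golds: list[bool] = []
    reads: list[int] = []
    pools: list[int] = []
    for query in queries:
        episode = make_episode(query, index)
        result, _ = run_episode(agent, episode, classifier, 0.0, rng, env_config)
        if query.gold_associated is not None:
            preds.append(result.predicted_association)
            golds.append(query.gold_associated)
        reads.append(result.articles_read)
        pools.append(result.pool_size)
    precision, recall, f1 = precision_recall_f1(preds, golds) if golds else (0.0, 0.0, 0.0)
    accuracy = float(np.mean(np.array(preds) == np.array(golds))) if golds else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": accuracy,
        "mean_articles_read": float(np.mean(reads)) if reads else 0.0,
        "mean_pool_size": float(np.mean(pools)) if pools else 0.0,
        "n_queries": float(len(queries)),
    }
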