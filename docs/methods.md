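# Methods

`genetriage` builds a gene–trait association knowledge base by simulating
the way a researcher works through search results: retrieve candidate
abstracts for a (gene, trait) query, decide which are worth reading,
classify the ones read, and stop when the evidence is sufficient. This
note documents the models, the design choices made where the design was
genuinely open, and what the bundled synthetic benchmarks do and do not
show.

## The decision process

Each query is one episode of a Markov decision process over a
retrieval-ranked pool of candidate articles. At every step the agent
holds a cursor on the current article and chooses one action:

- **read** — run the relation classifier on the current article (at most
  once per article);
- **select** — keep the article as supporting evidence and advance;
- **reject** — discard it and advance;
- **stop** — end the episode (pool exhaustion and a step cap of
  `2·|pool| + 2` also terminate it).

The per-query verdict is a confidence-weighted vote over the selected
articles: each contributes its classifier probability `p` with weight
`p`, so the aggregate is `Σp² / Σp`, and the query is called associated
when that exceeds 0.5. With nothing selected the system abstains, which
counts as a negative call.

**Reading is how the agent buys information.** Classifier outputs enter
the state vector, and the vote, only for articles the agent has read; an
unread selected article contributes an uninformative 0.5. Without this
rule "read" would be strictly dominated — the classifier is deterministic,
so its verdict could be harvested for free at selection time — and no
cost-aware reading policy could exist.

### Reward

The reward of every atomic step is the change in binary correctness of
the running aggregate verdict (1 if it currently matches the gold label,
else 0) plus a constant step penalty of −0.001. Episode returns therefore
telescope to final correctness minus 0.001 per step taken: accuracy pays
once, and every wasted action costs exactly one penalty. The penalty is
deliberately small; the margins that separate a prompt stop from a
dawdling one are fractions of 10⁻³ in Q-value, which drives several
training choices below.

### State

The state is a small continuous vector: the current article's classifier
probability and a has-read indicator (so "unread" and "read, negative
verdict" are distinguishable), the article embedding projected to
`d_emb` dimensions (fixed seeded Gaussian projection, `tanh`-squashed;
default 16, 4 in the desk-scale experiments), the softmax margin of the
previous action choice, the fraction of the pool consumed, normalised
selected/rejected counts, the aggregate confidence, and an agreement flag
between the current article's verdict and the aggregate. The composition
is a documented design choice; nothing in it peeks at gold labels.

## The relation classifier

A two-layer bidirectional LSTM over encoded concept sequences. Abstracts
are annotated into UMLS-style concept tokens (concept id, one of 136
semantic-category slots — 133 named categories plus unknown and two
reserved — an annotator confidence normalised to [0, 1], and gene/disease
ontology bits). Sequences are encoded as `SOS + content + EOS`, truncated
at the head (abstracts front-load their findings) and padded to exactly
300 positions (40 in the desk-scale runs). Each position feeds the
concatenation of a learned embedding (512 dims at full scale), the
136-slot category one-hot, and the two ontology bits; confidence is
carried in the data model but not fed to the network unless
`use_confidence` is set. The classification representation is the
concatenation of the final forward and backward top-layer hidden states
(mean pooling over positions is available by configuration), followed by
a two-class softmax. Training is Adam on cross-entropy, jointly with the
embedding matrix; the default step size is 4·10⁻⁵ with batch 64, and the
desk-scale experiments use 10⁻² with batch 32.

Everything — the LSTM, backpropagation through time with length masking,
Adam — is implemented in NumPy in float64, which keeps training bitwise
reproducible under a fixed seed; the backward pass is validated against
finite differences in the test suite. Padding positions are masked out of
the recurrence, so the "final" state is each sequence's true final state
and padding cannot leak signal.

Two deliberately small numerical choices matter. Embeddings are
initialised at scale 0.01 so concepts never seen in training stay near
the zero vector and prediction falls back on the semantic-category
channel, which generalises across queries. And the vocabulary keeps only
the most frequent concepts (30,000 at full scale, 100–150 at desk scale,
matching the full corpus's roughly two records per concept type); rarer
concepts map to UNK while keeping their category and flags. Both
decisions trade memorisation capacity for the category-level rule, which
is what transfers to unseen queries.

A maximum-entropy baseline extractor (logistic regression on
bag-of-concept counts, via scikit-learn) sits behind the same interface
for comparison.

## The triage agent

A deep Q-network: two hidden ReLU layers of 20 units and two separate
linear output heads, one scoring {select, reject, read} and one scoring
the stop decision. The agent issues **one atomic action per step**,
chosen ε-greedily over the concatenation of both heads restricted to the
legal actions (read is illegal once the current article has been read;
the continuation head's no-op slot is never selected or trained — not
stopping simply defers to the decision head). An earlier design applied
a decision-head action and a continuation-head action jointly in one
step with a shared summed reward; it was abandoned because it entangles
the stop value with whichever decision exploration happened to pair it
with, producing Q-gaps two orders of magnitude larger than the true
stopping margins and an agent that systematically stopped one step late.

Training is textbook Q-learning: squared Bellman error against a frozen
target network (`r + γ·max Q_target(s′)` over the next state's legal
actions, no bootstrap at terminals), plain SGD, uniform experience
replay in a bounded FIFO, linear ε anneal, and periodic bit-exact target
synchronisation. Defaults are γ = 0.8, learning rate 2.5·10⁻⁵, replay
500k, ε from 1.0 to 0.1 over 500k transitions, sync every 5k steps.
Double-Q, duelling and prioritised replay are deliberately absent.

### Desk-scale training protocol

The bundled experiments (see `genetriage.experiments`) shrink widths, not
structure: classifier 32/64, state projection `d_emb` = 4, replay and
anneal windows of 4k (the full-scale ratio of buffer to anneal length,
scaled to the run), batch 128. The agent trains in phases of decreasing
learning rate and exploration floor (10⁻² down to 10⁻⁴, ε floor 0.1 down
to 0.01, target sync 100 then 50 steps). The late low-noise phases are
not cosmetic: the orderings that control reading cost differ by less
than the 10⁻³ step penalty, and the network only resolves them once
gradient noise drops below that scale. A bounded sliding-window replay
matters for the same reason — retaining the entire high-ε history keeps
re-fitting stale behaviour and blurs those margins. Problem sizes
(100–200 training queries, pools of 3–8, worlds of 100–150 concepts)
were chosen so a full experiment runs in minutes on one CPU.

## Synthetic worlds

The generator emulates the joined structure of a curated association
database and a search-engine crawl: per-query candidate pools mixing
*reliable* articles, whose concept sequences carry a query-specific
signal concept correlated with the gold label, and *less favorable*
articles whose signal occurrence is label-independent noise. Gold labels
are balanced 50/50. Specifics worth knowing:

- **Signal.** One signal concept id per query, all sharing a dedicated
  semantic category; the category channel is what lets the classifier
  generalise to unseen queries. A reliable article reflects its query's
  label with probability `p_signal_given_reliable_assoc` (default 0.95);
  unreliable articles carry the signal with probability 0.5 regardless of
  the label. Signal concepts are mentioned about once per ten background
  concepts, as associations are in real abstracts, keeping salience
  constant across article lengths.
- **Background.** Concept ids drawn from a Zipf-weighted vocabulary
  (default 150 types); each background concept keeps one fixed semantic
  category per world, as concepts do in a real metathesaurus. Queried
  gene/trait mentions live in the title and abstract text (so the
  explicit-mention corpus filter passes) but not in the concept
  sequence, where they would only leak query identity.
- **Ranking.** Retrieval order is sampled with a Gumbel perturbation on
  `rank_bias · reliable`, so reliable articles drift toward early ranks;
  the default bias of 1.0 is mild, the "first-article-suffices" preset
  (`rank_bias = 10⁹`, deterministic signal, 95% reliable) makes the
  Bayes-optimal policy "read the first article, decide, stop".

What passing these benchmarks shows — and does not. The worlds are
constructed so the optimal behaviour is analytically known, which is what
makes the tests sharp; real literature has no planted single-concept
signal, annotation noise is not i.i.d., labels are not balanced, and
retrieval pools are far larger. Results on the synthetic worlds validate
the machinery (the classifier recovers a recoverable rule; the agent
converges to the cost-optimal reading policy; triage matches exhaustive
reading under contamination while reading a fraction of each pool), not
any clinical claim about specific gene–trait associations.

## Corpus construction and I/O

Corpora are line-delimited JSON (one article per line), query lists are
TSV. The corpus filters mirror how a curated gold standard is joined
against crawl results: articles must explicitly mention both the queried
gene and trait (case-insensitive substring by default, word-boundary
matching by flag), a year cutoff is exclusive (`year < cutoff`, matching
"published before"), and train/test splits are seeded shuffles with
half-up rounding on the train size. Live retrieval is an optional
E-utilities adapter (esearch/efetch XML over an injectable transport);
tests exercise it only against canned payloads. A parser for MetaMap's
machine-readable (MMI) output is provided — scores are normalised from
the 0–1000 scale, concepts ordered by text offset — but the annotator
interface is pluggable and all bundled data uses the dictionary mock.

## Knowledge base

One row per (gene, trait): verdict, aggregate confidence, supporting
article ids, number of articles read, timestamp. Upserts keep prior
versions in a history; exports (TSV/JSON) are sorted by (gene, trait) and
round-trip losslessly. The extraction pipeline stamps records with a
fixed configurable timestamp so runs are byte-reproducible.

## Known limitations

- The reward's accuracy term requires gold labels, so agent training is
  supervised at the query level; extraction over unlabelled queries runs
  the greedy policy with penalties only.
- Stop-promptness margins are bounded by the step penalty; at realistic
  noise levels the trained agent reads slightly more than the
  theoretical minimum (the benchmarks bound, not eliminate, this gap).
- Query reformulation ("query again" with a new query string) is modelled
  as rejection within the same pool; issuing new query strings is out of
  scope.
- The MetaMap category→slot mapping ships with a small default table;
  full mappings are annotator configuration.
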