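# genetriage

Curating gene–trait associations from the biomedical literature is slow
because the bottleneck is not classifying a given abstract — it is
deciding *which* of the hundreds of retrieved abstracts deserve reading
and trust, and when the evidence is sufficient to stop. `genetriage`
implements an "artificial researcher" for that workflow: for each
(gene, trait) query it walks the ranked retrieval pool, sequentially
decides to **read**, **select**, **reject**, or **stop**, and writes the
aggregated association verdict — with supporting article identifiers —
into a knowledge base.

It is aimed at text-mining and knowledge-base researchers who want a
complete, reproducible, dependency-light reference implementation of
reinforcement-learning document triage: every component, including the
recurrent relation classifier and the Q-network, is implemented in NumPy
and trainable end to end on bundled synthetic corpora with no downloads.

## The model

Each query is an episode of an MDP ⟨S, A, T, R⟩. The state `s` is a
continuous vector built from the relation classifier's outputs on the
current article (probability and pooled BiLSTM embedding, available only
after a *read*), the previous action's confidence margin, and pool
statistics. The reward is the change in correctness of the running
aggregate verdict plus a step penalty:

    r_t = [acc_t − acc_{t−1}] − 0.001,   acc_t = 1{vote_t = gold}

so episode returns telescope to final correctness minus 0.001 per step —
accuracy pays once, every extra action costs. The agent is a deep
Q-network (2 × 20 ReLU units, two output heads over {select, reject,
read} and {stop}) trained with experience replay, an ε-greedy policy
annealed linearly from 1.0 to 0.1, and a target network synced every 5k
steps toward the tabular backup

    Q(s, a) ← r + γ · max_{a′ legal} Q_target(s′, a′),   γ = 0.8.

The relation classifier is a 2-layer bidirectional LSTM over
concept-annotated abstracts (UMLS-style concept ids, 136-slot semantic
categories, gene/disease ontology bits), encoded as `SOS + concepts +
EOS` and padded to 300 positions. The per-query verdict is a
confidence-weighted vote over selected articles, `Σp²/Σp > 0.5`.

See `docs/methods.md` for the full model description, design decisions,
and what the synthetic benchmarks do and do not demonstrate.

## Worked example

Run the bundled pipeline on a synthetic world (a YAML config can shrink
every constant; paper-scale values are the defaults):

```bash
genetriage simulate        --config examples/desk.yaml --outdir run/
genetriage prepare         --config examples/desk.yaml --outdir run/
genetriage train-classifier --config examples/desk.yaml --outdir run/
genetriage train-agent     --config examples/desk.yaml --outdir run/
genetriage evaluate        --config examples/desk.yaml --outdir run/
genetriage extract         --config examples/desk.yaml --outdir run/
```

`evaluate` prints the held-out metrics of the greedy policy:

```json
{
  "accuracy": 0.7,
  "f1": 0.8,
  "mean_articles_read": 3.3,
  "mean_pool_size": 4.5,
  "n_queries": 10.0,
  "precision": 0.666667,
  "recall": 1.0
}
```

Read: on the ten held-out queries of this 50-query world the agent
called associations with F1 = 0.8 while reading on average 3.3 of the
4.5 retrieved articles per query — the point of triage is that the two
numbers move together. `extract` then writes `run/kb.tsv`, one
association per (gene, trait):

```
gene    trait    associated  confidence  supporting_ids              n_articles_read
GENE20  trait20  1           0.647776    S000096;S000095             2
GENE23  trait23  1           0.820736    S000110;S000112             2
GENE25  trait25  0           0.500000    S000119                     2
```

The same machinery is callable as a library:

```python
from genetriage.experiments import triage_vs_read_all
print(triage_vs_read_all(seed=0))
```

which trains classifier and agent on a contaminated world (30%
unreliable articles) and compares the greedy triage policy against a
baseline that reads and aggregates every candidate.

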