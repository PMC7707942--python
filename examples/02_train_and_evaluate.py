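"""Pretrain embeddings, train a BiLSTM-CRF tagger, report entity-level F1.

Runs the first pretraining mode end to end at small scale: skip-gram
character vectors from the (unlabeled) training text initialize the
tagger's embedding layer, the tagger is trained with the CRF loss, and
the held-out test split is scored with exact-span P/R/F1 per class plus
macro and support-weighted averages.  Takes a couple of minutes on one
CPU.
"""

from emrner import (SynthConfig, TrainConfig, evaluate_corpus,
                    generate_corpus, split, train, train_skipgram,
                    unlabeled_text)

corpus = generate_corpus(SynthConfig(seed=3, n_sentences=600))
train_set, test_set = split(corpus, 0.8, seed=3)

table = train_skipgram(unlabeled_text(train_set), dim=96, epochs=3, seed=3)
print(f"pretrained {len(table)} x {table.dim} character vectors")

config = TrainConfig(seed=3, epochs=15, hidden=48)
model, history = train(train_set, table, config, encoder_kind="bilstm",
                       scheme=corpus.config.scheme)
for h in history[::3]:
    print(f"epoch {h['epoch']:2d}  loss {h['train_loss']:7.3f}  "
          f"dev macro-F1 {h['dev_macro_f1']:6.2f}")

report = evaluate_corpus(test_set.sentences, model.predict(test_set.sentences),
                         corpus.config.scheme)
print("\ntest-set report (exact span match, percent):")
print(report.to_table())

# The macro row averages the four classes equally; the weighted row
# weights them by gold entity count.  Frequent classes (symptom,
# operation) are usually learned best, so the weighted average tends to
# sit above the macro one.
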