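"""Canned end-to-end experiments on synthetic corpora.

These functions bundle the study conditions under which the toolkit's
headline behaviors are demonstrated, so tests, scripts and users run the
exact same procedures:

* :func:`learnability` — a BiLSTM-CRF with in-domain skip-gram embeddings
  on a cleanly separable (unambiguous) corpus should essentially solve
  the task;
* :func:`encoder_comparison` — with few training sentences the BiLSTM
  tends to beat the Transformer encoder, whose capacity wants more data;
* :func:`transfer` — fine-tuning from a donor tagger trained on a larger
  related corpus beats training from scratch when the target corpus is
  small;
* :func:`determinism` — a fixed seed reproduces the training trajectory
  and every prediction bit-exactly.

Problem sizes are kept at desk scale (hundreds to a couple thousand
sentences, single CPU, minutes); each function takes a base seed that
drives corpus generation, pretraining and model training.
"""

from __future__ import annotations

import numpy as np

from .embeddings import train_skipgram
from .evaluation import evaluate_corpus
from .synth import SynthConfig, generate_corpus, make_related_corpus, split, \
    unlabeled_text
from .training import TrainConfig, fine_tune, train

__all__ = ["learnability", "encoder_comparison", "transfer", "determinism"]


def _eval_f1(model, test_corpus, scheme) -> float:
    pred = model.predict(test_corpus.sentences)
    return evaluate_corpus(test_corpus.sentences, pred, scheme).macro_f1


def learnability(seed: int = 11, n_sentences: int = 2000,
                 dim: int = 150, epochs: int = 30) -> dict:
    """BiLSTM-CRF + pretrained embeddings on an unambiguous corpus.

    Generates ``n_sentences`` with ambiguity 0, pretrains ``dim``-d
    skip-gram vectors on the training text, trains up to ``epochs`` and
    reports entity-level test Macro-F1 (percent).
    """
    cfg = SynthConfig(seed=seed, n_sentences=n_sentences, ambiguity_rate=0.0)
    corp = generate_corpus(cfg)
    tr, te = split(corp, 0.8, seed=seed)
    table = train_skipgram(unlabeled_text(tr), dim=dim, epochs=3, seed=seed)
    tc = TrainConfig(seed=seed, epochs=epochs, hidden=50)
    model, history = train(tr, table, tc, encoder_kind="bilstm",
                           scheme=cfg.scheme)
    return {"macro_f1": _eval_f1(model, te, cfg.scheme),
            "n_train": len(tr), "n_test": len(te),
            "epochs_run": len(history)}


def encoder_comparison(seed: int = 21, n_sentences: int = 500,
                       n_seeds: int = 3, epochs: int = 12) -> dict:
    """BiLSTM-CRF vs Transformer-CRF at small training scale.

    One corpus and one pretrained table; each encoder is trained with
    ``n_seeds`` different training seeds and the median test Macro-F1 per
    encoder is reported.
    """
    cfg = SynthConfig(seed=seed, n_sentences=n_sentences)
    corp = generate_corpus(cfg)
    tr, te = split(corp, 0.8, seed=seed)
    table = train_skipgram(unlabeled_text(tr), dim=96, epochs=3, seed=seed)
    out: dict = {"n_train": len(tr), "n_test": len(te)}
    for enc in ("bilstm", "transformer"):
        f1s = []
        for k in range(1, n_seeds + 1):
            tc = TrainConfig(seed=seed + k, epochs=epochs, hidden=48,
                             n_layers=2, n_heads=4)
            model, _ = train(tr, table, tc, encoder_kind=enc, scheme=cfg.scheme)
            f1s.append(_eval_f1(model, te, cfg.scheme))
        out[enc] = {"f1_per_seed": f1s, "median_f1": float(np.median(f1s))}
    return out


def transfer(seed: int = 31, n_target: int = 220, n_donor: int = 800,
             divergence: float = 0.5, n_seeds: int = 3,
             epochs: int = 15) -> dict:
    """Donor fine-tuning vs from-scratch training on a small target corpus.

    The donor tagger is trained once on a larger corpus from a related
    generator (``divergence`` fraction of its entity vocabulary is
    resampled).  For each seed the same small target training set is used
    both to fine-tune the donor (lr 1e-4) and to train from scratch
    (lr 1e-3); medians of test Macro-F1 are reported.
    """
    tgt_cfg = SynthConfig(seed=seed, n_sentences=n_target)
    tgt = generate_corpus(tgt_cfg)
    tgt_tr, tgt_te = split(tgt, 0.55, seed=seed)
    don_cfg = SynthConfig(seed=seed, n_sentences=n_donor)
    donor_corp = make_related_corpus(don_cfg, divergence=divergence)

    table = train_skipgram(unlabeled_text(donor_corp) + unlabeled_text(tgt_tr),
                           dim=96, epochs=3, seed=seed)
    donor_model, _ = train(donor_corp, table,
                           TrainConfig(seed=seed + 100, epochs=12, hidden=48),
                           scheme=don_cfg.scheme)
    scratch, tuned = [], []
    for k in range(1, n_seeds + 1):
        m_sc, _ = train(tgt_tr, table,
                        TrainConfig(seed=seed + k, epochs=epochs, hidden=48),
                        scheme=tgt_cfg.scheme)
        scratch.append(_eval_f1(m_sc, tgt_te, tgt_cfg.scheme))
        m_ft, _ = fine_tune(donor_model, tgt_tr,
                            TrainConfig(seed=seed + k, epochs=epochs,
                                        hidden=48, lr=1e-4))
        tuned.append(_eval_f1(m_ft, tgt_te, tgt_cfg.scheme))
    return {"n_target_train": len(tgt_tr), "n_donor": len(donor_corp),
            "scratch": {"f1_per_seed": scratch,
                        "median_f1": float(np.median(scratch))},
            "finetune": {"f1_per_seed": tuned,
                         "median_f1": float(np.median(tuned))}}


def determinism(seed: int = 41, n_sentences: int = 100,
                epochs: int = 3) -> dict:
    """Train the same configuration twice; compare bit-exactly."""
    cfg = SynthConfig(seed=seed, n_sentences=n_sentences)
    corp = generate_corpus(cfg)
    tr, te = split(corp, 0.8, seed=seed)
    table = train_skipgram(unlabeled_text(tr), dim=32, epochs=2, seed=seed)

    def run():
        tc = TrainConfig(seed=seed, epochs=epochs, hidden=16)
        model, history = train(tr, table, tc, scheme=cfg.scheme)
        pred = model.predict(te.sentences)
        return [h["train_loss"] for h in history], [p.tags for p in pred]

    losses1, pred1 = run()
    losses2, pred2 = run()
    return {"losses_identical": losses1 == losses2,
            "predictions_identical": pred1 == pred2,
            "n_epochs": len(losses1), "n_test": len(pred1)}
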