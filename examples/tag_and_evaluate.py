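"""Train the ADR/indication tagger and evaluate it on held-out posts.

Trains skip-gram embeddings and the window feed-forward tagger on labeled
sentences from a generated corpus, then reports strict and overlap
micro-averaged precision/recall/F on a fresh same-template corpus.
"""

from adrsignal.embeddings import train_embeddings
from adrsignal.ner import evaluate_ner, tag_post, train_tagger
from adrsignal.synth import default_config, generate_corpus

train_bundle = generate_corpus(default_config(n_users=600, seed=13))
labeled = train_bundle.labeled_sentences()
print(f"training data: {len(labeled)} sentences, "
      f"{len(train_bundle.gold_spans)} gold spans")

embeddings = train_embeddings([s for s, _ in labeled], dim=50, seed=13, epochs=2)
model = train_tagger(labeled[:500], embeddings, seed=13, epochs=20, hidden=100)
print(f"epoch loss: {model.epoch_losses[0]:.4f} -> {model.epoch_losses[-1]:.4f}")

held_out = generate_corpus(default_config(n_users=150, seed=14))
predicted = [s for p in held_out.posts for s in tag_post(model, p)]
for mode in ("strict", "overlap"):
    m = evaluate_ner(predicted, held_out.gold_spans, mode=mode)
    print(f"{mode:8s} P={m.precision:.3f} R={m.recall:.3f} F={m.f_measure:.3f}")
print("-> strict requires exact offsets and label; overlap credits partial")
print("   spans; micro-averaging pools TP/FP/FN over all posts first.")
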