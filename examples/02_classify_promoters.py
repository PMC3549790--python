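"""Train the ten-class perceptron and classify held-out promoters.

Builds a balanced labeled training set (5 synthetic promoters per
class), trains the single-layer perceptron on their rasterized
patterns, then scores a held-out set.  Prints the training trajectory,
held-out macro recall, and one full classification with its match
percentages and transitional flag.
"""

import promkic as pk

train_pairs = pk.make_fixture_set(5, seed=101)
test_pairs = pk.make_fixture_set(5, seed=102)

rasterize = lambda s: pk.rasterize(pk.build_pattern(s), binarize=False)
r_train = [rasterize(s) for s, _ in train_pairs]
r_test = [rasterize(s) for s, _ in test_pairs]

model = pk.train(r_train, [lab for _, lab in train_pairs], seed=101)
print(f"trained on {len(r_train)} patterns in {model.epochs_run} epochs; "
      f"final training accuracy {model.training_log[-1]:.0f}%")

cm, recall, macro = pk.evaluate(model, r_test, [lab for _, lab in test_pairs])
print(f"held-out macro recall over 10 classes: {macro:.2f}")

seq, true_label = test_pairs[0]
res = pk.classify(model, r_test[0], sequence_id=seq.id)
print(f"\n{seq.id} (true class {true_label}):")
print(f"  best = {res.best}, runner-up = {res.runner_up}, "
      f"margin = {res.margin:.1f} points, transitional = {res.transitional}")
top3 = sorted(res.match_percentage.items(), key=lambda kv: -kv[1])[:3]
for lab, pct in top3:
    print(f"  match {lab}: {pct:.1f}%")
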