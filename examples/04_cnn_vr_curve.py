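"""Train the snapshot CNN briefly and trace its Validation-Rate curve.

Uses a reduced epoch count to stay quick; the curve shows VR as a function
of the controlled prediction count, the pipeline's analogue of a
precision-at-k sweep.
"""

from dresnap import (
    SyntheticConfig,
    balance_classes,
    filter_zero_signal,
    generate_dataset,
    make_split_set,
    vr_curve,
)
from dresnap.models import ModelConfig, build_model, predict_scores, train

config = SyntheticConfig(n_chroms=1, chrom_length=2_000_000, n_dre=220,
                         n_tss=180, seed=6)
examples, markers, _ = generate_dataset(config)
examples = balance_classes(filter_zero_signal(examples), seed=7)
splits = make_split_set(examples, seed=8)

mc = ModelConfig(kind="cnn", seed=9, epochs=15)
model = train(build_model(mc), splits.train_sets[0], mc)
test_pool = [e for ts in splits.test_sets for e in ts]
scores = predict_scores(model, test_pool)

curve = vr_curve(scores, markers, [10, 25, 50, 75, 100])
print(f"scored {len(test_pool)} held-out locations "
      f"(~{sum(e.label for e in test_pool)} true positives)")
for n, vr in zip(curve.n_predictions, curve.vr):
    print(f"  top {n:4d} predictions: VR = {vr:.3f}")
# VR stays high while n is below the number of true positives in the pool
# and declines once the controlled count forces negatives into the top set.
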