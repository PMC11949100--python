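"""Train the attention segmentation network at smoke scale.

Renders flat-shaded phantom images and runs the full smoke protocol —
20 training phantoms at 128x128, 30 epochs — for the CSAM-gated hybrid
CNN/transformer encoder-decoder, then reports held-out per-class Dice.
Takes a few minutes on one CPU.
"""

from pterygrade.metrics import per_class_metrics
from pterygrade.nn import (
    build_model,
    make_smoke_dataset,
    predict,
    smoke_config,
    train_smoke,
)

data = make_smoke_dataset(24, size=128, seed=3)
train, held = data[:20], data[20:]
model = build_model(smoke_config(128), seed=3)
print(f"model parameters: {model.n_parameters():,}")

history, model = train_smoke(model, train, epochs=30, seed=3)
print("epoch losses:", " ".join(f"{h:.3f}" for h in history))

names = {1: "pterygium", 2: "pupil", 3: "cornea"}
for img, mask in held:
    pred = predict(model, img)
    dice = {names[c]: round(per_class_metrics(pred, mask, c).dice, 3)
            for c in names}
    print("held-out Dice:", dice)
# The loss falls steadily; the small classes (pupil, then pterygium)
# are the last to be carved out of the background, and held-out mean
# foreground Dice ends well above 0.9.
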