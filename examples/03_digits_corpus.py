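"""Generate the synthetic rotated-digits corpus and its train/val/test split.

Emulates a 10,000-image handwritten-digits collection (1000 per class,
each rotated by a random angle) with procedurally stroked glyphs; the split
follows the 90/10 protocol with 10% of the training pool for validation."""

import numpy as np

from vortexdiff import generate_corpus, split_dataset, upscale_to_object

corpus = generate_corpus(n_per_class=10, rotation_range=(-45, 45), seed=0)
hist = np.bincount([s.digit_class for s in corpus], minlength=10)
rots = np.array([s.rotation_deg for s in corpus])
print(f"{len(corpus)} glyphs, per-class counts {list(hist)}")
print(f"rotations in [{rots.min():.1f}, {rots.max():.1f}] deg")

sample = corpus[13]
print(f"\nSample {sample.sample_id}: digit {sample.digit_class}, "
      f"rotated {sample.rotation_deg:+.1f} deg, "
      f"28x28 uint8 in [{sample.image.min()}, {sample.image.max()}]")
up = upscale_to_object(sample, 512)
print(f"Upscaled phase-object image: {up.shape}, range [{up.min():.0f}, {up.max():.0f}]")

for row in sample.image[::2]:
    print("".join(" .:*#"[min(4, v // 52)] for v in row))

m = split_dataset(10_000, seed=0)
print(f"Split at n = 10,000: train {len(m.train_ids)}, "
      f"val {len(m.val_ids)}, test {len(m.test_ids)}")
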