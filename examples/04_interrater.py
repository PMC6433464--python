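"""Inter-rater reliability from two scorings of the same trial.

Simulates one trial, derives a second "scorer" by randomly relabeling 10%
of scored seconds, and prints the confusion-matrix diagonal and percent
coherence (seconds on which the scorers agree, unscored-by-both seconds
excluded).
"""

import numpy as np

from ethoseq import Ethogram, coherence, interrater_confusion, simulate_ethogram
from ethoseq.catalogue import NONE_LABEL
from ethoseq.simulate import make_condition_presets

bank = make_condition_presets("female_intruder", True)
scorer1 = simulate_ethogram(bank.kernels["Fed"], 1200, seed=2, catalogue=bank.catalogue)

rng = np.random.default_rng(12)
labels = list(scorer1.labels)
pool = list(bank.catalogue.labels)
for i, label in enumerate(labels):
    if label != NONE_LABEL and rng.random() < 0.10:
        labels[i] = pool[rng.integers(len(pool))]
scorer2 = Ethogram(labels=tuple(labels), catalogue=bank.catalogue)

cm = interrater_confusion(scorer1, scorer2)
agree = int(np.trace(cm.counts.to_numpy()))
print(f"seconds scored identically: {agree} of {cm.total_seconds}")
print(f"coherence (NONE-NONE excluded): {coherence(cm):.1f}%")
print(
    "A 10% per-second relabeling noise still leaves coherence far above the\n"
    "~70% agreement regarded as acceptable for manual scoring."
)
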