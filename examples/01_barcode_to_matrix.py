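"""From a per-second barcode to a normalized transition matrix.

Builds a tiny hand-written ethogram, segments it into bouts, projects the
time-agnostic label sequence, and prints the row-conditional transition
matrix.  Each printed row is the probability distribution over which
behavior follows the row's behavior.
"""

from ethoseq import (
    catalogue_preset,
    count_transitions,
    extract_label_sequence,
    normalize_transitions,
    parse_ethogram,
    segment_bouts,
)

cat = catalogue_preset("resident_vs_female")

# Ten seconds of scoring: two eating bouts separated by an unscored gap,
# then grooming, then eating again.
barcode = """\
0\teating
1\teating
3\teating
4\tgrooming
5\tgrooming
7\teating
8\teating
"""
etho = parse_ethogram(barcode, cat, duration_s=10)
bouts = segment_bouts(etho)
seq = extract_label_sequence(bouts)
print("bout sequence:", " -> ".join(seq))

matrix = normalize_transitions(count_transitions(seq, cat.labels), "conditional")
print(matrix.to_frame().round(2).loc[["eating", "grooming"], ["eating", "grooming"]])
print(
    "The eating row splits 0.5/0.5: after an eating bout the animal was as\n"
    "likely to eat again (across a gap) as to switch to grooming."
)
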