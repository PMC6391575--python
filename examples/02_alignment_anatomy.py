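"""Inspect how the aligner decomposes a mention into M / I / D sets.

The matcher aligns a token window against a slot-sequence principle by
dynamic programming: matched slots add their corpus-derived score, every
inserted token and deleted slot subtracts a penalty.  This script prints
the decomposition for three classic surface forms, under statistics in
which every slot is mention-exclusive (matched slots are worth exactly
100, penalties are 0).
"""

from mirslot import SlotStatistics, align, default_scheme
from mirslot.text import label_sentence

scheme = default_scheme()
stats = SlotStatistics(
    slot_counts={s: [10.0, 0.0] for s in
                 ["Species", "Precursor", "miRNA", "Order", "Conj", "Suffix", "Hairpin"]},
    nonslot_counts={"-": [10.0, 0.0], ",": [10.0, 0.0]},
)

cases = [
    ("miR-16-2", ("Species", "miRNA", "Order", "Order")),
    ("pre-miR-149", ("Precursor", "miRNA", "Order", "Order")),
    ("miR-21, 221, 128a, 128b, 128c, 181a, 181b, 181c",
     ("Precursor", "Species", "miRNA", "Order", "Conj", "Order", "Suffix")),
]

for text, principle in cases:
    window = label_sentence(text, scheme)
    r = align(window, principle, stats)
    print(f"{text!r}  vs  {''.join(f'[{s}]' for s in principle)}")
    print("  matched :", [(window.tokens[i].text, r.slot_sequence[j]) for i, j in r.M])
    print("  inserted:", [window.tokens[i].text for i in r.I])
    print("  deleted :", r.deleted_slots)
    print(f"  score   : {r.score:.1f}\n")
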