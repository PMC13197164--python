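"""Model predictions: involuntary visuomotor feedback responses (VFRs).

Solves the two-player reaching game under each of the four policy
hypotheses, simulates noise-free force-channel probe trials for all four
target-relevance conditions, and prints the mean applied lateral force
difference over the involuntary epoch (180-230 ms after the cursor jump
is displayed).

Reading the table: each row is a hypothesis about how a player's control
policy treats the partner.  A pr/si value above the pi/si value means the
model pushes against the channel to help a partner whose target is narrow
even though its own target is wide — only joint-cost policies do that.
A pi/sr value above pr/sr means the model works less hard when it expects
a relevant-target partner to share the correction — only the weighted
joint cost does that.
"""

from dyadreach import CONDITION_LABELS, HYPOTHESES, model_predictions

header = f"{'hypothesis':<14}" + "".join(f"{c:>9}" for c in CONDITION_LABELS)
print(header)
print("-" * len(header))
for hyp in HYPOTHESES:
    preds = model_predictions(hyp, noise=False)
    row = "".join(f"{preds[c]:>9.3f}" for c in CONDITION_LABELS)
    print(f"{hyp:<14}{row}")
print("\nvalues: involuntary-epoch VFR in N (left-minus-right probe force)")
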