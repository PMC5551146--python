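"""Classify compounds with the two-ellipse egg model and draw the plot.

A compound inside the large "white" ellipse in (tPSA, WLogP) space is
predicted to be well absorbed in the human intestine (Fa >= 0.30); inside
the smaller "yolk" it is additionally predicted to cross the blood-brain
barrier (LogBB >= 0).
"""

from boiledegg import classify_table, load_model, load_oxon_pairs, plot_egg

model = load_model()
table = load_oxon_pairs()
preds = classify_table(table, model)

print(preds[["id", "tpsa", "wlogp", "gi_label", "bbb_label"]].head(8).to_string(index=False))
n_gi = (preds["gi_label"] == "high").sum()
n_bbb = (preds["bbb_label"] == "yes").sum()
print(f"\n{n_gi}/{len(preds)} compounds GI-high, {n_bbb}/{len(preds)} brain-permeant "
      f"(model checksum {model.config_checksum})")

out = plot_egg(preds, model, "egg.svg")
print(f"egg plot written to {out}")
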